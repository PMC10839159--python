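"""Optional electroosmotic flow coupling (axisymmetric Stokes).

Solves creeping flow driven by the electric body force on the space charge,

    mu lap(u) - grad(p) - F (c_Na - c_Cl) grad(phi) = 0,   div(u) = 0,

with no-slip on glass and protein surfaces, symmetry on the axis and open
(do-nothing) reservoirs.  Discretised with P1-P1 elements plus
Brezzi-Pitkaranta pressure stabilisation; velocities feed back into the
Nernst-Planck fluxes as an extra advective term.  This coupling is an
opt-in refinement (``SolverOptions.include_stokes``): the headline currents
of the package are computed from the pure drift-diffusion PNP system.

Nondimensionalisation: velocities are scaled by the electroosmotic scale
``u0 = eps0 eps_w V_T^2 / (mu l0)`` (~0.5 m/s for water at 1 nm), pressure
by ``mu u0 / l0``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import FARADAY, VACUUM_PERMITTIVITY, Electrolyte

__all__ = ["solve_stokes", "advection_field", "VELOCITY_SCALE"]

L0 = 1e-9
_STAB = 0.05  # Brezzi-Pitkaranta stabilisation constant


def VELOCITY_SCALE(el: Electrolyte) -> float:
    """Electroosmotic velocity scale u0 in m/s."""
    return (
        VACUUM_PERMITTIVITY * el.eps_water * el.thermal_voltage**2
        / (el.viscosity * L0)
    )


def _force_coefficient(el: Electrolyte) -> float:
    """gamma = F c_bulk V_T l0 / (mu u0), the nondimensional force scale."""
    u0 = VELOCITY_SCALE(el)
    return FARADAY * el.c_bulk_si * el.thermal_voltage * L0 / (el.viscosity * u0)


def solve_stokes(system, psi: np.ndarray, c_na: np.ndarray, c_cl: np.ndarray):
    """Solve stabilised Stokes flow on the electrolyte subdomain.

    Returns nondimensional velocity (n, 2) and pressure (n,) arrays.
    ``system`` is the PNP ``_System`` (reused for mesh/masks/FEM data).
    """
    mesh = system.mesh
    fem = system.fem
    el = mesh.domain.electrolyte
    n = mesh.n_nodes
    mask = system.elec_mask
    idx = np.where(mask)[0]
    tri = fem.tri[idx]
    area = fem.area[idx]
    rbar = fem.rbar[idx]
    grad = fem.grad[idx]  # (ne,3,2)

    # viscous blocks: stiffness + lumped u_r / r^2 term
    S = fem.stiffness(np.ones(len(fem.area)), mask)
    m_r2 = np.zeros(n)
    w = area * rbar / 3.0
    for k in range(3):
        nodes = tri[:, k]
        r = np.maximum(mesh.points[nodes, 0], 0.05)
        np.add.at(m_r2, nodes, w / r**2)
    A_r = S + sp.diags(m_r2)
    A_z = S

    # B: continuity  int q (dur/dr + duz/dz) r + int q ur  dOmega
    rows, cols, vr_vals, vz_vals = [], [], [], []
    third = area * rbar / 3.0
    m_plain = area / 12.0
    for jq in range(3):
        for iu in range(3):
            rows.append(tri[:, jq])
            cols.append(tri[:, iu])
            extra = m_plain * (2.0 if iu == jq else 1.0)
            vr_vals.append(third * grad[:, iu, 0] + extra)
            vz_vals.append(third * grad[:, iu, 1])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    B_r = sp.coo_matrix((np.concatenate(vr_vals), (rows, cols)), shape=(n, n)).tocsr()
    B_z = sp.coo_matrix((np.concatenate(vz_vals), (rows, cols)), shape=(n, n)).tocsr()

    # pressure stabilisation  alpha sum_e h^2 int grad p . grad q r
    h2 = 2.0 * area  # ~ h_e^2
    coef = np.zeros(len(fem.area))
    coef[idx] = _STAB * h2
    S_p = fem.stiffness(coef, mask)

    # body force f = -gamma (c_na - c_cl) grad psi, P1-projected
    gamma = _force_coefficient(el)
    rho_e = c_na - c_cl
    f_r = np.zeros(n)
    f_z = np.zeros(n)
    ge_psi = np.einsum("eik,ei->ek", grad, psi[tri])  # (ne,2)
    rho_bar = rho_e[tri].mean(axis=1)
    fw = -gamma * rho_bar
    for k in range(3):
        np.add.at(f_r, tri[:, k], fw * ge_psi[:, 0] * w)
        np.add.at(f_z, tri[:, k], fw * ge_psi[:, 1] * w)

    # Dirichlet sets
    noslip = [mesh.nodes_of("glass_wall")]
    for tag in mesh.edges:
        if tag.startswith("protein_surface"):
            noslip.append(mesh.nodes_of(tag))
    noslip = np.unique(np.concatenate(noslip)) if noslip else np.empty(0, int)
    axis = mesh.nodes_of("axis")
    elec_nodes = system.elec_nodes
    in_elec = np.zeros(n, dtype=bool)
    in_elec[elec_nodes] = True
    noslip = noslip[in_elec[noslip]]
    axis = axis[in_elec[axis]]

    fixed_r = np.unique(np.concatenate([noslip, axis]))
    fixed_z = noslip
    inactive = np.where(~in_elec)[0]
    fixed_r = np.unique(np.concatenate([fixed_r, inactive]))
    fixed_z = np.unique(np.concatenate([fixed_z, inactive]))
    fixed_p = inactive

    free_r = np.setdiff1d(np.arange(n), fixed_r)
    free_z = np.setdiff1d(np.arange(n), fixed_z)
    free_p = np.setdiff1d(np.arange(n), fixed_p)

    # assemble saddle system on free dofs: [A 0 -Br^T; 0 A -Bz^T; Br Bz -Sp]
    Arr = A_r[free_r][:, free_r]
    Azz = A_z[free_z][:, free_z]
    Brp = B_r[free_p][:, free_r]
    Bzp = B_z[free_p][:, free_z]
    Spp = S_p[free_p][:, free_p]
    K = sp.bmat(
        [
            [Arr, None, -Brp.T],
            [None, Azz, -Bzp.T],
            [Brp, Bzp, -Spp],
        ],
        format="csc",
    )
    rhs = np.concatenate([f_r[free_r], f_z[free_z], np.zeros(len(free_p))])
    sol = spla.spsolve(K, rhs)
    nr, nz = len(free_r), len(free_z)
    u = np.zeros((n, 2))
    p = np.zeros(n)
    u[free_r, 0] = sol[:nr]
    u[free_z, 1] = sol[nr: nr + nz]
    p[free_p] = sol[nr + nz:]
    return u, p


def advection_field(system, u_nd: np.ndarray):
    """Per-species EAFE advection vectors (units of D / nm) from u-tilde."""
    el = system.mesh.domain.electrolyte
    u0 = VELOCITY_SCALE(el)
    adv_na = (u0 * L0 / el.D_Na) * u_nd
    adv_cl = (u0 * L0 / el.D_Cl) * u_nd
    return adv_na, adv_cl
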