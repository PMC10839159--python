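"""Steady-state Poisson-Nernst-Planck solver on the axisymmetric mesh.

Model
-----
Electrostatics (Poisson, with the glass as a dielectric subdomain):

    div(eps0 eps_r grad phi) = -F (c_Na - c_Cl)      in the electrolyte
    div(eps0 eps_g grad phi) = 0                     in the glass
    eps0 [eps dphi/dn] = -sigma                      on charged surfaces

Ion transport (steady Nernst-Planck, drift-diffusion):

    div J_i = 0,   J_i = -D_i (grad c_i + z_i c_i grad psi) + u c_i

with psi = phi F / (R T) the potential in thermal units and u an optional
electroosmotic (Stokes) velocity.  Boundary conditions: phi fixed at the
inner electrode (pipette top) and the grounded outer bath, bulk
concentration at both reservoirs, zero normal ion flux on glass and protein
surfaces.

Discretisation
--------------
P1 triangles in the (r, z) half-plane with axisymmetric weighting.  The
Nernst-Planck equations use the edge-averaged finite element (EAFE)
exponential-fitting scheme - the multidimensional generalisation of the
Scharfetter-Gummel flux - which is positivity-preserving on Delaunay meshes
and well conditioned at tens of thermal volts of bias.  The nonlinear system
is solved by Gummel fixed-point iteration (Newton on a Boltzmann-linearised
Poisson step, then linear transport solves), with voltage continuation from
equilibrium for cold starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import ELECTROLYTE, GLASS, Mesh
from .model import FARADAY, VACUUM_PERMITTIVITY, Domain

__all__ = [
    "SolverOptions",
    "Fields",
    "SolverError",
    "ConvergenceError",
    "NegativeConcentrationError",
    "solve_pnp",
    "compute_current",
    "check_flux_conservation",
    "fields_to_csv",
    "fields_to_hdf5",
]

L0 = 1e-9  # mesh length unit (1 nm) in metres


class SolverError(RuntimeError):
    pass


class ConvergenceError(SolverError):
    def __init__(self, message: str, history: list | None = None):
        super().__init__(message)
        self.history = history or []


class NegativeConcentrationError(SolverError):
    def __init__(self, node: int, value: float):
        super().__init__(
            f"negative concentration {value:.3e} (relative) at node {node}"
        )
        self.node = node
        self.value = value


@dataclass
class SolverOptions:
    """Iteration controls for the coupled PNP solve."""

    tol: float = 1e-6  # relative current / potential update tolerance
    max_gummel: int = 80
    newton_max: int = 30
    voltage_step: float = 0.2  # V, continuation step for cold starts
    include_stokes: bool = False
    include_glass_dielectric: bool = True
    relaxation: float = 1.0  # Gummel concentration under-relaxation
    clip_exponent: float = 45.0
    strict: bool = True  # raise on non-convergence instead of flagging

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class Fields:
    """Solved potential and ion concentrations on a mesh.

    ``phi`` is in volts, ``c_na``/``c_cl`` in mol/m^3 (NaN on glass nodes),
    ``psi`` the potential in thermal units.  ``u`` (m/s) and ``p`` (Pa) are
    populated only when the Stokes coupling is enabled.
    """

    mesh: Mesh
    phi: np.ndarray
    psi: np.ndarray
    c_na: np.ndarray
    c_cl: np.ndarray
    electrode_current: float  # A, from the discrete electrode flux
    converged: bool
    iterations: int
    history: list = dc_field(default_factory=list)
    u: np.ndarray | None = None
    p: np.ndarray | None = None

    @property
    def domain(self) -> Domain:
        return self.mesh.domain


# ---------------------------------------------------------------------------
# FEM plumbing
# ---------------------------------------------------------------------------

class _FemData:
    """Per-element geometry factors shared by all assemblies on one mesh."""

    def __init__(self, mesh: Mesh):
        pts = mesh.points
        tri = mesh.triangles
        p0, p1, p2 = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
        det = (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1]) - (
            p2[:, 0] - p0[:, 0]
        ) * (p1[:, 1] - p0[:, 1])
        self.area = 0.5 * np.abs(det)
        inv = 1.0 / det
        # grad N_k = (b_k, c_k)
        b = np.stack(
            [
                (p1[:, 1] - p2[:, 1]) * inv,
                (p2[:, 1] - p0[:, 1]) * inv,
                (p0[:, 1] - p1[:, 1]) * inv,
            ],
            axis=1,
        )
        c = np.stack(
            [
                (p2[:, 0] - p1[:, 0]) * inv,
                (p0[:, 0] - p2[:, 0]) * inv,
                (p1[:, 0] - p0[:, 0]) * inv,
            ],
            axis=1,
        )
        self.grad = np.stack([b, c], axis=2)  # (ntri, 3, 2), units 1/nm
        self.rbar = pts[tri, 0].mean(axis=1)  # mean radius, nm
        self.tri = tri
        self.n = len(pts)
        self.coords = pts

    def stiffness(self, coef: np.ndarray, mask: np.ndarray) -> sp.csr_matrix:
        """Assemble sum_e coef_e * rbar_e * A_e * gradNi . gradNj."""
        idx = np.where(mask)[0]
        g = self.grad[idx]
        w = (coef[idx] * self.rbar[idx] * self.area[idx])[:, None, None]
        ke = w * np.einsum("eik,ejk->eij", g, g)
        t = self.tri[idx]
        rows = np.repeat(t, 3, axis=1).ravel()
        cols = np.tile(t, (1, 3)).ravel()
        return sp.coo_matrix(
            (ke.ravel(), (rows, cols)), shape=(self.n, self.n)
        ).tocsr()

    def lumped_mass(self, mask: np.ndarray) -> np.ndarray:
        """Axisymmetric lumped mass vector over masked elements."""
        idx = np.where(mask)[0]
        m = np.zeros(self.n)
        w = self.rbar[idx] * self.area[idx] / 3.0
        for k in range(3):
            np.add.at(m, self.tri[idx, k], w)
        return m


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (e^x - 1), numerically stable."""
    x = np.clip(x, -500.0, 500.0)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    out[small] = 1.0 - 0.5 * x[small]
    xs = x[~small]
    out[~small] = xs / np.expm1(xs)
    return out


def _eafe_matrix(
    fem: _FemData,
    diffusivity: float,
    zval: int,
    psi: np.ndarray,
    mask: np.ndarray,
    adv: np.ndarray | None = None,
) -> sp.csr_matrix:
    """EAFE (Scharfetter-Gummel) stiffness for one ion species.

    ``adv`` is an optional per-node advective velocity in units of D / nm
    (i.e. already nondimensionalised); it enters as an extra effective
    potential drop along each edge.
    """
    idx = np.where(mask)[0]
    g = fem.grad[idx]
    w = (fem.rbar[idx] * fem.area[idx])[:, None, None]
    ke = -(w * np.einsum("eik,ejk->eij", g, g))  # edge weights omega_ij = -S_ij
    t = fem.tri[idx]
    pts_psi = zval * psi[t]  # (ne, 3)

    rows, cols, vals = [], [], []
    pairs = ((0, 1), (1, 2), (2, 0))
    coords = fem.coords if adv is not None else None
    for i, j in pairs:
        om = ke[:, i, j]
        delta = pts_psi[:, j] - pts_psi[:, i]
        if adv is not None:
            xi = coords[t[:, i]]
            xj = coords[t[:, j]]
            u_edge = 0.5 * (adv[t[:, i]] + adv[t[:, j]])
            pe = np.clip(np.einsum("ek,ek->e", u_edge, xj - xi), -25.0, 25.0)
            delta = delta - pe
        # SG edge flux J_ij = om * (B(delta) c_i - B(-delta) c_j); at the
        # Boltzmann ratio c_j/c_i = exp(-delta) the flux vanishes exactly.
        bp = _bernoulli(delta)
        bm = _bernoulli(-delta)
        rows += [t[:, i], t[:, i], t[:, j], t[:, j]]
        cols += [t[:, i], t[:, j], t[:, j], t[:, i]]
        vals += [om * bp, -om * bm, om * bm, -om * bp]
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(fem.n, fem.n),
    ).tocsr()
    return diffusivity * mat


def _surface_load(mesh: Mesh, tags_sigma: dict[str, float]) -> np.ndarray:
    """Axisymmetric line integral of sigma * N_i along tagged edges."""
    load = np.zeros(mesh.n_nodes)
    pts = mesh.points
    for tag, sigma in tags_sigma.items():
        edges = mesh.edges.get(tag)
        if edges is None or len(edges) == 0 or sigma == 0.0:
            continue
        pa, pb = pts[edges[:, 0]], pts[edges[:, 1]]
        length = np.linalg.norm(pb - pa, axis=1)
        ra, rb = pa[:, 0], pb[:, 0]
        la = sigma * length * (2.0 * ra + rb) / 6.0
        lb = sigma * length * (ra + 2.0 * rb) / 6.0
        np.add.at(load, edges[:, 0], la)
        np.add.at(load, edges[:, 1], lb)
    return load


class _RecycledSolver:
    """Direct solve with factorisation recycling.

    Successive systems in a Gummel iteration share the sparsity pattern and
    drift slowly in values, so the previous LU factor is an excellent
    preconditioner: refactorise on the first call (and whenever GMRES with
    the stale factor stalls), otherwise solve iteratively in a few
    Krylov steps.
    """

    def __init__(self) -> None:
        self.lu = None
        self.shape = None

    def solve(self, A: sp.csc_matrix, b: np.ndarray) -> np.ndarray:
        if self.lu is None or self.shape != A.shape:
            self.lu = spla.splu(A)
            self.shape = A.shape
            return self.lu.solve(b)
        bnorm = np.linalg.norm(b)
        if bnorm == 0.0:
            return np.zeros_like(b)
        x, info = spla.gmres(
            A, b, M=spla.LinearOperator(A.shape, self.lu.solve),
            rtol=1e-9, atol=0.0, maxiter=12, restart=12,
        )
        if info != 0:
            self.lu = spla.splu(A)
            x = self.lu.solve(b)
        return x


def _solve_dirichlet(A: sp.csr_matrix, b: np.ndarray, fixed: np.ndarray,
                     values: np.ndarray, free: np.ndarray,
                     solver: _RecycledSolver | None = None) -> np.ndarray:
    x = np.zeros(A.shape[0])
    x[fixed] = values
    rhs = b[free] - A[free][:, fixed] @ values
    Af = A[free][:, free].tocsc()
    if solver is None:
        x[free] = spla.spsolve(Af, rhs)
    else:
        x[free] = solver.solve(Af, rhs)
    return x


# ---------------------------------------------------------------------------
# the coupled solve
# ---------------------------------------------------------------------------

class _System:
    """Assembled node sets, masks and constants for one mesh."""

    def __init__(self, mesh: Mesh, options: SolverOptions):
        self.mesh = mesh
        self.options = options
        dom = mesh.domain
        el = dom.electrolyte
        self.vt = el.thermal_voltage
        self.beta = FARADAY * el.c_bulk_si * L0**2 / (
            VACUUM_PERMITTIVITY * self.vt
        )
        self.sigma_scale = L0 / (VACUUM_PERMITTIVITY * self.vt)

        self.fem = _FemData(mesh)
        self.elec_mask = mesh.labels == ELECTROLYTE
        self.glass_mask = mesh.labels == GLASS

        n = mesh.n_nodes
        self.elec_nodes = np.unique(mesh.triangles[self.elec_mask])
        is_elec = np.zeros(n, dtype=bool)
        is_elec[self.elec_nodes] = True
        self.is_elec_node = is_elec

        if options.include_glass_dielectric:
            phi_mask = self.elec_mask | self.glass_mask
        else:
            phi_mask = self.elec_mask
        self.phi_mask = phi_mask
        self.phi_nodes = np.unique(mesh.triangles[phi_mask])
        active = np.zeros(n, dtype=bool)
        active[self.phi_nodes] = True
        self.is_phi_node = active

        top = mesh.nodes_of("pipette_top")
        ground = mesh.nodes_of("bath_far")
        self.top_nodes = top[active[top]]
        self.ground_nodes = ground[active[ground]]

        # Poisson operator (voltage independent)
        coef = np.where(self.elec_mask, el.eps_water, dom.geometry.eps_glass)
        self.S_phi = self.fem.stiffness(coef, phi_mask)
        self.mass_elec = self.fem.lumped_mass(self.elec_mask)

        sigmas = {"glass_wall": dom.geometry.scd_glass * self.sigma_scale}
        for k, s in enumerate(dom.spheroids):
            sigmas[f"protein_surface_{k}"] = s.scd * self.sigma_scale
        self.b_sigma = _surface_load(mesh, sigmas)

        fixed = np.concatenate([self.ground_nodes, self.top_nodes])
        self.phi_fixed = np.unique(fixed)
        free = np.setdiff1d(self.phi_nodes, self.phi_fixed)
        self.phi_free = free

        c_fixed = self.phi_fixed[is_elec[self.phi_fixed]]
        self.c_fixed = c_fixed
        self.c_free = np.setdiff1d(self.elec_nodes, c_fixed)

        self._phi_solver = _RecycledSolver()
        self._ion_solvers = {+1: _RecycledSolver(), -1: _RecycledSolver()}

    def phi_dirichlet(self, v_applied: float) -> np.ndarray:
        vals = np.zeros(len(self.phi_fixed))
        is_top = np.isin(self.phi_fixed, self.top_nodes)
        vals[is_top] = v_applied / self.vt
        return vals

    # -- Poisson step -------------------------------------------------------
    def poisson_newton(self, psi, c_na, c_cl, v_applied, max_inner=None):
        opts = self.options
        clip = opts.clip_exponent
        psi = psi.copy()
        vals = self.phi_dirichlet(v_applied)
        psi[self.phi_fixed] = vals
        psi_ref = psi.copy()
        for _ in range(max_inner or opts.newton_max):
            d = np.clip(psi - psi_ref, -clip, clip)
            na = c_na * np.exp(-d)
            cl = c_cl * np.exp(d)
            charge = self.beta * self.mass_elec * (na - cl)
            resid = self.S_phi @ psi - charge - self.b_sigma
            jac_diag = self.beta * self.mass_elec * (na + cl)
            A = self.S_phi + sp.diags(jac_diag)
            free = self.phi_free
            rhs = -resid[free]
            dpsi = self._phi_solver.solve(A[free][:, free].tocsc(), rhs)
            mx = np.max(np.abs(dpsi)) if len(dpsi) else 0.0
            if mx > 8.0:  # damp large Newton steps (thermal units)
                dpsi *= 8.0 / mx
            psi[free] += dpsi
            if mx < 1e-9:
                break
        return psi

    # -- Nernst-Planck step -------------------------------------------------
    def np_solve(self, zval, diffusivity, psi, adv=None):
        A = _eafe_matrix(self.fem, diffusivity, zval, psi, self.elec_mask, adv)
        fixed = self.c_fixed
        ones = np.ones(len(fixed))
        c = _solve_dirichlet(A, np.zeros(self.fem.n), fixed, ones, self.c_free,
                             solver=self._ion_solvers[zval])
        cmin = c[self.elec_nodes].min()
        if cmin < -1e-6:
            node = self.elec_nodes[int(np.argmin(c[self.elec_nodes]))]
            raise NegativeConcentrationError(int(node), float(cmin))
        np.clip(c, 1e-12, None, out=c)
        c[~self.is_elec_node] = 0.0
        return c, A

    def electrode_current(self, c_na, A_na, c_cl, A_cl) -> float:
        """Discrete flux through the inner electrode (A), reaction method."""
        el = self.mesh.domain.electrolyte
        top = self.top_nodes[self.is_elec_node[self.top_nodes]]
        rho_na = (A_na @ c_na)[top].sum()
        rho_cl = (A_cl @ c_cl)[top].sum()
        scale = 2.0 * math.pi * FARADAY * el.c_bulk_si * L0
        return scale * (rho_na - rho_cl)


def _gummel(system: _System, psi, c_na, c_cl, v_applied, options, history):
    """Anderson-accelerated Gummel iteration at one applied voltage.

    One sweep = Boltzmann-linearised Poisson-Newton step followed by the two
    linear EAFE transport solves.  The fixed-point sequence on the packed
    state (psi, log c) is accelerated with depth-5 type-II Anderson mixing,
    which removes the slowdown of plain Gummel at tens of thermal volts.
    """
    el = system.mesh.domain.electrolyte
    en = system.elec_nodes
    n = system.fem.n

    def pack(psi_a, na_a, cl_a):
        return np.concatenate(
            [psi_a, np.log(np.clip(na_a[en], 1e-12, None)),
             np.log(np.clip(cl_a[en], 1e-12, None))]
        )

    def unpack(x):
        psi_a = x[:n]
        na_a = np.zeros(n)
        cl_a = np.zeros(n)
        ne = len(en)
        na_a[en] = np.exp(np.clip(x[n: n + ne], -60, 60))
        cl_a[en] = np.exp(np.clip(x[n + ne:], -60, 60))
        return psi_a, na_a, cl_a

    def sweep(psi_a, na_a, cl_a):
        psi_b = system.poisson_newton(psi_a, na_a, cl_a, v_applied, max_inner=3)
        adv = None
        u_loc = None
        if options.include_stokes:
            from .stokes import solve_stokes, advection_field

            u_loc, _ = solve_stokes(system, psi_b, na_a, cl_a)
            adv = advection_field(system, u_loc)
        na_b, A_na = system.np_solve(+1, el.D_Na, psi_b,
                                     adv[0] if adv is not None else None)
        cl_b, A_cl = system.np_solve(-1, el.D_Cl, psi_b,
                                     adv[1] if adv is not None else None)
        return psi_b, na_b, cl_b, A_na, A_cl, u_loc

    depth = 5
    F: list[np.ndarray] = []
    G: list[np.ndarray] = []
    x = pack(psi, c_na, c_cl)
    current = np.nan
    ok_streak = 0
    u_nd = None
    for it in range(1, options.max_gummel + 1):
        psi_a, na_a, cl_a = unpack(x)
        try:
            psi_b, na_b, cl_b, A_na, A_cl, u_nd = sweep(psi_a, na_a, cl_a)
        except NegativeConcentrationError:
            if not F:
                raise
            # Anderson extrapolation overshot; restart from plain iterate
            F.clear()
            x = G[-1]
            G.clear()
            psi_a, na_a, cl_a = unpack(x)
            psi_b, na_b, cl_b, A_na, A_cl, u_nd = sweep(psi_a, na_a, cl_a)
        g = pack(psi_b, na_b, cl_b)
        f = g - x
        dpsi = float(np.max(np.abs(psi_b - psi_a)))
        new_current = system.electrode_current(na_b, A_na, cl_b, A_cl)
        di = abs(new_current - current) / max(abs(new_current), 1e-30)
        history.append(
            {"V": v_applied, "iter": it, "dpsi": dpsi, "dI": di,
             "I": new_current}
        )
        current = new_current
        psi_scale = max(1.0, float(np.max(np.abs(psi_b))))
        tight = dpsi < max(options.tol, 1e-9) * psi_scale
        ok_streak = ok_streak + 1 if di < options.tol else 0
        if tight or (ok_streak >= 2 and dpsi < 1e-3 * psi_scale):
            return psi_b, na_b, cl_b, current, True, it, u_nd

        F.append(f)
        G.append(g)
        if len(F) > depth:
            F.pop(0)
            G.pop(0)
        if len(F) >= 2 and options.relaxation == 1.0:
            dF = np.stack([F[i + 1] - F[i] for i in range(len(F) - 1)], axis=1)
            try:
                gamma, *_ = np.linalg.lstsq(dF, f, rcond=None)
                dG = np.stack(
                    [G[i + 1] - G[i] for i in range(len(G) - 1)], axis=1
                )
                x_new = g - dG @ gamma
            except np.linalg.LinAlgError:
                x_new = g
            if np.all(np.isfinite(x_new)):
                x = x_new
            else:
                x = g
        else:
            x = x + options.relaxation * f
    psi_b, na_b, cl_b = unpack(g)
    return psi_b, na_b, cl_b, current, False, options.max_gummel, u_nd


def solve_pnp(
    domain: Domain,
    mesh: Mesh,
    options: SolverOptions | None = None,
    initial: Fields | None = None,
) -> Fields:
    """Solve the coupled steady PNP system on ``mesh``.

    ``initial`` supplies a warm start (fields from a nearby geometry /
    voltage, interpolated by nearest node); without it the solver ramps the
    voltage from equilibrium in ``options.voltage_step`` increments.
    """
    options = options or SolverOptions()
    if abs(domain.applied_voltage) > 1.0 + 1e-9:
        raise ValueError("applied voltage outside the +-1 V validated range")
    if options.include_stokes and initial is None:
        # electroosmosis is a correction: converge the pure drift-diffusion
        # problem first, then iterate the flow coupling from that state
        from dataclasses import replace as _dc_replace

        initial = solve_pnp(
            domain, mesh, _dc_replace(options, include_stokes=False)
        )
    system = _System(mesh, options)
    el = domain.electrolyte
    n = mesh.n_nodes
    v_target = domain.applied_voltage
    history: list[dict] = []

    def cold_ramp(step):
        psi = np.zeros(n)
        c_na = np.where(system.is_elec_node, 1.0, 0.0)
        c_cl = c_na.copy()
        n_steps = max(1, int(math.ceil(abs(v_target) / step))) if v_target else 1
        volts = np.linspace(0.0, v_target, n_steps + 1)
        ok, it_total, current, u_nd = True, 0, 0.0, None
        for v in volts:
            psi, c_na, c_cl, current, ok, it, u_nd = _gummel(
                system, psi, c_na, c_cl, v, options, history
            )
            it_total += it
            if not ok:
                break
        return psi, c_na, c_cl, current, ok, it_total, u_nd

    if initial is not None:
        from scipy.interpolate import LinearNDInterpolator
        from scipy.spatial import cKDTree

        tree = cKDTree(initial.mesh.points)
        _, nearest = tree.query(mesh.points)
        psi0 = initial.psi[nearest]
        try:
            lin = LinearNDInterpolator(initial.mesh.points, initial.psi)
            vals = lin(mesh.points)
            good = np.isfinite(vals)
            psi0[good] = vals[good]
        except Exception:
            pass  # nearest-neighbour fallback already in place
        cna0 = np.where(system.is_elec_node,
                        np.nan_to_num(initial.c_na[nearest] / el.c_bulk_si,
                                      nan=1.0), 0.0)
        ccl0 = np.where(system.is_elec_node,
                        np.nan_to_num(initial.c_cl[nearest] / el.c_bulk_si,
                                      nan=1.0), 0.0)
        np.clip(cna0, 1e-12, None, out=cna0)
        np.clip(ccl0, 1e-12, None, out=ccl0)
        psi, c_na, c_cl, current, ok, its, u_nd = _gummel(
            system, psi0, cna0, ccl0, v_target, options, history
        )
        if not ok:
            psi, c_na, c_cl, current, ok, its, u_nd = cold_ramp(
                options.voltage_step
            )
    else:
        psi, c_na, c_cl, current, ok, its, u_nd = cold_ramp(options.voltage_step)
        if not ok:
            psi, c_na, c_cl, current, ok, its, u_nd = cold_ramp(
                0.5 * options.voltage_step
            )

    if not ok and options.strict:
        raise ConvergenceError(
            f"Gummel iteration did not reach tol={options.tol} at "
            f"V={v_target} V", history
        )

    phi = psi * system.vt
    cna_out = np.where(system.is_elec_node, c_na * el.c_bulk_si, np.nan)
    ccl_out = np.where(system.is_elec_node, c_cl * el.c_bulk_si, np.nan)
    u_out = None
    if u_nd is not None:
        from .stokes import VELOCITY_SCALE

        u_out = u_nd * VELOCITY_SCALE(el)
    return Fields(
        mesh=mesh,
        phi=phi,
        psi=psi,
        c_na=cna_out,
        c_cl=ccl_out,
        electrode_current=current,
        converged=ok,
        iterations=its,
        history=history,
        u=u_out,
    )


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def compute_current(fields: Fields, z_section: float) -> float:
    """Ionic current (A) through the plane z = ``z_section``.

    Integrates F * (J_Na - J_Cl) . z_hat over the *pore* cross-section
    (r < inner wall radius for sections inside the pipette; the external
    bath annulus outside the glass carries its own return current to the
    grounded window boundaries and is excluded) using the piecewise-linear
    field gradients.  This estimate is independent of the electrode
    reaction-flux current, so the two can cross-check each other.
    Positive current flows in the -z direction for positive applied voltage
    with the default geometry (electrode inside, ground in the bath).
    """
    mesh = fields.mesh
    dom = mesh.domain
    W = dom.window_half_extent
    if not (-W < z_section < W):
        raise ValueError("cross-section lies outside the simulation window")
    el = dom.electrolyte
    pts = mesh.points
    tri = mesh.electrolyte_elements
    zs = pts[:, 1][tri]
    zmin, zmax = zs.min(axis=1), zs.max(axis=1)
    hit = np.where((zmin < z_section) & (zmax > z_section))[0]
    if len(hit) == 0:
        raise ValueError("cross-section intersects no electrolyte elements")

    cna = np.nan_to_num(fields.c_na / el.c_bulk_si, nan=0.0)
    ccl = np.nan_to_num(fields.c_cl / el.c_bulk_si, nan=0.0)
    psi = fields.psi
    total = 0.0
    for e in hit:
        nodes = tri[e]
        p = pts[nodes]
        # P1 gradients
        det = (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1]) - (
            p[2, 0] - p[0, 0]
        ) * (p[1, 1] - p[0, 1])
        gz = np.array(
            [p[2, 0] - p[1, 0], p[0, 0] - p[2, 0], p[1, 0] - p[0, 0]]
        ) / det
        dpsi_dz = float(gz @ psi[nodes])
        dna_dz = float(gz @ cna[nodes])
        dcl_dz = float(gz @ ccl[nodes])
        na_bar = float(cna[nodes].mean())
        cl_bar = float(ccl[nodes].mean())
        jz_na = -el.D_Na * (dna_dz + na_bar * dpsi_dz)
        jz_cl = -el.D_Cl * (dcl_dz - cl_bar * dpsi_dz)
        # chord of the plane through the triangle
        rs = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            za, zb = p[a, 1], p[b, 1]
            if (za - z_section) * (zb - z_section) < 0:
                t = (z_section - za) / (zb - za)
                rs.append(p[a, 0] + t * (p[b, 0] - p[a, 0]))
            elif za == z_section:
                rs.append(p[a, 0])
        if len(rs) < 2:
            continue
        r1, r2 = min(rs), max(rs)
        if z_section > 0.0:
            r_bore = float(dom.geometry.inner_radius(z_section))
            if 0.5 * (r1 + r2) > r_bore:
                continue  # external bath annulus, not pore current
        total += (jz_na - jz_cl) * 0.5 * (r2**2 - r1**2)
    # sign: match the electrode convention (current positive out of the
    # inner electrode for positive V, i.e. flowing in -z through the pore)
    return -2.0 * math.pi * FARADAY * el.c_bulk_si * L0 * total


def check_flux_conservation(
    fields: Fields, sections: list[float]
) -> tuple[float, bool]:
    """Max relative spread of the current across cross-sections.

    Returns ``(deviation, absolute_flag)``; when the mean current is ~0
    (equilibrium) the deviation is reported in amperes instead and flagged.
    """
    if len(sections) < 2:
        raise ValueError("need at least two cross-sections")
    currents = np.array([compute_current(fields, z) for z in sections])
    mean = currents.mean()
    if abs(mean) < 1e-15:
        return float(np.max(np.abs(currents - mean))), True
    return float(np.max(np.abs(currents - mean)) / abs(mean)), False


def fields_to_csv(fields: Fields, path) -> None:
    """Flat (r, z, phi, c_Na, c_Cl) table, nm / V / mol m^-3."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "r_nm": fields.mesh.points[:, 0],
            "z_nm": fields.mesh.points[:, 1],
            "phi_V": fields.phi,
            "c_na_mol_m3": fields.c_na,
            "c_cl_mol_m3": fields.c_cl,
        }
    )
    df.to_csv(path, index=False)


def fields_to_hdf5(fields: Fields, path) -> None:
    """Mesh + fields container (HDF5)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("points", data=fields.mesh.points)
        h5.create_dataset("triangles", data=fields.mesh.triangles)
        h5.create_dataset("labels", data=fields.mesh.labels)
        h5.create_dataset("phi", data=fields.phi)
        h5.create_dataset("c_na", data=fields.c_na)
        h5.create_dataset("c_cl", data=fields.c_cl)
        h5.attrs["electrode_current_A"] = fields.electrode_current
        h5.attrs["applied_voltage_V"] = fields.domain.applied_voltage
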