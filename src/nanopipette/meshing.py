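"""Axisymmetric triangular mesh generation for the pipette domain.

The (r, z) half-plane window ``[0, W] x [-W, +W]`` is meshed with graded
Delaunay triangles: node clouds are laid down on hexagonal lattices whose
pitch follows a sizing field (coarse in the far bath, fine in the electric
double layer along the glass and around the orifice / protein surfaces),
boundary polylines are sampled explicitly so Delaunay edges align with the
material interfaces, and triangles are classified by centroid into
electrolyte, glass, or protein (removed).

Touching spheroids in a chain meet pole-to-pole in a cusp; the unmeshable
crevice around each contact point is filled by a short "neck" cylinder whose
radius matches the spheroid cross-section a small axial offset away.  The
crevice is a dead-end volume that carries no axial current, so filling it
leaves the blockade physics unchanged while keeping element quality bounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .model import Domain, SpheroidSurface

__all__ = ["Mesh", "generate_mesh", "MeshSizing"]

ELECTROLYTE = 0
GLASS = 1

NECK_HALF_LENGTH = 0.35  # nm, axial half-extent of the contact-filling neck


@dataclass(frozen=True)
class MeshSizing:
    """Target edge lengths (nm) of the graded mesh at refinement level 0.

    Each refinement level multiplies every pitch by ``shrink`` (< 1).  The
    defaults resolve the 125 mM Debye layer (~0.86 nm) with ~5 elements
    across it near the tip and protein, per the double-layer resolution
    requirement (element size <= 0.2 Debye lengths there).
    """

    h_coarse: float = 1.9
    h_mid: float = 0.55
    h_edl: float = 0.20
    h_fine: float = 0.13
    h_glass: float = 1.1
    edl_band: float = 1.0  # nm, fine band normal to wetted glass
    fine_band_tip: float = 2.2  # nm, radius of finest zone around orifice ring
    fine_band_protein: float = 1.3  # nm, finest band around protein surfaces
    mid_band: float = 6.5  # nm, mid-resolution zone around the orifice
    shrink: float = 0.75

    def at_level(self, level: int) -> "MeshSizing":
        s = self.shrink**level
        return MeshSizing(
            h_coarse=self.h_coarse * s,
            h_mid=self.h_mid * s,
            h_edl=self.h_edl * s,
            h_fine=self.h_fine * s,
            h_glass=self.h_glass * s,
            edl_band=self.edl_band,
            fine_band_tip=self.fine_band_tip,
            fine_band_protein=self.fine_band_protein,
            mid_band=self.mid_band,
            shrink=self.shrink,
        )


@dataclass
class Mesh:
    """Triangulated axisymmetric domain with tagged boundary edges.

    ``points`` are (r, z) in nm; ``triangles`` index into points;
    ``labels`` is 0 for electrolyte and 1 for glass elements.  ``edges``
    maps a boundary tag to an (n, 2) array of node pairs; protein surfaces
    are tagged ``protein_surface_0`` .. ``protein_surface_{k-1}`` (lead
    protein first).
    """

    points: np.ndarray
    triangles: np.ndarray
    labels: np.ndarray
    edges: dict[str, np.ndarray]
    refinement: int
    domain: Domain
    sizing: MeshSizing = field(default_factory=MeshSizing)

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def electrolyte_elements(self) -> np.ndarray:
        return self.triangles[self.labels == ELECTROLYTE]

    def nodes_of(self, tag: str) -> np.ndarray:
        """Sorted unique node indices belonging to a boundary tag."""
        e = self.edges.get(tag)
        if e is None or len(e) == 0:
            return np.empty(0, dtype=int)
        return np.unique(e)

    def min_edge_length(self, near: tuple[float, float] | None = None,
                        radius: float = 2.0) -> float:
        """Shortest element edge, optionally restricted near a point."""
        tri = self.triangles
        p = self.points
        edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        lengths = np.linalg.norm(p[edges[:, 0]] - p[edges[:, 1]], axis=1)
        if near is not None:
            mids = 0.5 * (p[edges[:, 0]] + p[edges[:, 1]])
            mask = np.linalg.norm(mids - np.asarray(near), axis=1) < radius
            if mask.any():
                lengths = lengths[mask]
        return float(lengths.min())


# ---------------------------------------------------------------------------
# geometric helpers
# ---------------------------------------------------------------------------

def _neck_specs(spheroids: tuple[SpheroidSurface, ...]):
    """(z_contact, half_length, radius) cylinders filling chain contact cusps."""
    specs = []
    for s1, s2 in zip(spheroids[:-1], spheroids[1:]):
        zc = 0.5 * (s1.z_center + s2.z_center)
        a, b = s1.axial_semiaxis, s1.radial_semiaxis
        d = min(NECK_HALF_LENGTH, 0.5 * a)
        r_neck = b * math.sqrt(max(d * (2 * a - d), 0.0)) / a
        specs.append((zc, d, r_neck))
    return specs


def _inside_obstacle(r, z, spheroids, necks):
    """Boolean mask: points inside the protein chain (spheroids + necks)."""
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    inside = np.zeros(r.shape, dtype=bool)
    for s in spheroids:
        inside |= ((z - s.z_center) / s.axial_semiaxis) ** 2 + (
            r / s.radial_semiaxis
        ) ** 2 < 1.0
    for zc, d, rn in necks:
        inside |= (np.abs(z - zc) <= d) & (r < rn)
    return inside


def _in_glass(r, z, geom):
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    r_in = np.asarray(geom.inner_radius(np.maximum(z, 0.0)))
    return (z > 0.0) & (r > r_in) & (r < r_in + geom.wall_thickness_orifice)


def _polyline_resample(pts: np.ndarray, spacing: np.ndarray,
                       levels: list[float] | None = None,
                       anchor: float = 0.0) -> np.ndarray:
    """Resample a polyline with locally varying target spacing.

    Sample positions are anchored to absolute multiples of each spacing
    level along the arc length, so nearby geometry changes (a protein
    moving along the axis alters the local sizing) do not shift the sample
    positions elsewhere on the polyline.  This keeps meshes of successive
    protein positions identical away from the protein and makes position
    sweeps numerically smooth.
    """
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return pts[:1]
    if levels is None:
        levels = sorted(set(np.round(spacing, 12)), reverse=True)
    out_s = [0.0, total]
    for k, pitch in enumerate(levels):
        upper = levels[k - 1] if k else math.inf
        j0 = int(math.floor(anchor / pitch)) + 1
        j1 = int(math.ceil((anchor + total) / pitch))
        cand = pitch * np.arange(j0, j1) - anchor
        cand = cand[(cand > 1e-9) & (cand < total - 1e-9)]
        if len(cand) == 0:
            continue
        h = np.interp(cand, s, spacing)
        keep = (h >= pitch - 1e-12) & (h < upper)
        out_s.extend(cand[keep])
    out_s = np.unique(np.asarray(out_s))
    # drop samples closer than half the local spacing to their predecessor
    keep = [0]
    for i in range(1, len(out_s)):
        h = float(np.interp(out_s[i], s, spacing))
        if out_s[i] - out_s[keep[-1]] >= 0.45 * h or i == len(out_s) - 1:
            keep.append(i)
    out_s = out_s[keep]
    r = np.interp(out_s, s, pts[:, 0])
    z = np.interp(out_s, s, pts[:, 1])
    return np.column_stack([r, z])


def _hex_lattice(bbox, pitch, phase=0.0):
    """Hexagonal lattice anchored at the global origin (not the bbox)."""
    r0, r1, z0, z1 = bbox
    dz = pitch * math.sqrt(3.0) / 2.0
    k0 = int(math.floor(z0 / dz))
    k1 = int(math.ceil(z1 / dz))
    pts = []
    for k in range(k0, k1 + 1):
        z = k * dz
        if z < z0 - 1e-12 or z > z1 + 1e-12:
            continue
        off = 0.5 * pitch if k % 2 else 0.0
        j0 = int(math.floor((r0 - off - phase) / pitch))
        j1 = int(math.ceil((r1 - off - phase) / pitch))
        rs = off + phase + pitch * np.arange(j0, j1 + 1)
        rs = rs[(rs >= r0) & (rs <= r1 + pitch * 0.999)]
        pts.append(np.column_stack([rs, np.full_like(rs, z)]))
    return np.concatenate(pts) if pts else np.empty((0, 2))


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

def generate_mesh(
    domain: Domain,
    refinement: int = 0,
    sizing: MeshSizing | None = None,
) -> Mesh:
    """Build the graded, deterministic axisymmetric mesh for a domain.

    ``refinement`` >= 0 shrinks every target edge length geometrically;
    node count strictly increases with the level.
    """
    base = sizing or MeshSizing()
    sz = base.at_level(refinement)
    geom = domain.geometry
    W = domain.window_half_extent
    spheroids = domain.spheroids
    necks = _neck_specs(spheroids)

    lam_d = domain.electrolyte.debye_length
    edl_band = min(sz.edl_band, 1.4 * lam_d)

    # --- feature polylines (dense, for distance queries) -------------------
    zw = np.linspace(0.0, W, 400)
    inner = np.column_stack([np.asarray(geom.inner_radius(zw)), zw])
    outer = np.column_stack([np.asarray(geom.outer_radius(zw)), zw])
    rfront = np.linspace(geom.pore_radius, geom.outer_radius(0.0), 200)
    front = np.column_stack([rfront, np.zeros_like(rfront)])
    wall_pts = np.concatenate([inner, front, outer])
    wall_tree = cKDTree(wall_pts)
    tip = np.array([geom.pore_radius, 0.0])

    prot_trees = []
    prot_dense = []
    for s in spheroids:
        th = np.linspace(0.0, math.pi, 300)
        pz = s.z_center + s.axial_semiaxis * np.cos(th)
        pr = s.radial_semiaxis * np.sin(th)
        pts = np.column_stack([pr, pz])
        prot_dense.append(pts)
        prot_trees.append(cKDTree(pts))

    def size_field(pts: np.ndarray) -> np.ndarray:
        glass_mask = _in_glass(pts[:, 0], pts[:, 1], geom)
        d_tip = np.linalg.norm(pts - tip, axis=1)
        # far-field growth keeps large reservoirs affordable
        h = sz.h_coarse * np.clip(d_tip / 25.0, 1.0, 50.0)
        h[glass_mask] = np.minimum(
            sz.h_glass * np.clip(d_tip[glass_mask] / 25.0, 1.0, 50.0),
            h[glass_mask],
        )
        h = np.where((d_tip < sz.mid_band) & ~glass_mask, np.minimum(h, sz.h_mid), h)
        # the bore carries the whole current: keep >= ~4 elements across it
        r_in_here = np.asarray(geom.inner_radius(np.maximum(pts[:, 1], 0.0)))
        in_bore = (pts[:, 1] > 0.0) & (pts[:, 0] < r_in_here) & ~glass_mask
        h_bore = np.clip(0.25 * r_in_here, sz.h_edl, sz.h_coarse)
        h = np.where(in_bore, np.minimum(h, h_bore), h)
        d_wall, _ = wall_tree.query(pts)
        h = np.where(d_wall < edl_band, np.minimum(h, sz.h_edl), h)
        fine = d_tip < sz.fine_band_tip
        for t in prot_trees:
            dp, _ = t.query(pts)
            fine |= dp < sz.fine_band_protein
        h = np.where(fine, np.minimum(h, sz.h_fine), h)
        return h

    # --- boundary samples --------------------------------------------------
    boundary: list[np.ndarray] = []
    size_levels = sorted(
        {48 * sz.h_coarse, 24 * sz.h_coarse, 12 * sz.h_coarse,
         6 * sz.h_coarse, 3 * sz.h_coarse, 1.7 * sz.h_coarse,
         sz.h_coarse, sz.h_glass, sz.h_mid, sz.h_edl, sz.h_fine},
        reverse=True,
    )
    level_arr = np.asarray(size_levels)

    def snap(h: np.ndarray) -> np.ndarray:
        # largest discrete level not exceeding h (clamped at the finest)
        idx = np.searchsorted(-level_arr, -h, side="left")
        return level_arr[np.minimum(idx, len(level_arr) - 1)]

    def sample(polyline: np.ndarray, anchor: float = 0.0) -> np.ndarray:
        sp = snap(size_field(polyline))
        return _polyline_resample(polyline, sp, size_levels, anchor)

    boundary.append(sample(inner))
    boundary.append(sample(outer))
    boundary.append(sample(front))
    # window frame
    zb = np.linspace(-W, W, 200)
    boundary.append(sample(np.column_stack([np.full_like(zb, W), zb])))
    rb = np.linspace(0.0, W, 200)
    boundary.append(sample(np.column_stack([rb, np.full_like(rb, -W)])))
    rt = np.linspace(0.0, W, 400)
    boundary.append(sample(np.column_stack([rt, np.full_like(rt, W)])))
    # axis segments (split at protein interiors, anchored in absolute z)
    blocked = sorted(
        (s.z_center - s.axial_semiaxis, s.z_center + s.axial_semiaxis)
        for s in spheroids
    )
    z_cursor = -W
    axis_segments = []
    for lo, hi in blocked:
        if lo > z_cursor:
            axis_segments.append((z_cursor, min(lo, W)))
        z_cursor = max(z_cursor, hi)
    if z_cursor < W:
        axis_segments.append((z_cursor, W))
    for lo, hi in axis_segments:
        za = np.linspace(lo, hi, max(int((hi - lo) * 20), 8))
        seg = np.column_stack([np.zeros_like(za), za])
        boundary.append(sample(seg, anchor=lo + W))
    # protein surfaces: ellipse arcs outside necks, plus neck walls
    for k, s in enumerate(spheroids):
        pts = prot_dense[k]
        inside_neck = np.zeros(len(pts), dtype=bool)
        for zc, d, rn in necks:
            inside_neck |= (np.abs(pts[:, 1] - zc) < d) & (pts[:, 0] <= rn + 1e-9)
        arc = pts[~inside_neck]
        if len(arc) > 1:
            boundary.append(sample(arc))
    for zc, d, rn in necks:
        znk = np.linspace(zc - d, zc + d, 30)
        boundary.append(sample(np.column_stack([np.full_like(znk, rn), znk])))

    bpts = np.concatenate(boundary)
    bpts[:, 0] = np.clip(bpts[:, 0], 0.0, W)
    bpts[:, 1] = np.clip(bpts[:, 1], -W, W)
    # dedupe boundary points
    tree = cKDTree(bpts)
    pairs = tree.query_pairs(r=0.35 * sz.h_fine, output_type="ndarray")
    drop = np.zeros(len(bpts), dtype=bool)
    for i, j in pairs:
        if not drop[i]:
            drop[j] = True
    bpts = bpts[~drop]

    # --- interior lattices -------------------------------------------------
    levels = size_levels
    # each pitch only needs candidates where the sizing field can reach it
    r_top = float(geom.outer_radius(W))
    if spheroids:
        z_chain_lo = min(s.z_center - s.axial_semiaxis for s in spheroids)
        z_chain_hi = max(s.z_center + s.axial_semiaxis for s in spheroids)
    else:
        z_chain_lo = z_chain_hi = 0.0

    def level_bbox(pitch: float):
        if pitch >= sz.h_coarse:
            return (0.0, W, -W, W)
        if pitch >= sz.h_mid:
            return (
                0.0,
                min(W, r_top + 3.0),
                max(-W, min(-sz.mid_band - 3.0, z_chain_lo - 3.0)),
                W,
            )
        if pitch > sz.h_fine:
            return (0.0, min(W, r_top + 2.0),
                    max(-W, min(-3.0, z_chain_lo - 2.0)), W)
        return (
            0.0,
            min(W, geom.outer_radius(0.0) + 3.0),
            max(-W, min(-sz.fine_band_tip - 1.5, z_chain_lo - 2.0)),
            min(W, max(sz.fine_band_tip + 1.5, z_chain_hi + 2.0)),
        )

    interior: list[np.ndarray] = []
    for k, pitch in enumerate(levels):
        cand = _hex_lattice(level_bbox(pitch), pitch)
        if len(cand) == 0:
            continue
        if pitch < sz.h_mid:
            # cheap arithmetic pre-filter: near-wall / near-chain strip only
            rin = np.asarray(geom.inner_radius(np.maximum(cand[:, 1], 0.0)))
            band = edl_band + 2.0
            near_wall = (
                (cand[:, 1] > -band)
                & (cand[:, 0] > rin - band)
                & (cand[:, 0] < rin + geom.wall_thickness_orifice + band)
            )
            near_tip = (
                np.abs(cand[:, 1]) < sz.mid_band
            ) & (cand[:, 0] < geom.outer_radius(0.0) + band)
            near_chain = (
                (cand[:, 1] > z_chain_lo - 3.0)
                & (cand[:, 1] < z_chain_hi + 3.0)
                & (cand[:, 0] < 6.0)
            ) if spheroids else np.zeros(len(cand), dtype=bool)
            in_bore = (cand[:, 1] > 0.0) & (cand[:, 0] < rin)
            cand = cand[near_wall | near_tip | near_chain | in_bore]
        if len(cand) == 0:
            continue
        hloc = size_field(cand)
        upper = levels[k - 1] if k else math.inf
        cand = cand[(hloc >= pitch) & (hloc < upper)]
        if len(cand):
            interior.append(cand)
    ipts = np.concatenate(interior) if interior else np.empty((0, 2))
    # drop interior points hugging boundaries or inside the protein chain
    if len(ipts):
        btree = cKDTree(bpts)
        d_b, _ = btree.query(ipts)
        hloc = size_field(ipts)
        keep = d_b > 0.65 * hloc
        keep &= ~_inside_obstacle(ipts[:, 0], ipts[:, 1], spheroids, necks)
        keep &= (ipts[:, 0] > 0.0) & (ipts[:, 0] < W)
        keep &= (ipts[:, 1] > -W) & (ipts[:, 1] < W)
        ipts = ipts[keep]

    points = np.concatenate([bpts, ipts])

    # --- triangulate and classify -----------------------------------------
    tri = Delaunay(points)
    cells = tri.simplices
    cent = points[cells].mean(axis=1)
    in_prot = _inside_obstacle(cent[:, 0], cent[:, 1], spheroids, necks)
    in_glass = _in_glass(cent[:, 0], cent[:, 1], geom)
    # guard against degenerate (zero-area) triangles
    v1 = points[cells[:, 1]] - points[cells[:, 0]]
    v2 = points[cells[:, 2]] - points[cells[:, 0]]
    area2 = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    ok = np.abs(area2) > 1e-12
    keep = ok & ~in_prot
    cells = cells[keep]
    labels = np.where(in_glass[keep], GLASS, ELECTROLYTE).astype(np.int8)

    edges = _tag_edges(points, cells, labels, domain, prot_dense, wall_pts, necks)

    # drop nodes not referenced by any kept cell
    used = np.unique(cells)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    points = points[used]
    cells = remap[cells]
    edges = {t: remap[e] for t, e in edges.items()}

    return Mesh(
        points=points,
        triangles=cells,
        labels=labels,
        edges=edges,
        refinement=refinement,
        domain=domain,
        sizing=sz,
    )


def _tag_edges(points, cells, labels, domain, prot_dense, wall_pts, necks):
    """Extract and classify boundary / interface edges."""
    W = domain.window_half_extent
    geom = domain.geometry

    e_all = np.concatenate([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]])
    lab_all = np.tile(labels, 3)
    key = np.sort(e_all, axis=1)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key = key[order]
    lab_all = lab_all[order]
    uniq, start, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )

    boundary_edges = uniq[counts == 1]
    # interface: appears twice with different labels
    dup = uniq[counts == 2]
    dup_start = start[counts == 2]
    if len(dup):
        l0 = lab_all[dup_start]
        l1 = lab_all[dup_start + 1]
        interface = dup[l0 != l1]
    else:
        interface = np.empty((0, 2), dtype=int)

    tags: dict[str, list] = {}

    def add(tag, edge):
        tags.setdefault(tag, []).append(edge)

    for e in interface:
        add("glass_wall", e)

    if len(boundary_edges):
        mids = 0.5 * (points[boundary_edges[:, 0]] + points[boundary_edges[:, 1]])
        # candidate feature distances
        d_axis = mids[:, 0]
        d_bottom = np.abs(mids[:, 1] + W)
        d_side = np.abs(mids[:, 0] - W)
        d_top = np.abs(mids[:, 1] - W)
        d_wall = cKDTree(wall_pts).query(mids)[0] if len(wall_pts) else np.full(len(mids), np.inf)
        d_prot = np.full((len(mids), max(len(prot_dense), 1)), np.inf)
        for k, pts in enumerate(prot_dense):
            d_prot[:, k] = cKDTree(pts).query(mids)[0]
        for zc, d, rn in necks:
            d_neck = np.hypot(np.maximum(np.abs(mids[:, 1] - zc) - d, 0.0),
                              mids[:, 0] - rn)
            # necks belong to the nearest spheroid surface of the pair
            if len(prot_dense):
                col = np.argmin(d_prot, axis=1)
                better = d_neck < d_prot[np.arange(len(mids)), col]
                d_prot[better, col[better]] = d_neck[better]

        stack = [d_axis, d_bottom, d_side, d_top, d_wall]
        names = ["axis", "bath_far", "bath_far", "top", "glass_wall"]
        for k in range(len(prot_dense)):
            stack.append(d_prot[:, k])
            names.append(f"protein_surface_{k}")
        dist = np.column_stack(stack)
        choice = np.argmin(dist, axis=1)
        r_in_top = geom.inner_radius(W)
        r_out_top = geom.outer_radius(W)
        for i, e in enumerate(boundary_edges):
            tag = names[choice[i]]
            if tag == "top":
                r = mids[i, 0]
                if r < r_in_top:
                    tag = "pipette_top"
                elif r <= r_out_top:
                    tag = "glass_top"
                else:
                    tag = "bath_far"
            add(tag, e)

    return {t: np.asarray(v, dtype=int) for t, v in tags.items()}
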