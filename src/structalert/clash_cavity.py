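"""Local clash scoring and dual-probe grid cavity volumes.

The clash score counts non-bonded heavy-atom pairs whose van-der-Waals
spheres overlap by at least 0.4 Å, per 1000 atoms, restricted to atoms within
20 Å of the variant residue's Cα.  It is computed without adding hydrogens;
numerical agreement with MolProbity's hydrogen-aware dot-surface score is
deliberately not claimed — only the threshold semantics (score ≥ 30, increase
≥ 18) are used downstream.

Cavity volume uses the dual-probe grid method: a grid point belongs to a
cavity when a small probe (1.4 Å) fits there but the point is not reachable
by the bulk solvent defined by a large probe (4.0 Å).  Surface pockets count
as cavities.  Volumes are connected-component voxel counts × grid³
(26-neighbour connectivity).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import DEFAULT_CONFIG, RunConfig
from .structure_io import Residue, Structure
from .geometry import vdw_radius

__all__ = ["ClashResult", "CavityResult", "local_clash_score", "clash_feature",
           "cavity_volumes", "cavity_feature"]


@dataclasses.dataclass
class ClashResult:
    score: float                                   # clashes per 1000 local atoms
    clashes: list[tuple[tuple, str, tuple, str, float]]  # (res, atom, res, atom, overlap)
    n_local_atoms: int


@dataclasses.dataclass
class CavityResult:
    volumes: list[float]    # per connected cavity, Å^3
    grid: float

    @property
    def total(self) -> float:
        return float(sum(self.volumes))


def _heavy(s: Structure):
    recs = []
    for res, atom in s.atoms():
        if atom.element.upper() in ("H", "D"):
            continue
        recs.append((res, atom))
    return recs


def _bonded_exclusion(res_a: Residue, atom_a, res_b: Residue, atom_b,
                      chain_pos: dict[tuple, int]) -> bool:
    """True when the pair is covalently bonded or 1-3 and must not count as a clash."""
    if res_a is res_b:
        return True  # all intra-residue pairs excluded (≤ 1-4 in a side chain)
    ia, ib = chain_pos.get(res_a.res_id), chain_pos.get(res_b.res_id)
    if ia is None or ib is None or res_a.chain_id != res_b.chain_id:
        # disulfide partner exclusion handled by caller
        return False
    if abs(ia - ib) == 1:
        # backbone-backbone contacts across a peptide bond are all within
        # 1-4 connectivity; with hydrogen-free radii they would register as
        # systematic false clashes (e.g. C(i)-C(i+1) at ~3.0 Å), so the whole
        # adjacent backbone-backbone set is excluded
        backbone = ("N", "CA", "C", "O")
        if atom_a.name in backbone and atom_b.name in backbone:
            return True
    return False


def local_clash_score(s: Structure, variant_res: Residue,
                      config: RunConfig = DEFAULT_CONFIG) -> ClashResult:
    """Clashes per 1000 atoms among heavy atoms within 20 Å of the variant Cα."""
    ca = variant_res.atom("CA")
    if ca is None:
        raise ValueError(f"{variant_res.label()} has no CA atom")
    recs = _heavy(s)
    coords = np.array([a.coord for _, a in recs])
    local_idx = np.nonzero(np.linalg.norm(coords - ca.coord, axis=1)
                           <= config.clash_local_radius)[0]
    local = [recs[i] for i in local_idx]
    n_local = len(local)
    if n_local == 0:
        return ClashResult(0.0, [], 0)

    chain_pos: dict[tuple, int] = {}
    for cid in s.chain_ids():
        k = 0
        for res in s.chains[cid]:
            if res.het or res.one_letter is None:
                continue
            chain_pos[res.res_id] = k
            k += 1

    # disulfide partners excluded from clash counting
    from .interactions import find_disulfides
    ss_pairs = {frozenset((d.res_a, d.res_b)) for d in
                find_disulfides(s, config.disulfide_cutoff)}

    lc = np.array([a.coord for _, a in local])
    lr = np.array([vdw_radius(a.element) for _, a in local])
    tree = cKDTree(lc)
    pairs = tree.query_pairs(float(2 * lr.max()), output_type="ndarray")
    clashes = []
    for i, j in pairs:
        res_a, atom_a = local[i]
        res_b, atom_b = local[j]
        d = float(np.linalg.norm(lc[i] - lc[j]))
        overlap = lr[i] + lr[j] - d
        if overlap < config.clash_overlap:
            continue
        if _bonded_exclusion(res_a, atom_a, res_b, atom_b, chain_pos):
            continue
        if frozenset((res_a.res_id, res_b.res_id)) in ss_pairs \
                and {atom_a.name, atom_b.name} <= {"SG", "CB"}:
            continue
        clashes.append((res_a.res_id, atom_a.name, res_b.res_id, atom_b.name,
                        float(overlap)))
    score = 1000.0 * len(clashes) / n_local
    return ClashResult(score, clashes, n_local)


def clash_feature(wt: ClashResult, mut: ClashResult,
                  config: RunConfig = DEFAULT_CONFIG) -> bool:
    """Damaging iff the mutant local score reaches 30 and the increase is ≥ 18."""
    return (mut.score >= config.clash_score_min
            and (mut.score - wt.score) >= config.clash_delta_min)


def cavity_volumes(s: Structure, probe_in: float | None = None,
                   probe_out: float | None = None,
                   grid: float | None = None,
                   config: RunConfig = DEFAULT_CONFIG) -> CavityResult:
    """Dual-probe grid cavity volumes (includes surface pockets)."""
    probe_in = config.cavity_probe_in if probe_in is None else probe_in
    probe_out = config.cavity_probe_out if probe_out is None else probe_out
    grid = config.cavity_grid if grid is None else grid

    recs = _heavy(s)
    if not recs:
        raise ValueError("structure has no heavy atoms")
    coords = np.array([a.coord for _, a in recs])
    radii = np.array([vdw_radius(a.element) for _, a in recs])

    pad = probe_out + float(radii.max()) + 2.0 * grid
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    # grid anchored at a fixed offset from the structure's bounding box
    shape = np.ceil((hi - lo) / grid).astype(int) + 1

    axes = [lo[k] + grid * np.arange(shape[k]) for k in range(3)]

    # three masks per grid point, stamped atom by atom:
    #   occupied  – inside an atom's van-der-Waals sphere
    #   free_in   – a small-probe centre fits (distance > r + probe_in)
    #   free_out  – a large-probe centre fits (distance > r + probe_out)
    occupied = np.zeros(shape, dtype=bool)
    free_in = np.ones(shape, dtype=bool)
    free_out = np.ones(shape, dtype=bool)
    for c, r in zip(coords, radii):
        for mask, reach, sense in ((occupied, r, True),
                                   (free_in, r + probe_in, False),
                                   (free_out, r + probe_out, False)):
            i0 = np.maximum(((c - reach - lo) / grid).astype(int), 0)
            i1 = np.minimum(((c + reach - lo) / grid).astype(int) + 2, shape)
            if np.any(i0 >= i1):
                continue
            sub = [axes[k][i0[k]:i1[k]] for k in range(3)]
            dx = sub[0][:, None, None] - c[0]
            dy = sub[1][None, :, None] - c[1]
            dz = sub[2][None, None, :] - c[2]
            inside = dx * dx + dy * dy + dz * dz < reach * reach
            view = mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
            if sense:
                view |= inside
            else:
                view &= ~inside

    # bulk solvent: large-probe-accessible region connected to the boundary,
    # dilated by the large-probe radius (space its surface can sweep)
    structure26 = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(free_out, structure=structure26)
    boundary_labels = set(np.unique(labels[0, :, :])) | set(np.unique(labels[-1, :, :])) \
        | set(np.unique(labels[:, 0, :])) | set(np.unique(labels[:, -1, :])) \
        | set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
    boundary_labels.discard(0)
    outside_centers = np.isin(labels, sorted(boundary_labels))
    dist_to_outside = ndimage.distance_transform_edt(~outside_centers,
                                                     sampling=(grid, grid, grid))
    bulk = dist_to_outside <= probe_out

    # candidate void space: outside the vdW volume, not reachable by bulk
    # solvent.  A component counts as a cavity only if the small probe fits
    # somewhere inside it (mere packing crevices are not cavities); the volume
    # of a detected cavity is its full vdW-free space, with sub-voxel
    # supersampling of boundary voxels to suppress grid quantization.
    void = ~occupied & ~bulk
    labels, n = ndimage.label(void, structure=structure26)
    volumes = []
    if n:
        probe_ok = [int(l) for l in np.unique(labels[free_in & void]) if l != 0]
        radius_trees = [(float(r), cKDTree(coords[radii == r]))
                        for r in np.unique(radii)]

        def occupied_fraction(pts: np.ndarray) -> np.ndarray:
            inside = np.zeros(len(pts), dtype=bool)
            for r, tree in radius_trees:
                counts = tree.query_ball_point(pts, r, return_length=True)
                inside |= counts > 0
            return inside

        for lab in probe_ok:
            comp = labels == lab
            # voxels fully interior to the component count as whole voxels
            eroded = ndimage.binary_erosion(comp, structure=np.ones((3, 3, 3), bool))
            n_interior = int(eroded.sum())
            # boundary band: non-interior component voxels plus adjacent
            # occupied voxels (the surface slab the centre test misses)
            shell = comp & ~eroded
            near = ndimage.binary_dilation(comp, structure=structure26) & occupied & ~bulk
            band_idx = np.argwhere(shell | near)
            frac_sum = 0.0
            if len(band_idx):
                centres = lo + band_idx * grid
                offs = (np.array(np.meshgrid([-1, 1], [-1, 1], [-1, 1],
                                             indexing="ij")).reshape(3, -1).T
                        * (grid / 4.0))
                pts = (centres[:, None, :] + offs[None, :, :]).reshape(-1, 3)
                inside = occupied_fraction(pts)
                frac_sum = float((~inside).reshape(len(band_idx), -1).mean(axis=1).sum())
            volumes.append((n_interior + frac_sum) * grid ** 3)
    return CavityResult(sorted(volumes, reverse=True), grid)


def _ball_vox(radius: float, grid: float) -> np.ndarray:
    """Spherical structuring element of physical ``radius`` on a voxel grid."""
    r_vox = int(np.ceil(radius / grid))
    ax = np.arange(-r_vox, r_vox + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    r_frac = radius / grid
    return dx * dx + dy * dy + dz * dz <= r_frac * r_frac


def cavity_feature(wt: CavityResult, mut: CavityResult,
                   config: RunConfig = DEFAULT_CONFIG) -> bool:
    """Damaging iff total cavity volume changes by ≥ 70 Å^3."""
    return abs(mut.total - wt.total) >= config.cavity_delta
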