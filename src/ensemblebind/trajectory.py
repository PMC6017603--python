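"""Geometry core for conformational-ensemble analysis.

Implements rigid-body superposition (Kabsch), RMSD/RMSF, Shrake–Rupley
solvent-accessible surface area with a deterministic golden-spiral sphere
lattice, per-frame hydrophobic-surface series, time-equidistant frame
subsampling, and leader (GROMOS-style) conformational clustering with
representative-frame extraction.

All distances are Å; frame indices in results are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, GeometryError
from .io_formats import Structure, Trajectory

#: van der Waals radii (Å), Bondi-like; overridable per call.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}

#: Residues counted as hydrophobic in surface analyses (overridable).
DEFAULT_HYDROPHOBIC = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
)


# ---------------------------------------------------------------------------
# superposition / RMSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Superposition:
    """Optimal rigid transform mapping mobile onto reference.

    ``apply(x)`` computes ``x @ rotation.T + translation``; ``rmsd_after``
    is the RMSD over the fitted selection after the transform.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_after: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def _check_selection(coords: np.ndarray, what: str) -> None:
    if coords.shape[0] < 3:
        raise GeometryError(f"{what}: need at least 3 atoms for superposition")
    centered = coords - coords.mean(axis=0)
    # collinear points leave rank <= 1 after centering
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError(f"{what}: selection is collinear (degenerate geometry)")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> Superposition:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    The rotation is the Kabsch solution (SVD of the covariance of the centred
    selections) with the determinant sign corrected so reflections are
    excluded (det = +1).

    Parameters
    ----------
    mobile, reference : (n, 3) arrays
    selection : optional index array; the transform is fitted on this subset
        (both structures) but applies to all coordinates.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    a = mobile if selection is None else mobile[selection]
    b = reference if selection is None else reference[selection]
    if a.shape != b.shape:
        raise GeometryError(f"selection size mismatch: {a.shape[0]} vs {b.shape[0]}")
    _check_selection(a, "mobile")
    _check_selection(b, "reference")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb - rot @ ca
    fitted = a @ rot.T + trans
    rmsd_after = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd_after=rmsd_after)


def rmsd(
    a: np.ndarray,
    b: np.ndarray,
    selection: np.ndarray | None = None,
    superpose: bool = False,
) -> float:
    """Root-mean-square deviation (Å) between two coordinate sets.

    With ``superpose=True`` the optimal rigid transform is removed first,
    which can only lower the value.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if selection is not None:
        a, b = a[selection], b[selection]
    if a.shape != b.shape:
        raise AnalysisError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if superpose:
        return kabsch_superpose(a, b).rmsd_after
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _batch_superpose(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superpose every frame of ``frames`` (m, n, 3) onto ``reference`` (n, 3),
    fitting and applying on all atoms. Returns the transformed stack."""
    ref_c = reference - reference.mean(axis=0)
    centred = frames - frames.mean(axis=1, keepdims=True)
    h = np.einsum("mni,nj->mij", centred, ref_c)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("mij,mjk->mik", vt.transpose(0, 2, 1), u.transpose(0, 2, 1))))
    corr = np.zeros_like(h)
    corr[:, 0, 0] = 1.0
    corr[:, 1, 1] = 1.0
    corr[:, 2, 2] = d
    rot = np.einsum("mij,mjk,mkl->mil", vt.transpose(0, 2, 1), corr, u.transpose(0, 2, 1))
    out = np.einsum("mni,mji->mnj", centred, rot) + reference.mean(axis=0)
    return out


def pairwise_rmsd_matrix(
    coords: np.ndarray,
    block_pairs: int = 2_000_000,
) -> np.ndarray:
    """Pairwise minimum (superposed) RMSD over a coordinate stack (m, n, 3).

    Each pair is optimally superposed on the given atoms. Work proceeds in
    blocks of at most ``block_pairs`` frame pairs so memory stays bounded at
    roughly ``block_pairs × 9`` floats for the covariance stack.
    """
    coords = np.asarray(coords, float)
    m, n, _ = coords.shape
    centred = coords - coords.mean(axis=1, keepdims=True)
    sq = np.einsum("mni,mni->m", centred, centred)  # per-frame sum of squares
    out = np.zeros((m, m), dtype=float)
    ii, jj = np.triu_indices(m, k=1)
    for start in range(0, ii.size, block_pairs):
        bi = ii[start : start + block_pairs]
        bj = jj[start : start + block_pairs]
        h = np.einsum("pni,pnj->pij", centred[bi], centred[bj])
        s = np.linalg.svd(h, compute_uv=False)
        det = np.linalg.det(h)
        # Kabsch: optimal trace is s0 + s1 ± s2, minus sign when det < 0
        tr = s[:, 0] + s[:, 1] + np.where(det < 0, -s[:, 2], s[:, 2])
        msd = np.maximum(sq[bi] + sq[bj] - 2.0 * tr, 0.0) / n
        out[bi, bj] = out[bj, bi] = np.sqrt(msd)
    return out


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

@dataclass
class RmsfProfile:
    """Per-residue root-mean-square fluctuation (Å) over an ensemble."""

    residue_ids: np.ndarray
    rmsf_A: np.ndarray
    selection: str = "backbone"


def rmsf(traj: Trajectory, selection: np.ndarray | None = None) -> RmsfProfile:
    """Per-residue RMSF of the selected atoms (default: backbone N, CA, C, O).

    Frames are superposed onto the ensemble-average structure; the average is
    refined once (superpose → re-average → re-superpose) so the reference is
    self-consistent. The residue value is the RMS over its selected atoms of
    the per-atom fluctuation √⟨|r − ⟨r⟩|²⟩.
    """
    if traj.n_frames < 2:
        raise AnalysisError("RMSF requires at least 2 frames")
    sel = traj.topology.backbone_indices() if selection is None else np.asarray(selection, int)
    if sel.size == 0:
        raise AnalysisError("empty atom selection for RMSF")
    frames = traj.xyz[:, sel, :]
    mean = frames.mean(axis=0)
    for _ in range(2):
        frames = _batch_superpose(frames, mean)
        mean = frames.mean(axis=0)
    msf_atom = np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0)  # per atom
    resids = traj.topology.residue_ids()[sel]
    uniq = np.unique(resids)
    per_res = np.array([np.sqrt(np.mean(msf_atom[resids == r])) for r in uniq])
    return RmsfProfile(residue_ids=uniq, rmsf_A=per_res)


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA
# ---------------------------------------------------------------------------

@dataclass
class SasaResult:
    """Solvent-accessible surface area decomposition (Å²)."""

    per_atom_A2: np.ndarray
    residue_ids: np.ndarray
    per_residue_A2: np.ndarray
    total_A2: float
    probe_radius_A: float
    n_points: int


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    struct: Structure,
    n_points: int = 1200,
    probe_radius: float = 1.4,
    radii: dict[str, float] | None = None,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom carries a deterministic golden-spiral lattice of ``n_points``
    points on its solvent-expanded sphere (r_atom + probe); a point counts as
    accessible iff it lies outside every other atom's expanded sphere. The
    atom's area is 4π(r+probe)² times its accessible fraction; residue areas
    are sums over their atoms.
    """
    if n_points < 1:
        raise AnalysisError("n_points must be >= 1")
    radii = DEFAULT_RADII if radii is None else radii
    elements = [a.element.upper() for a in struct.atoms]
    missing = sorted({e for e in elements if e not in radii})
    if missing:
        raise AnalysisError(f"no van der Waals radius for element(s): {', '.join(missing)}")
    coords = struct.coords()
    rads = np.array([radii[e] for e in elements]) + probe_radius
    n = coords.shape[0]
    sphere = _golden_spiral(n_points)
    areas = np.empty(n)
    # neighbour prefilter: atom j can occlude i only if centres are closer
    # than r_i + r_j (both already probe-expanded)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    for i in range(n):
        pts = coords[i] + rads[i] * sphere
        cutoff2 = (rads[i] + rads) ** 2
        nbr = np.where((d2[i] < cutoff2) & (np.arange(n) != i))[0]
        if nbr.size:
            dist2 = np.sum((pts[:, None, :] - coords[nbr][None, :, :]) ** 2, axis=2)
            buried = np.any(dist2 < rads[nbr] ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * rads[i] ** 2 * frac
    resids = struct.residue_ids()
    uniq = np.unique(resids)
    per_res = np.array([areas[resids == r].sum() for r in uniq])
    return SasaResult(
        per_atom_A2=areas,
        residue_ids=uniq,
        per_residue_A2=per_res,
        total_A2=float(areas.sum()),
        probe_radius_A=probe_radius,
        n_points=n_points,
    )


# ---------------------------------------------------------------------------
# hydrophobic-surface series
# ---------------------------------------------------------------------------

def hydrophobic_surface_series(
    traj: Trajectory,
    region_residue_ids: set[int] | None = None,
    hydrophobic_residues: frozenset[str] | set[str] = DEFAULT_HYDROPHOBIC,
    n_points: int = 1200,
    probe_radius: float = 1.4,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-frame exposed hydrophobic surface (Å²) within a region.

    For each frame the full-structure SASA is computed and summed over
    residues that are (a) in the hydrophobic class and (b) inside the region
    (``region_residue_ids``; ``None`` means the whole protein). The region is
    a required scientific choice for pocket-scale analyses — whole-protein
    hydrophobic area is on a much larger scale than a single patch.
    """
    if region_residue_ids is not None and len(region_residue_ids) == 0:
        raise AnalysisError("empty region selection for hydrophobic surface series")
    topo = traj.topology
    res_names = {a.residue_id: a.residue_name for a in topo.atoms}
    region = set(res_names) if region_residue_ids is None else set(region_residue_ids)
    targets = {r for r in region if res_names.get(r) in hydrophobic_residues}
    out = np.zeros(traj.n_frames)
    for k in range(traj.n_frames):
        sasa = shrake_rupley(
            topo.with_coords(traj.xyz[k]), n_points=n_points,
            probe_radius=probe_radius, radii=radii,
        )
        mask = np.isin(sasa.residue_ids, sorted(targets))
        out[k] = sasa.per_residue_A2[mask].sum()
    return out


def max_hydrophobic_frame(series: np.ndarray) -> tuple[int, float]:
    """(1-based frame index, area) of the maximum; ties -> lowest frame."""
    series = np.asarray(series, float)
    if series.size == 0:
        raise AnalysisError("empty hydrophobic-surface series")
    i = int(np.argmax(series))  # argmax returns the first maximum
    return i + 1, float(series[i])


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def subsample_frames(
    traj: Trajectory,
    n_equidistant: int | None = None,
    stride: int | None = None,
) -> Trajectory:
    """Time-equidistant subsampling, always keeping the first frame.

    Exactly one of ``n_equidistant`` or ``stride`` must be given. With a
    stride ``s`` the selected 1-based frames are 1, 1+s, 1+2s, …; with
    ``n_equidistant`` the stride is the largest integer giving at least that
    many frames, truncated to exactly ``n_equidistant``. The timestep
    metadata is scaled by the effective stride.
    """
    if (n_equidistant is None) == (stride is None):
        raise AnalysisError("give exactly one of n_equidistant or stride")
    m = traj.n_frames
    if stride is not None:
        if stride < 1:
            raise AnalysisError("stride must be >= 1")
        idx = np.arange(0, m, stride)
        eff = stride
    else:
        if not 1 <= n_equidistant <= m:
            raise AnalysisError(f"n_equidistant={n_equidistant} outside 1..{m}")
        eff = max(m // n_equidistant, 1)
        idx = np.arange(0, m, eff)[:n_equidistant]
    return Trajectory(
        topology=traj.topology,
        xyz=traj.xyz[idx],
        timestep_ps=traj.timestep_ps * eff,
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Leader-clustering partition of trajectory frames.

    ``labels`` holds a 0-based cluster id per frame, clusters ordered by
    occupancy descending; ``centroid_frames`` are 1-based frame indices.
    """

    labels: np.ndarray
    centroid_frames: np.ndarray
    occupancies: np.ndarray
    cutoff_A: float

    @property
    def n_clusters(self) -> int:
        return int(self.centroid_frames.size)


def cluster_conformations(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    cutoff_A: float = 2.0,
    block_pairs: int = 2_000_000,
) -> ClusterAssignment:
    """Leader (GROMOS-style) clustering on pairwise superposed RMSD.

    Repeatedly the unassigned frame with the most unassigned neighbours
    within ``cutoff_A`` becomes a centroid and claims those neighbours; ties
    go to the lowest frame index. Deterministic given the frame order.
    """
    sel = traj.topology.backbone_indices() if selection is None else np.asarray(selection, int)
    if sel.size == 0:
        raise AnalysisError("empty atom selection for clustering")
    dmat = pairwise_rmsd_matrix(traj.xyz[:, sel, :], block_pairs=block_pairs)
    m = traj.n_frames
    within = dmat <= cutoff_A
    np.fill_diagonal(within, True)
    unassigned = np.ones(m, dtype=bool)
    labels = np.full(m, -1, dtype=int)
    centroids: list[int] = []
    while unassigned.any():
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        c = int(np.argmax(counts))  # first maximum -> lowest frame index
        members = np.where(within[c] & unassigned)[0]
        labels[members] = len(centroids)
        centroids.append(c)
        unassigned[members] = False
    occ = np.array([(labels == k).mean() for k in range(len(centroids))])
    order = np.lexsort((centroids, -occ))  # occupancy desc, centroid index asc
    remap = np.empty(len(centroids), dtype=int)
    remap[order] = np.arange(len(centroids))
    return ClusterAssignment(
        labels=remap[labels],
        centroid_frames=np.asarray(centroids, int)[order] + 1,
        occupancies=occ[order],
        cutoff_A=cutoff_A,
    )


def representative_conformation(assignment: ClusterAssignment) -> int:
    """1-based frame index of the most-populated cluster's centroid."""
    if assignment.n_clusters < 1:
        raise AnalysisError("assignment has no clusters")
    return int(assignment.centroid_frames[0])
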