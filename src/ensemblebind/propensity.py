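"""Inverse-docking binding propensity over a conformational ensemble.

The workflow mirrors ensemble ("inverse") docking: a ligand is docked — or
externally produced poses are ingested — against many conformations of one
protein; per frame the best pose is compared with a reference pose (the
stable pose from the bound-complex dynamics), poses are grouped by their
distance to that reference, and the binding propensity is the fraction of
frames whose best pose is both geometrically close to the reference and
energetically favourable. That fraction is the "pocket time availability":
how often the ensemble presents a binding-competent pocket.

The built-in :func:`toy_dock` is a deliberately simple rigid-body grid
docking engine with a transparent scoring function (soft-sphere clash
penalty, distance-weighted contact reward, geometric H-bond bonus). It
exists so the pipeline is exercisable end to end and bit-reproducible;
externally produced pose files plug in through the same :class:`PoseSet`
container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, GeometryError, TopologyError
from .io_formats import Pose, PoseSet, Structure, Trajectory
from .trajectory import kabsch_superpose

# hydrogen-bond capable protein atoms, by residue template
_PROTEIN_DONORS: dict[str, set[str]] = {
    "*": {"N"},
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "TRP": {"NE1"},
    "HIS": {"ND1", "NE2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_PROTEIN_ACCEPTORS: dict[str, set[str]] = {
    "*": {"O", "OXT"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
_AROMATIC_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2"],
            ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
}

_BOND_CUTOFF_A = 1.8  # connectivity inferred from interatomic distance


@dataclass(frozen=True)
class Pocket:
    """A binding sub-pocket: a labelled set of residue ids on one topology."""

    label: str
    residue_ids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.residue_ids:
            raise AnalysisError(f"pocket {self.label!r} has an empty residue set")

    def atom_indices(self, struct: Structure) -> np.ndarray:
        idx = struct.select(residue_ids=self.residue_ids)
        if idx.size == 0:
            raise AnalysisError(
                f"pocket {self.label!r}: none of its residues exist in the topology"
            )
        return idx

    def backbone_indices(self, struct: Structure) -> np.ndarray:
        return struct.select(names=("N", "CA", "C", "O"), residue_ids=self.residue_ids)

    def centroid(self, struct: Structure) -> np.ndarray:
        return struct.coords()[self.atom_indices(struct)].mean(axis=0)


@dataclass
class PoseGroup:
    """Poses binned together by distance to the reference pose."""

    bin_lo_A: float
    bin_hi_A: float
    frame_indices: list[int]
    mean_score: float
    mean_distance_A: float

    @property
    def n(self) -> int:
        return len(self.frame_indices)


@dataclass
class PropensityResult:
    """Fraction of ensemble frames competent to bind a ligand."""

    ligand: str
    n_frames: int
    n_bound: int
    propensity: float
    distance_cutoff_A: float
    score_threshold: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.propensity <= 1.0


@dataclass(frozen=True)
class Contact:
    kind: str  # "hbond" | "pipi"
    ligand_atoms: tuple[str, ...]
    protein_residue: tuple[int, str]
    distance_A: float
    angle_deg: float | None = None


@dataclass
class ContactReport:
    contacts: list[Contact]

    def of_kind(self, kind: str) -> list[Contact]:
        return [c for c in self.contacts if c.kind == kind]


# ---------------------------------------------------------------------------
# toy docking engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DockParams:
    """Scoring coefficients for the toy rigid-body engine (kcal/mol-like)."""

    clash_dist_A: float = 2.6
    clash_weight: float = 10.0
    contact_dist_A: float = 4.5
    contact_weight: float = 0.4
    hbond_dist_A: float = 3.5
    hbond_bonus: float = 1.0


def score_pose(
    frame: Structure,
    ligand: Structure,
    ligand_xyz: np.ndarray,
    params: DockParams = DockParams(),
) -> float:
    """Toy interaction score (lower = better) for a rigid ligand placement.

    clash penalty  +w_clash · Σ (d_clash − d)²  over pairs closer than d_clash
    contact reward −w_contact · Σ (1 − d/d_contact)  over pairs within d_contact
    H-bond bonus   −b · (# donor/acceptor heavy-atom pairs within d_hb)

    Invariant under any global rigid motion applied jointly to the frame and
    the placement, since only interatomic distances enter.
    """
    p = frame.coords()[frame.select(heavy=True)]
    l = np.asarray(ligand_xyz, float)[ligand.select(heavy=True)]
    d = np.sqrt(np.sum((l[:, None, :] - p[None, :, :]) ** 2, axis=2))
    clash = d[d < params.clash_dist_A]
    score = params.clash_weight * float(np.sum((params.clash_dist_A - clash) ** 2))
    contact = d[(d >= params.clash_dist_A) & (d < params.contact_dist_A)]
    score -= params.contact_weight * float(np.sum(1.0 - contact / params.contact_dist_A))
    # crude H-bond term: polar ligand atoms near polar protein atoms
    pol_p = [i for i in frame.select(heavy=True) if frame.atoms[i].element.upper() in ("N", "O")]
    pol_l = [i for i, a in enumerate(ligand.atoms) if a.element.upper() in ("N", "O")]
    if pol_p and pol_l:
        dd = np.sqrt(
            np.sum(
                (np.asarray(ligand_xyz, float)[pol_l][:, None, :] - frame.coords()[pol_p][None, :, :]) ** 2,
                axis=2,
            )
        )
        score -= params.hbond_bonus * float(np.sum((dd >= params.clash_dist_A) & (dd <= params.hbond_dist_A)))
    return score


def _orientation_set(n: int, seed: int) -> np.ndarray:
    """n rotation matrices: identity plus seeded quasi-random orientations."""
    rng = np.random.default_rng(seed)
    mats = [np.eye(3)]
    while len(mats) < n:
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        mats.append(
            np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                    [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                    [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
                ]
            )
        )
    return np.stack(mats[:n])


def toy_dock(
    frame: Structure,
    ligand: Structure,
    pocket: Pocket,
    frame_index: int = 1,
    grid_step_A: float = 1.0,
    n_orientations: int = 8,
    seed: int = 0,
    top_k: int = 5,
    params: DockParams = DockParams(),
) -> PoseSet:
    """Deterministic rigid-body grid docking inside a pocket's bounding box.

    Ligand-centroid translations on a cubic grid spanning the pocket bounding
    box are combined with ``n_orientations`` seeded rigid orientations; every
    placement is scored with :func:`score_pose` and the best ``top_k`` poses
    are returned sorted ascending by score (ties by placement order).
    """
    if ligand.n_atoms < 1:
        raise AnalysisError("ligand must contain at least one atom")
    pocket_xyz = frame.coords()[pocket.atom_indices(frame)]
    lo, hi = pocket_xyz.min(axis=0), pocket_xyz.max(axis=0)
    axes = [np.arange(lo[k], hi[k] + 1e-9, grid_step_A) for k in range(3)]
    if any(a.size == 0 for a in axes):
        raise GeometryError(f"pocket {pocket.label!r}: empty docking grid")
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    lig0 = ligand.coords()
    lig0 = lig0 - lig0.mean(axis=0)
    rots = _orientation_set(n_orientations, seed)
    scored: list[tuple[float, int, np.ndarray]] = []
    order = 0
    for rot in rots:
        lig_r = lig0 @ rot.T
        for c in centers:
            xyz = lig_r + c
            scored.append((score_pose(frame, ligand, xyz, params), order, xyz))
            order += 1
    scored.sort(key=lambda t: (t[0], t[1]))
    poses = [
        Pose(frame_index=frame_index, model_index=m + 1, xyz=xyz, score=s)
        for m, (s, _o, xyz) in enumerate(scored[:top_k])
    ]
    return PoseSet(ligand_topology=ligand, poses=poses)


# ---------------------------------------------------------------------------
# pose geometry
# ---------------------------------------------------------------------------

def pose_distance(
    pose_xyz: np.ndarray,
    reference_xyz: np.ndarray,
    frame: Structure | np.ndarray,
    reference_frame: Structure | np.ndarray,
    pocket: Pocket,
    topology: Structure | None = None,
    heavy_mask: np.ndarray | None = None,
) -> float:
    """Ligand heavy-atom RMSD to the reference pose after frame alignment.

    The frame carrying the pose is superposed onto the reference frame using
    the pocket's backbone atoms; the same rigid transform is applied to the
    pose (no ligand re-fitting), and the plain heavy-atom RMSD to the
    reference pose is returned. This captures both translational and
    orientational departure from the reference binding mode while being
    insensitive to global tumbling of the protein.
    """
    pose_xyz = np.asarray(pose_xyz, float)
    reference_xyz = np.asarray(reference_xyz, float)
    if pose_xyz.shape != reference_xyz.shape:
        raise TopologyError(
            f"pose/reference atom mismatch: {pose_xyz.shape} vs {reference_xyz.shape}"
        )
    topo = frame if isinstance(frame, Structure) else topology
    if topo is None:
        raise AnalysisError("pass Structure frames or an explicit topology")
    sel = pocket.backbone_indices(topo)
    fx = frame.coords() if isinstance(frame, Structure) else np.asarray(frame, float)
    rx = (
        reference_frame.coords()
        if isinstance(reference_frame, Structure)
        else np.asarray(reference_frame, float)
    )
    sup = kabsch_superpose(fx, rx, selection=sel)
    moved = sup.apply(pose_xyz)
    if heavy_mask is not None:
        moved, reference_xyz = moved[heavy_mask], reference_xyz[heavy_mask]
    return float(np.sqrt(np.mean(np.sum((moved - reference_xyz) ** 2, axis=1))))


def _best_pose_distances(
    pose_set: PoseSet,
    reference_pose: np.ndarray,
    traj: Trajectory,
    reference_frame_xyz: np.ndarray,
    pocket: Pocket,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame best pose: (frame indices, distances to reference, scores).

    Superpositions for all frames are solved in one vectorised batch.
    """
    best = pose_set.best_pose_per_frame()
    if not best:
        raise AnalysisError("pose set is empty")
    frames = np.array(sorted(best), dtype=int)
    sel = pocket.backbone_indices(traj.topology)
    if sel.size < 3:
        raise GeometryError(f"pocket {pocket.label!r}: fewer than 3 backbone atoms")
    heavy = traj_heavy_mask = pose_set.ligand_topology.select(heavy=True)
    ref = np.asarray(reference_pose, float)

    mob = traj.xyz[frames - 1][:, sel, :]
    tgt = np.asarray(reference_frame_xyz, float)[sel]
    tgt_c = tgt - tgt.mean(axis=0)
    cen = mob.mean(axis=1, keepdims=True)
    h = np.einsum("mni,nj->mij", mob - cen, tgt_c)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("mij,mjk->mik", vt.transpose(0, 2, 1), u.transpose(0, 2, 1))))
    corr = np.zeros_like(h)
    corr[:, 0, 0] = corr[:, 1, 1] = 1.0
    corr[:, 2, 2] = d
    rot = np.einsum("mij,mjk,mkl->mil", vt.transpose(0, 2, 1), corr, u.transpose(0, 2, 1))

    poses = np.stack([np.asarray(best[f].xyz, float) for f in frames])
    moved = np.einsum("mni,mji->mnj", poses - cen, rot) + tgt.mean(axis=0)
    diff = moved[:, heavy, :] - ref[heavy]
    dists = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    scores = np.array([best[f].score for f in frames])
    return frames, dists, scores


def group_poses(
    pose_set: PoseSet,
    reference_pose: np.ndarray,
    traj: Trajectory,
    reference_frame_xyz: np.ndarray,
    pocket: Pocket,
    bin_width_A: float = 2.0,
) -> list[PoseGroup]:
    """Bin each frame's best pose by distance to the reference pose.

    Bins are [0, w), [w, 2w), …; each group reports its member frames, mean
    score and mean distance. Groups are disjoint and cover every frame that
    has at least one pose.
    """
    if bin_width_A <= 0:
        raise AnalysisError("bin_width_A must be positive")
    frames, dists, scores = _best_pose_distances(
        pose_set, reference_pose, traj, reference_frame_xyz, pocket
    )
    bins = (dists // bin_width_A).astype(int)
    groups = []
    for b in sorted(set(bins)):
        m = bins == b
        groups.append(
            PoseGroup(
                bin_lo_A=b * bin_width_A,
                bin_hi_A=(b + 1) * bin_width_A,
                frame_indices=[int(f) for f in frames[m]],
                mean_score=float(scores[m].mean()),
                mean_distance_A=float(dists[m].mean()),
            )
        )
    return groups


def binding_propensity(
    pose_set: PoseSet,
    reference_pose: np.ndarray,
    traj: Trajectory,
    reference_frame_xyz: np.ndarray,
    pocket: Pocket,
    distance_cutoff_A: float = 2.0,
    score_threshold: float | None = None,
    ligand_label: str = "",
) -> PropensityResult:
    """Fraction of frames whose best pose reproduces the reference binding mode.

    A frame is binding-competent iff its best (lowest-score) pose lies within
    ``distance_cutoff_A`` of the reference pose (after pocket-backbone frame
    alignment) and its score is at most ``score_threshold``. The default
    threshold is permissive (+infinity → geometry-only); the pipeline default
    sets it to the reference-pose score + 1 kcal/mol.
    """
    frames, dists, scores = _best_pose_distances(
        pose_set, reference_pose, traj, reference_frame_xyz, pocket
    )
    if frames.size == 0:
        raise AnalysisError("no frames with poses")
    thr = np.inf if score_threshold is None else score_threshold
    bound = (dists <= distance_cutoff_A) & (scores <= thr)
    return PropensityResult(
        ligand=ligand_label,
        n_frames=int(frames.size),
        n_bound=int(bound.sum()),
        propensity=float(bound.mean()),
        distance_cutoff_A=distance_cutoff_A,
        score_threshold=float(thr),
    )


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _donor_acceptor(struct: Structure, kind: str) -> list[int]:
    table = _PROTEIN_DONORS if kind == "donor" else _PROTEIN_ACCEPTORS
    out = []
    for i, a in enumerate(struct.atoms):
        if a.hetero:
            continue
        name = a.name.strip()
        if name in table["*"] or name in table.get(a.residue_name, ()):
            out.append(i)
    return out


def _bonded_neighbors(coords: np.ndarray, i: int) -> np.ndarray:
    d = np.sqrt(np.sum((coords - coords[i]) ** 2, axis=1))
    nbr = np.where((d > 1e-6) & (d <= _BOND_CUTOFF_A))[0]
    return nbr


def _ligand_rings(ligand: Structure, xyz: np.ndarray) -> list[np.ndarray]:
    """Planar 5/6-membered rings from distance-inferred connectivity."""
    n = ligand.n_atoms
    heavy = set(ligand.select(heavy=True).tolist())
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        if i not in heavy:
            continue
        for j in _bonded_neighbors(xyz, i):
            if int(j) in heavy:
                adj[i].add(int(j))
    rings: set[frozenset[int]] = set()

    def dfs(start: int, current: int, path: list[int]) -> None:
        if len(path) > 6:
            return
        for nxt in adj[current]:
            if nxt == start and len(path) >= 5:
                rings.add(frozenset(path))
            elif nxt not in path and len(path) < 6:
                dfs(start, nxt, path + [nxt])

    for s in sorted(heavy):
        dfs(s, s, [s])
    out = []
    for ring in sorted(rings, key=lambda r: sorted(r)):
        idx = np.array(sorted(ring), int)
        pts = xyz[idx]
        centred = pts - pts.mean(axis=0)
        # planarity: smallest singular value = RMS out-of-plane extent
        s = np.linalg.svd(centred, compute_uv=False)
        if s[-1] / np.sqrt(len(idx)) < 0.15:
            out.append(idx)
    return out


def annotate_contacts(
    frame: Structure,
    ligand: Structure,
    pose_xyz: np.ndarray,
    hbond_dist_max_A: float = 3.5,
    hbond_angle_min_deg: float = 120.0,
    pipi_dist_max_A: float = 5.5,
) -> ContactReport:
    """Geometric protein-ligand contact detection.

    H-bond: a donor/acceptor heavy-atom pair (either direction) within
    ``hbond_dist_max_A`` whose angle at the donor — between the donor's
    bonded antecedent and the acceptor — is at least ``hbond_angle_min_deg``
    (pairs with no resolvable antecedent pass on distance alone; explicit
    hydrogens are not required).

    π-π: an aromatic-ring centroid pair (protein residue template ring vs a
    planar 5/6-cycle perceived on the ligand) within ``pipi_dist_max_A``.
    """
    pose_xyz = np.asarray(pose_xyz, float)
    pcoords = frame.coords()
    contacts: list[Contact] = []

    lig_polar = [
        i for i, a in enumerate(ligand.atoms) if a.element.upper() in ("N", "O", "S")
    ]

    def angle_ok(donor_xyz, antecedents, acceptor_xyz) -> tuple[bool, float | None]:
        if len(antecedents) == 0:
            return True, None
        best = -1.0
        for ant in antecedents:
            v1 = ant - donor_xyz
            v2 = acceptor_xyz - donor_xyz
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            best = max(best, ang)
        return best >= hbond_angle_min_deg, best

    pairs = []  # (donor side, lig_atom, prot_atom)
    for li in lig_polar:
        for pi in _donor_acceptor(frame, "acceptor"):
            pairs.append(("ligand", li, pi))
        for pi in _donor_acceptor(frame, "donor"):
            pairs.append(("protein", li, pi))
    seen = set()
    for side, li, pi in pairs:
        d = float(np.linalg.norm(pose_xyz[li] - pcoords[pi]))
        if d > hbond_dist_max_A:
            continue
        if side == "ligand":
            ants = pose_xyz[_bonded_neighbors(pose_xyz, li)]
            ok, ang = angle_ok(pose_xyz[li], ants, pcoords[pi])
        else:
            same_res = np.array(
                [j for j in _bonded_neighbors(pcoords, pi)
                 if frame.atoms[j].residue_id == frame.atoms[pi].residue_id],
                int,
            )
            ok, ang = angle_ok(pcoords[pi], pcoords[same_res] if same_res.size else [], pose_xyz[li])
        key = (li, pi)
        if ok and key not in seen:
            seen.add(key)
            pa = frame.atoms[pi]
            contacts.append(
                Contact(
                    kind="hbond",
                    ligand_atoms=(ligand.atoms[li].name.strip(),),
                    protein_residue=(pa.residue_id, pa.residue_name),
                    distance_A=d,
                    angle_deg=ang,
                )
            )

    # pi-pi stacking
    residues: dict[int, list[int]] = {}
    for i, a in enumerate(frame.atoms):
        residues.setdefault(a.residue_id, []).append(i)
    lig_rings = _ligand_rings(ligand, pose_xyz)
    for rid, idxs in residues.items():
        rname = frame.atoms[idxs[0]].residue_name
        for template in _AROMATIC_RINGS.get(rname, ()):  # type: ignore[call-overload]
            ring_idx = [
                i for i in idxs if frame.atoms[i].name.strip() in template
            ]
            if len(ring_idx) != len(template):
                continue
            pcen = pcoords[ring_idx].mean(axis=0)
            for lring in lig_rings:
                lcen = pose_xyz[lring].mean(axis=0)
                d = float(np.linalg.norm(pcen - lcen))
                if d <= pipi_dist_max_A:
                    contacts.append(
                        Contact(
                            kind="pipi",
                            ligand_atoms=tuple(ligand.atoms[k].name.strip() for k in lring),
                            protein_residue=(rid, rname),
                            distance_A=d,
                        )
                    )
    return ContactReport(contacts=contacts)


def pocket_overlap(a: Pocket, b: Pocket) -> tuple[set[int], float]:
    """Shared residue ids and Jaccard fraction |∩|/|∪| of two pockets."""
    inter = set(a.residue_ids) & set(b.residue_ids)
    union = set(a.residue_ids) | set(b.residue_ids)
    return inter, (len(inter) / len(union) if union else 0.0)
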