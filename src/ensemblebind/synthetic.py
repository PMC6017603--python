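"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here with the generating
parameters recorded alongside, so downstream estimates have an exact target:

* toy protein trajectories on an ideal α-helical backbone with prescribed
  per-residue fluctuation amplitudes and an optional two-state (open/closed)
  pocket of known occupancy;
* per-frame scored ligand pose sets with a known bound fraction;
* 1:1 Langmuir sensorgrams and equilibrium isotherms with stated
  Kd/kon/koff/Rmax, Gaussian noise and drift;
* paired alone/mixture equilibrium traces implementing a known signed
  competition effect.

The trajectory noise model is i.i.d. Gaussian per atom — deliberately
non-physical, but it gives RMSF, clustering and SASA closed-form or
enumerable targets without a molecular-dynamics engine. All generators are
deterministic under a fixed seed (NumPy PCG64 via ``default_rng``);
changing only the seed changes noise realisations, never ground-truth
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError
from .io_formats import Atom, Isotherm, Pose, PoseSet, Sensorgram, Structure, Trajectory

RNG_ALGORITHM = "numpy.random.PCG64"

# ideal alpha-helix parameters
HELIX_RISE_A = 1.5       # rise per residue along the axis
HELIX_TWIST_DEG = 100.0  # rotation per residue
HELIX_RADIUS_A = 2.3     # Calpha radius


# ---------------------------------------------------------------------------
# template structures
# ---------------------------------------------------------------------------

def helical_backbone(
    n_residues: int,
    sequence: list[str] | None = None,
    chain: str = "A",
) -> Structure:
    """Ideal α-helical backbone (N, CA, C, O per residue).

    Cα atoms sit on a helix of radius 2.3 Å with 1.5 Å rise and 100°
    twist per residue; N/C/O are placed at fixed offsets around each Cα
    (plausible 1.2–1.5 Å bond lengths, not force-field geometry). Fully
    determined by formulas, so cross-platform reproducible.
    """
    if n_residues < 1:
        raise AnalysisError("need at least one residue")
    if sequence is None:
        # alternating apolar/polar pattern
        pattern = ["LEU", "SER", "ALA", "GLU"]
        sequence = [pattern[i % 4] for i in range(n_residues)]
    if len(sequence) != n_residues:
        raise AnalysisError("sequence length must equal n_residues")
    atoms: list[Atom] = []
    serial = 1
    twist = math.radians(HELIX_TWIST_DEG)
    for i in range(n_residues):
        theta = i * twist
        z = i * HELIX_RISE_A
        ca = np.array([HELIX_RADIUS_A * math.cos(theta), HELIX_RADIUS_A * math.sin(theta), z])
        # offsets in the local (radial, tangential, axial) frame
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        tangent = np.array([-math.sin(theta), math.cos(theta), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        offsets = {
            "N": -0.8 * tangent - 0.9 * axial - 0.4 * radial,
            "CA": np.zeros(3),
            "C": 0.9 * tangent + 0.8 * axial - 0.3 * radial,
            "O": 0.9 * tangent + 1.2 * axial + 0.8 * radial,
        }
        for name in ("N", "CA", "C", "O"):
            pos = ca + offsets[name]
            element = name[0]
            atoms.append(
                Atom(serial, name, element, i + 1, sequence[i], chain, tuple(pos))
            )
            serial += 1
    return Structure(atoms)


def make_ligand(label: str = "LIG", n_tail: int = 2) -> Structure:
    """A small rigid hetero ligand: planar six-ring plus a short polar tail."""
    atoms: list[Atom] = []
    serial = 1
    for k in range(6):
        ang = math.radians(60.0 * k)
        pos = (1.39 * math.cos(ang), 1.39 * math.sin(ang), 0.0)
        atoms.append(Atom(serial, f"C{k + 1}", "C", 1, label, "L", pos, hetero=True))
        serial += 1
    tail_elements = ["N", "O", "C", "C"]
    for k in range(n_tail):
        pos = (1.39 + 1.4 * (k + 1), 0.0, 0.3 * (k + 1))
        atoms.append(
            Atom(serial, f"{tail_elements[k]}{k + 1}", tail_elements[k], 1, label, "L", pos, hetero=True)
        )
        serial += 1
    return Structure(atoms)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySpec:
    """Ground-truth description of a synthetic ensemble.

    ``sigma_A`` is the per-residue isotropic per-coordinate fluctuation
    (so the expected per-residue RMSF is σ√3). ``open_fraction`` of frames
    additionally displace the ``pocket_residue_ids`` subset by
    ``displacement_A`` along x (a two-state open/closed pocket).
    """

    n_residues: int = 12
    sigma_A: float | np.ndarray = 0.3
    n_frames: int = 200
    timestep_ps: float = 200.0
    open_fraction: float = 0.0
    pocket_residue_ids: tuple[int, ...] = ()
    displacement_A: tuple[float, float, float] = (5.0, 0.0, 0.0)
    sequence: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        sig = np.asarray(self.sigma_A, dtype=float)
        if np.any(sig < 0):
            raise AnalysisError("sigma_A must be non-negative")
        if not 0.0 <= self.open_fraction <= 1.0:
            raise AnalysisError("open_fraction must be in [0, 1]")


@dataclass
class TrajectoryTruth:
    """Generating parameters recorded for downstream recovery checks."""

    rmsf_target_A: np.ndarray          # per residue, sigma*sqrt(3)
    open_frames: list[int]             # 1-based
    open_fraction_nominal: float
    open_fraction_realized: float
    cluster_fractions: tuple[float, float]  # (closed, open), realized
    seed: int
    rng_algorithm: str = RNG_ALGORITHM


def make_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, TrajectoryTruth]:
    """Template + per-residue Gaussian noise, with optional two-state pocket."""
    template = helical_backbone(spec.n_residues, sequence=spec.sequence)
    coords0 = template.coords()
    resids = template.residue_ids()
    sigma = np.broadcast_to(np.asarray(spec.sigma_A, float), (spec.n_residues,))
    atom_sigma = sigma[resids - 1][:, None]
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(size=(spec.n_frames, template.n_atoms, 3)) * atom_sigma
    xyz = coords0[None, :, :] + noise
    open_frames: list[int] = []
    if spec.open_fraction > 0 and spec.pocket_residue_ids:
        states = rng.random(spec.n_frames) < spec.open_fraction
        mask = np.isin(resids, spec.pocket_residue_ids)
        disp = np.asarray(spec.displacement_A, float)
        xyz[np.ix_(states, mask)] += disp
        open_frames = [int(i) + 1 for i in np.where(states)[0]]
    realized = len(open_frames) / spec.n_frames
    truth = TrajectoryTruth(
        rmsf_target_A=sigma * math.sqrt(3.0),
        open_frames=open_frames,
        open_fraction_nominal=spec.open_fraction,
        open_fraction_realized=realized,
        cluster_fractions=(1.0 - realized, realized),
        seed=spec.seed,
    )
    return Trajectory(topology=template, xyz=xyz, timestep_ps=spec.timestep_ps), truth


# ---------------------------------------------------------------------------
# pose sets
# ---------------------------------------------------------------------------

@dataclass
class PoseTruth:
    bound_frames: list[int]
    bound_fraction_nominal: float
    bound_fraction_realized: float
    score_threshold: float
    seed: int
    rng_algorithm: str = RNG_ALGORITHM


def make_pose_sets(
    traj: Trajectory,
    ligand: Structure,
    reference_pose: np.ndarray,
    bound_fraction: float,
    bound_noise_A: float = 0.5,
    unbound_offset_A: float = 6.0,
    bound_score: float = -8.0,
    unbound_score: float = -4.0,
    score_sd: float = 0.5,
    score_threshold: float = -6.0,
    pocket=None,
    reference_frame_xyz: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[PoseSet, PoseTruth]:
    """One best pose per frame with a Bernoulli(bound_fraction) bound state.

    Bound frames carry the reference pose rigidly shifted by a random vector
    of norm ≤ ``bound_noise_A`` with a score safely below the threshold;
    unbound frames are shifted by ≥ ``unbound_offset_A`` with a score above
    it. When a ``pocket`` (and the reference frame's coordinates) are given,
    each pose is expressed in its own frame's coordinate system — the
    reference frame is superposed onto the target frame by the pocket
    backbone and the shifted reference pose is carried along, exactly as a
    docking engine would report poses in frame coordinates. The truth record
    lists the bound frames exactly.
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise AnalysisError("bound_fraction must be in [0, 1]")
    from .trajectory import kabsch_superpose  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    ref = np.asarray(reference_pose, float)
    sel = None
    ref_frame = None
    if pocket is not None:
        if reference_frame_xyz is None:
            raise AnalysisError("reference_frame_xyz required when pocket is given")
        sel = pocket.backbone_indices(traj.topology)
        ref_frame = np.asarray(reference_frame_xyz, float)
    poses: list[Pose] = []
    bound_frames: list[int] = []
    for k in range(traj.n_frames):
        frame_idx = k + 1
        is_bound = rng.random() < bound_fraction
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        if is_bound:
            shift = direction * (rng.random() * bound_noise_A)
            score = bound_score + rng.normal() * score_sd
            score = min(score, score_threshold - 0.1)
            bound_frames.append(frame_idx)
        else:
            shift = direction * (unbound_offset_A + abs(rng.normal()))
            score = unbound_score + rng.normal() * score_sd
            score = max(score, score_threshold + 0.1)
        xyz = ref + shift
        if sel is not None:
            sup = kabsch_superpose(ref_frame, traj.xyz[k], selection=sel)
            xyz = sup.apply(xyz)
        poses.append(Pose(frame_index=frame_idx, model_index=k + 1, xyz=xyz, score=float(score)))
    truth = PoseTruth(
        bound_frames=bound_frames,
        bound_fraction_nominal=bound_fraction,
        bound_fraction_realized=len(bound_frames) / traj.n_frames,
        score_threshold=score_threshold,
        seed=seed,
    )
    return PoseSet(ligand_topology=ligand, poses=poses), truth


# ---------------------------------------------------------------------------
# SPR
# ---------------------------------------------------------------------------

@dataclass
class SensorgramSpec:
    """1:1 Langmuir kinetic generator: dR/dt = kon·C·(Rmax − R) − koff·R."""

    Kd_M: float = 24.2e-6
    kon_M_s: float = 1.0e3
    Rmax_RU: float = 100.0
    concentrations_M: tuple[float, ...] = ()
    association_s: float = 90.0
    dissociation_s: float = 120.0
    baseline_s: float = 10.0
    dt_s: float = 0.5
    noise_sd_RU: float = 0.0
    drift_RU_per_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Kd_M <= 0 or self.kon_M_s <= 0 or self.Rmax_RU <= 0:
            raise AnalysisError("Kd, kon and Rmax must be positive")
        if not self.concentrations_M:
            # default design spanning the Kd: Kd/4 ... 8 Kd, log-spaced
            self.concentrations_M = tuple(
                float(c) for c in np.geomspace(self.Kd_M / 4.0, 8.0 * self.Kd_M, 8)
            )
        if any(c <= 0 for c in self.concentrations_M):
            raise AnalysisError("concentrations must be positive")

    @property
    def koff_s(self) -> float:
        return self.Kd_M * self.kon_M_s


@dataclass
class SensorgramTruth:
    Kd_M: float
    kon_M_s: float
    koff_s: float
    Rmax_RU: float
    req_RU: dict[float, float]  # concentration -> true equilibrium response
    seed: int
    rng_algorithm: str = RNG_ALGORITHM


def langmuir_response(
    t: np.ndarray, c: float, kd: float, kon: float, rmax: float, t_on: float, t_off: float
) -> np.ndarray:
    """Closed-form 1:1 response: exponential association then dissociation."""
    koff = kd * kon
    req = rmax * c / (c + kd)
    kobs = kon * c + koff
    r = np.zeros_like(t, dtype=float)
    assoc = (t >= t_on) & (t <= t_off)
    r[assoc] = req * (1.0 - np.exp(-kobs * (t[assoc] - t_on)))
    r_end = req * (1.0 - np.exp(-kobs * (t_off - t_on)))
    dissoc = t > t_off
    r[dissoc] = r_end * np.exp(-koff * (t[dissoc] - t_off))
    return r


def make_sensorgram_set(spec: SensorgramSpec) -> tuple[list[Sensorgram], Isotherm, SensorgramTruth]:
    """Sensorgram per concentration plus the matching equilibrium isotherm.

    Traces are the closed-form Langmuir response with additive Gaussian
    noise and linear drift; isotherm points are the true Req values plus the
    same noise level.
    """
    rng = np.random.default_rng(spec.seed)
    t_on = spec.baseline_s
    t_off = spec.baseline_s + spec.association_s
    t_total = t_off + spec.dissociation_s
    t = np.arange(0.0, t_total + spec.dt_s / 2, spec.dt_s)
    traces: list[Sensorgram] = []
    req_true: dict[float, float] = {}
    for c in spec.concentrations_M:
        r = langmuir_response(t, c, spec.Kd_M, spec.kon_M_s, spec.Rmax_RU, t_on, t_off)
        r = r + spec.drift_RU_per_s * t
        if spec.noise_sd_RU > 0:
            r = r + rng.normal(scale=spec.noise_sd_RU, size=t.shape)
        traces.append(
            Sensorgram(
                time_s=t.copy(),
                response_RU=r,
                injection_start_s=t_on,
                injection_end_s=t_off,
                label=f"C={c:.3e}M",
            )
        )
        req_true[c] = spec.Rmax_RU * c / (c + spec.Kd_M)
    req_noisy = np.array(
        [req_true[c] + (rng.normal(scale=spec.noise_sd_RU) if spec.noise_sd_RU > 0 else 0.0)
         for c in spec.concentrations_M]
    )
    iso = Isotherm(
        concentration_M=np.asarray(spec.concentrations_M, float),
        req_RU=req_noisy,
        label="synthetic",
    )
    truth = SensorgramTruth(
        Kd_M=spec.Kd_M,
        kon_M_s=spec.kon_M_s,
        koff_s=spec.koff_s,
        Rmax_RU=spec.Rmax_RU,
        req_RU=req_true,
        seed=spec.seed,
    )
    return traces, iso, truth


def make_competition_set(
    req_alone_RU: float,
    effect_percent: float,
    noise_sd_RU: float = 0.0,
    seed: int = 0,
    association_s: float = 90.0,
    baseline_s: float = 10.0,
    dt_s: float = 0.5,
) -> tuple[Sensorgram, Sensorgram, dict]:
    """Paired alone/mixture equilibrium traces with a known signed effect.

    The mixture plateau is ``Req_alone × (1 + effect_percent/100)``; −50
    emulates 50% inhibition, positive values emulate enhancement.
    """
    if req_alone_RU <= 0:
        raise AnalysisError("Req_alone must be positive")
    rng = np.random.default_rng(seed)
    t_on, t_off = baseline_s, baseline_s + association_s
    t = np.arange(0.0, t_off + 30.0, dt_s)
    kobs = 0.25  # fast approach: plateau well within the injection

    def trace(plateau: float, label: str) -> Sensorgram:
        r = np.where(t >= t_on, plateau * (1.0 - np.exp(-kobs * np.maximum(t - t_on, 0.0))), 0.0)
        r[t > t_off] = plateau * np.exp(-0.001 * (t[t > t_off] - t_off))
        if noise_sd_RU > 0:
            r = r + rng.normal(scale=noise_sd_RU, size=t.shape)
        return Sensorgram(t.copy(), r, injection_start_s=t_on, injection_end_s=t_off, label=label)

    req_mix = req_alone_RU * (1.0 + effect_percent / 100.0)
    alone = trace(req_alone_RU, "alone")
    mix = trace(req_mix, "mixture")
    truth = {
        "req_alone_RU": req_alone_RU,
        "req_mix_RU": req_mix,
        "effect_percent": effect_percent,
        "seed": seed,
        "rng_algorithm": RNG_ALGORITHM,
    }
    return alone, mix, truth
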