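"""Typed containers and strict readers/writers for the pipeline's file formats.

Formats handled
---------------
* multi-model PDB (``MODEL``/``ENDMDL`` blocks, fixed-column ``ATOM``/``HETATM``
  records, ``%8.3f`` coordinates) — protein trajectories;
* pose PDB — the same, with ``REMARK SCORE <float>`` and ``REMARK FRAME <int>``
  lines preceding each ``MODEL`` (a self-contained dialect for scored docking
  poses, since parsing engine-native docking output is out of scope here);
* sensorgram CSV ``time_s,response_RU`` with ``#key=value`` header comments;
* isotherm CSV ``concentration_M,Req_RU``.

Conventions: frame and MODEL indices are 1-based (PDB convention); coordinates
are Å; SPR time is seconds, trajectory time is picoseconds. A blank chain
identifier is normalised to chain ``"A"``. Readers validate strictly and never
silently drop records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, PDBParseError, TopologyError

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass(frozen=True)
class Atom:
    """One atom record: identity plus a 3-vector of Å coordinates."""

    serial: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain: str
    xyz: tuple[float, float, float]
    hetero: bool = False


@dataclass
class Structure:
    """A set of atoms with residue/chain topology (coordinates in Å)."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise TopologyError("duplicate atom serial numbers in structure")
        for a in self.atoms:
            if not a.element:
                raise PDBParseError(f"atom serial {a.serial} has empty element")
            if not np.all(np.isfinite(a.xyz)):
                raise PDBParseError(f"atom serial {a.serial} has non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates, Å."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise TopologyError(
                f"coordinate array shape {xyz.shape} does not match {self.n_atoms} atoms"
            )
        atoms = [replace(a, xyz=tuple(p)) for a, p in zip(self.atoms, xyz)]
        return Structure(atoms)

    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_id for a in self.atoms], dtype=int)

    def select(
        self,
        names: Iterable[str] | None = None,
        residue_ids: Iterable[int] | None = None,
        heavy: bool = False,
        protein_only: bool = False,
    ) -> np.ndarray:
        """Indices of atoms matching all given filters (0-based)."""
        names_s = {n.strip() for n in names} if names is not None else None
        resid_s = set(residue_ids) if residue_ids is not None else None
        keep = []
        for i, a in enumerate(self.atoms):
            if names_s is not None and a.name.strip() not in names_s:
                continue
            if resid_s is not None and a.residue_id not in resid_s:
                continue
            if heavy and a.element.upper() == "H":
                continue
            if protein_only and a.hetero:
                continue
            keep.append(i)
        return np.array(keep, dtype=int)

    def backbone_indices(self) -> np.ndarray:
        """Protein backbone atoms (N, CA, C, O)."""
        return self.select(names=("N", "CA", "C", "O"), protein_only=True)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, uniformly spaced in time.

    ``xyz`` has shape (n_frames, n_atoms, 3) in Å; frame indices reported to
    users are 1-based (frame ``k`` is ``xyz[k - 1]``).
    """

    topology: Structure
    xyz: np.ndarray
    timestep_ps: float = 1.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise TopologyError(f"trajectory coordinates must be (frames, atoms, 3), got {self.xyz.shape}")
        if self.xyz.shape[0] < 1:
            raise TopologyError("trajectory must contain at least one frame")
        if self.xyz.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frame atom count {self.xyz.shape[1]} does not match topology ({self.topology.n_atoms})"
            )
        if not self.timestep_ps > 0:
            raise FormatError("timestep_ps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.xyz.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.xyz.shape[1])

    def frame(self, index: int) -> Structure:
        """Structure for 1-based frame ``index``."""
        if not 1 <= index <= self.n_frames:
            raise IndexError(f"frame index {index} outside 1..{self.n_frames}")
        return self.topology.with_coords(self.xyz[index - 1])


@dataclass(frozen=True)
class Pose:
    """One scored ligand pose referencing a trajectory frame (both 1-based)."""

    frame_index: int
    model_index: int
    xyz: np.ndarray
    score: float


@dataclass
class PoseSet:
    """Scored ligand poses over an ensemble; scores in kcal/mol, lower = better."""

    ligand_topology: Structure
    poses: list[Pose]

    def __post_init__(self) -> None:
        n = self.ligand_topology.n_atoms
        for p in self.poses:
            if np.asarray(p.xyz).shape != (n, 3):
                raise TopologyError(
                    f"pose model {p.model_index} has {np.asarray(p.xyz).shape[0]} atoms, expected {n}"
                )
            if not np.isfinite(p.score):
                raise FormatError(f"pose model {p.model_index} has non-finite score")

    def frames(self) -> np.ndarray:
        return np.array(sorted({p.frame_index for p in self.poses}), dtype=int)

    def best_pose_per_frame(self) -> dict[int, Pose]:
        """Lowest-score pose for each frame (ties -> lowest model index)."""
        best: dict[int, Pose] = {}
        for p in self.poses:
            cur = best.get(p.frame_index)
            if cur is None or (p.score, p.model_index) < (cur.score, cur.model_index):
                best[p.frame_index] = p
        return best


@dataclass
class Sensorgram:
    """An SPR response-vs-time trace (RU vs s) with its injection window."""

    time_s: np.ndarray
    response_RU: np.ndarray
    injection_start_s: float | None = None
    injection_end_s: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response_RU = np.asarray(self.response_RU, dtype=float)
        if self.time_s.shape != self.response_RU.shape or self.time_s.ndim != 1:
            raise FormatError("time and response must be 1-D arrays of equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            i = int(np.argmax(np.diff(self.time_s) <= 0))
            raise FormatError(f"time not strictly increasing at row {i + 2}")
        if self.injection_start_s is not None and self.injection_end_s is not None:
            if not self.injection_start_s < self.injection_end_s:
                raise FormatError("injection_start_s must precede injection_end_s")
            if self.time_s.size and (
                self.injection_start_s < self.time_s[0] or self.injection_end_s > self.time_s[-1]
            ):
                raise FormatError("injection window lies outside the recorded time range")


@dataclass
class Isotherm:
    """Equilibrium binding points: Req (RU) vs analyte concentration (M)."""

    concentration_M: np.ndarray
    req_RU: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.concentration_M = np.asarray(self.concentration_M, dtype=float)
        self.req_RU = np.asarray(self.req_RU, dtype=float)
        if self.concentration_M.shape != self.req_RU.shape or self.concentration_M.ndim != 1:
            raise FormatError("isotherm columns must be 1-D arrays of equal length")
        if np.any(self.concentration_M <= 0):
            raise FormatError("concentrations must be positive")
        uniq, counts = np.unique(self.concentration_M, return_counts=True)
        if np.any(counts > 1):
            dups = ", ".join(f"{c:g}" for c in uniq[counts > 1])
            raise FormatError(f"duplicated concentrations in isotherm: {dups} M")

    @property
    def n_points(self) -> int:
        return int(self.concentration_M.size)


# ---------------------------------------------------------------------------
# multi-model PDB
# ---------------------------------------------------------------------------

_PDB_ATOM_FMT = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resid:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str) -> str:
    # PDB column 13 is blank for 1-3 char names of light elements
    name = name.strip()
    return name if len(name) >= 4 else f" {name:<3s}"


def _parse_atom_line(line: str, lineno: int) -> Atom:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record too short for coordinates")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed fixed-column field ({exc})") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the leading letter of the atom name (stripping digits)
        element = "".join(c for c in name if c.isalpha())[:1].upper()
    if not element:
        raise PDBParseError(f"line {lineno}: cannot determine element for atom {serial}")
    hetero = line.startswith("HETATM")
    return Atom(serial, name, element, resid, resname, chain, (x, y, z), hetero=hetero)


def _topology_key(struct: Structure) -> list[tuple]:
    return [(a.name, a.residue_id, a.residue_name, a.chain) for a in struct.atoms]


def _read_models(path: str | Path):
    """Yield (model_index, remark_lines, list_of_atoms) per MODEL block."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    models: list[tuple[int, list[str], list[Atom]]] = []
    atoms: list[Atom] = []
    remarks: list[str] = []
    in_model = False
    model_index = 0
    saw_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if in_model:
                    raise PDBParseError(f"line {lineno}: MODEL opened before previous ENDMDL")
                in_model = True
                saw_model_record = True
                model_index += 1
                atoms = []
            elif rec == "ENDMDL":
                if not in_model:
                    raise PDBParseError(f"line {lineno}: ENDMDL without matching MODEL")
                models.append((model_index, remarks, atoms))
                remarks, atoms, in_model = [], [], False
            elif rec in ("ATOM", "HETATM"):
                atoms.append(_parse_atom_line(line, lineno))
            elif rec == "REMARK":
                remarks.append(line.rstrip("\n"))
    if in_model:
        raise PDBParseError(f"MODEL {model_index} not closed by ENDMDL")
    if not saw_model_record:
        if atoms:  # plain single-structure PDB
            models.append((1, remarks, atoms))
        else:
            raise PDBParseError(f"{path}: no MODEL blocks and no ATOM/HETATM records")
    return models


def read_multimodel_pdb(path: str | Path, timestep_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one frame per MODEL).

    The topology is taken from the first MODEL; any later MODEL whose atom
    count or atom identity sequence differs raises :class:`TopologyError`
    naming that frame.
    """
    models = _read_models(path)
    first = Structure(models[0][2])
    ref_key = _topology_key(first)
    frames = np.empty((len(models), first.n_atoms, 3), dtype=float)
    for j, (idx, _remarks, atoms) in enumerate(models):
        if len(atoms) != first.n_atoms:
            raise TopologyError(
                f"frame {idx}: {len(atoms)} atoms, expected {first.n_atoms} (from frame 1)"
            )
        st = Structure(atoms)
        if _topology_key(st) != ref_key:
            raise TopologyError(f"frame {idx}: atom identities differ from frame 1")
        frames[j] = st.coords()
    return Trajectory(topology=first, xyz=frames, timestep_ps=timestep_ps)


def _write_atom_lines(fh, struct: Structure, xyz: np.ndarray) -> None:
    for a, p in zip(struct.atoms, xyz):
        fh.write(
            _PDB_ATOM_FMT.format(
                record="HETATM" if a.hetero else "ATOM",
                serial=a.serial,
                name=_format_atom_name(a.name),
                altloc=" ",
                resname=a.residue_name,
                chain=a.chain,
                resid=a.residue_id,
                icode=" ",
                x=p[0],
                y=p[1],
                z=p[2],
                occ=1.0,
                b=0.0,
                element=a.element.upper(),
            )
        )


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (%8.3f coordinates)."""
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"MODEL {k + 1:>8d}\n")
            _write_atom_lines(fh, traj.topology, traj.xyz[k])
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# pose files
# ---------------------------------------------------------------------------

def read_pose_file(path: str | Path) -> PoseSet:
    """Read a scored pose set: a multi-model PDB whose every MODEL is preceded
    by ``REMARK SCORE <float>`` and ``REMARK FRAME <int>`` records."""
    models = _read_models(path)
    if not models or not models[0][2]:
        raise FormatError(f"{path}: pose file contains no poses")
    topology = Structure(models[0][2])
    poses: list[Pose] = []
    for idx, remarks, atoms in models:
        score = frame = None
        for r in remarks:
            parts = r.split()
            if len(parts) >= 3 and parts[1] == "SCORE":
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise FormatError(f"pose model {idx}: non-numeric SCORE {parts[2]!r}") from exc
            elif len(parts) >= 3 and parts[1] == "FRAME":
                try:
                    frame = int(parts[2])
                except ValueError as exc:
                    raise FormatError(f"pose model {idx}: non-integer FRAME {parts[2]!r}") from exc
        if score is None:
            raise FormatError(f"pose model {idx}: missing REMARK SCORE")
        if frame is None:
            raise FormatError(f"pose model {idx}: missing REMARK FRAME")
        st = Structure(atoms)
        if _topology_key(st) != _topology_key(topology):
            raise TopologyError(f"pose model {idx}: ligand atoms differ from model 1")
        poses.append(Pose(frame_index=frame, model_index=idx, xyz=st.coords(), score=score))
    return PoseSet(ligand_topology=topology, poses=poses)


def write_pose_file(pose_set: PoseSet, path: str | Path) -> None:
    """Write a pose set in the REMARK SCORE/FRAME dialect (scores %.6f)."""
    with open(path, "w") as fh:
        for p in pose_set.poses:
            fh.write(f"REMARK SCORE {p.score:.6f}\n")
            fh.write(f"REMARK FRAME {p.frame_index}\n")
            fh.write(f"MODEL {p.model_index:>8d}\n")
            _write_atom_lines(fh, pose_set.ligand_topology, np.asarray(p.xyz))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# SPR CSV
# ---------------------------------------------------------------------------

def _read_csv_with_meta(path: str | Path, n_cols: int):
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != n_cols:
                raise FormatError(f"{path} line {lineno}: expected {n_cols} columns, got {len(parts)}")
            if not _is_number(parts[0]):
                # header row
                continue
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: non-numeric value ({exc})") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return meta, np.asarray(rows, dtype=float)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_sensorgram_csv(path: str | Path) -> Sensorgram:
    """Read ``time_s,response_RU`` CSV with optional ``#key=value`` metadata
    (``injection_start_s``, ``injection_end_s``, ``label``)."""
    meta, data = _read_csv_with_meta(path, 2)
    start = float(meta["injection_start_s"]) if "injection_start_s" in meta else None
    end = float(meta["injection_end_s"]) if "injection_end_s" in meta else None
    return Sensorgram(
        time_s=data[:, 0],
        response_RU=data[:, 1],
        injection_start_s=start,
        injection_end_s=end,
        label=meta.get("label", ""),
    )


def write_sensorgram_csv(s: Sensorgram, path: str | Path) -> None:
    with open(path, "w") as fh:
        if s.label:
            fh.write(f"# label={s.label}\n")
        if s.injection_start_s is not None:
            fh.write(f"# injection_start_s={s.injection_start_s:.6g}\n")
        if s.injection_end_s is not None:
            fh.write(f"# injection_end_s={s.injection_end_s:.6g}\n")
        fh.write("time_s,response_RU\n")
        for t, r in zip(s.time_s, s.response_RU):
            fh.write(f"{t:.6f},{r:.6f}\n")


def read_isotherm_csv(path: str | Path) -> Isotherm:
    """Read ``concentration_M,Req_RU`` CSV; duplicate concentrations are an error."""
    meta, data = _read_csv_with_meta(path, 2)
    return Isotherm(concentration_M=data[:, 0], req_RU=data[:, 1], label=meta.get("label", ""))


def write_isotherm_csv(iso: Isotherm, path: str | Path) -> None:
    with open(path, "w") as fh:
        if iso.label:
            fh.write(f"# label={iso.label}\n")
        fh.write("concentration_M,Req_RU\n")
        for c, r in zip(iso.concentration_M, iso.req_RU):
            fh.write(f"{c:.10g},{r:.6f}\n")
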