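"""Trajectory I/O, torsion geometry and rotamer classification.

Reads Cartesian trajectories (plain XYZ with a JSON side-car topology, or
multi-model PDB), measures the five O-C-C-O torsions of a polyol, classifies
every frame into one of the 243 rotamer states, segments the state series
into dwell episodes and performs geometric hydrogen-bond counting on bound
poses.  Units are Å and ps throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rotamers import (
    N_TORSIONS,
    RotamerState,
    classify_words_to_indices,
    index_to_word,
    wrap_angle,
)


class TrajectoryError(ValueError):
    """Malformed trajectory input (message carries frame/line context)."""


class GeometryError(ValueError):
    """Undefined geometry (e.g. collinear atoms in a dihedral)."""


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


@dataclass
class Topology:
    """Atom names/elements plus the five labelled torsion quadruples.

    ``torsion_quads`` maps alpha..epsilon (in order) to ordered 4-tuples of
    atom indices; each quad must be chemically ordered O-C-C-O.  ``donors``
    and ``acceptors`` list atom indices for hydrogen-bond analysis and
    ``donor_hydrogens`` optionally maps a donor index to its hydrogen.
    """

    atoms: list[tuple[str, str]]
    torsion_quads: list[tuple[int, int, int, int]]
    donors: list[int] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    donor_hydrogens: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.torsion_quads) != N_TORSIONS:
            raise ValueError(
                f"expected exactly {N_TORSIONS} torsion quads, got {len(self.torsion_quads)}"
            )
        n = len(self.atoms)
        for quad in self.torsion_quads:
            if any(not 0 <= i < n for i in quad):
                raise ValueError(f"torsion quad {quad} has out-of-range atom index")
            elems = [self.atoms[i][1] for i in quad]
            if elems != ["O", "C", "C", "O"]:
                raise ValueError(f"torsion quad {quad} is {elems}, must be O-C-C-O")
        for group in (self.donors, self.acceptors):
            if any(not 0 <= i < n for i in group):
                raise ValueError("donor/acceptor index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def to_json(self, path) -> None:
        payload = {
            "atoms": [list(a) for a in self.atoms],
            "torsion_quads": [list(q) for q in self.torsion_quads],
            "donors": self.donors,
            "acceptors": self.acceptors,
            "donor_hydrogens": {str(k): v for k, v in self.donor_hydrogens.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "Topology":
        payload = json.loads(Path(path).read_text())
        return cls(
            atoms=[tuple(a) for a in payload["atoms"]],
            torsion_quads=[tuple(q) for q in payload["torsion_quads"]],
            donors=list(payload.get("donors", [])),
            acceptors=list(payload.get("acceptors", [])),
            donor_hydrogens={
                int(k): v for k, v in payload.get("donor_hydrogens", {}).items()
            },
        )


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CartesianTrajectory:
    """Frames of Cartesian coordinates: times (ps) and (n_frames, n_atoms, 3) Å."""

    times: np.ndarray
    coords: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class TorsionTrajectory:
    """Time series of the five O-C-C-O torsions of one polyol molecule."""

    times: np.ndarray  # ps, strictly increasing
    angles: np.ndarray  # (n_frames, 5) degrees in [-180, 180)
    temperature: float = 277.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != N_TORSIONS:
            raise ValueError("angles must be (n_frames, 5)")
        if len(self.times) != len(self.angles):
            raise ValueError("times and angles length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        self.angles = wrap_angle(self.angles)

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class RotamerTrajectory:
    """Per-frame rotamer state indices plus dwell segmentation."""

    times: np.ndarray
    states: np.ndarray  # 1-based indices
    temperature: float = 277.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def dwell_segments(self) -> list[tuple[int, float, float]]:
        """(state, start time, duration) runs tiling the time axis.

        The final segment is closed with the trailing frame spacing so the
        durations sum to n_frames * dt on a uniform grid.
        """
        if self.n_frames == 0:
            return []
        if self.n_frames == 1:
            return [(int(self.states[0]), float(self.times[0]), 0.0)]
        change = np.flatnonzero(np.diff(self.states) != 0)
        starts = np.concatenate([[0], change + 1])
        dt_last = self.times[-1] - self.times[-2]
        edge_times = np.concatenate([self.times[starts], [self.times[-1] + dt_last]])
        return [
            (int(self.states[s]), float(edge_times[k]), float(edge_times[k + 1] - edge_times[k]))
            for k, s in enumerate(starts)
        ]


@dataclass
class HBond:
    """A geometric donor(-H)...acceptor contact."""

    donor: int
    acceptor: int
    distance: float  # Å
    angle: float  # donor-H-acceptor, degrees; 180 when no hydrogen given
    hydrogen: int | None = None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_xyz(path) -> CartesianTrajectory:
    """Read a (possibly multi-frame) plain XYZ file.

    Frame times are taken from a ``time=<ps>`` token on the comment line when
    present, otherwise the frame number (1 ps spacing) is used.
    """
    lines = Path(path).read_text().splitlines()
    coords, times = [], []
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 2 + n > len(lines):
            raise TrajectoryError(
                f"{path}: truncated final frame after {frame} complete frame(s)"
            )
        comment = lines[i + 1]
        t = float(frame)
        for token in comment.split():
            if token.startswith("time="):
                t = float(token[5:])
        xyz = np.empty((n, 3))
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise TrajectoryError(
                    f"{path}: line {i + 3 + j}: malformed atom record {lines[i + 2 + j]!r}"
                )
            try:
                xyz[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise TrajectoryError(
                    f"{path}: line {i + 3 + j}: non-numeric coordinate"
                ) from exc
        coords.append(xyz)
        times.append(t)
        frame += 1
        i += 2 + n
    return CartesianTrajectory(np.array(times), np.array(coords))


def write_xyz(traj: CartesianTrajectory, topology: Topology, path) -> None:
    with open(path, "w") as fh:
        for t, frame in zip(traj.times, traj.coords):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"time={t:g}\n")
            for (name, elem), xyz in zip(topology.atoms, frame):
                fh.write(f"{elem} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def read_pdb(path) -> CartesianTrajectory:
    """Read a multi-model PDB; one frame per MODEL record (or a single frame)."""
    frames, current = [], []
    n_models = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            n_models += 1
            current = []
        elif rec in ("ATOM", "HETATM"):
            try:
                current.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError as exc:
                raise TrajectoryError(f"{path}: line {ln}: malformed coordinates") from exc
        elif rec == "ENDMDL":
            frames.append(np.array(current))
            current = []
    if n_models == 0 and current:
        frames.append(np.array(current))
    if n_models > len(frames):
        raise TrajectoryError(
            f"{path}: MODEL record without ENDMDL (after {len(frames)} complete frame(s))"
        )
    if not frames:
        raise TrajectoryError(f"{path}: no coordinates found")
    counts = {f.shape[0] for f in frames}
    if len(counts) > 1:
        raise TrajectoryError(f"{path}: inconsistent atom counts across models: {counts}")
    return CartesianTrajectory(np.arange(len(frames), dtype=float), np.array(frames))


def write_pdb(traj: CartesianTrajectory, topology: Topology, path) -> None:
    with open(path, "w") as fh:
        for m, frame in enumerate(traj.coords, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for k, ((name, elem), xyz) in enumerate(zip(topology.atoms, frame), start=1):
                fh.write(
                    f"HETATM{k:5d} {name:<4s} MOL A   1    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {elem:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(path, topology: Topology) -> CartesianTrajectory:
    """Auto-detecting reader (XYZ or multi-model PDB) with topology check."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        head = fh.read(10000).lstrip()
    if path.suffix.lower() == ".pdb" or head[:6].rstrip() in ("MODEL", "ATOM", "HETATM"):
        traj = read_pdb(path)
    else:
        traj = read_xyz(path)
    if traj.n_atoms != topology.n_atoms:
        raise TrajectoryError(
            f"{path}: frame 1 has {traj.n_atoms} atoms, topology expects {topology.n_atoms}"
        )
    return traj


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def compute_dihedral(p1, p2, p3, p4) -> float:
    """IUPAC-signed torsion angle (degrees, in [-180, 180)) of four points."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear or coincident atoms: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def _dihedrals_vectorized(coords: np.ndarray, quad) -> np.ndarray:
    p1, p2, p3, p4 = (coords[:, i, :] for i in quad)
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / b2n
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def extract_torsions(
    traj: CartesianTrajectory, topology: Topology, temperature: float = 277.0
) -> TorsionTrajectory:
    """Measure the five labelled O-C-C-O torsions in every frame."""
    if traj.n_atoms != topology.n_atoms:
        raise TrajectoryError("trajectory/topology atom count mismatch")
    angles = np.column_stack(
        [_dihedrals_vectorized(traj.coords, q) for q in topology.torsion_quads]
    )
    return TorsionTrajectory(traj.times, angles, temperature=temperature)


def classify_trajectory(traj: TorsionTrajectory) -> RotamerTrajectory:
    """Assign each frame to one of the 243 rotamer states."""
    states = classify_words_to_indices(traj.angles)
    return RotamerTrajectory(traj.times, states, temperature=traj.temperature)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def detect_hbonds(
    frame: np.ndarray,
    topology: Topology,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[HBond]:
    """Geometric hydrogen-bond count on a single frame.

    A donor-acceptor pair is counted when the heavy-atom distance is at most
    ``d_max`` (Å) and, when the donor's hydrogen is known, the D-H...A angle is
    at least ``angle_min`` degrees.  Without hydrogens the criterion is
    distance-only.
    """
    frame = np.asarray(frame, dtype=float)
    out: list[HBond] = []
    for d in topology.donors:
        for a in topology.acceptors:
            if d == a:
                continue
            r = float(np.linalg.norm(frame[a] - frame[d]))
            if r > d_max:
                continue
            h = topology.donor_hydrogens.get(d)
            if h is None:
                out.append(HBond(d, a, r, 180.0, None))
                continue
            v1 = frame[d] - frame[h]
            v2 = frame[a] - frame[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang >= angle_min:
                out.append(HBond(d, a, r, ang, h))
    return out


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def rotamer_trajectory_to_tsv(rt: RotamerTrajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("# time_ps\tindex\tword\n")
        for t, s in zip(rt.times, rt.states):
            fh.write(f"{t:g}\t{s}\t{index_to_word(int(s))}\n")


def rotamer_trajectory_from_tsv(path, temperature: float = 277.0) -> RotamerTrajectory:
    times, states = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        times.append(float(parts[0]))
        states.append(int(parts[1]))
    return RotamerTrajectory(np.array(times), np.array(states), temperature=temperature)


def dwell_segments_to_tsv(rt: RotamerTrajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("# state_index\tword\tstart_ps\tduration_ps\n")
        for s, t0, dur in rt.dwell_segments():
            fh.write(f"{s}\t{index_to_word(s)}\t{t0:g}\t{dur:g}\n")


def torsion_trajectory_to_tsv(tt: TorsionTrajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("# time_ps\talpha\tbeta\tgamma\tdelta\tepsilon\n")
        for t, row in zip(tt.times, tt.angles):
            fh.write(f"{t:g}\t" + "\t".join(f"{a:.4f}" for a in row) + "\n")


def torsion_trajectory_from_tsv(path, temperature: float = 277.0) -> TorsionTrajectory:
    data = np.loadtxt(path, comments="#", delimiter="\t")
    data = np.atleast_2d(data)
    return TorsionTrajectory(data[:, 0], data[:, 1:6], temperature=temperature)


def _state(word: str) -> RotamerState:  # small convenience used by the CLI
    return RotamerState(word)
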