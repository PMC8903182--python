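"""Rotamer population and switching-kinetics estimation.

Populations are frame fractions over the 243 rotamer states with block-
averaged standard errors; relative free energies follow from the Boltzmann
relation dG_i = -RT ln(p_i / p_max).  Switching kinetics are counted at
frame resolution (transitions between consecutive snapshots), matching
snapshot-based trajectory analysis; 1 transition/ps equals 1 THz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import R_KJ
from .rotamers import N_STATES, index_to_word, word_to_index
from .trajectory import RotamerTrajectory


@dataclass
class PopulationTable:
    """Per-rotamer probabilities with block-averaged standard errors."""

    probabilities: np.ndarray  # length 243, sums to 1
    standard_errors: np.ndarray  # length 243, >= 0
    n_frames: int
    temperature: float = 277.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.standard_errors = np.asarray(self.standard_errors, dtype=float)
        if self.probabilities.shape != (N_STATES,):
            raise ValueError(f"probabilities must have length {N_STATES}")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")
        if np.any(self.standard_errors < 0):
            raise ValueError("standard errors must be >= 0")

    def prob(self, word: str) -> float:
        return float(self.probabilities[word_to_index(word) - 1])

    def se(self, word: str) -> float:
        return float(self.standard_errors[word_to_index(word) - 1])

    def to_tsv(self, path, free_energies: np.ndarray | None = None) -> None:
        if free_energies is None:
            free_energies = population_free_energies(self, self.temperature)
        with open(path, "w") as fh:
            fh.write(
                f"# n_frames={self.n_frames} temperature_K={self.temperature:g}\n"
            )
            fh.write("# index\tword\tprobability\tstandard_error\tdG_kJ_mol\n")
            for i in range(N_STATES):
                dg = free_energies[i]
                dg_s = f"{dg:.4f}" if np.isfinite(dg) else "inf"
                fh.write(
                    f"{i + 1}\t{index_to_word(i + 1)}\t"
                    f"{self.probabilities[i]:.8f}\t{self.standard_errors[i]:.8f}\t"
                    f"{dg_s}\n"
                )


@dataclass
class KineticsSummary:
    """Frame-resolution switching kinetics of a rotamer trajectory."""

    mean_switch_rate: float  # ps^-1 == THz
    n_transitions: int
    total_time: float  # ps
    transition_counts: np.ndarray  # (243, 243) integer counts
    mean_dwell_times: dict[int, float] = field(default_factory=dict)  # state -> ps

    @property
    def rate_thz(self) -> float:
        return self.mean_switch_rate

    def to_json_dict(self) -> dict:
        nz = np.nonzero(self.transition_counts)
        return {
            "mean_switch_rate_per_ps": self.mean_switch_rate,
            "mean_switch_rate_THz": self.mean_switch_rate,
            "n_transitions": int(self.n_transitions),
            "total_time_ps": self.total_time,
            "transition_counts": [
                [int(i + 1), int(j + 1), int(self.transition_counts[i, j])]
                for i, j in zip(*nz)
            ],
            "mean_dwell_times_ps": {
                str(k): v for k, v in self.mean_dwell_times.items()
            },
        }


def estimate_populations(rt: RotamerTrajectory, block_count: int = 5) -> PopulationTable:
    """Frame-fraction populations with block-averaged standard errors.

    The trajectory is split into ``block_count`` contiguous blocks; the SE of
    each state's population is the standard deviation of the block means
    divided by sqrt(block_count).
    """
    if rt.n_frames == 0:
        raise ValueError("empty trajectory")
    if block_count < 2:
        raise ValueError("block_count must be >= 2 for error bars")
    if rt.n_frames < block_count:
        raise ValueError(
            f"fewer frames ({rt.n_frames}) than blocks ({block_count})"
        )
    occ = np.bincount(rt.states - 1, minlength=N_STATES).astype(float)
    probs = occ / rt.n_frames

    edges = np.linspace(0, rt.n_frames, block_count + 1).astype(int)
    block_means = np.empty((block_count, N_STATES))
    for b in range(block_count):
        chunk = rt.states[edges[b] : edges[b + 1]] - 1
        block_means[b] = np.bincount(chunk, minlength=N_STATES) / len(chunk)
    se = block_means.std(axis=0, ddof=1) / np.sqrt(block_count)
    return PopulationTable(probs, se, rt.n_frames, temperature=rt.temperature)


def population_free_energies(pt: PopulationTable, temperature: float) -> np.ndarray:
    """dG_i = -RT ln(p_i / p_max), kJ/mol; zero-probability states are +inf."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    p = pt.probabilities
    p_max = p.max()
    with np.errstate(divide="ignore"):
        return np.where(p > 0, -R_KJ * temperature * np.log(p / p_max), np.inf)


def switching_kinetics(rt: RotamerTrajectory) -> KineticsSummary:
    """Transitions between consecutive frames; rate in ps^-1 (== THz)."""
    if rt.n_frames < 2:
        raise ValueError("need at least 2 frames")
    s = rt.states - 1
    changed = s[1:] != s[:-1]
    n_trans = int(changed.sum())
    total_time = float(rt.times[-1] - rt.times[0])
    counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    if n_trans:
        np.add.at(counts, (s[:-1][changed], s[1:][changed]), 1)
    dwell: dict[int, list[float]] = {}
    for state, _start, dur in rt.dwell_segments():
        dwell.setdefault(state, []).append(dur)
    mean_dwell = {k: float(np.mean(v)) for k, v in dwell.items()}
    return KineticsSummary(
        mean_switch_rate=n_trans / total_time,
        n_transitions=n_trans,
        total_time=total_time,
        transition_counts=counts,
        mean_dwell_times=mean_dwell,
    )


def equilibration_trim(rt: RotamerTrajectory, t_burn: float) -> RotamerTrajectory:
    """Drop frames with time < t_burn (surface runs default to a 5 ns burn-in)."""
    if t_burn < 0:
        raise ValueError("t_burn must be >= 0")
    keep = rt.times >= t_burn
    if not keep.any():
        raise ValueError(
            f"burn-in {t_burn} ps >= trajectory span [{rt.times[0]}, {rt.times[-1]}] ps"
        )
    return RotamerTrajectory(rt.times[keep], rt.states[keep], temperature=rt.temperature)
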