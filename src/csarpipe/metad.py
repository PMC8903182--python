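"""Well-tempered metadynamics post-processing.

Reconstructs free-energy surfaces from hill-deposit files (PLUMED HILLS
dialect), extracts torsional barriers by minimax path search, and computes
funnel-corrected standard-state binding free energies from 1D separation
profiles.

The well-tempered estimator used is final-bias rescaling:
F(s) = -(g/(g-1)) V_final(s), shifted so min F = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import C_STANDARD_PER_NM3, R_KJ


class HillsFormatError(ValueError):
    """Malformed HILLS file (message carries file/line context)."""


@dataclass
class HillsFile:
    """Parsed hill deposits: times (ps), centers/sigmas per CV, heights (kJ/mol)."""

    cv_names: list[str]
    times: np.ndarray
    centers: np.ndarray  # (n_hills, n_cv)
    sigmas: np.ndarray  # (n_hills, n_cv)
    heights: np.ndarray  # kJ/mol
    bias_factor: float
    walkers: np.ndarray | None = None
    periods: list[float | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        self.heights = np.asarray(self.heights, dtype=float)
        if not self.periods:
            self.periods = [None] * len(self.cv_names)
        if self.bias_factor <= 1.0:
            raise ValueError("bias factor must be > 1")

    @property
    def n_hills(self) -> int:
        return len(self.times)

    @property
    def n_cv(self) -> int:
        return len(self.cv_names)


def read_hills(paths) -> HillsFile:
    """Read one HILLS file or a sequence of walker files (merged time-sorted).

    Expected layout per file::

        #! FIELDS time cv1 [cv2] sigma_cv1 [sigma_cv2] height biasf
        #! SET min_cv1 -pi        (optional, marks cv1 periodic)
        #! SET max_cv1 pi
        <numbers...>
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    all_times, all_centers, all_sigmas, all_heights, all_walkers = [], [], [], [], []
    cv_names: list[str] | None = None
    periods: list[float | None] = []
    bias_factor = None
    for w, path in enumerate(paths):
        names, mins, maxs = None, {}, {}
        rows = []
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            if line.startswith("#!"):
                parts = line.split()
                if parts[1] == "FIELDS":
                    cols = parts[2:]
                    if cols[0] != "time" or cols[-1] != "biasf" or cols[-2] != "height":
                        raise HillsFormatError(
                            f"{path}: line {ln}: unexpected FIELDS layout {cols}"
                        )
                    n_cv = (len(cols) - 3) // 2
                    names = cols[1 : 1 + n_cv]
                elif parts[1] == "SET" and parts[2].startswith("min_"):
                    mins[parts[2][4:]] = _parse_pi(parts[3])
                elif parts[1] == "SET" and parts[2].startswith("max_"):
                    maxs[parts[2][4:]] = _parse_pi(parts[3])
                continue
            if names is None:
                raise HillsFormatError(f"{path}: line {ln}: data before FIELDS header")
            vals = line.split()
            if len(vals) != 2 * len(names) + 3:
                raise HillsFormatError(
                    f"{path}: line {ln}: expected {2 * len(names) + 3} columns, "
                    f"got {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise HillsFormatError(f"{path}: line {ln}: non-numeric value") from exc
        if names is None:
            raise HillsFormatError(f"{path}: missing FIELDS header")
        if cv_names is None:
            cv_names = names
            periods = [
                (maxs[n] - mins[n]) if (n in mins and n in maxs) else None
                for n in names
            ]
        elif names != cv_names:
            raise HillsFormatError(f"{path}: CV names {names} differ from {cv_names}")
        n_cv = len(names)
        arr = np.array(rows) if rows else np.empty((0, 2 * n_cv + 3))
        t = arr[:, 0]
        if len(t) > 1 and np.any(np.diff(t) < 0):
            bad = int(np.flatnonzero(np.diff(t) < 0)[0])
            raise HillsFormatError(
                f"{path}: times not non-decreasing at record {bad + 2}"
            )
        all_times.append(t)
        all_centers.append(arr[:, 1 : 1 + n_cv])
        all_sigmas.append(arr[:, 1 + n_cv : 1 + 2 * n_cv])
        all_heights.append(arr[:, 1 + 2 * n_cv])
        all_walkers.append(np.full(len(t), w))
        if len(arr):
            bf = arr[0, -1]
            if bias_factor is not None and abs(bf - bias_factor) > 1e-9:
                raise HillsFormatError(f"{path}: bias factor changed across files")
            bias_factor = bf
    times = np.concatenate(all_times)
    order = np.argsort(times, kind="stable")
    return HillsFile(
        cv_names=cv_names,
        times=times[order],
        centers=np.concatenate(all_centers)[order],
        sigmas=np.concatenate(all_sigmas)[order],
        heights=np.concatenate(all_heights)[order],
        bias_factor=float(bias_factor) if bias_factor is not None else 5.0,
        walkers=np.concatenate(all_walkers)[order],
        periods=periods,
    )


def _parse_pi(token: str) -> float:
    if token == "-pi":
        return -math.pi
    if token == "pi":
        return math.pi
    return float(token)


def write_hills(hills: HillsFile, path) -> None:
    n_cv = hills.n_cv
    with open(path, "w") as fh:
        sig = " ".join(f"sigma_{n}" for n in hills.cv_names)
        fh.write(f"#! FIELDS time {' '.join(hills.cv_names)} {sig} height biasf\n")
        for name, period in zip(hills.cv_names, hills.periods):
            if period is not None:
                fh.write(f"#! SET min_{name} {-period / 2:g}\n")
                fh.write(f"#! SET max_{name} {period / 2:g}\n")
        for i in range(hills.n_hills):
            cs = " ".join(f"{c:.6f}" for c in hills.centers[i])
            ss = " ".join(f"{s:.6f}" for s in hills.sigmas[i])
            fh.write(
                f"{hills.times[i]:.3f} {cs} {ss} {hills.heights[i]:.6f} "
                f"{hills.bias_factor:g}\n"
            )


# ---------------------------------------------------------------------------
# bias evaluation and FES reconstruction
# ---------------------------------------------------------------------------


def _wrapped_delta(x: np.ndarray, period: float | None) -> np.ndarray:
    if period is None:
        return x
    return x - period * np.round(x / period)


def bias_potential(hills: HillsFile, s, n_hills: int | None = None) -> float:
    """Total deposited bias at CV point ``s`` (kJ/mol); additive in hills."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if len(s) != hills.n_cv:
        raise ValueError(f"point has {len(s)} CVs, hills have {hills.n_cv}")
    stop = hills.n_hills if n_hills is None else n_hills
    total = np.ones(stop)
    for k in range(hills.n_cv):
        d = _wrapped_delta(s[k] - hills.centers[:stop, k], hills.periods[k])
        total *= np.exp(-(d**2) / (2.0 * hills.sigmas[:stop, k] ** 2))
    return float(np.dot(hills.heights[:stop], total))


@dataclass
class FreeEnergySurface:
    """F on a regular grid over 1 or 2 CVs, min-shifted to zero (kJ/mol)."""

    grids: list[np.ndarray]
    F: np.ndarray
    periodic: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if not self.periodic:
            self.periodic = [False] * len(self.grids)
        if not np.all(np.isfinite(self.F)):
            raise ValueError("free energy must be finite on the grid")

    @property
    def ndim(self) -> int:
        return len(self.grids)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.ndim == 1:
                fh.write("# cv\tF_kJ_mol\n")
                for x, f in zip(self.grids[0], self.F):
                    fh.write(f"{x:.6f}\t{f:.6f}\n")
            else:
                fh.write("# cv1\tcv2\tF_kJ_mol\n")
                for i, x in enumerate(self.grids[0]):
                    for j, y in enumerate(self.grids[1]):
                        fh.write(f"{x:.6f}\t{y:.6f}\t{self.F[i, j]:.6f}\n")


def _bias_on_grid(
    hills: HillsFile, grids: list[np.ndarray], stop: int, chunk: int = 20000
) -> np.ndarray:
    shape = tuple(len(g) for g in grids)
    total = np.zeros(shape if len(shape) > 1 else shape[0])
    for lo in range(0, stop, chunk):
        hi = min(lo + chunk, stop)
        axes = []
        for k, grid in enumerate(grids):
            d = _wrapped_delta(
                grid[:, None] - hills.centers[None, lo:hi, k], hills.periods[k]
            )
            axes.append(np.exp(-(d**2) / (2.0 * hills.sigmas[None, lo:hi, k] ** 2)))
        if len(grids) == 1:
            total += axes[0] @ hills.heights[lo:hi]
        else:
            total += np.einsum("ih,jh,h->ij", axes[0], axes[1], hills.heights[lo:hi])
    return total


def fes_from_hills(
    hills: HillsFile,
    grids,
    convergence_interval_ps: float | None = None,
) -> FreeEnergySurface | tuple[FreeEnergySurface, list[tuple[float, np.ndarray]]]:
    """Well-tempered FES estimate F = -(g/(g-1)) V_final, min-shifted to 0.

    When ``convergence_interval_ps`` is given, a series of intermediate
    (time, F) snapshots is also returned for convergence diagnostics.
    """
    if isinstance(grids, np.ndarray) and grids.ndim == 1:
        grids = [grids]
    grids = [np.asarray(g, dtype=float) for g in grids]
    g = hills.bias_factor
    scale = g / (g - 1.0)
    periodic = [p is not None for p in hills.periods]

    def estimate(stop: int) -> np.ndarray:
        if stop == 0:
            shape = tuple(len(gr) for gr in grids)
            return np.zeros(shape if len(shape) > 1 else shape[0])
        f = -scale * _bias_on_grid(hills, grids, stop)
        return f - f.min()

    final = FreeEnergySurface(grids, estimate(hills.n_hills), periodic)
    if convergence_interval_ps is None:
        return final
    series = []
    if hills.n_hills:
        t_end = hills.times[-1]
        checkpoints = np.arange(convergence_interval_ps, t_end, convergence_interval_ps)
        for t in checkpoints:
            stop = int(np.searchsorted(hills.times, t, side="right"))
            series.append((float(t), estimate(stop)))
    return final, series


# ---------------------------------------------------------------------------
# barriers
# ---------------------------------------------------------------------------


def _local_min_in_window(fes: FreeEnergySurface, window) -> tuple:
    """Index of the lowest grid point inside a window; reject if not a local min."""
    if fes.ndim == 1:
        lo, hi = window
        mask = (fes.grids[0] >= lo) & (fes.grids[0] <= hi)
        if not mask.any():
            raise ValueError(f"basin window {window} contains no grid points")
        idx = np.flatnonzero(mask)[np.argmin(fes.F[mask])]
        n = len(fes.F)
        for nb in (idx - 1, idx + 1):
            j = nb % n if fes.periodic[0] else min(max(nb, 0), n - 1)
            if fes.F[j] < fes.F[idx] - 1e-12:
                raise ValueError(f"basin window {window} contains no local minimum")
        return (int(idx),)
    (lo0, hi0), (lo1, hi1) = window
    m0 = (fes.grids[0] >= lo0) & (fes.grids[0] <= hi0)
    m1 = (fes.grids[1] >= lo1) & (fes.grids[1] <= hi1)
    if not (m0.any() and m1.any()):
        raise ValueError(f"basin window {window} contains no grid points")
    sub = fes.F[np.ix_(m0, m1)]
    i, j = np.unravel_index(np.argmin(sub), sub.shape)
    return (int(np.flatnonzero(m0)[i]), int(np.flatnonzero(m1)[j]))


def _minimax_saddle(fes: FreeEnergySurface, a, b) -> float:
    """Lowest maximum F along any grid path from a to b (union-find flooding)."""
    F = fes.F
    shape = F.shape if F.ndim == 2 else (len(F),)
    flat = F.ravel()
    order = np.argsort(flat, kind="stable")
    parent = np.full(flat.size, -1, dtype=int)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def neighbors(idx: int):
        if F.ndim == 1:
            n = shape[0]
            for d in (-1, 1):
                j = idx + d
                if fes.periodic[0]:
                    yield j % n
                elif 0 <= j < n:
                    yield j
        else:
            n0, n1 = shape
            i, j = divmod(idx, n1)
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ii, jj = i + di, j + dj
                if fes.periodic[0]:
                    ii %= n0
                if fes.periodic[1]:
                    jj %= n1
                if 0 <= ii < n0 and 0 <= jj < n1:
                    yield ii * n1 + jj

    ia = a[0] if F.ndim == 1 else a[0] * shape[1] + a[1]
    ib = b[0] if F.ndim == 1 else b[0] * shape[1] + b[1]
    for idx in order:
        parent[idx] = idx
        for nb in neighbors(int(idx)):
            if parent[nb] >= 0:
                parent[find(int(idx))] = find(nb)
        if parent[ia] >= 0 and parent[ib] >= 0 and find(ia) == find(ib):
            return float(flat[idx])
    raise RuntimeError("basins never connect")  # pragma: no cover


def barrier_height(fes: FreeEnergySurface, basin_a, basin_b) -> float:
    """Barrier from basin_a's minimum to the lowest saddle towards basin_b.

    1D: highest point on the best path between the two window minima.
    2D: lowest saddle over the 4-connected grid graph (minimax path).
    """
    a = _local_min_in_window(fes, basin_a)
    b = _local_min_in_window(fes, basin_b)
    saddle = _minimax_saddle(fes, a, b)
    f_a = fes.F[a] if fes.ndim == 2 else fes.F[a[0]]
    return float(saddle - f_a)


# ---------------------------------------------------------------------------
# funnel binding free energy
# ---------------------------------------------------------------------------


@dataclass
class FunnelSpec:
    """Cylindrical funnel restraint geometry and analysis windows (nm)."""

    radius: float = 0.5
    bound_window: tuple[float, float] = (0.0, 0.6)
    unbound_window: tuple[float, float] | None = None  # default: outer 20% of axis
    standard_concentration: float = 1.0  # mol/L

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("funnel radius must be > 0")
        if self.unbound_window is not None:
            b0, b1 = self.bound_window
            u0, u1 = self.unbound_window
            if max(b0, u0) < min(b1, u1):
                raise ValueError("bound and unbound windows must be disjoint")


@dataclass
class BindingResult:
    """Standard-state binding free energy and desorption barrier (kJ/mol)."""

    dG_bind: float
    desorption_barrier: float
    K_ratio: float  # Boltzmann integral ratio bound/unbound (dimensionless)
    correction: float  # -RT ln(pi r^2 l_ref c0 NA) term, kJ/mol
    plateau_flat: bool = True


def binding_free_energy(
    fes: FreeEnergySurface, funnel: FunnelSpec, temperature: float
) -> BindingResult:
    """Funnel-corrected standard-state binding free energy from a 1D profile.

    The bound-basin Boltzmann weight is integrated relative to the unbound
    plateau and converted to a standard-state free energy with the funnel
    volume correction:

        dG_bind = -RT ln( K * pi r^2 * l_ref * c0 * N_A )

    with K the bound/unbound Boltzmann-integral ratio and l_ref the length
    of the unbound reference window.  The result is invariant to the
    arbitrary zero of F.  A non-flat unbound plateau (std > RT/2) sets
    ``plateau_flat=False``.
    """
    if fes.ndim != 1:
        raise ValueError("binding analysis needs a 1D separation-CV profile")
    z = fes.grids[0]
    rt = R_KJ * temperature
    unbound = funnel.unbound_window
    if unbound is None:
        span = z[-1] - z[0]
        unbound = (z[-1] - 0.2 * span, z[-1])
    mb = (z >= funnel.bound_window[0]) & (z <= funnel.bound_window[1])
    mu = (z >= unbound[0]) & (z <= unbound[1])
    if mb.sum() < 2 or mu.sum() < 2:
        raise ValueError("bound/unbound windows must each cover >= 2 grid points")
    f_ref = fes.F[mu].min()  # common shift for numeric stability
    ib = np.trapezoid(np.exp(-(fes.F[mb] - f_ref) / rt), z[mb])
    iu = np.trapezoid(np.exp(-(fes.F[mu] - f_ref) / rt), z[mu])
    k_ratio = float(ib / iu)
    l_ref = float(unbound[1] - unbound[0])
    volume_term = (
        math.pi * funnel.radius**2 * l_ref * funnel.standard_concentration
        * C_STANDARD_PER_NM3
    )
    dg = -rt * math.log(k_ratio * volume_term)
    correction = -rt * math.log(
        math.pi * funnel.radius**2 * l_ref * funnel.standard_concentration
        * C_STANDARD_PER_NM3
    )

    # desorption barrier: highest F between the bound minimum and the plateau
    ib_min = np.flatnonzero(mb)[np.argmin(fes.F[mb])]
    iu_start = int(np.flatnonzero(mu)[0])
    lo, hi = sorted((int(ib_min), iu_start))
    saddle = float(fes.F[lo : hi + 1].max())
    barrier = saddle - float(fes.F[ib_min])

    plateau_flat = bool(np.std(fes.F[mu]) <= 0.5 * rt)
    return BindingResult(
        dG_bind=float(dg),
        desorption_barrier=barrier,
        K_ratio=k_ratio,
        correction=float(correction),
        plateau_flat=plateau_flat,
    )
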