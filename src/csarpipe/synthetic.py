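"""Synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage of the pipeline (rotamer classification, population
and kinetics estimation, 2PT, CNT fitting, metadynamics post-processing) is
exercised on data produced here, so the generators are first-class, tested
code.  They emulate

* bulk- and surface-regime torsional dynamics as a Markov chain over the 243
  rotamer states with a prescribed stationary law and switching rate,
  continuous angles emitted as wrapped-normal noise around the T/P/N wells
  (with the surface regime's characteristic cis spikes at 0 deg),
* overdamped Langevin dynamics on periodic torsional potentials (for
  barrier-dominated dynamics at desk scale),
* excess-Gibbs cluster-size curves of the classical-nucleation-theory shape,
* well-tempered metadynamics hill deposition on a known model free-energy
  surface, and
* atomic velocity ensembles (harmonic, diffusive, mixtures) with closed-form
  thermodynamics for the 2PT engine.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KCAL_TO_KJ, R_KJ
from .cnt import ClusterGibbsCurve, calibrated_surface_coefficient
from .metad import HillsFile
from .rotamers import (
    N_STATES,
    N_TORSIONS,
    RotamerState,
    STATE_CENTERS,
    centers_for_indices,
    word_to_index,
)
from .trajectory import Topology, TorsionTrajectory
from .twopt import VelocityTrajectory

#: wrapped-normal emission width around each torsional well, degrees
ANGLE_NOISE_SD = 15.0


# ---------------------------------------------------------------------------
# regime specification and Markov-chain generator
# ---------------------------------------------------------------------------


def distribution_with_background(named: dict[str, float]) -> dict[str, float]:
    """Fix the listed rotamer populations, spread the rest uniformly.

    The remaining probability mass is shared equally among the states not
    named, which is the smoothest completion when only headline rotamers
    have stated populations.
    """
    for word in named:
        word_to_index(word)  # raises with the offending name
    total = float(sum(named.values()))
    if total > 1.0 + 1e-12:
        raise ValueError(f"named populations sum to {total} > 1")
    rest = N_STATES - len(named)
    out = dict(named)
    if rest:
        fill = (1.0 - total) / rest
        for i in range(1, N_STATES + 1):
            w = RotamerState.from_index(i).word
            if w not in named:
                out[w] = fill
    return out


@dataclass
class RegimeSpec:
    """Stationary law and switching kinetics of one dynamical regime.

    ``mean_switch_rate`` is the mean number of observed inter-state
    transitions per picosecond (1 ps^-1 == 1 THz) counted at frame
    resolution.  ``cis_spike_weight`` is the probability that a gauche
    torsion is emitted from the near-0-deg (cis) spike instead of its well
    center; it only makes sense for the surface regime, where hydrogen
    bonding to the protein stabilizes cis arrangements.
    """

    regime: str  # "bulk" | "surface"
    stationary_distribution: dict[str, float]
    mean_switch_rate: float  # ps^-1
    cis_spike_weight: float = 0.0
    temperature: float = 277.0

    def __post_init__(self) -> None:
        if self.regime not in ("bulk", "surface"):
            raise ValueError(f"unknown regime {self.regime!r}")
        for word in self.stationary_distribution:
            word_to_index(word)
        probs = np.array(list(self.stationary_distribution.values()), dtype=float)
        if np.any(probs < 0):
            raise ValueError("negative probability in stationary distribution")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"stationary distribution sums to {probs.sum():.12f}, not 1"
            )
        if self.mean_switch_rate < 0:
            raise ValueError("mean_switch_rate must be >= 0")
        if not 0.0 <= self.cis_spike_weight < 1.0:
            raise ValueError("cis_spike_weight must be in [0, 1)")

    def stationary_vector(self) -> np.ndarray:
        """The stationary law as a length-243 vector indexed by state-1."""
        pi = np.zeros(N_STATES)
        for word, p in self.stationary_distribution.items():
            pi[word_to_index(word) - 1] = p
        return pi


def _simulate_state_chain(
    pi: np.ndarray, rate: float, n_steps: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Frame-resolution Markov chain with stationary law ``pi``.

    Kernel: each frame the state is resampled from ``pi`` with probability
    ``p``; a resample landing on the current state produces no visible
    transition.  This satisfies detailed balance with ``pi`` exactly, and
    ``p = rate*dt / (1 - sum(pi^2))`` makes the expected frame-counted
    transition rate equal to ``rate``.
    """
    if rate == 0.0 or n_steps == 1:
        return np.full(n_steps, rng.choice(N_STATES, p=pi), dtype=np.int64)
    collision = float(np.sum(pi**2))
    p_event = rate * dt / (1.0 - collision)
    q_max = p_event * (1.0 - pi.min())
    if q_max > 1.0:
        raise ValueError(
            f"switch rate {rate}/ps unresolvable at dt={dt} ps (per-frame leave "
            f"probability {q_max:.3f} > 1); use a smaller dt"
        )
    leave_p = p_event * (1.0 - pi)  # per-state probability of visible departure

    states = np.empty(n_steps, dtype=np.int64)
    # pre-drawn candidate targets from pi (rejection against the current state)
    n_events_exp = int(rate * n_steps * dt)
    buf = rng.choice(N_STATES, size=max(64, int(1.4 * n_events_exp) + 64), p=pi)
    buf_i = 0
    current = int(rng.choice(N_STATES, p=pi))
    pos = 0
    while pos < n_steps:
        q = leave_p[current]
        dwell = int(rng.geometric(q)) if q > 0 else n_steps
        end = min(pos + dwell, n_steps)
        states[pos:end] = current
        pos = end
        if pos >= n_steps:
            break
        while True:
            if buf_i >= len(buf):
                buf = rng.choice(N_STATES, size=len(buf), p=pi)
                buf_i = 0
            cand = int(buf[buf_i])
            buf_i += 1
            if cand != current:
                current = cand
                break
    return states


def gen_rotamer_chain(
    spec: RegimeSpec, n_steps: int, dt: float, seed: int
) -> TorsionTrajectory:
    """Sample a torsion-angle trajectory from a rotamer-state Markov chain.

    States follow a stationary Markov chain with the requested law and
    switching rate; angles are wrapped-normal (sd 15 deg) around the state
    centers T=180, P=+60, N=-60, with optional cis spikes at 0 deg for
    gauche torsions (surface regime).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed)
    pi = spec.stationary_vector()
    states = _simulate_state_chain(pi, spec.mean_switch_rate, n_steps, dt, rng)

    centers = centers_for_indices(states + 1)
    angles = centers + rng.normal(0.0, ANGLE_NOISE_SD, size=centers.shape)
    if spec.cis_spike_weight > 0.0:
        gauche = np.abs(centers) < 120.0  # P (+60) and N (-60) wells
        spike = gauche & (rng.random(centers.shape) < spec.cis_spike_weight)
        # half-normal at 0 deg on the sign side of the letter: the histogram
        # spikes at 0 without moving mass across the P/N boundary
        mag = np.abs(rng.normal(0.0, ANGLE_NOISE_SD, size=centers.shape))
        angles = np.where(spike, np.sign(centers) * mag, angles)
    times = np.arange(n_steps, dtype=float) * dt
    return TorsionTrajectory(
        times,
        angles,
        temperature=spec.temperature,
        provenance=f"gen_rotamer_chain regime={spec.regime} seed={seed}",
    )


# ---------------------------------------------------------------------------
# Langevin dynamics on a periodic torsional potential
# ---------------------------------------------------------------------------


@dataclass
class TorsionPES:
    """Periodic torsional potential: sum of A*(1+cos(m*theta - phase)) terms.

    ``barrier_height`` states the dominant well-to-well barrier and is
    validated (within 1%) against the numeric range of the potential.
    """

    terms: list[tuple[float, int, float]]  # (amplitude kJ/mol, multiplicity, phase deg)
    barrier_height: float  # kJ/mol

    def __post_init__(self) -> None:
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be >= 0")
        grid = np.linspace(-180.0, 180.0, 7201)
        v = self.energy(grid)
        numeric = float(v.max() - v.min())
        if self.barrier_height > 0 and abs(numeric - self.barrier_height) > 0.01 * self.barrier_height:
            raise ValueError(
                f"declared barrier {self.barrier_height} kJ/mol inconsistent with "
                f"potential range {numeric:.3f} kJ/mol"
            )

    def energy(self, theta_deg) -> np.ndarray:
        th = np.radians(np.asarray(theta_deg, dtype=float))
        v = np.zeros_like(th)
        for a, m, phase in self.terms:
            v += a * (1.0 + np.cos(m * th - math.radians(phase)))
        return v

    def denergy_dtheta(self, theta_deg):
        """dV/dtheta in kJ/mol per degree."""
        th = np.radians(np.asarray(theta_deg, dtype=float))
        dv = np.zeros_like(th)
        for a, m, phase in self.terms:
            dv += -a * m * np.sin(m * th - math.radians(phase))
        return dv * (math.pi / 180.0)


def double_well_pes(barrier: float = 80.0) -> TorsionPES:
    """Symmetric double well with minima at 0/180 deg and the given barrier."""
    return TorsionPES(terms=[(barrier / 2.0, 2, 180.0)], barrier_height=barrier)


def gen_langevin_torsion(
    pes: TorsionPES,
    temperature: float,
    n_steps: int,
    dt: float,
    seed: int,
    diffusion: float = 2000.0,
    theta0: float | None = None,
) -> TorsionTrajectory:
    """Overdamped Langevin dynamics of one torsion on a periodic potential.

    Euler-Maruyama in degrees with angular diffusion coefficient
    ``diffusion`` (deg^2/ps); the long-time angle law is Boltzmann at
    ``temperature``.  The step size must keep the RMS angular move below
    30 deg (enforced), and an exploding step aborts with a diagnostic.
    """
    rms_step = math.sqrt(2.0 * diffusion * dt)
    if rms_step >= 30.0:
        raise ValueError(
            f"dt={dt} ps too large: RMS angular step {rms_step:.1f} deg >= 30 deg"
        )
    rng = np.random.default_rng(seed)
    beta = 1.0 / (R_KJ * temperature)
    noise = rng.normal(0.0, rms_step, size=n_steps - 1)
    mobility = diffusion * beta * dt  # deg^2/ps * mol/kJ * ps
    theta = np.empty(n_steps)
    theta[0] = 0.0 if theta0 is None else theta0
    terms = [(a, m, math.radians(ph)) for a, m, ph in pes.terms]
    deg2rad = math.pi / 180.0
    th = float(theta[0])
    for k in range(1, n_steps):
        dv = 0.0
        thr = th * deg2rad
        for a, m, ph in terms:
            dv += -a * m * math.sin(m * thr - ph)
        dv *= deg2rad
        step = -mobility * dv + noise[k - 1]
        if abs(step) > 120.0:
            raise RuntimeError(
                f"unstable integration at step {k}: angle step {step:.1f} deg"
            )
        th = (th + step + 180.0) % 360.0 - 180.0
        theta[k] = th
    angles = np.column_stack([theta] + [np.full(n_steps, 180.0)] * (N_TORSIONS - 1))
    return TorsionTrajectory(
        np.arange(n_steps, dtype=float) * dt,
        angles,
        temperature=temperature,
        provenance=f"gen_langevin_torsion seed={seed}",
    )


# ---------------------------------------------------------------------------
# CNT excess-Gibbs curves
# ---------------------------------------------------------------------------


@dataclass
class CNTCurveSpec:
    """Shape of a synthetic excess-Gibbs-vs-cluster-size curve.

    ``two_term_cnt``: dG_ex(N) = -delta_mu*N + b*N^(2/3) (volume driving force
    plus surface penalty).  ``saturating``: dG_ex approaches ``g_slab``
    exponentially with onset scale ``plateau_onset`` (mimics restrained-cluster
    data that levels off at the 2D-periodic slab reference).
    """

    form: str = "two_term_cnt"
    delta_mu: float | None = None  # kJ/mol per molecule
    b: float | None = None  # kJ/mol per N^(2/3)
    g_slab: float = -100.0  # kJ/mol (saturating form)
    plateau_onset: float = 20.0  # molecules
    noise_sd: float = 0.0  # kJ/mol
    n_min: int = 4
    n_max: int = 75

    def __post_init__(self) -> None:
        # default calibration: surface coefficient giving gamma = 34 mJ/m^2
        # at the crystal-structure molecular volume, volume term giving N* = 64
        if self.b is None:
            self.b = calibrated_surface_coefficient(34.0)
        if self.delta_mu is None:
            self.delta_mu = 2.0 * self.b / (3.0 * 64.0 ** (1.0 / 3.0))
        if self.form not in ("two_term_cnt", "saturating"):
            raise ValueError(f"unknown CNT curve form {self.form!r}")
        if not (2 <= self.n_min < self.n_max <= 1000):
            raise ValueError("N range must satisfy 2 <= n_min < n_max <= 1000")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def exact(self, n: np.ndarray) -> np.ndarray:
        if self.form == "two_term_cnt":
            return -self.delta_mu * n + self.b * n ** (2.0 / 3.0)
        return self.g_slab * (1.0 - np.exp(-3.0 * n / self.plateau_onset))


def gen_cnt_curve(spec: CNTCurveSpec, seed: int) -> ClusterGibbsCurve:
    """One dG_ex value per cluster size, with optional Gaussian noise."""
    rng = np.random.default_rng(seed)
    n = np.arange(spec.n_min, spec.n_max + 1)
    dg = spec.exact(n.astype(float))
    if spec.noise_sd > 0:
        dg = dg + rng.normal(0.0, spec.noise_sd, size=len(n))
    sd = np.full(len(n), spec.noise_sd)
    slab = spec.g_slab if spec.form == "saturating" else None
    return ClusterGibbsCurve(N=n, dG=dg, sd=sd, slab_reference=slab)


# ---------------------------------------------------------------------------
# well-tempered metadynamics hill deposition
# ---------------------------------------------------------------------------


@dataclass
class HillsSpec:
    """Protocol and model surface for simulated hill deposition.

    Defaults mirror the reference protocol: deposits every 0.5 ps with
    initial height (277/T) x 1.0 kcal/mol, bias factor g = 5, Gaussian width
    0.01 (radian-valued torsional CV), 10 communicating walkers.
    ``duration_ns`` is per walker.
    """

    cv_grid: np.ndarray  # model CV axis (e.g. radians for a torsion)
    fes_values: np.ndarray  # model free energy, kJ/mol
    periodic: bool = True
    pace_ps: float = 0.5
    initial_height_kcal: float = 1.0
    bias_factor: float = 5.0
    width: float = 0.01
    duration_ns: float = 3.0
    n_walkers: int = 10
    temperature: float = 277.0

    def __post_init__(self) -> None:
        self.cv_grid = np.asarray(self.cv_grid, dtype=float)
        self.fes_values = np.asarray(self.fes_values, dtype=float)
        if self.cv_grid.ndim != 1 or self.cv_grid.shape != self.fes_values.shape:
            raise ValueError("cv_grid and fes_values must be matching 1D arrays")
        if self.bias_factor <= 1.0:
            raise ValueError("bias factor must be > 1")
        if self.pace_ps <= 0 or self.width <= 0:
            raise ValueError("pace and width must be > 0")

    @property
    def initial_height_kj(self) -> float:
        return (277.0 / self.temperature) * self.initial_height_kcal * KCAL_TO_KJ

    @property
    def period(self) -> float:
        dx = self.cv_grid[1] - self.cv_grid[0]
        return (self.cv_grid[-1] - self.cv_grid[0]) + dx


def gen_hills(spec: HillsSpec, seed: int) -> tuple[HillsFile, np.ndarray]:
    """Simulate well-tempered, multiple-walker hill deposition on a model FES.

    At every pace tick each of the ``n_walkers`` walkers is drawn from the
    instantaneous well-tempered measure exp(-(F + V_bias)/kT) on the CV grid
    (the adiabatic-sampling limit that underlies well-tempered convergence),
    and deposits a Gaussian whose height decays as exp(-V_bias/(kB*DeltaT))
    at the deposit point.  The generator emulates the *statistics* of hill
    deposition, not the kinetics of barrier crossing (see
    :func:`gen_langevin_torsion` for the latter).  Returns the hill list
    (merged over walkers) and the visited-CV series of shape
    (n_deposits, n_walkers).
    """
    rng = np.random.default_rng(seed)
    n_dep = int(round(spec.duration_ns * 1000.0 / spec.pace_ps))
    grid = spec.cv_grid
    ngrid = len(grid)
    dx = grid[1] - grid[0]
    if dx > spec.width:
        # refine the bias grid so the narrow hills are resolved
        factor = int(np.ceil(dx / (spec.width / 2.0)))
        fine = np.linspace(grid[0], grid[-1], (ngrid - 1) * factor + 1)
        fvals = np.interp(fine, grid, spec.fes_values)
        grid, ngrid, dx = fine, len(fine), fine[1] - fine[0]
    else:
        fvals = spec.fes_values.copy()

    period = spec.period if spec.periodic else None
    beta = 1.0 / (R_KJ * spec.temperature)
    kdt = R_KJ * spec.temperature * (spec.bias_factor - 1.0)  # kB*DeltaT
    bias = np.zeros(ngrid)
    halfwin = max(2, int(np.ceil(6.0 * spec.width / dx)))
    offsets = np.arange(-halfwin, halfwin + 1)
    kernel = np.exp(-((offsets * dx) ** 2) / (2.0 * spec.width**2))

    if n_dep == 0:
        empty = HillsFile(
            cv_names=["cv"],
            times=np.empty(0),
            centers=np.empty((0, 1)),
            sigmas=np.empty((0, 1)),
            heights=np.empty(0),
            bias_factor=spec.bias_factor,
            walkers=np.empty(0, dtype=int),
            periods=[period],
        )
        return empty, np.empty((0, spec.n_walkers))

    times = np.empty(n_dep * spec.n_walkers)
    centers = np.empty(n_dep * spec.n_walkers)
    heights = np.empty(n_dep * spec.n_walkers)
    walker_ids = np.empty(n_dep * spec.n_walkers, dtype=int)
    cv_series = np.empty((n_dep, spec.n_walkers))

    k = 0
    for d in range(n_dep):
        u = fvals + bias
        w_prob = np.exp(-beta * (u - u.min()))
        cdf = np.cumsum(w_prob)
        draws = np.searchsorted(cdf, rng.random(spec.n_walkers) * cdf[-1])
        # all walkers of one tick read the shared bias before the tick's deposits
        tick_heights = spec.initial_height_kj * np.exp(-bias[draws] / kdt)
        for w, pos in enumerate(draws):
            idx = pos + offsets
            if spec.periodic:
                bias[idx % ngrid] += tick_heights[w] * kernel
            else:
                ok = (idx >= 0) & (idx < ngrid)
                bias[idx[ok]] += tick_heights[w] * kernel[ok]
            times[k] = d * spec.pace_ps
            centers[k] = grid[pos]
            heights[k] = tick_heights[w]
            walker_ids[k] = w
            cv_series[d, w] = grid[pos]
            k += 1

    hills = HillsFile(
        cv_names=["cv"],
        times=times,
        centers=centers[:, None],
        sigmas=np.full((k, 1), spec.width),
        heights=heights,
        bias_factor=spec.bias_factor,
        walkers=walker_ids,
        periods=[period],
    )
    return hills, cv_series


# ---------------------------------------------------------------------------
# velocity ensembles for the 2PT engine
# ---------------------------------------------------------------------------


def gen_velocities(
    kind: str,
    n_atoms: int,
    temperature: float,
    seed: int,
    n_frames: int = 4096,
    dt: float = 0.004,
    mass: float = 12.0,
    frequencies: tuple[float, ...] = (20.0,),
    tau: float = 0.1,
    gas_fraction: float = 0.5,
) -> VelocityTrajectory:
    """Atomic velocity trajectories with known thermodynamics.

    ``harmonic_crystal``: each degree of freedom oscillates at one of the
    given frequencies (THz) with a random phase, amplitudes set by
    equipartition.  ``free_diffusive``: Ornstein-Uhlenbeck velocities with
    relaxation time ``tau`` ps (exponential VACF, nonzero DoS intercept).
    ``mixture``: a fraction ``gas_fraction`` of atoms diffusive, the rest
    harmonic.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    kt_mech = R_KJ * temperature / 0.01  # amu Å^2/ps^2
    sigma_v = math.sqrt(kt_mech / mass)  # Å/ps per DOF
    t = np.arange(n_frames) * dt

    def harmonic_block(n_at: int) -> np.ndarray:
        v = np.empty((n_frames, n_at, 3))
        amp = sigma_v * math.sqrt(2.0)
        for a in range(n_at):
            for c in range(3):
                nu = frequencies[(a * 3 + c) % len(frequencies)]
                phase = rng.uniform(0.0, 2.0 * math.pi)
                v[:, a, c] = amp * np.cos(2.0 * math.pi * nu * t + phase)
        return v

    def diffusive_block(n_at: int) -> np.ndarray:
        decay = math.exp(-dt / tau)
        innov = sigma_v * math.sqrt(1.0 - decay**2)
        v = np.empty((n_frames, n_at, 3))
        v[0] = rng.normal(0.0, sigma_v, size=(n_at, 3))
        noise = rng.normal(0.0, innov, size=(n_frames - 1, n_at, 3))
        for k in range(1, n_frames):
            v[k] = v[k - 1] * decay + noise[k - 1]
        return v

    if kind == "harmonic_crystal":
        vel = harmonic_block(n_atoms)
    elif kind == "free_diffusive":
        vel = diffusive_block(n_atoms)
    elif kind == "mixture":
        n_gas = int(round(gas_fraction * n_atoms))
        vel = np.concatenate(
            [diffusive_block(n_gas), harmonic_block(n_atoms - n_gas)], axis=1
        )
    else:
        raise ValueError(f"unknown velocity ensemble kind {kind!r}")

    return VelocityTrajectory(
        times=t,
        velocities=vel,
        masses=np.full(n_atoms, mass),
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# idealized hexitol coordinates
# ---------------------------------------------------------------------------

_CC_BOND = 1.53
_CO_BOND = 1.43
_CCC_ANGLE = 112.0
_CCO_ANGLE = 109.47


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: new atom X bonded to c with dihedral(a,b,c,X)=torsion."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            bond * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def hexitol_topology() -> Topology:
    """Idealized 12-atom hexitol: C1..C6 backbone, one O per carbon."""
    atoms = [(f"C{i}", "C") for i in range(1, 7)] + [(f"O{i}", "O") for i in range(1, 7)]
    quads = [(6 + i, i, i + 1, 7 + i) for i in range(5)]  # (O_i, C_i, C_i+1, O_i+1)
    oxy = list(range(6, 12))
    return Topology(atoms=atoms, torsion_quads=quads, donors=oxy, acceptors=oxy)


def build_polyol_coordinates(state: RotamerState | str) -> tuple[np.ndarray, Topology]:
    """Cartesian coordinates of an idealized hexitol in the given rotamer state.

    The six-carbon backbone is built all-anti; each hydroxyl oxygen is placed
    so that the five O-C-C-O torsions equal the state's canonical angles
    (T=180, P=+60, N=-60 deg) to within 0.1 deg.
    """
    if isinstance(state, str):
        state = RotamerState(state)
    targets = [STATE_CENTERS[c] for c in state.word]

    coords = np.zeros((12, 3))
    # backbone C1..C6, all-anti
    coords[0] = [0.0, 0.0, 0.0]
    coords[1] = [_CC_BOND, 0.0, 0.0]
    ang = math.radians(180.0 - _CCC_ANGLE)
    coords[2] = coords[1] + _CC_BOND * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(3, 6):
        coords[i] = _place_atom(
            coords[i - 3], coords[i - 2], coords[i - 1], _CC_BOND, _CCC_ANGLE, 180.0
        )
    # O1 via refs (C3, C2, C1); its own torsion against C3 is arbitrary
    coords[6] = _place_atom(coords[2], coords[1], coords[0], _CO_BOND, _CCO_ANGLE, 60.0)
    # O_{i+1} placed with dihedral(O_i, C_i, C_{i+1}, O_{i+1}) = target
    for i in range(5):
        coords[7 + i] = _place_atom(
            coords[6 + i], coords[i], coords[i + 1], _CO_BOND, _CCO_ANGLE, targets[i]
        )
    return coords, hexitol_topology()
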