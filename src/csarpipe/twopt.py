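"""Two-phase thermodynamics (2PT): absolute entropy and free energy from
velocity trajectories.

The mass-weighted velocity autocorrelation function is Fourier-transformed
into a vibrational density of states S(nu) normalized so that its integral
equals the number of degrees of freedom.  The zero-frequency intercept
measures diffusivity; the dimensionless diffusivity Delta determines the
fluidicity f through the universal 2PT self-consistency equation

    2 Delta^{-9/2} f^{15/2} - 6 Delta^{-3} f^5 - Delta^{-3/2} f^{7/2}
        + 6 Delta^{-3/2} f^{5/2} + 2 f - 2 = 0 .

S(nu) is then split into a gas-like component (a hard-sphere Lorentzian
carrying a fraction f of the modes) and a solid-like remainder; entropy and
energy follow from hard-sphere expressions for the gas part and
quantum-harmonic-oscillator weighting for the solid part.  Working units:
ps, Å, amu, K; energies are reported in kJ/mol for the whole N-molecule
system (monoatomic molecules assumed, as in the velocity fixtures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import BAR_NM3_TO_KJ_MOL, H_PLANCK, R_KJ

_KJ_PER_MECH = 0.01  # 1 amu Å^2/ps^2 in kJ/mol


class TwoPTError(RuntimeError):
    """Numeric failure inside the 2PT pipeline."""


@dataclass
class VelocityTrajectory:
    """Per-atom velocity time series: (n_frames, n_atoms, 3) in Å/ps."""

    times: np.ndarray  # ps, uniformly spaced
    velocities: np.ndarray
    masses: np.ndarray  # amu
    temperature: float  # K

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.velocities.ndim != 3 or self.velocities.shape[2] != 3:
            raise ValueError("velocities must be (n_frames, n_atoms, 3)")
        if len(self.times) != self.velocities.shape[0]:
            raise ValueError("times/velocities mismatch")
        if len(self.masses) != self.velocities.shape[1]:
            raise ValueError("masses/velocities mismatch")
        if len(self.times) > 2:
            dts = np.diff(self.times)
            if not np.allclose(dts, dts[0], rtol=1e-6):
                raise ValueError("non-uniform timestep")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_atoms(self) -> int:
        return self.velocities.shape[1]


@dataclass
class VACF:
    """Mass-weighted velocity autocorrelation, amu Å^2/ps^2 vs lag (ps)."""

    lags: np.ndarray
    values: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


@dataclass
class DoSSpectrum:
    """Vibrational density of states S(nu): modes per THz vs frequency (THz)."""

    frequencies: np.ndarray  # ps^-1 == THz
    S: np.ndarray  # dimensionless density (ps)
    n_dof: int
    raw_integral: float | None = None  # integral before normalization enforcement

    def integral(self) -> float:
        return float(np.trapezoid(self.S, self.frequencies))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# frequency_THz\tS_per_THz\n")
            for nu, s in zip(self.frequencies, self.S):
                fh.write(f"{nu:.6f}\t{s:.8f}\n")


@dataclass
class ThermoResult:
    """2PT-decomposed thermodynamics of an N-molecule system."""

    fluidicity: float
    entropy: float  # J/mol/K (whole system)
    energy: float  # kJ/mol
    helmholtz: float  # kJ/mol
    gibbs: float  # kJ/mol
    temperature: float  # K
    pressure_bar: float = 1.0
    gas_dof: float = 0.0
    solid_dof: float = 0.0
    gibbs_err: float = 0.0
    decomposition: dict = field(default_factory=dict)


def velocity_autocorrelation(vt: VelocityTrajectory, max_lag: float) -> VACF:
    """C(tau) = sum_j m_j <v_j(t).v_j(t+tau)>, averaged over time origins.

    Computed with FFT (unbiased normalization per lag); C(0) equals twice the
    mean kinetic energy in amu Å^2/ps^2.
    """
    dt = vt.dt
    n_frames = vt.velocities.shape[0]
    n_lag = int(round(max_lag / dt))
    if n_lag < 1 or 2 * n_lag > n_frames:
        raise ValueError("need at least 2*max_lag/dt frames")
    nfft = 1 << int(np.ceil(np.log2(2 * n_frames)))
    # FFT autocorrelation over all atoms/components at once
    v = vt.velocities.reshape(n_frames, -1)
    fv = np.fft.rfft(v, n=nfft, axis=0)
    acf = np.fft.irfft(fv * np.conj(fv), n=nfft, axis=0)[: n_lag + 1]
    weights = np.repeat(vt.masses, 3)
    c = acf @ weights
    c /= n_frames - np.arange(n_lag + 1)
    return VACF(np.arange(n_lag + 1) * dt, c)


def density_of_states(
    vacf: VACF, temperature: float, n_dof: int, window: str = "bartlett",
    zero_pad: int = 4
) -> DoSSpectrum:
    """One-sided cosine transform of the (windowed) VACF.

    S(nu) = (2 / k_B T) * FT[C](nu); with a window that is 1 at zero lag the
    integral of S equals C(0)/k_B T, i.e. N_dof up to the sampling error of
    the kinetic temperature.  The normalization invariant (integral exactly
    N_dof) is enforced by rescaling -- equivalent to using the trajectory's
    own kinetic temperature -- provided the raw integral is within 5% of
    N_dof; a larger discrepancy raises.  The raw integral is kept on the
    result for diagnostics.  The default Bartlett (Fejér) window has a
    non-negative transform, so the spectral estimate itself is non-negative
    and clipping is a no-op; a Hann window is available where narrower side
    lobes matter more than positivity.
    """
    c = vacf.values.copy()
    k = np.arange(len(c))
    if window == "bartlett":
        c *= 1.0 - k / len(c)
    elif window == "hann":
        c *= 0.5 * (1.0 + np.cos(math.pi * k / (len(c) - 1)))
    elif window not in (None, "none"):
        raise ValueError(f"unknown window {window!r}")
    m = zero_pad * (1 << int(np.ceil(np.log2(2 * len(c)))))
    sym = np.zeros(m)
    sym[: len(c)] = c
    sym[-(len(c) - 1):] = c[1:][::-1]  # even extension
    spec = np.fft.rfft(sym).real * vacf.dt
    kt_mech = R_KJ * temperature / _KJ_PER_MECH
    s = 2.0 * spec / kt_mech
    if s.sum() < 0:
        raise TwoPTError("negative total spectral power")
    s = np.clip(s, 0.0, None)
    freqs = np.fft.rfftfreq(m, vacf.dt)
    raw = float(np.trapezoid(s, freqs))
    if abs(raw - n_dof) > 0.05 * n_dof:
        raise TwoPTError(
            f"DoS normalization violated: integral {raw:.2f} vs N_dof {n_dof}"
        )
    s *= n_dof / raw
    return DoSSpectrum(freqs, s, n_dof, raw_integral=raw)


def _fluidicity_polynomial(f: float, delta: float) -> float:
    return (
        2.0 * delta ** (-4.5) * f**7.5
        - 6.0 * delta**-3 * f**5
        - delta**-1.5 * f**3.5
        + 6.0 * delta**-1.5 * f**2.5
        + 2.0 * f
        - 2.0
    )


def normalized_diffusivity(
    s0: float, n_molecules: int, temperature: float, density: float, mass: float
) -> float:
    """Dimensionless 2PT diffusivity Delta from the DoS intercept.

    ``density`` in molecules/nm^3, ``mass`` amu, ``s0`` in ps.
    """
    kt_mech = R_KJ * temperature / _KJ_PER_MECH
    rho_a3 = density / 1000.0  # molecules per Å^3
    return (
        (2.0 * s0 / (9.0 * n_molecules))
        * math.sqrt(math.pi * kt_mech / mass)
        * rho_a3 ** (1.0 / 3.0)
        * (6.0 / math.pi) ** (2.0 / 3.0)
    )


def solve_fluidicity(delta: float) -> float:
    """Root of the universal 2PT equation in [0, 1]."""
    if delta <= 0.0:
        return 0.0
    lo, hi = 1e-12, 1.0
    flo = _fluidicity_polynomial(lo, delta)
    fhi = _fluidicity_polynomial(hi, delta)
    if flo * fhi > 0:
        raise TwoPTError(f"no fluidicity root in [0,1] for Delta={delta:.4g}")
    return float(brentq(_fluidicity_polynomial, lo, hi, args=(delta,), xtol=1e-12))


def _qho_weights(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quantum-harmonic entropy and energy weights vs x = h nu / kT."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ex = np.exp(-x)
        w_s = np.where(x > 0, x * ex / (1.0 - ex) - np.log1p(-ex), 0.0)
        w_e = np.where(x > 0, x / 2.0 + x * ex / (1.0 - ex), 1.0)
    w_s = np.nan_to_num(w_s, nan=0.0, posinf=0.0)
    w_e = np.nan_to_num(w_e, nan=1.0, posinf=0.0)
    return w_s, w_e


def hard_sphere_entropy_weight(f: float, delta: float, density: float,
                               mass: float, temperature: float) -> float:
    """Per-mode entropy weight (units of k_B) of the hard-sphere gas component.

    Carnahan-Starling excess on top of the ideal term, with packing fraction
    y = f^(5/2) / Delta^(3/2); the gas occupies a fraction f of the N
    molecules in volume V.
    """
    kt_mech = R_KJ * temperature / _KJ_PER_MECH
    lam = (H_PLANCK / _KJ_PER_MECH) / math.sqrt(2.0 * math.pi * mass * kt_mech)  # Å
    y = f**2.5 / delta**1.5 if delta > 0 else 0.0
    if y >= 1.0:
        raise TwoPTError(f"hard-sphere packing fraction y={y:.3f} >= 1")
    z = (1.0 + y + y**2 - y**3) / (1.0 - y) ** 3
    rho_a3 = density / 1000.0
    s_ig = 2.5 + math.log((1.0 / (rho_a3 * f * lam**3)) * z) if f > 0 else 0.0
    s_exc = y * (3.0 * y - 4.0) / (1.0 - y) ** 2
    return (s_ig + s_exc) / 3.0


def two_pt_thermo(
    dos: DoSSpectrum,
    density: float,
    mass: float,
    temperature: float,
    pressure_bar: float = 1.0,
) -> ThermoResult:
    """Full 2PT decomposition of a density of states.

    ``density`` is the molecular number density in molecules/nm^3 and
    ``mass`` the molecular mass in amu; the DoS is assumed to describe
    N = n_dof/3 monoatomic molecules.
    """
    n_mol = dos.n_dof // 3
    s0 = float(dos.S[0])
    if not math.isfinite(s0):
        raise TwoPTError("S(0) not finite")
    delta = normalized_diffusivity(s0, n_mol, temperature, density, mass)
    f = solve_fluidicity(delta)
    # Solid limit: as Delta -> 0 the packing fraction y -> 1 and the
    # hard-sphere excess entropy diverges per mode while the gas mode count
    # vanishes.  When the gas component carries less than a tenth of one
    # mode it is physically empty; treat the system as fully solid.
    if 3.0 * f * n_mol < 0.1:
        f, s0 = 0.0, 0.0

    nu = dos.frequencies
    if f > 0 and s0 > 0:
        s_gas = s0 / (1.0 + (math.pi * s0 * nu / (6.0 * f * n_mol)) ** 2)
        s_gas = np.minimum(s_gas, dos.S)
    else:
        s_gas = np.zeros_like(dos.S)
    s_solid = dos.S - s_gas

    x = H_PLANCK * nu / (R_KJ * temperature)
    w_s, w_e = _qho_weights(x)
    gas_dof = float(np.trapezoid(s_gas, nu))
    solid_dof = float(np.trapezoid(s_solid, nu))

    w_s_gas = hard_sphere_entropy_weight(f, delta, density, mass, temperature)
    entropy_kj = R_KJ * (
        float(np.trapezoid(s_solid * w_s, nu)) + w_s_gas * gas_dof
    )  # kJ/mol/K
    energy = R_KJ * temperature * (
        float(np.trapezoid(s_solid * w_e, nu)) + 0.5 * gas_dof
    )
    helmholtz = energy - temperature * entropy_kj
    volume_nm3 = n_mol / density
    gibbs = helmholtz + pressure_bar * volume_nm3 * BAR_NM3_TO_KJ_MOL

    return ThermoResult(
        fluidicity=f,
        entropy=entropy_kj * 1000.0,
        energy=energy,
        helmholtz=helmholtz,
        gibbs=gibbs,
        temperature=temperature,
        pressure_bar=pressure_bar,
        gas_dof=gas_dof,
        solid_dof=solid_dof,
        decomposition={
            "delta": delta,
            "S_gas_J_mol_K": R_KJ * w_s_gas * gas_dof * 1000.0,
            "S_solid_J_mol_K": R_KJ * float(np.trapezoid(s_solid * w_s, nu)) * 1000.0,
        },
    )


def excess_gibbs_point(
    cluster: ThermoResult, n_molecules: int, bulk_reference: ThermoResult
) -> tuple[float, float]:
    """Excess Gibbs energy of an N-molecule cluster vs n times the bulk.

    Returns (dG_ex, 1-SD uncertainty) in kJ/mol; uncertainties combine in
    quadrature.  Temperatures (and pressures) must match.
    """
    if abs(cluster.temperature - bulk_reference.temperature) > 1e-9:
        raise ValueError(
            f"temperature mismatch: cluster {cluster.temperature} K vs "
            f"bulk {bulk_reference.temperature} K"
        )
    dg = cluster.gibbs - n_molecules * bulk_reference.gibbs
    err = math.hypot(cluster.gibbs_err, n_molecules * bulk_reference.gibbs_err)
    return float(dg), float(err)


def gas_tau_for_fluidicity(
    f0: float, n_molecules: int, mass: float, temperature: float, density: float
) -> float:
    """OU relaxation time whose DoS intercept is 2PT-consistent with ``f0``.

    A mixture fixture whose diffusive component has this relaxation time
    produces a zero-frequency intercept for which the universal fluidicity
    equation returns ``f0``; used to build recovery-against-construction
    fixtures.  Inverts the fluidicity polynomial through the substitution
    u = f^(5/2)/Delta^(3/2) (a cubic in u for fixed f).
    """
    if not 0.0 < f0 < 1.0:
        raise ValueError("f0 must be in (0, 1)")
    roots = np.roots([2.0, -6.0, 6.0 - f0, 2.0 * f0 - 2.0])
    real = [r.real for r in roots if abs(r.imag) < 1e-10 and 0.0 < r.real < 1.0]
    if not real:
        raise TwoPTError(f"no packing-fraction root for f0={f0}")
    u = min(real)
    delta = f0 ** (5.0 / 3.0) / u ** (2.0 / 3.0)
    kt_mech = R_KJ * temperature / _KJ_PER_MECH
    rho_a3 = density / 1000.0
    s0 = (
        delta
        * 9.0
        * n_molecules
        / 2.0
        / (math.sqrt(math.pi * kt_mech / mass) * rho_a3 ** (1.0 / 3.0)
           * (6.0 / math.pi) ** (2.0 / 3.0))
    )
    return s0 / (12.0 * f0 * n_molecules)


def qho_entropy(frequency_thz: float, temperature: float) -> float:
    """Closed-form quantum harmonic oscillator entropy per mode, J/mol/K."""
    x = H_PLANCK * frequency_thz / (R_KJ * temperature)
    w_s, _ = _qho_weights(np.array([x]))
    return float(R_KJ * w_s[0] * 1000.0)
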