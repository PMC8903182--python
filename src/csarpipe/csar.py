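"""Catch-switch-and-release (CSaR) steady-state depletion model.

A master equation over 2 x 243 states (each rotamer in the bulk and on the
protein surface) realizes the mechanism by which an antifreeze protein
depletes the crystal-forming rotamer (CFR) from solution:

* bulk <-> bulk interconversion is slow (barrier-dominated, Arrhenius rate
  from an ~80 kJ/mol torsional barrier) and satisfies detailed balance with
  the bulk stationary law;
* bulk -> surface adsorption is rotamer-selective: attractive binding
  captures at the diffusion-limited rate, repulsive binding is penalized by
  exp(-dG_bind/RT);
* surface <-> surface randomization is fast (THz-scale switching against
  the surface stationary law);
* surface -> bulk desorption is Arrhenius in the desorption barrier,
  weighted so that each rotamer's adsorption/desorption pair alone is in
  detailed balance with its binding free energy.

Because the bulk law, the surface law and the per-rotamer binding energies
are independently specified, the cycles of the chain are thermodynamically
inconsistent and the steady state is a driven one: CFR molecules are caught,
randomized, and released as long-lived non-crystal-forming rotamers, so the
bulk CFR population is depleted far below its equilibrium value.  The
steady state is solved with the subtraction-free GTH elimination, which
stays accurate over the ~18 orders of magnitude spanned by the rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import R_KJ
from .populations import PopulationTable
from .rotamers import CFR_WORD, N_STATES, word_to_index


def rate_from_barrier(barrier: float, prefactor: float, temperature: float) -> float:
    """Arrhenius/Kramers rate k = prefactor * exp(-barrier / RT), ps^-1."""
    if barrier < 0:
        raise ValueError("barrier must be >= 0")
    return prefactor * math.exp(-barrier / (R_KJ * temperature))


#: sentinel binding free energy for rotamers the protein does not favour
DEFAULT_BINDING_DG = 30.0
#: class default desorption barrier where not individually stated
DEFAULT_DESORPTION_BARRIER = 3.0

#: per-rotamer binding free energies to the ice-binding site, kJ/mol
STATED_BINDING_DG = {CFR_WORD: -20.5, "NPTNP": 14.5, "NNNPN": 22.0}
#: desorption activation barriers of the two release rotamers, kJ/mol
STATED_DESORPTION_BARRIERS = {"NPTNP": 3.0, "NNNPN": 3.5}


@dataclass
class CSaRParameters:
    """Inputs of the depletion model (energies kJ/mol, rates ps^-1, conc mol/L)."""

    bulk_distribution: np.ndarray  # length-243 stationary law in bulk
    surface_distribution: np.ndarray  # length-243 stationary law on the surface
    bulk_barrier: float = 80.0
    bulk_prefactor: float = 10.0
    surface_switch_rate: float = 10.0
    binding_dG: dict[str, float] = field(
        default_factory=lambda: dict(STATED_BINDING_DG)
    )
    default_binding_dG: float = DEFAULT_BINDING_DG
    desorption_barriers: dict[str, float] = field(
        default_factory=lambda: dict(STATED_DESORPTION_BARRIERS)
    )
    default_desorption_barrier: float = DEFAULT_DESORPTION_BARRIER
    protein_concentration: float = 2.8e-6  # mol/L
    polyol_concentration: float = 1.0  # mol/L
    k_on: float = 1e-2  # L/mol/ps, diffusion-limited association
    desorption_prefactor: float = 10.0  # ps^-1 (the surface switching ceiling)
    temperature: float = 277.0

    def __post_init__(self) -> None:
        self.bulk_distribution = np.asarray(self.bulk_distribution, dtype=float)
        self.surface_distribution = np.asarray(self.surface_distribution, dtype=float)
        for name, dist in (
            ("bulk", self.bulk_distribution),
            ("surface", self.surface_distribution),
        ):
            if dist.shape != (N_STATES,):
                raise ValueError(f"{name} distribution must have length {N_STATES}")
            if np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} distribution must be normalized")
        for word in list(self.binding_dG) + list(self.desorption_barriers):
            word_to_index(word)
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        for val, name in (
            (self.k_on, "k_on"),
            (self.protein_concentration, "protein_concentration"),
            (self.surface_switch_rate, "surface_switch_rate"),
            (self.bulk_prefactor, "bulk_prefactor"),
            (self.desorption_prefactor, "desorption_prefactor"),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")

    def binding_vector(self) -> np.ndarray:
        dg = np.full(N_STATES, self.default_binding_dG)
        for word, val in self.binding_dG.items():
            dg[word_to_index(word) - 1] = val
        return dg

    def desorption_barrier_vector(self) -> np.ndarray:
        bar = np.full(N_STATES, self.default_desorption_barrier)
        for word, val in self.desorption_barriers.items():
            bar[word_to_index(word) - 1] = val
        return bar


@dataclass
class CSaRModel:
    """Rate matrix Q (Q[i,j] = rate i->j, rows sum to 0) over bulk+surface states."""

    Q: np.ndarray  # (486, 486)
    params: CSaRParameters

    @property
    def n(self) -> int:
        return self.Q.shape[0]


@dataclass
class DepletionResult:
    """Steady state of the CSaR chain and the CFR depletion it implies."""

    bulk_populations: PopulationTable  # conditional on being in the bulk
    surface_mass: float  # total stationary probability on the surface
    depletion_factor: float  # p_bulk,0(CFR) / p_bulk,inf(CFR)
    depleted_word: str
    fluxes: dict[str, float] = field(default_factory=dict)  # events/ps (x c NA for /L)


@dataclass
class InductionEstimate:
    """Nucleation induction time scaled by the depletion factor."""

    baseline_days: float
    extrapolated_days: float
    scaling_assumption: str = "linear nucleation rate in CFR concentration"

    @property
    def extrapolated_years(self) -> float:
        return self.extrapolated_days / 365.25


def build_model(params: CSaRParameters) -> CSaRModel:
    """Assemble the 486-state rate matrix from the kinetic parameters."""
    rt = R_KJ * params.temperature
    pi_b = params.bulk_distribution
    pi_s = params.surface_distribution
    dg = params.binding_vector()
    bar = params.desorption_barrier_vector()

    n = 2 * N_STATES
    Q = np.zeros((n, n))
    B = slice(0, N_STATES)
    S = slice(N_STATES, n)

    # bulk <-> bulk: resampling kernel c_b * pi_b(j), detailed balance with pi_b
    c_b = rate_from_barrier(params.bulk_barrier, params.bulk_prefactor,
                            params.temperature)
    Q[B, B] = c_b * pi_b[None, :]

    # surface <-> surface: same construction against the surface law
    Q[S, S] = params.surface_switch_rate * pi_s[None, :]

    # bulk -> surface: selective capture
    k_ads = params.k_on * params.protein_concentration * np.exp(
        -np.maximum(0.0, dg) / rt
    )
    # surface -> bulk: Arrhenius in the desorption barrier, weighted by
    # exp(+min(0, dG)/RT) so each vertical pair alone obeys detailed balance
    # with its binding free energy
    k_des = params.desorption_prefactor * np.exp(-bar / rt) * np.exp(
        np.minimum(0.0, dg) / rt
    )
    idx = np.arange(N_STATES)
    Q[idx, idx + N_STATES] = k_ads
    Q[idx + N_STATES, idx] = k_des

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
        raise RuntimeError("rate matrix rows do not sum to zero")
    return CSaRModel(Q=Q, params=params)


def gth_stationary(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a rate matrix by GTH elimination.

    The Grassmann-Taksar-Heyman algorithm uses only additions of
    non-negative quantities, so it keeps full relative accuracy even when
    the rates (and the stationary probabilities) span many orders of
    magnitude -- which a null-space SVD does not.  State 0 must belong to
    the chain's recurrent class; transient states receive probability 0.
    """
    n = Q.shape[0]
    W = np.where(np.eye(n, dtype=bool), 0.0, np.maximum(Q, 0.0))
    for k in range(n - 1, 0, -1):
        s = W[k, :k].sum()
        if s <= 0.0:
            # k cannot reach the lower states even through eliminated ones:
            # it lies outside the recurrent class containing state 0
            W[:k, k] = 0.0
            continue
        # censor state k: fold its through-traffic into the remaining states
        W[:k, :k] += np.outer(W[:k, k], W[k, :k]) / s
    pi = np.zeros(n)
    pi[0] = 1.0
    for k in range(1, n):
        s = W[k, :k].sum()
        if s <= 0.0:
            pi[k] = 0.0
            continue
        pi[k] = float(pi[:k] @ W[:k, k]) / s
    total = pi.sum()
    if total <= 0:
        raise RuntimeError("GTH elimination produced a zero vector")
    return pi / total


def steady_state(model: CSaRModel, depleted_word: str = CFR_WORD) -> DepletionResult:
    """Solve the chain's stationary law and quantify bulk depletion.

    The depletion factor compares the named rotamer's share of the *bulk*
    compartment before (the input bulk law) and after (the stationary
    conditional-on-bulk law) the protein is switched on.
    """
    Q = model.Q
    if model.params.protein_concentration == 0.0:
        warnings.warn(
            "zero protein concentration: surface states unreachable; "
            "solving the bulk component",
            stacklevel=2,
        )
    pi = gth_stationary(Q)
    if abs(pi.sum() - 1.0) > 1e-9:
        raise RuntimeError("stationary law not normalized")
    bulk = pi[:N_STATES]
    surface = pi[N_STATES:]
    bulk_mass = float(bulk.sum())
    if bulk_mass <= 0:
        raise RuntimeError("no stationary mass in the bulk compartment")
    bulk_cond = bulk / bulk_mass

    i_dep = word_to_index(depleted_word) - 1
    p0 = float(model.params.bulk_distribution[i_dep])
    p_inf = float(bulk_cond[i_dep])
    factor = math.inf if p_inf == 0.0 else p0 / p_inf

    idx = np.arange(N_STATES)
    k_ads = Q[idx, idx + N_STATES]
    k_des = Q[idx + N_STATES, idx]
    fluxes = {
        "adsorption_per_ps": float(bulk @ k_ads),
        "desorption_per_ps": float(surface @ k_des),
        "net_exchange_per_ps": float(bulk @ k_ads - surface @ k_des),
        "bulk_interconversion_per_ps": float(
            np.sum(bulk[:, None] * Q[:N_STATES, :N_STATES])
            - np.sum(bulk * np.diag(Q[:N_STATES, :N_STATES]))
        ),
        "depleted_rotamer_capture_per_ps": float(bulk[i_dep] * k_ads[i_dep]),
    }
    table = PopulationTable(
        probabilities=bulk_cond / bulk_cond.sum(),
        standard_errors=np.zeros(N_STATES),
        n_frames=0,
        temperature=model.params.temperature,
    )
    return DepletionResult(
        bulk_populations=table,
        surface_mass=float(surface.sum()),
        depletion_factor=factor,
        depleted_word=depleted_word,
        fluxes=fluxes,
    )


def induction_time(
    depletion: DepletionResult | float, baseline_days: float = 14.0
) -> InductionEstimate:
    """Extrapolate the induction time: baseline x depletion factor.

    Assumes the nucleation rate is linear in the crystal-forming rotamer
    concentration, so depleting the CFR by a factor F stretches the
    induction time by the same factor.
    """
    if baseline_days <= 0:
        raise ValueError("baseline must be > 0 days")
    factor = (
        depletion.depletion_factor
        if isinstance(depletion, DepletionResult)
        else float(depletion)
    )
    if factor < 0:
        raise ValueError("depletion factor must be >= 0")
    return InductionEstimate(
        baseline_days=baseline_days,
        extrapolated_days=baseline_days * factor,
    )
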