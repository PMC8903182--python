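"""Canonical study-condition fixtures.

These bundle the generator configurations that the recovery experiments run
on: the bulk and surface regime specifications with the stated headline
rotamer populations, the calibrated excess-Gibbs curve (critical size 64,
interfacial tension 34 mJ/m^2 at the crystal-structure molecular volume),
the 80 kJ/mol torsional double well for metadynamics round trips, and
analytically calibrated funnel binding profiles.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import C_STANDARD_PER_NM3, R_KJ
from .csar import CSaRParameters
from .metad import FreeEnergySurface, FunnelSpec
from .rotamers import BR_WORD, CFR_WORD
from .synthetic import (
    CNTCurveSpec,
    HillsSpec,
    RegimeSpec,
    distribution_with_background,
    double_well_pes,
)

#: bulk-solution headline populations at 277 K
BULK_POPULATIONS = {BR_WORD: 0.337, CFR_WORD: 0.0045}
#: surface (ice-binding-site) headline populations
SURFACE_POPULATIONS = {"NNNPN": 0.012, "NPTNP": 0.010}

#: frame spacing of bulk-regime snapshots, ps
BULK_DT = 1.0
#: frame spacing of surface-regime snapshots, ps (resolves THz switching)
SURFACE_DT = 0.01
#: bulk-regime observed switching rate used for sampling fixtures, ps^-1.
#: This is a decorrelation scale for equilibrium-ensemble emulation, not the
#: physical barrier-limited rate (see docs/methods.md).
BULK_SWITCH_RATE = 0.1
#: surface-regime switching rate, ps^-1 (THz-scale randomization)
SURFACE_SWITCH_RATE = 10.0
#: probability mass of the near-0-degree cis spikes on surface gauche torsions
SURFACE_CIS_SPIKE = 0.15


def bulk_regime_spec(temperature: float = 277.0) -> RegimeSpec:
    """Bulk-solution regime: BR at 33.7%, CFR at 0.45%, slow switching."""
    return RegimeSpec(
        regime="bulk",
        stationary_distribution=distribution_with_background(BULK_POPULATIONS),
        mean_switch_rate=BULK_SWITCH_RATE,
        cis_spike_weight=0.0,
        temperature=temperature,
    )


def surface_regime_spec(temperature: float = 277.0) -> RegimeSpec:
    """Surface regime: release rotamers at 1.2%/1.0%, 10 THz switching, cis spikes."""
    return RegimeSpec(
        regime="surface",
        stationary_distribution=distribution_with_background(SURFACE_POPULATIONS),
        mean_switch_rate=SURFACE_SWITCH_RATE,
        cis_spike_weight=SURFACE_CIS_SPIKE,
        temperature=temperature,
    )


def calibrated_cnt_spec(noise_sd: float = 0.0) -> CNTCurveSpec:
    """Two-term CNT curve over N = 4..75 calibrated to N* = 64, gamma = 34 mJ/m^2."""
    return CNTCurveSpec(form="two_term_cnt", noise_sd=noise_sd, n_min=4, n_max=75)


def torsion_double_well_hills_spec(
    barrier: float = 80.0,
    duration_ns: float = 40.0,
    n_grid: int = 720,
) -> HillsSpec:
    """Metadynamics protocol on the reference torsional double well.

    The model surface is the 2-fold cosine well with the given barrier on a
    periodic torsion CV in radians; deposition follows the reference
    protocol (pace 0.5 ps, initial height 277/T x 1 kcal/mol, bias factor 5,
    width 0.01 rad, 10 walkers); ``duration_ns`` is per walker.
    """
    pes = double_well_pes(barrier)
    grid = -math.pi + np.arange(n_grid) * (2.0 * math.pi / n_grid)
    fes = pes.energy(np.degrees(grid))
    return HillsSpec(
        cv_grid=grid,
        fes_values=fes,
        periodic=True,
        duration_ns=duration_ns,
    )


def binding_profile_fixture(
    dG_target: float,
    desorption_barrier: float = 3.0,
    temperature: float = 277.0,
    funnel: FunnelSpec | None = None,
    n_grid: int = 1601,
) -> tuple[FreeEnergySurface, FunnelSpec]:
    """Noise-free separation-CV profile calibrated to a target binding dG.

    The bound basin is a flat well whose depth is inverted analytically from
    the funnel-corrected standard-state relation

        dG = -RT ln( L_b e^{-F_b/RT} * pi r^2 * c0 N_A ),

    so running the binding analysis on the profile must recover
    ``dG_target``.  A bump of height ``desorption_barrier`` above the bound
    level separates the basin from the flat unbound plateau at 0.
    """
    if funnel is None:
        funnel = FunnelSpec(radius=0.5, bound_window=(0.1, 0.5))
    rt = R_KJ * temperature
    b0, b1 = funnel.bound_window
    l_b = b1 - b0
    volume = math.pi * funnel.radius**2 * funnel.standard_concentration * C_STANDARD_PER_NM3
    f_b = dG_target + rt * math.log(l_b * volume)

    z = np.linspace(0.0, 4.0, n_grid)
    flat_lo, flat_hi = b0 - 0.02, b1 + 0.02  # flat slightly beyond the window
    peak_z, plateau_z = 1.0, 1.5
    peak = max(f_b + desorption_barrier, 0.0)
    f = np.empty_like(z)
    for i, x in enumerate(z):
        if x < flat_lo:
            f[i] = f_b + 200.0 * (flat_lo - x)  # repulsive wall
        elif x <= flat_hi:
            f[i] = f_b
        elif x <= peak_z:
            u = (x - flat_hi) / (peak_z - flat_hi)
            f[i] = f_b + (peak - f_b) * 0.5 * (1.0 - math.cos(math.pi * u))
        elif x <= plateau_z:
            u = (x - peak_z) / (plateau_z - peak_z)
            f[i] = peak + (0.0 - peak) * 0.5 * (1.0 - math.cos(math.pi * u))
        else:
            f[i] = 0.0
    f -= f.min()  # the analysis is invariant to the zero; keep min(F)=0
    return FreeEnergySurface([z], f, [False]), funnel


def csar_default_parameters(temperature: float = 277.0) -> CSaRParameters:
    """CSaR model at the stated binding/desorption energetics and micromolar protein."""
    return CSaRParameters(
        bulk_distribution=bulk_regime_spec(temperature).stationary_vector(),
        surface_distribution=surface_regime_spec(temperature).stationary_vector(),
        temperature=temperature,
    )
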