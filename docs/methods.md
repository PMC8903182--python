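# Methods

`csarpipe` re-implements, as a tested and reusable pipeline, the
computational analysis behind a striking observation in additive-mediated
crystallization control: a hyperactive beetle antifreeze protein (DAFP1)
completely suppresses nucleation of supersaturated D-mannitol at micromolar
concentrations.  The mechanism — *catch, switch and release* (CSaR) — is
conformational: the protein selectively binds the one rotamer of the sugar
alcohol that can join the crystal, randomizes its torsions at THz rates on
the ice-binding site, and releases it as long-lived non-crystal-forming
conformers, depleting the crystal-forming rotamer from solution.

This note records the models implemented, the parameters that matter, what
the synthetic data do and do not emulate, and the numerical choices made
where the design was genuinely open.

## 1. Rotamer state space

A hexitol has five O–C–C–O backbone torsions (α…ε).  Each torsion occupies
one of three staggered wells — trans (T, 180°), gauche+ (P, +60°), gauche−
(N, −60°) — giving 3⁵ = 243 conformers, written as 5-letter words.  Two
states are distinguished: the crystal-forming rotamer (CFR, N-T-P-T-N, the
conformer found in β-mannitol) and the dominant bulk rotamer
(BR, T-T-P-T-T).

*Encoding.* `index = 1 + Σᵢ dᵢ·3^(4−i)` with T→0, P→1, N→2 and α most
significant; "TTTTT" is state 1 and N-T-P-T-N is state 174.  This numbering
is the package's own deterministic convention; externally published state
labels can be mapped through a user-supplied alias table (a plain
word↔label dictionary), since such labels rarely document their encoding.

*Classification.* Angles are folded to [−180°, 180°) and partitioned at
±120°, the Voronoi boundaries of the three well centers; −180° belongs to
T.  Cis (0°) arrangements have no state of their own: the sign of the angle
carries them to P or N, and exactly 0° ties to P.  This keeps the state
space at 243 while still letting cis-rich surface data be represented.

## 2. Synthetic torsional dynamics

Because no trajectories are distributed with the analysis, the pipeline is
validated on synthetic data whose *statistical structure* matches what the
estimators assume.

**Regime chains.** `gen_rotamer_chain` draws a stationary Markov chain over
the 243 states at frame resolution: each frame, with probability
`p = r·dt/(1 − Σπᵢ²)`, the state is resampled from the stationary law π (a
resample landing on the current state is invisible).  This kernel satisfies
detailed balance with π exactly, and the calibration factor makes the
expected *frame-counted* transition rate equal the requested rate `r` —
the same frame-resolution counting the kinetics estimator uses, so rate
recovery is unbiased by construction.  Angles are emitted as wrapped
normals (sd 15°) around the well centers; 15° keeps adjacent wells ≥ 4 sd
from the classification boundaries, so emission noise corrupts state
assignments at a negligible (< 10⁻⁴) rate.

Fixture conditions:

| parameter | bulk | surface |
|---|---|---|
| named populations | BR 33.7%, CFR 0.45% | N-N-N-P-N 1.2%, N-P-T-N-P 1.0% |
| unnamed states | uniform share of the rest | uniform share of the rest |
| switch rate | 0.1 ps⁻¹ (see below) | 10 ps⁻¹ (= 10 THz) |
| frame spacing | 1 ps | 0.01 ps |
| cis spikes | none | weight 0.15 per gauche torsion |
| temperature | 277 K | 277 K |

*The bulk switch rate is a sampling choice, not barrier physics.*  Bulk
torsional interconversion is barrier-dominated (~80 kJ/mol), i.e. an
Arrhenius rate of order 10⁻¹⁴ ps⁻¹ — a chain at that rate never moves on
any simulable length, and population recovery would be meaningless.  The
bulk fixture instead decorrelates on a ~10-frame scale (0.1 ps⁻¹ at 1 ps
frames), emulating an *equilibrium ensemble* of weakly correlated
snapshots such as enhanced sampling produces.  The barrier-dominated
immobility itself is demonstrated separately by the Langevin generator,
and the Arrhenius form is available as `csar.rate_from_barrier`.

*Cis spikes.* On the surface, hydrogen bonding to the protein stabilizes
near-cis torsions, visible as spikes at 0° in the torsion histograms.  The
generator emits them as half-normal magnitudes on the gauche side matching
the letter (P → 0⁺, N → 0⁻), so the spikes appear in the angle
distributions without moving probability across the P/N boundary — the
configured surface populations remain exactly recoverable.  The weight
0.15 is a fixture choice sized to make the spikes unmistakable.

**Langevin torsions.** `gen_langevin_torsion` integrates overdamped
Euler–Maruyama dynamics on a periodic cosine potential (angular diffusion
default 2000 deg²/ps; the step guard enforces RMS moves < 30°).  At the
80 kJ/mol double well and 277 K the Kramers rate is ~10⁻¹⁵ ps⁻¹ and a 10⁶
step run shows no well-to-well crossing, which is the point.  Note the
Euler–Maruyama stationary variance carries an O(a·dt) inflation (a =
D·β·k): resolving a stiff well requires dt ≪ 2/a, which the tests do.

## 3. Two-phase thermodynamics (2PT)

The 2PT engine converts velocity trajectories into absolute entropies and
free energies:

1. mass-weighted velocity autocorrelation C(τ) (FFT, per-lag unbiased
   normalization; C(0) = 2⟨KE⟩);
2. density of states S(ν) = (2/k_BT)·FT[C] via a one-sided cosine
   transform with a **Bartlett (Fejér) window** and 4× zero padding.  The
   Fejér kernel is non-negative, so the spectral estimate is non-negative
   without clipping — a Hann window (narrower side lobes, small negative
   lobes) is available as an option.  The normalization invariant
   ∫S dν = 3N is enforced by rescaling, which is equivalent to using the
   trajectory's own kinetic temperature; a raw integral more than 5% from
   3N raises instead, and the raw value is kept for diagnostics;
3. dimensionless diffusivity Δ from S(0) and the universal fluidicity
   equation 2Δ^{-9/2}f^{15/2} − 6Δ^{-3}f^5 − Δ^{-3/2}f^{7/2} +
   6Δ^{-3/2}f^{5/2} + 2f − 2 = 0, solved by bisection in [0, 1];
4. the gas component as the hard-sphere Lorentzian
   S_g(ν) = s₀/(1 + (π s₀ ν / 6fN)²) (integral 3fN), the solid component
   as the remainder;
5. entropy/energy from quantum-harmonic-oscillator weights for the solid
   part and Carnahan–Starling hard-sphere expressions (packing fraction
   y = f^{5/2}/Δ^{3/2}) for the gas part; G = A + PV at 1 bar (the PV term
   is ~0.06 kJ/mol per nm³, negligible at condensed densities).

*Solid-limit guard.* As Δ→0 the fluidicity equation forces y→1 and the
hard-sphere excess entropy diverges per mode while the gas mode count
vanishes as f→0 — their product decays only like f^{1/3}, so a spurious
leakage-driven f ~ 10⁻³ would contribute a visible negative entropy.  When
the gas component carries less than a tenth of one mode the system is
treated as fully solid (f = 0).  This is the physically meaningful limit,
not an approximation of it.

The engine is validated against closed forms: harmonic ensembles reproduce
the QHO entropy within 2%, diffusive (Ornstein–Uhlenbeck) ensembles give
f > 0.9, and a mixture whose OU relaxation time is chosen 2PT-consistently
(`gas_tau_for_fluidicity`, which inverts the fluidicity equation through
the cubic in y) recovers its constructed gas fraction.

## 4. Classical nucleation theory

Cluster excess Gibbs energies follow ΔG_ex(N) = −δμ·N + b·N^{2/3}; the
critical nucleus is the vanishing-chemical-potential point
N\* = (2b/3δμ)³ (rounded to the nearest integer), fitted by weighted
linear least squares.  δμ ≤ 0 yields "no finite critical size" rather
than an error.  A `saturating` analysis is provided for restrained-cluster
data that levels off at a 2D-slab reference: an exponential approach to
the plateau is fitted (the slab value anchors the plateau when available)
and N\* is the smallest size whose fitted slope falls below 1% of the
maximum slope — a pure logarithmic guide curve has no stationary point,
so an explicit operational rule is required.

The surface coefficient converts to an interfacial tension through the
spherical-cluster surface factor s = (36π)^{1/3} v_m^{2/3}:
γ = b/(s·N_A).  The default molecular volume v_m = 0.203 nm³ follows from
M = 182.17 g/mol at the β-mannitol crystal density (≈1.49 g/cm³); a facet
area could be substituted, but the spherical equivalent is the
conventional CNT choice.  The calibrated fixture curve is defined by
γ = 34 mJ/m² and N\* = 64 (hence b ≈ 34.2 kJ/mol·N^{−2/3},
δμ = b/6 ≈ 5.70 kJ/mol) over N = 4…75; under 2 kJ/mol Gaussian noise the
recovered N\* is unbiased (mean within ±2 over 100 seeds).

## 5. Well-tempered metadynamics post-processing

`read_hills` parses the common HILLS layout (`#! FIELDS time cv…
sigma_cv… height biasf`, optional `#! SET min/max` lines marking periodic
CVs), merges multi-walker files time-sorted, and validates column counts
and per-walker time ordering with line-number diagnostics.  The bias is
the sum of (periodically wrapped, multi-CV product) Gaussians; the FES
estimator is final-bias rescaling F = −(g/(g−1))·V_final with min(F) = 0,
with an optional convergence series (F every n ps) for diagnostics.
Time-averaged reweighting estimators exist but the rescaling form is the
simplest estimator consistent with the deposition rule and its residual
ripple is quantified below.

*Hill generation.* The deposition protocol follows the reference recipe:
pace 0.5 ps, initial height (277/T)·1 kcal/mol, bias factor g = 5, width
0.01 (radians, the conventional torsion CV unit), 10 communicating
walkers.  At each pace tick every walker is drawn directly from the
instantaneous well-tempered measure e^{−β(F+V)} on the CV grid — the
adiabatic-sampling limit that well-tempered convergence theory assumes —
and deposits a Gaussian scaled by e^{−V/k_BΔT}.  The generator therefore
emulates the *statistics* of hill deposition, not barrier-crossing
kinetics (the Langevin generator covers kinetics).  A kinetic walker
would deposit full-height hills at rarely visited saddle points in
clusters, leaving frozen kJ-scale needles in the reconstruction;
adiabatic sampling spreads deposits with the proper measure and the
reconstruction error then decays with deposition time.

With the double-well fixture (2-fold cosine, 80 kJ/mol barrier) and
40 ns per walker (800 k hills), the reconstruction RMS against the model
is ≈ 0.5 kJ/mol and the recovered barrier is 80–81 kJ/mol across seeds;
the default fixture duration is set there so the round trip meets its
1 kJ/mol RMS / 2 kJ/mol barrier tolerances with margin.  1D collective
variables cover every use here; bias evaluation and barrier search also
support 2D grids.

*Barriers.* The barrier is (minimax-path saddle) − (basin minimum).  On a
grid this is computed exactly by union-find flooding: cells are activated
in increasing F and the saddle is the level at which the two basin minima
first connect (4-neighbour adjacency, periodic wrapping respected); a
window whose minimum is not a local minimum of the grid is rejected.

*Funnel binding free energies.* For a 1D profile F(z) along the
protein–ligand separation inside a cylindrical funnel restraint of radius
r, the bound-basin Boltzmann integral relative to the unbound plateau is
converted to a standard-state binding free energy

    ΔG_bind = −RT ln( K · π r² · l_ref · c° · N_A ),

with K the bound/unbound integral ratio and l_ref the unbound-window
length; the result is invariant to the arbitrary zero of F and to the
choice of l_ref as long as the plateau is flat (a non-flat plateau, std
> RT/2, flags the result).  The unbound window defaults to the outer 20%
of the axis; the funnel radius defaults to 0.5 nm (the restraint geometry
is otherwise unreported, and the standard-state correction makes the
reported number geometry-explicit rather than geometry-free).  Binding
fixtures are built by inverting this relation analytically for a flat
square well, so recovery is exact up to grid discretization (< 0.05
kJ/mol at 2.5 pm spacing).

## 6. The CSaR depletion model

The mechanism is stated in the source analysis without equations; the
model here is a minimal master-equation realization over 2×243 states
(each rotamer in bulk and on the protein surface):

* **bulk ↔ bulk**: resampling kernel c_b·π_bulk(j) with
  c_b = k₀·e^{−80 kJ/mol / RT} (k₀ = 10 ps⁻¹, the observed surface
  switching ceiling, standing in for the unreported attempt frequency) —
  detailed balance with the bulk law, astronomically slow;
* **bulk → surface**: k_on·[P]·e^{−max(0, ΔG_bind)/RT} with diffusion-
  limited k_on = 10⁻² L/mol/ps and [P] = 2.8 µM (the experimental protein
  concentration; 1 mM appears elsewhere in the source figures — the
  depletion bound holds for either, and the concentration is a parameter);
* **surface ↔ surface**: resampling against the surface law at 10 ps⁻¹;
* **surface → bulk**: k₀·e^{−ΔG‡/RT}·e^{+min(0, ΔG_bind)/RT}, so each
  rotamer's adsorption/desorption pair alone is in detailed balance with
  its binding free energy (the min(0,·) avoids double-counting repulsive
  ΔG, which already penalizes adsorption).

Stated energetics: ΔG_bind = −20.5 (CFR), +14.5 (N-P-T-N-P), +22.0
(N-N-N-P-N) kJ/mol, desorption barriers +3.0/+3.5 kJ/mol for the two
release rotamers; unnamed rotamers share class defaults (+30 kJ/mol
binding sentinel, 3.0 kJ/mol barrier).

Because the bulk law, the surface law and the binding energetics are
*independently measured* inputs, the chain's cycles are thermodynamically
inconsistent and the stationary state is a driven one: CFR is captured,
randomized and returned as other rotamers, and with bulk re-equilibration
essentially frozen the bulk CFR share collapses.  With the default
parameters the depletion factor is ~10⁶–10⁷, comfortably satisfying the
three-orders-of-magnitude observation; the model makes no claim to the
exact printed factor (the source's own numbers — 0.45%/2.0×10⁻⁴% = 2250,
a printed 2,500, and 14 days → "~75 years" where 2250×14 d ≈ 86 a — are
mutually inconsistent at face value, so only the ≥10³ bound is asserted
and the induction-time operation is verified as exact baseline×factor
arithmetic).

*Selectivity-free limit.* "No selectivity" must mean both uniform binding
ΔG *and* a surface law equal to the bulk law; then every cycle is
consistent, full detailed balance holds, and the stationary bulk law is
exactly the input law (machine precision).  With uniform ΔG but a
different surface law the steady state provably differs — the surface
randomization itself is then a selective pump.

*Depletion factor.* Defined on the bulk-compartment conditional
distribution (the rotamer make-up of molecules currently in solution),
since the unconditional fraction would register mere surface occupancy as
depletion.

*Solver.* The rate matrix spans ~18 orders of magnitude (10⁻¹⁴ to 10³
ps⁻¹), and the stationary CFR component is ~10⁻⁹ of the total — far below
the relative resolution of an SVD null space of such a matrix.  The
stationary law is therefore computed with the Grassmann–Taksar–Heyman
(GTH) elimination, which uses only additions of non-negative quantities
and retains full relative accuracy per component; it also handles
transient states (zero protein → surface unreachable) by assigning them
zero mass.  GTH is cross-checked in the tests against matrix-exponential
time integration on small generators.

## 7. What the synthetic data do not show

The generators reproduce the *statistical assumptions* of the estimators,
not molecular physics: there is no force field, no water, no protein
structure (the surface regime is a stationary law, not a binding site),
no coupling between the five torsions beyond the state law, and the
cluster thermodynamics are closed-form curves rather than restrained MD.
Passing recovery tests therefore demonstrates that the estimators are
correct and well-calibrated at the study's stated conditions — not that
those conditions are what real MD of this system would produce.  In
particular the −120 kJ/mol crystal-face binding energy, the real-MD
determination of N\* = 64, and all wet-lab observations are outside what
this package can reproduce; they enter only as fixture calibration
targets or documented context.

## 8. Problem sizes and numerical defaults

Population/kinetics recovery uses 10⁶-frame chains (bulk: 1 µs at 1 ps
frames; surface: 10 ns at 0.01 ps frames), block-averaged errors with 5
contiguous blocks (block means' sd / √5 — the count is conventional; the
source reports 1-sd error bars without stating a method).  2PT fixtures
use 32 atoms × 2¹⁴–2¹⁶ frames at 4 fs.  The metadynamics round trip uses
800 k hills (10 walkers × 40 ns).  The CNT noise study uses 100 seeds at
2 kJ/mol noise.  The full test suite runs in about a minute on one CPU;
the acceptance script in about one to two minutes.
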