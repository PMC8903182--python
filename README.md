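# csarpipe

Analysis pipeline for conformer-selective crystallization inhibition:
rotamer state-space populations of polyol trajectories, two-phase
thermodynamics (2PT) and classical nucleation theory (CNT) of cluster
excess Gibbs energies, well-tempered metadynamics post-processing, and the
catch-switch-and-release (CSaR) steady-state depletion model.

## The problem

D-mannitol has five O–C–C–O backbone torsions, each near trans (T, 180°),
gauche+ (P, +60°) or gauche− (N, −60°), so a molecule occupies one of
3⁵ = 243 rotamer states.  Only one of them — the crystal-forming rotamer
(CFR, N-T-P-T-N) — can join the β-mannitol lattice, and in solution at
277 K it is rare (≈0.45%, against ≈33.7% for the best bulk rotamer
T-T-P-T-T).  A hyperactive beetle antifreeze protein (DAFP1) suppresses
mannitol nucleation completely at micromolar levels by exploiting this:
its threonine-ladder ice-binding site preferentially *catches* the CFR
(ΔG_bind = −20.5 kJ/mol), *switches* its torsions at ~10 THz (cis-stabilized,
barrier-free randomization on the surface, versus ~80 kJ/mol torsional
barriers in solution), and *releases* it as unfavourably bound rotamers
(ΔG_bind = +14.5/+22.0 kJ/mol, desorption barriers ≈3 kJ/mol).  The net
effect is a steady-state depletion of the bulk CFR pool by orders of
magnitude and a correspondingly stretched nucleation induction time.

`csarpipe` implements the complete computational side of that analysis as
a library plus CLI, with synthetic-data generators that reproduce the
statistical structure of every input, so the whole pipeline is testable
without molecular dynamics or external data.  See `docs/methods.md` for
the models, assumptions and numerical choices.

## What's in the box

| module | contents |
|---|---|
| `csarpipe.rotamers` | 243-state encoding, T/P/N classification |
| `csarpipe.trajectory` | XYZ/PDB readers (+JSON topology), dihedrals, dwell segmentation, H-bond counting |
| `csarpipe.populations` | block-averaged populations, ΔG = −RT ln(p/p_max), THz switching kinetics |
| `csarpipe.twopt` | VACF → density of states → fluidicity → 2PT entropy/free energy |
| `csarpipe.cnt` | ΔG_ex(N) = −δμ·N + b·N^{2/3} fits, N* = (2b/3δμ)³, γ = b/(s·N_A) |
| `csarpipe.metad` | HILLS parsing, F = −(g/(g−1))·V reconstruction, minimax barriers, funnel-corrected ΔG_bind |
| `csarpipe.csar` | 486-state master equation, GTH steady state, depletion factor, induction time |
| `csarpipe.synthetic` / `fixtures` | generators for all of the above, with the study conditions as defaults |
| `csarpipe.cli` | `csarpipe generate/classify/populations/twopt/cnt/fes/csar/pipeline` |

## Worked example

Recover the surface-regime kinetics and populations from a synthetic
10 ns trajectory (10⁶ frames at 0.01 ps), then solve the depletion model
at the stated binding energetics:

```python
from csarpipe import (fixtures, gen_rotamer_chain, classify_trajectory,
                      estimate_populations, switching_kinetics,
                      build_model, steady_state, induction_time)

traj = gen_rotamer_chain(fixtures.surface_regime_spec(), 10**6, 0.01, seed=1)
rt = classify_trajectory(traj)
pt = estimate_populations(rt, block_count=5)
kin = switching_kinetics(rt)
print(f"switching rate: {kin.mean_switch_rate:.2f} THz")
for w in ("NNNPN", "NPTNP"):
    print(f"p({w}) = {100*pt.prob(w):.2f} +- {100*pt.se(w):.2f} %")

res = steady_state(build_model(fixtures.csar_default_parameters()))
est = induction_time(res, baseline_days=14.0)
print(f"CFR depletion factor: {res.depletion_factor:.3g}")
print(f"induction time: 14 days -> {est.extrapolated_years:.3g} years")
```

prints

```
switching rate: 10.09 THz
p(NNNPN) = 1.19 +- 0.04 %
p(NPTNP) = 0.99 +- 0.05 %
CFR depletion factor: 3.41e+06
induction time: 14 days -> 1.31e+05 years
```

The estimator recovers the configured 10 THz switching rate and the
1.2%/1.0% surface populations of the two release rotamers within their
block-averaged standard errors.  The depletion model — whose only fitted
ingredients are the stated per-rotamer binding and desorption energetics —
keeps the bulk CFR suppressed by far more than the three orders of
magnitude the mechanism requires (the factor itself depends strongly on
the unreported association prefactor and protein concentration, so only
the ≥10³ bound is a claim; the induction time scales linearly with it).

The same stages run from the shell:

```
csarpipe pipeline --config examples/bulk.toml --seed 1 --out run/
```

which writes `torsions.tsv`, `rotamers.tsv`, `populations.tsv` (243 rows
with probabilities, standard errors and ΔG), `kinetics.json`, `csar.json`
and a `resolved_config.toml` that reproduces the run byte-for-byte.

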