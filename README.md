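# chaperkit

Analysis toolkit for studying how an ATP-independent, cradle-shaped
chaperone dimer binds and releases client proteins, with a focus on
the role of its intrinsically disordered N-terminal tail. The package
bundles four quantitative pipelines that are usually scattered across
instrument software and one-off scripts:

- **Binding kinetics** from biolayer-interferometry sensorgrams:
  per-phase fits of `y = a(1 - e^{-k_obs t}) + y0 t` (association)
  and `y = a e^{-k_off t} + y0 t` (dissociation), the linear
  concentration dependence `k_obs = k_on[C] + k_off`, and
  `K_d = k_off / k_on` with delta-method errors.
- **Chaperone activity** from light-scattering aggregation curves:
  window slopes and a one-phase exponential-decay standard curve that
  converts a variant's slope into a fraction of wild-type activity.
- **NMR chemical-shift analysis**: amide CSPs
  `sqrt(dH^2 + (0.2 dN)^2)`, secondary Ca/Cb shifts against a
  random-coil table, and per-residue one-site titration fits of
  `d_obs = d_max ((K_d+P0+L0) - sqrt((K_d+P0+L0)^2 - 4 P0 L0))/(2 P0)`
  with median pooling and bootstrap confidence intervals.
- **PRE analysis**: `I_red/I_ox` intensity-ratio profiles from
  paramagnetic/diamagnetic peak lists, concave-vs-convex surface
  enrichment above a reference ratio, RMSD comparison between variant
  profiles, and a four-way classification against a control band.
- **Disordered-tail modelling**: a coarse-grained (one bead per
  residue) re-implementation of the sample/score/filter/select
  protocol — self-avoiding coil sampling anchored to a two-chain
  scaffold, soft-sphere + screened-Coulomb scoring, the four-point
  upper cavity plane, removal of conformers whose acidic residue-26
  bead sits inside the cavity, lowest-energy selection, and
  spin-label cavity-occupancy metrics from resampled trajectories.

A synthetic-data module generates every input with known ground truth
(sensorgram series, titration series, PRE profiles, and a charged
cradle scaffold with disordered tails), so each estimator is validated
by generator -> fit round trips. See `docs/methods.md` for models,
defaults and limitations.

## Worked example

Run the bundled end-to-end demo (synthetic data generated under the
seed, then every analysis stage):

```python
from chaperkit.config import RunConfig, run

report = run(RunConfig(seed=7, out_dir="demo",
                       ensemble={"n_conformers": 300}))
print(report["stages"]["fit-kinetics"]["K_d"])
print(report["stages"]["titrate"]["pooled_kd_mM"])
print(report["stages"]["compare-pre"]["category"])
```

which prints (numbers from this exact invocation):

```
1.0354858734616174e-07
4.054172368695006
below_diagonal
```

The sensorgrams were generated with `k_on = 1e5 /(M s)` and
`k_off = 0.01 /s`, so the true `K_d` is `1e-7` M — the refit at 1%
instrument noise lands within 3.5%. The titration was generated at a
true `K_d` of 4.7 mM under 0.005 ppm noise; the pooled median over ten
residues recovers 4.05 mM with a bootstrap CI of [3.2, 5.5] mM (a
deliberately weak-binding, hard regime — the ligand never reaches
`K_d`). The PRE comparison pits a variant whose residue-26 bead charge
is reversed against the native system: its profile is systematically
weaker, so it classifies as `below_diagonal` — the tail no longer
visits the cavity. The same run writes `demo/report.json` plus
per-stage CSV/TSV/JSON/PDB outputs.

The same stages are available as a CLI (`chaperkit simulate`,
`fit-kinetics`, `activity`, `csp`, `titrate`, `pre`, `compare-pre`,
`ensemble`, `occupancy`, `report`, `validate`); run
`chaperkit --help`.

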