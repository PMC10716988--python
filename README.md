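# fontansim

A 0D (lumped-parameter) simulator of mechanical dyssynchrony in the
single-ventricle (Fontan) circulation, with longitudinal-strain synthesis and
clinical response-surface analysis.

Patients with a functional single ventricle show widely varying ventricular
morphology, and hence widely varying ratios of the ventricular wall that
contracts late when conduction is disturbed. This package asks the question a
clinician would: **how much does the *size* of the delayed wall — not just
the electrical delay itself — determine cardiac dysfunction?** It provides:

- **A two-compartment time-varying elastance ventricle** in a closed-loop
  Fontan circulation. Each chamber follows
  `P(V,t) = P_ed(V) + e(t)·(P_es(V) − P_ed(V))` with
  `P_ed = A(e^{B(V−V0)} − 1)`, `P_es = E_max(V − V0)` and a raised-cosine
  activation `e(t)`; the ventricle is built from 20 identical parallel units
  so any 5%-step split into an earlier and a delayed compartment (activation
  delay ΔT) is algebraically consistent with the whole chamber.
- **Hemiglobal strain synthesis** on a hemispherical ventricle: the identity
  `AR = (1 − cos(π·LR))/2` maps wall length fractions to area/volume
  fractions, and seven-segment longitudinal strains are computed the way
  speckle-tracking echocardiography measures them. The rebound-stretch index
  `R_strains = (100 + S_ejection)/(100 + S_isovolumic)` (> 1 flags an
  early-activated wall that shortens and is then stretched back in systole)
  and the time-to-peak-strain difference quantify discoordination.
- **The delay × fraction sweep**: 19 activation delays (0–90 ms) × 19
  delayed-wall fractions (5–95%), each run to periodic steady state, with
  changes of cardiac output, contractility (single-beat elastance surrogate)
  and dP/dt-max relative to each fraction's own zero-delay baseline, and
  Spearman correlations of the discoordination markers against the
  contractility loss.
- **Cohort statistics**: the contractility surrogate
  `estEes = AP_dic / ESVi`, second-order polynomial response surfaces of
  log10 BNP and estEes over (QRS-duration Z-score, delayed-wall area ratio)
  with standardized coefficients and vertex (extremum) localisation, and a
  **synthetic cohort generator** that reproduces the published cohort
  structure so the whole clinical pipeline is testable without patient data.

## Worked example

```python
import fontansim as fs

p = fs.default_params()                      # 40-kg postoperative Fontan set
tr = fs.simulate_to_steady_state(p)          # ΔT = 0 baseline, ~30 beats
m = fs.beat_metrics(tr, p)
print(f"EDV {m.edv:.1f} ml  EF {m.ef:.1f} %  CI {m.ci:.2f} L/min/m2")
print(f"CVP {m.mean_cvp:.1f}  atrial {m.mean_atrial_p:.1f}  "
      f"arterial {m.arterial_sys:.0f}/{m.arterial_dia:.0f} ({m.arterial_mean:.0f}) mmHg")
print(f"PVRi {m.pvri:.2f}  SVRi {m.svri:.1f} units·m2")
```

prints

```
EDV 102.2 ml  EF 51.8 %  CI 3.14 L/min/m2
CVP 10.0  atrial 5.8  arterial 111/70 (90) mmHg
PVRi 1.35  SVRi 25.6 units·m2
```

— a typical postoperative Fontan operating point: a 102-ml ventricle ejecting
half its volume, a cardiac index of 3.1 L/min/m², the 10-mmHg central venous
pressure that drives pulmonary flow without a subpulmonary pump, and normal
pulmonary/systemic resistance indices. Adding a 90-ms activation delay to a
delayed compartment of 70%:

```python
from fontansim.sweep import run_condition
cond, tr90, strains = run_condition(p, dT_ms=90, fraction=0.70)
print(f"R_strains (earlier wall): {fs.r_strains(strains.t_ms, strains.earlier, tr90.events):.3f}")
```

prints `R_strains (earlier wall): 1.069` — the earlier-activated wall now
shortens before aortic opening and is stretched back during ejection, the
hallmark of mechanical discoordination. Across the full sweep
(`fs.run_grid(p)`, 361 conditions, ≈2 min) the cardiac-output loss at the
largest delay peaks when the delayed compartment holds ~70–75% of the
ventricle, and `fs.correlate_predictors` shows the earlier-wall R_strains to
be the strongest rank correlate of the contractility loss (ρ ≈ −0.91),
ahead of ΔdP/dt-max, systolic reverse flow and the time-to-peak gap.

A command-line interface mirrors the library:

```bash
fontansim simulate --out-traces traces.csv --out-metrics metrics.csv
fontansim sweep --out sweep.csv && fontansim correlate --sweep sweep.csv
fontansim synth-cohort --n 62 --seed 1 --out cohort.csv
fontansim cohort-fit --cohort cohort.csv --response log10BNP
```

Model equations, parameter meanings, conventions and limitations are
documented in [docs/methods.md](docs/methods.md).

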