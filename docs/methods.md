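# Methods

## Model overview

`fontansim` simulates the acute hemodynamics of mechanical dyssynchrony in a
single-ventricle (Fontan) circulation with a zero-dimensional, closed-loop
lumped-parameter model. The single ventricle is assembled from 20 identical
time-varying elastance units and split into two compartments — an
earlier-activated one and a delayed one whose activation onset is postponed
by ΔT — coupled through a small intercompartment resistance. The circulation
is a series loop: ventricle → aortic valve → three-element Windkessel
systemic bed → systemic venous compliance → caval/pulmonary junction →
pulmonary bed → single atrium → inertial atrioventricular valve → ventricle.
There is no subpulmonary pump; pulmonary flow is driven passively by the
systemic venous pressure, which is the defining feature of the Fontan state.

### Chamber law

Each chamber interpolates between a passive exponential end-diastolic
pressure–volume relation and a linear end-systolic relation,

    P(V, t) = P_ed(V) + e(t) · (P_es(V) − P_ed(V)),
    P_ed(V) = A (exp(B (V − V0)) − 1),       P_es(V) = E_max (V − V0),

driven by a raised-cosine activation e(t): a rise `(1 − cos(π t/T_max))/2`
over `[0, T_max)` followed by a relaxation `(1 + cos(π (t−T_max)/(r·T_max)))/2`
over `[T_max, (1+r)·T_max)`, with the relaxation ratio r = 0.5 by default and
exposed as `relax_ratio`. The raised cosine is the conventional choice in this
family of lumped models; the baseline acceptance checks below bound how much
this choice can matter. Volumes below V0 return negative pressure: a small
compartment stretched paradoxically by its neighbour must be able to pull
below its unstressed volume.

A compartment holding a fraction f of the ventricle consists of n = 20·f
units in parallel: E_max and B are divided by n, V0 multiplied by n, A and
T_max unchanged. This scaling is exact: two compartments at a common pressure
hold, together, precisely the volume of the single whole-ventricle chamber,
for both the passive and the active law (property-tested).

### Circuit topology and measurement sites

The series chain of stores is

    ventricle (delayed cmp.) →R_ao→ [ascending aorta] →Z_art→ C_art →R_art→
    C_ven →R_ven→ [CVP node] →Z_pa→ C_pa →R_pa→ C_pv →R_pv→ atrium
    →AV valve→ ventricle (earlier cmp.)

Node pressures follow from stressed volumes (P = V/C); total stressed volume
(720 ml by default) is conserved to round-off because the volume derivatives
cancel pairwise. Atrioventricular inflow enters the earlier compartment and
aortic outflow leaves the delayed compartment (the delayed wall carries the
outflow tract); both assignments are configurable. The placement of the
systemic venous resistance downstream of the venous compliance, and the
reading of central venous pressure at the junction between that resistance
and the pulmonary characteristic impedance (the surgical SVC/TCPC site), are
fixed by mean-pressure bookkeeping: with the default resistances and a
cardiac output near 70 ml/s they are the only arrangement that makes the
reference CVP (10 mmHg), mean atrial pressure (5.8 mmHg) and mean arterial
pressure (90 mmHg) simultaneously consistent.

Valves are diodes. The aortic valve is an ideal diode with a 0.005
mmHg·s/ml series resistance; the AV valve is a Bernoulli orifice
(ΔP = ρQ²/(2K·EOA²)) in series with a blood inertance L, integrated as a
flow state that is clamped at zero and reset on closure.

### Integration and steady state

The 8-state ODE is advanced with fixed-step classical RK4 at 0.05 ms (numba-
compiled; the step is halved and the run restarted if the state ever becomes
non-finite). Beats are integrated from a documented analytic initial
allocation; convergence requires the beat-to-beat relative change of both
end-diastolic volume and forward stroke output to fall below 1e-5, with at
least 30 and at most 300 beats. The tight drift tolerance is deliberate: the
slowest eigenmode of the loop (venous compliance × systemic resistance) has a
time constant of roughly 50 beats, so a looser per-beat criterion (e.g. 1e-3)
can stop several percent short of the periodic fixed point. With the analytic
initial allocation the default condition converges in ~30 beats (a few
seconds on one CPU); the full default sweep (361 conditions) takes about two
minutes.

### Metric conventions

Table-style summary metrics are extracted from the converged beat as a
catheterization lab would: EDV is the beat's maximal total ventricular
volume; ESV the total volume at aortic valve closure; EDP the ventricular
pressure at the earlier compartment's activation onset (QRS-onset
convention — at the instant of maximal volume the activation has already
started to rise, which would contaminate a "passive" EDP); ESP the peak
pressure of the outflow compartment (which slightly exceeds systolic aortic
pressure, as in the reference hemodynamics). The contractility surrogate is
the single-beat elastance `max_t P_v(t)/(V_total(t) − V0_total)`; only its
relative change between conditions is interpreted. Systolic reverse flow is
the time-integral of delayed→earlier intercompartment backflow between the
earlier activation onset and aortic closure, normalised by the same
fraction's zero-delay per-beat output.

## Strain synthesis

The ventricle is a hemisphere (V = 2πr³/3); a coronal cut through the vertex
gives a semicircular wall outline of length πr. A wall region occupying a
length fraction LR of the outline occupies the area/volume fraction
AR = (1 − cos(π·LR))/2 — this identity converts the clinical delayed-wall
length ratio into an area ratio, and, applied instantaneously to the
simulated volume fractions, maps compartment volumes onto outline arcs. At
end-diastole the outline is divided into seven equal material segments; each
material point keeps its relative position within its compartment's arc
(uniform stretch within a compartment; a segment straddling the boundary is
split there). A hemiglobal strain is the relative length change of the three
basal segments on one side, excluding the apical cap, in percent, zero at
end-diastole. Under uniform contraction this reduces exactly to the
cube-root law strain = 100·(k^{1/3} − 1) for a volume factor k.

The rebound-stretch index of a trace is
`R_strains = (100 + S_ej)/(100 + S_ivc)` with S_ivc the minimum strain
between activation onset and aortic opening and S_ej the minimum during
ejection; a configurable window start supports the clinical QRS-period proxy.
Values above 1 flag the early-shortening / systolic-rebound pattern. The
time-to-peak difference is the gap between the global strain minima of the
two sides (first occurrence on ties).

One known artifact of lumping the inflow into the earlier compartment: at
ΔT = 0 the two hemiglobal strains coincide during systole (< 1% apart) but
diverge during diastole, when the filling volume transits the earlier
compartment before redistributing through the intercompartment resistance.
The discoordination indices, which are systolic, agree to < 0.01 at ΔT = 0.
The instantaneous-fraction arc mapping is isolated behind
`strain.segment_lengths`, so an alternative compartment-shape model can be
substituted at one function boundary.

## Sweep experiment

The default grid crosses 19 activation delays (0–90 ms, 5-ms steps) with 19
delayed fractions (5–95%, 5% steps): 361 steady-state conditions. Relative
changes of cardiac output, the elastance surrogate and dP/dt-max are computed
against each fraction's own ΔT = 0 baseline (which is simulated whether or
not 0 is in the requested delay list). Rows are sorted by (ΔT, fraction) and
are independent of execution order; a non-convergent condition is flagged and
skipped rather than aborting the sweep. Spearman correlations (midrank ties,
via `scipy.stats.spearmanr`) of the four discoordination markers against the
contractility change summarise the grid.

## Cohort analysis and the synthetic generator

The clinical layer fits a second-order polynomial response surface by OLS
(statsmodels) in QRSZ, AR, (QRSZ−c₁)², (AR−c₂)² and the cross term, with the
centering constants equal to the sample means. Standardized coefficients are
obtained by z-scoring the response and each *constructed* term (the
alternative — z-scoring QRSZ and AR before constructing the terms — is
available behind `standardize_first=True`). P-values are classical OLS
t-tests without multiplicity correction. The AR extremum at a fixed QRSZ is
the vertex of the fitted quadratic, clipped to the observed AR range with a
`clipped` flag rather than extrapolated.

The synthetic generator emulates the published cohort structure: QRSZ from a
shifted log-normal left-truncated at the inclusion threshold of 2, AR from a
scaled Beta with mean 57.2% and SD 21%, responses from planted quadratic
surfaces plus Gaussian noise, an inverse-U for log10 BNP (maximum at
AR = 62% at QRSZ = 10) and a U for estEes (minimum at 68%). The three
post-truncation QRSZ quantile targets (2.5/3.8/6.2) are jointly infeasible
for this family, so the calibration is a weighted least-squares fit of the
post-truncation quantiles with the median weighted 4:1; the achieved
quantiles (2.68/3.79/6.22) are reported by `calibrate_qrsz`. Raw surface
coefficients are derived from standardized effect sizes that mirror the
clinical sign pattern (strong positive linear QRSZ effect on log10 BNP,
negative AR curvature; the reverse for estEes), with the linear AR
coefficient solved so the planted vertex sits exactly at the requested
location. ESVi is log-normal around its clinical median and the dicrotic
notch pressure is derived as estEes × ESVi, so the elastance-surrogate
identity holds exactly on generated records. R_strains co-varies with
log10 BNP with a noise level set for a rank correlation near 0.65.

Two noise regimes matter. The default noise SDs (0.04 log10-units for BNP,
0.05 for estEes) were chosen by error propagation so that the planted
extremum location is recoverable to ±5 AR points from a 62-patient sample in
well over 95% of replicates; they correspond to a nearly noise-free surface.
At the clinically observed model fit (R² ≈ 0.45 for log10 BNP) the vertex of
a −0.31-standardized-unit curvature has a sampling SD of roughly 13 AR
points at n = 62, i.e. the extremum *location* is not identifiable from one
real-sized cohort, although the *sign pattern* of the surface still is.
`clinical_noise_sd` returns the noise reproducing a target population R² so
cohorts can be generated in that realistic regime; the sign-pattern test
uses it. What the passing recovery tests show, therefore, is that the
pipeline is correct and unbiased — not that a 62-patient clinical study
could pin the extremum to ±5 points.

## What the synthetic data do not emulate

The generator draws QRSZ and AR independently (their clinical correlation is
unreported), makes no attempt to derive BNP mechanistically from simulated
wall stress, and produces occasional physiologically extreme AP_dic values
in the tails of estEes × ESVi. Passing cohort tests demonstrate estimator
correctness under the stated data-generating process, not clinical validity.

## Numerical choices and limitations

- Fixed-step RK4 at 0.05 ms resolves the fastest coupling time constants
  (small-compartment elastance through the 0.008 mmHg·s/ml intercompartment
  resistance, ~0.1 ms) with a comfortable stability margin; the automatic
  step-halving retry guards the extreme grid corners.
- Valve events are resolved on the step grid (no event interpolation);
  event times are therefore accurate to the step size, far below any window
  length used by the indices.
- Ties in `most_vulnerable_fraction` break toward the smaller fraction;
  strain trough counting uses a 0.1 percentage-point prominence to reject
  flat-minimum jitter while keeping the shallow mid-systolic rebound.
- The model is acute and open-loop in the physiological sense: no baroreflex,
  no chronic remodeling, no wave propagation, thick-wall or fiber mechanics;
  the hemisphere is a deliberate geometric idealisation. Absolute strain
  magnitudes and BNP levels are not patient-predictive; the object of study
  is the dependence of hemodynamics and discoordination indices on the
  activation delay and the delayed-wall ratio.
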