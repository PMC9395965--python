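# Methods

This note documents the model, its assumptions, the synthetic-data
conditions, numerical choices, and the design decisions taken where the
design was genuinely open.

## Partitioned survival model

Three states (progression-free, post-progression, dead) partitioned
directly from the PFS and OS curves on a 3-week cycle grid; the ordering
constraint S_PFS ≤ S_OS is enforced by taking the pointwise minimum before
partitioning, so occupancies are non-negative and sum to one at every cycle
by construction.  Horizon: 20 years ("lifetime" for this population; by
then both arms' survival is far below 1%).  Discounting: 5%/year,
continuous convention (1+r)^(−t), t in years with 1 cycle = 21/365.25 years.

**Integration.**  State-time accruals (life-years, QALYs, monitoring and
management costs) use trapezoid weights over each cycle interval — the
half-cycle-corrected convention — which keeps the cycle-grid integral of a
smooth survival curve within ~0.01% of the closed form (a right-endpoint
sum is off by ~3% at a 3-week cycle on these time scales; the
`integration="right"` flag restores it).  Event-type accruals are
point-discounted at their event time: drug doses and administration at the
cycle start weighted by PF occupancy, subsequent-therapy cost once per new
progressor at progression, end-of-life cost per death at death.

**Progression flow.**  A partitioned model cannot observe transitions, so
new progressors in a cycle are approximated as the PFS-curve decline minus
deaths attributed to PF in proportion to PF's share of survivors at the
cycle start.  This makes the degenerate all-die-at-once cohort accrue no
subsequent-therapy cost, at the price of a smaller subsequent-therapy
component (~$2.0–2.4k discounted) than the published $4,351, which equals
the undiscounted unit cost applied to every patient; the difference is
absorbed by the administration calibration knob (below) and is nearly
identical across arms, so increments are unaffected.

**Costs.**  Direct medical costs only, 2021 USD at 6.44 CNY/USD.  Drug
dosing assumes 65 kg and 1.6 m² with whole-vial rounding (200 mg
immunotherapy = 2×100 mg vials; gemcitabine 1250 mg/m² d1+d8 = 4×1 g;
cisplatin 75 mg/m² = 4×30 mg; carboplatin AUC 6 = 6×100 mg; nab-paclitaxel
100 mg/m² d1,8,15 = 5×100 mg).  Combination chemotherapy is capped at 4
cycles and immunotherapy at 24 months; patient-assistance programs are
paid-dose schedules (first k doses charged, the rest free, fractional k
prorated).  Adverse-event management cost is incidence × per-episode cost,
applied once at model start (grade ≥3 events cluster early on treatment).

**Utilities.**  u_PF = 0.804, u_PP = 0.321; AE QALY loss = incidence ×
disutility × duration/365.25, subtracted once from the PF component.

## Base-case calibration

The reference trial's IPD are proprietary, so the base case is calibrated
rather than fitted.  Reference-arm PFS and OS are log-normal (the family
the source model extrapolates with); σ is pinned at 1.0 per endpoint — a
typical spread for oncology time-to-event data at these medians — and μ is
solved by Brent's method.  Comparator curves are hazard-scaled versions of
the reference curves; since scaling the hazard by HR integrates exactly to
S(t)^HR, that closed form is used, and the two HRs are solved the same way.
Solve targets are the published per-arm discounted QALY and life-year
totals, inverted through the utility weights to per-state life-year
targets: L_PF = (QALY + AE loss − u_PP·LY)/(u_PF − u_PP).  The calibrated
comparator-vs-reference HRs come out at 0.90 (PFS) and 1.06 (OS): the
published QALY breakdown forces the comparator to have *more* PF time, even
though the published cross-trial PFS HR points the other way — one of the
source tables' internal inconsistencies, which the calibration resolves in
favour of the QALY/cost aggregates the decision actually rests on.

Cost knobs the source model leaves to supplementary material are
back-solved in order: paid doses per assistance program reproduce each
arm's drug component ($2,523 / $26,768 → 2.7 and 5.1 paid doses), the
monitoring-frequency scale reproduces the management component
($1,224 / $1,162), and the per-cycle administration scale absorbs the
remainder so arm totals equal $12,321 / $36,371 exactly.  The deterministic
increments then match the published base case to solver tolerance:
ΔC = −$24,050, ΔQ = −0.0183, ICER = $1,314,208/QALY.

Survival-parameter uncertainty for the PSA uses the analytic
observed-information covariance of an uncensored log-normal sample of
n = 179 per arm (the reference trial's arm size) on the (μ, log σ) scale:
Var(μ) = σ²/n, Var(log σ) = 1/(2n).  Ignoring censoring makes these
slightly optimistic; given the decision margin (NMB ≈ $23k against
parameter-induced NMB spreads of a few $k) this does not move the CEAC.

## Synthetic trial data

`psmcea.ipd` emulates the reference trial: n = 179/arm; the six baseline
factors drawn independently at their published prevalences (male 91.60%,
age 61.48 ± 8 years, brain metastasis 3.92%, stage IV 65.83%, smoking
84.59%, ECOG 1 85.43% — the age SD and independence are package choices;
no correlation structure is published); exponential latent PFS with medians
5.5 vs 4.9 months; OS = PFS + an independent exponential post-progression
draw (medians 13 vs 8 months), which guarantees PFS ≤ OS structurally;
45% of progressed control patients cross over, multiplying their
post-progression time by 1.3 (an AFT-world effect, matching the two-stage
method's assumption); administrative censoring at 24 months.  Crossover
probability and acceleration are not published; the defaults are typical of
immunotherapy trials with post-progression access and produce the
documented dilution of the ITT OS hazard ratio toward 1.

What the generator does **not** emulate: enrollment over calendar time,
dropout, covariate-dependent survival, visit schedules.  Passing tests
therefore demonstrate correctness of the estimators under the stated
generating law, not performance on the real trial.

## Estimation details

**Parametric fitting.**  One pinned parameterization per family (see
`psmcea.survfit`).  MLE by multi-start Nelder–Mead with BFGS polish on the
unconstrained scale (positive parameters as logs), gradient tolerance 1e-8;
the covariance is the inverse central-difference Hessian of the negative
log-likelihood at the optimum, on the same transformed scale, which is also
the sampling scale for Cholesky draws (one diagonal jitter of 1e-10;
a covariance still indefinite afterwards raises rather than being silently
repaired, mirroring the source analysis's rejection of a Weibull OS curve
on exactly that ground).  Recovery is verified at n = 1,000 with 20%
censoring over 40 replicates per family (≥90% of replicates inside 3 SE on
the transformed scale); replicate counts are sized so the whole suite runs
in minutes.

**Two-stage adjustment.**  Weibull AFT (lifelines) among progressed
control patients at the secondary baseline, regressing post-progression
time on the switch indicator plus the six baseline factors (the source
analysis does not list its covariate set; the matching factors are the
natural default and the set is configurable).  Recensoring defaults on, at
min(C, C/accel).  Hazard ratios are Cox partial likelihood with Efron ties
(lifelines), weighted when MAIC weights are supplied.

**MAIC.**  Entropy-balancing dual: minimize Σ exp(aᵀ(x_i − target)) by
damped Newton on its logarithm, covariates standardized internally (the
solution is affine-invariant), gradient tolerance 1e-10, moment residuals
checked to 1e-8 on the standardized scale.  Only first moments are matched
(only means/proportions are published).  The anchored comparison is the
Bucher estimator; the published cross-trial HRs are inconsistent with the
Bucher ratios of their own inputs, so model runs take HRs from config and
the package reports the Bucher value.  Published adjusted HRs carry no CIs;
PSA draws use a log-normal with an assumed log-scale SE of 0.15.

## Sensitivity analysis

DSA varies each parameter over its table bounds (immunotherapy prices over
the table's 80–100% band; everything else over its printed low/high, which
encode SE, 95% CI, or ±20% rules).  The default ranking metric is the NMB
excursion at WTP $33,749 — the ICER's sign is unstable in the southwest
quadrant — with the raw-ratio excursion also computed (`metric="icer"`,
the published tornado's convention).  Under either metric the PF-utility
bar exceeds the PP-utility bar on the calibrated base case, and this is
forced: with both utilities varied ±20%, a utility's bar is proportional
to 0.4·|ΔQALY in its state|, and ΔQALY_PF = ΔQ_total − ΔQALY_PP ≈
−0.0175 − ΔQALY_PP is strictly larger in magnitude than ΔQALY_PP whenever
the PP increment is positive — which the published QALY breakdown says it
is.  The source's report that the PP utility is the single most influential
parameter is therefore not reproducible from its printed aggregates; the
corresponding check is left failing by design rather than weakened.

PSA: 10,000 iterations by default (the analysis scripts use 2,000 and the
acceptance script 1,000; the CEAC is flat at these sizes).  Gamma/beta/
normal by method of moments with SD = (high − low)/3.92; drug acquisition
prices are held constant in the PSA and varied only in the DSA.  Failed
iterations are dropped and counted; >1% drops aborts.  CEAC(WTP) =
P(WTP·ΔQ − ΔC > 0).

## Mapped-utility scenario

The mapping is a linear predictor over QLQ-C30 domain scores clamped to the
value-set range [−0.391, 1].  The shipped coefficient set is **synthetic**
(for demonstration and tests; the published algorithm targets a UK value
set and is not reprinted); real coefficient sets are injected as config.
Per-patient state means, the mean(PF) < mean(PP) exclusion filter, and
cohort averaging follow the source procedure.  The scenario run uses the
published trial-derived utilities (PF 0.730, PP 0.615) as inputs, zeroes
the separate AE disutilities (mapped utilities already embed AEs), and
adjusts the comparator's PF utility by the annualized differential AE loss
divided by undiscounted PF exposure years — the package's explicit
formula; the source states only the principle.  Result: the cheaper
strategy gains QALYs (+0.049) and dominates, reproducing the published
qualitative flip.

## Known limitations

- The calibration reproduces published aggregates, not the underlying
  fitted curves; component-level splits (administration vs subsequent
  therapy) differ from the published table by construction.
- Independent baseline covariates understate the hardness of MAIC weight
  solving on real correlated data (ESS here ~60% of n).
- The analytic log-normal information ignores censoring.
- No EVPI, no Markov cross-check, societal costs out of scope.
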