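# Methods

## Data model and conventions

A biodistribution record is one tissue measurement expressed as percent
injected dose per gram (%ID/g), tagged with animal, sex, time point (hours
post-injection) and a blocked flag. %ID/g values are stored **decay-corrected
to injection time**, the conventional presentation of gamma-counter data;
conversion from raw counts applies e^(+λ_phys·t) with the physical decay
constant λ_phys = ln 2 / T½. The dosimetry path re-applies physical decay
explicitly before fitting, so the fitted curves describe the activity that
actually irradiates tissue and are guaranteed integrable on [0, ∞).

Isotope constants default to fluorine-18: T½ = 109.77 min, mean positron
energy 0.2498 MeV per decay, positron branching 0.9686. All three live in a
JSON data file and can be overridden for other nuclides.

CSV inputs come in two dialects declared by the header, never guessed: a
`pct_id_g` column (values given directly) or a `net_counts`/`count_time_h`/
`injected_counts` triple (raw gamma-counter dialect). Group summaries use the
sample SD (n−1); a single-animal group reports its SD as undefined rather
than zero, to avoid silently understating variability.

## Time–activity curve fitting

Organ kinetics are modelled as y(t) = Σᵢ Aᵢ e^(−λᵢt) with Aᵢ ≥ 0 and
λᵢ > 10⁻⁴ h⁻¹ (the floor keeps every fitted curve integrable). Fitting is
unweighted trust-region least squares with deterministic starts — log-linear
regression for the mono-exponential, classical curve peeling (late-time
log-linear fit, strip, refit the early residual) for the bi-exponential — and
no random restarts, so a fit is a pure function of its points. Bi-exponential
components are reported fast-first (λ₁ > λ₂). By default fits use all
individual animal points rather than group means: a bi-exponential on four
mean points is exactly determined and carries no evidence about model
adequacy. A fitted rate below λ_phys (apparent clearance slower than physical
decay on decayed data) triggers a warning but is not an error, since noise
can produce it legitimately.

**Model selection.** The bi-exponential replaces the mono fit only when all
three hold: (a) it converged with strictly positive amplitudes and a rate
separation λ₁/λ₂ ≥ 3 (below that the components are not identifiable from
4–8 time points); (b) it improves R² by more than `delta_r2_min`
(default 0.01); and (c) the mono residual signs fail a two-sided
Wald–Wolfowitz runs test at α = 0.05 while the bi residuals pass it — i.e.
the extra component must remove *systematic* structure, not just variance.
Residuals within 10⁻⁹ of the data scale carry no sign information and are
discarded; fewer than 8 signed residuals make the runs test powerless and
count as a pass. On noiseless data the ΔR² threshold should be set to 0: any
improvement is then real, and the runs-test criterion alone guards the
choice. The default 0.01 is calibrated for noisy data, where R² differences
below it are routinely produced by chance.

## Time-integrated activity coefficients

The integral of a fitted curve over [0, ∞) is the closed form Σ Aᵢ/λᵢ
(%ID·h/g); integration starts at t = 0 from the fitted intercept, i.e. an
instantaneous-distribution assumption with no modelled uptake phase. The
coefficient (residence time) for a phantom organ is

    τ = area × m_organ/100                      (direct)
    τ = area × (M_source/M_target) × m_organ/100 (relative body mass)

The relative-body-mass form is the default whenever source and target
phantoms differ (the standard concentration-scaling extrapolation from
rodent %ID/g to a human phantom); same-phantom calls reduce to the direct
form. Which variant to use for cross-species work is a genuine modelling
choice, so the pipeline logs it prominently in the run log and the dose
report's assumptions.

Unassigned activity goes to a remainder-of-body term: remainder = cap − Σ τ,
where the cap defaults to T½/ln 2 (≈ 2.6395 h for fluorine-18), the total
decays per unit administered activity for a subject that never excretes.
A fitted whole-body curve may override the cap. Organ totals above the cap
beyond 10⁻⁹ h raise a consistency error rather than clamping: they indicate
double-counted sources or an extrapolation mistake. Urinary bladder contents
are treated as an ordinary source organ fed by urine measurements; there is
no dynamic voiding model, which makes bladder (and hence total) dose
conservative.

## Dose engine

Organ doses follow the MIRD schema D(r_T) = Σ_S τ(r_S)·S(r_T←r_S), linear in
τ. Organ names are reconciled between study tables, phantoms and S-matrices
through an explicit alias map (a JSON file); there is no fuzzy matching, and
an unmapped source is an error naming the offender. Effective dose is the
ICRP-103 weighted sum E = Σ_T w_T H_T with weights from a data file that must
sum to 1; with radiation weighting factor 1 (photons/positrons) mGy/MBq and
mSv/MBq coincide numerically. Weighted tissues absent from a dose report
(e.g. breast or gonads with a male report, or tissues outside the bundled
organ set) take the report's remainder-of-body dose — the declared remainder
rule of the bundled scheme.

The bundled S-value matrices are deliberately simple, openly constructed
models: the diagonal is the unit-density-sphere self-dose
S = 576.7·Δ_np/m mGy/(MBq·h) (Δ_np = mean non-penetrating energy × branching;
576.7 = 3.6×10⁹ decays/MBq·h × 1.602×10⁻¹³ J/MeV × 10⁶ mGy·g/J), and every
target receives a uniform whole-body photon cross-dose term equal to 5% of
the sphere constant spread over the body mass. This keeps every number in
the chain hand-checkable and preserves the qualitative structure (self-dose
dominates each row) while making no claim to reproduce voxel-phantom dose
factors; absolute organ doses computed with them characterise the toy model
only. When a matrix lacks a remainder column, the remainder contributes
self-dose only via the sphere formula evaluated at the phantom's unassigned
mass, and the omission of its photon cross-dose is flagged in the report's
assumptions.

Patient dose is the product of an effective-dose coefficient and the
administered activity, reported to 3 significant figures as is conventional.

## Statistics

Blocking comparisons default to the one-tail unpaired pooled-variance t test
(df = n₁+n₂−2); Welch is available because published blocking p-values are
not always consistent with the pooled one-tail variant. The toxicity-style
`two_sample_test` gates on Shapiro–Wilk normality of each sample and a
two-sided F-ratio variance check, both at α = 0.05: pass → pooled t; fail →
Mann–Whitney, computed exactly when n₁+n₂ ≤ 20 and the data are tie-free,
otherwise by normal approximation with tie correction. No multiple-testing
correction is applied anywhere, matching the single-comparison design these
tests serve. Degenerate inputs (both SDs zero, equal means) return p = 1 by
convention with a note rather than dividing by zero.

## QC module

Batch summaries are plain mean ± SD (n−1) at full precision; display
rounding (3 significant figures by convention) is left to formatting, since
published tables sometimes truncate rather than round. Half-life estimation
from paired dose-calibrator readings uses t½ = ln 2·Δt / ln(A₁/A₂), invariant
to rescaling both readings. Release bounds are inclusive (a measured value
exactly at a limit passes). Below-quantification results are encoded as
`<LOQ:x` and pass any maximum bound ≥ x; they cannot demonstrate a minimum
bound and fail one.

## Synthetic studies

The generator emulates the standard GLP biodistribution design: groups at
0.5, 1, 2 and 4 h plus a blocked group at 1 h, two sexes × 8 animals per
group, ~20 organs. Ground-truth organ curves are mono- or bi-exponentials in
%ID/g whose defaults are loosely anchored to published means for an
SSTR2-targeting fluorine-18 peptide (pancreas near 30 %ID/g at 0.5 h, fast
blood clearance, urine-dominated excretion); they are configuration, not
claims about any real dataset. Sex enters as a per-organ multiplicative
factor, blocking as a residual fraction (default 0.01) applied to
receptor-positive organs in the blocked group. Noise is multiplicative
lognormal with mean 1 and configurable CV (default 0.15): %ID/g data are
positive and right-skewed, which additive Gaussian noise would violate.
Everything is driven by one seed and bit-reproducible.

`true_tiac` provides the closed-form oracle Σ Aᵢ/(λᵢ+λ_phys) × m/100 — the
residence time the analysis chain should recover — so zero-noise simulations
give machine-precision targets for the whole pipeline, and replicate noisy
simulations measure estimator bias (the suite checks |λ bias| < 5% over 200
studies at the default design).

What the generator does **not** emulate: uptake (rising) phases, organ mass
variability between animals, inter-animal kinetic heterogeneity beyond iid
noise, counting (Poisson) statistics on the pctid path, or time-varying
excreta compartments. Passing recovery tests therefore demonstrates the
correctness of the estimation chain under the stated noise model, not
robustness to those real-data features.

## Pipeline

Sexes are processed independently end to end, as biodistribution studies
report them. The analysis path is seed-free and deterministic: identical
configuration and inputs give byte-identical output files. Each run writes
the fit report, per-sex TIAC tables and dose reports (CSV + JSON with an
assumptions array), plus a run log recording every design flag (fit target,
ΔR² threshold, extrapolation strategy, remainder cap). Stage failures
propagate with the stage name and offending organ or group.

## Problem sizes and numerical choices

The default test and acceptance workloads use the study design itself
(8 animals × 4 time points = 32 points per organ fit), 100-seed selection
experiments, 200-replicate recovery experiments and 100-fit quadrature
comparisons; these sizes give stable Monte-Carlo estimates while keeping the
whole suite fast. Optimizer tolerances are set to machine level
(xtol = ftol = gtol = 10⁻¹⁵) so noiseless fits reach ~10⁻¹⁵ relative error;
the documented recovery guarantee is 10⁻⁶. Closed-form integrals are checked
against adaptive quadrature at 10⁻⁹ relative. Ties in bi-exponential rate
ordering cannot occur after the separation floor; permutation invariance of
fits follows from sorting points before fitting.

Known limitations: no uptake-phase modelling (curves are forced monotone
decreasing from t = 0, which overestimates early activity for organs that
fill slowly); no bladder-voiding or GI-transit kinetics; toy S-values only;
the runs-test operationalisation of "residual randomness" is one reasonable
choice among several and its α = 0.05 is a convention, not an optimum.
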