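# Methods

`nmrfield` re-implements, as a tested library, the chemometrics workflow used
to detect metabolic field effects in ¹H-NMR spectra of esophageal tissue
extracts: spectral preprocessing, orthogonal-signal-corrected PLS-DA and
multilevel PLS-DA with cross-validation and permutation testing, and
peak-based univariate statistics. Because the clinical spectra are not
available, every stage is exercised against a synthetic cohort generator that
reproduces the statistical structure of the study design. This note records
the models, the parameters that matter, and the design choices made where
the procedure was genuinely open.

## Synthetic cohorts

A spectrum is a sum of Lorentzian multiplets on a uniform ppm axis plus a
smooth baseline and i.i.d. Gaussian noise:

    s(x) = Σ_m exp(c_m) Σ_k h_{mk} · hw²_{mk} / ((x − μ_{mk})² + hw²_{mk})
           + baseline(x) + ε(x)

where `c_m` is metabolite *m*'s log-concentration, `(μ, h, hw)` its peak
list, `baseline` a 3-term random-phase cosine expansion, and
`ε ~ N(0, noise_sd)`. The shipped library holds the ~25 metabolites of the
tissue study plus the TSP reference singlet at 0 ppm, with literature
chemical shifts and linewidths of 1.2–2.2 Hz at 600 MHz. No J-coupling fine
structure is simulated: multiplets are explicit peak lists, which is enough
to exercise alignment and quantification.

Per-sample log-concentrations follow a hierarchical model

    c = base + ln(2) · class_offset + subject_effect + sample_noise

with `subject_effect ~ N(0, subject_sd)` shared by all samples of a subject
(default SD 0.2, which is what gives the multilevel analysis its paired-design
advantage) and `sample_noise ~ N(0, concentration_sd)` (default 0.15). Class
offsets come from an *effect table* of pairwise log₂ fold changes whose signs
encode the reported direction of every tissue-class comparison; magnitudes
default to |log₂FC| = 1 for the strongest significance tier and 0.5 for the
weaker one, and are free parameters: tissue studies of this kind report
directions and significance tiers, not calibrated fold changes, so
magnitudes are a simulation choice. Pairwise entries are reconciled into
per-class offsets by least squares on the constraint graph `o_b − o_a =
log₂FC`, anchored at the lowest class; a consistent table is reproduced
exactly, an inconsistent one is compromised in the least-squares sense with
dominant signs preserved (verified by test).

Two nuisance processes emulate real acquisition: a per-metabolite
chemical-shift jitter (default SD 0.002 ppm, the pH effect; whole multiplets
move together, TSP is pinned) and a per-spectrum global referencing error
(default SD 0.005 ppm, which shifts TSP too and is what TSP alignment
removes). The default cohort layout is the nine-class, 211-sample design:
68 control normals; 7 Barrett's patients contributing paired
normal/Barrett's samples; EAC patients contributing normal, Barrett's and
tumour tissue pre- and post-chemotherapy with 15 paired normal and 14 paired
tumour pre/post sets.

**Grid and linewidth floor.** The default axis is 2¹⁴ points over −0.5 to
10.0 ppm, a desk-scale stand-in for the instrument's 32k points. Simulated
linewidths are floored at 4 grid points FWHM: on coarse test grids a 1.5-Hz
line (0.0025 ppm FWHM) would otherwise be narrower than the spacing and peak
heights would alias with sub-point referencing shifts, destroying signal
that survives at native resolution. The floor keeps lines resolved at every
grid scale, just as they are at 32k points, at the cost of slightly broader
lines on 1024–2048-point grids.

What the generator does **not** emulate: FID-domain artifacts (phase errors,
truncation), water-suppression residuals, J-coupling, peak-shape asymmetry,
spectral crowding beyond ~50 lines, and any real biological covariance
between metabolites (effects are independent per metabolite). Passing tests
therefore demonstrate that the *pipeline machinery* is correct and calibrated
under the designed statistical structure — not that the biological
conclusions would replicate on new clinical data.

## Preprocessing

Fixed order, each step deterministic and logged:

1. **TSP alignment** — integer-point shift placing the apex within the
   ±0.25-ppm search window at the point nearest 0 ppm; edge-value fill; a
   flat window warns and applies zero shift.
2. **Spline baseline** — the spectrum is lightly smoothed, the minimum of
   each 0.25-ppm window gives an anchor, and a natural cubic spline through
   the anchors is subtracted. Negative intensities are retained. Min-based
   anchors sit at the noise floor, so a pure-noise spectrum keeps a positive
   residual offset of order the noise SD — the price of never cutting into
   peaks.
3. **Region exclusion** — water 4.49–5.89 ppm and TSP below 0.14 ppm removed;
   the axis may become non-uniform, which downstream steps accept.
4. **Segmental alignment** — per configured interval (defaults cover the
   lactate/3-hydroxybutyrate, glutamine/succinate, creatine/choline/taurine
   and purine regions), the integer shift within ±15 points maximizing
   Pearson correlation with the mean spectrum is applied, edge-fill within
   the segment. The target is the mean spectrum computed once, not iterated —
   the simplest deterministic interval-alignment mode. Ties prefer |shift| =
   0, so aligned data is untouched.
5. **Total-area scaling** — each row divided by its own sum (error naming the
   sample on non-positive area).
6. **Generalized log** — g(y) = ln((y − y₀ + √((y − y₀)² + λ))/2) with
   y₀ = 1e-7, λ = 5e-4; defined for all real y, ≈ ln y for y ≫ √λ, linear
   near zero, with analytic inverse y = y₀ + e^g − λ/(4e^g). Evaluated in a
   cancellation-safe form for large negative arguments.

Mean-centering is deliberately not part of the stored pipeline: it belongs
to model fitting, so held-out rows are centered with training means.

## Latent-variable models

**PCA** by SVD with a deterministic sign convention; per-sample Q-residuals
are squared reconstruction distances from the model plane, with the 95%
control limit from the Jackson–Mudholkar approximation computed on the
eigenvalues excluded from the model. Screening flags samples, never drops
them silently.

**OSC** (Wold-style NIPALS): each removed component's score is driven to the
intersection of the row space of X and the orthogonal complement of the
class targets by alternating projection, so its correlation with y vanishes
numerically; weights and loadings are stored so held-out rows are filtered
with training parameters. All heavy algebra runs on the n×n Gram matrix, so
cost is linear in the number of spectral points. Default one component; the
component count is configuration rather than a fixed constant.

**PLS-DA** by NIPALS: a single ±1 column for two classes (first class in
sorted order = −1), one-hot encoding otherwise; X deflated per latent
variable and Y deflated through the X-scores, so the regression vector
reproduces the training fit exactly. With all latent variables on a
full-rank matrix the fit equals minimum-norm least squares (tested against
the pseudo-inverse oracle). Class assignment is nearest encoded target;
exact ties go to the first class in sorted order.

**Multilevel split**: X = grand mean + (subject means − grand mean) +
(X − subject means); multilevel PLS-DA is ordinary PLS-DA on the within
part. Subjects need ≥ 2 class-balanced samples. The within matrix uses only
each subject's own rows, so the decomposition itself cannot leak across
subjects.

## Validation

- **Scheme rule**: leave-one-out for models of ≤ 20 spectra, otherwise
  Venetian blinds with min(10, ⌊n/3⌋) interleaved folds assigned over the
  class-sorted order (10 interleaved splits is conventional chemometrics
  practice).
- **Per fold**, centering, OSC and PLS are fitted on training rows only.
  A `--leaky` CLI flag reproduces whole-matrix filtering for comparison with
  legacy chemometrics software; the default never leaks.
- **LV selection**: arg-min of cross-validated error over 1..max_lv, fewest
  LVs on ties (parsimony).
- **AUROC** by the Mann–Whitney formulation (ties count half), one-vs-rest
  per class on the cross-validated continuous predictions; **CVER** is the
  misclassification fraction.
- **Permutation test**: each cycle permutes labels and re-runs the entire
  cross-validation including LV selection; empirical p uses the add-one
  estimator (#{null ≤ observed} + 1)/(n + 1), never exactly zero. Per-class
  p-values are one-sided Welch t-tests of each class's observed
  cross-validated scores against the pooled scores of permuted samples
  carrying that label — a documented interpretation of per-class "random
  t tests", reported alongside the empirical p (a single empirical p cannot
  produce two per-class values).
- **Double cross-validation** (multilevel models): outer loop leaves one
  subject out entirely; the inner loop on the remaining subjects picks the
  LV count (≤ 3 by default) by subject-fold error; 20 repeats with
  reshuffled inner folds; reported error is the mean outer misclassification
  over repeats, default 20 repeats. The paired permutation null permutes
  labels within each subject; null cycles use fewer double-CV repeats than
  the observed statistic (5 vs 20 by default) since the null's location is
  insensitive to the repeat count. OSC defaults to zero components here: the
  within-subject split has already removed the between-subject variation
  that OSC targets.
- All randomness flows from one seed through spawned `SeedSequence`
  children; every reported number is bit-reproducible.

## Univariate statistics

One well-resolved peak per metabolite is picked in the first spectrum
(maximum within ±0.03 ppm of the literature position; targets whose windows
overlap another target are flagged unresolved) and tracked across spectra as
the window maximum; picks below 3× a robust noise estimate are flagged, not
dropped. Intensities come from the normalized, pre-glog matrix so means, SDs
and fold changes stay concentration-proportional. Comparisons run the
Shapiro-gated tree (gate at p = .05): unpaired → Welch t if both groups pass,
otherwise Wilcoxon rank sum; paired → paired t if the within-pair
*differences* pass, otherwise signed rank. Testing normality of the
differences (rather than of each member) is the choice here because that is
the quantity whose normality the paired t-test assumes. Raw p-values are
tiered ns / p<.05 / p<.005 / p<.0005; a Benjamini–Hochberg column is emitted
alongside as a clearly-labelled extension, not used for the tiers.

## Problem sizes used in tests and the acceptance script

Simulation-heavy checks run at desk scale, chosen once: permutation
calibration on 200 effect-free cohorts (20 vs 20 samples, 1024-point grid,
99 cycles each); power and direction recovery on 50 cohorts at the study's
68-vs-28 class sizes (2048-point grid, 99 cycles); multilevel advantage on
20 paired cohorts of 12 subjects with between-subject SD three times the
within-subject effect; the end-to-end determinism check and the full-scale
control-vs-tumour model on the complete 211-sample cohort (the latter at the
default 2¹⁴-point grid with a 100-cycle permutation test).

## Known limitations

- Peak tracking by window maximum cannot separate overlapped multiplets
  (no lineshape deconvolution); the choline-region species are tracked at
  their literature positions and flagged unresolved.
- The min-anchored baseline leaves a noise-scale positive offset on
  signal-free spectra (see above); total-area scaling largely absorbs it.
- O-PLS-DA here means OSC followed by PLS-DA, not a formal orthogonal-PLS
  decomposition; the two give equivalent predictions but different variance
  bookkeeping.
- Rank-sum/signed-rank p-values use the large-sample approximation from
  scipy; for the smallest groups (n ≈ 4–7) exact-test p-values would differ
  slightly.
- The effect-table reconciliation intentionally compromises inconsistent
  pairwise designs; exact pairwise recovery is only guaranteed for
  consistent tables.
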