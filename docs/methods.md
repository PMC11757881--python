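# Methods

This note records the modelling choices, defaults and limitations behind
`pdcconnect`, in the package's own terms.

## Signal model and PDC

Each 2-s, 256 Hz segment is treated as a realization of a stationary
vector autoregression of order ρ on the 18 network electrodes,

y(t) = Σ_{ζ=1}^{ρ} C_ζ y(t−ζ) + ϵ(t),

with zero-mean Gaussian innovations. Coefficients are estimated by
per-segment ordinary least squares after removing channel means (no
intercept term; band-passed EEG is zero-mean up to slow drift). The
spectral coefficient matrix is Ā(ω) = I − Σ_ζ C_ζ e^{−jωζ} and the
reported connectivity is the squared, column-normalized partial directed
coherence PDC_vw(ω) = |Ā_vw|² / Σ_{v'} |Ā_v'w|². Squaring plus column
normalization keeps every value in [0, 1] and makes each source's outgoing
influence sum to one at any single frequency; both properties are asserted
in the tests. The magnitude (non-squared) variant is available via
`squared=False`.

Two readings of the spectral matrix are possible (with or without the
identity term); only the identity-bearing form yields the normalization
and Granger-nullity properties above, so that is what the package
implements throughout.

### Reference handling

The Cz electrode is the recording reference and is dropped *before* MVAR
fitting, leaving an 18-node network (`exclude="CZ"`, the default). Fitting
all 19 channels and deleting the reference row/column afterwards is
available by passing `exclude=None` and slicing; the pre-exclusion
column-sum identity is tested on the 19-channel fit.

### Frequency grid

64 equal bands tile [0.1, 70) Hz, width (70 − 0.1)/64 ≈ 1.092 Hz. A band
value is the mean squared PDC over K = 4 frequencies at the centres of K
equal sub-intervals (point evaluation versus averaging is not dictated by
the PDC definition; averaging was chosen as the less noisy summary, and K
is a parameter). Rhythms map to inclusive band-index ranges
delta 1–6, theta 7–12, alpha 13–19, beta 20–47, gamma 48–64; these index
ranges, not nominal Hz ranges, are the operative definition.

### Model order

The fitted order is a free parameter. `order="auto"` minimizes BIC over
1..20 on a common estimation window (statsmodels-style alignment). The
pipeline and test suite use a fixed ρ = 5 for reproducibility and speed:
segment-level BIC selection is noisy at 512 samples × 18 channels, and a
fixed moderate order keeps the per-segment regression well-conditioned
(90 regressors, 507 equations).

## Preprocessing

Recordings are resampled to 256 Hz by polyphase anti-aliased resampling
(exact rational conversion, e.g. 500→256 as 64/125), converted from nV to
µV where needed (×10⁻³), band-passed 0.1–70 Hz with a 4th-order Butterworth
applied forward–backward (zero phase), and notched at 50 Hz with a
second-order IIR of quality factor 30, also zero-phase. These filter
designs are common EEG defaults and are exposed as parameters. Manual or
ICA-based artifact cleaning is out of scope; an optional amplitude
threshold (default 100 µV when enabled) drops whole segments instead. The
0.1 Hz high-pass edge rings for seconds, which matters for short test
signals but is negligible on 5-minute recordings.

Synthetic cohorts are generated directly at 256 Hz in µV and contain no
mains interference or out-of-band artifacts, so the evaluation paths run
segmentation directly on them; the filter chain is exercised by its own
tests and by the end-to-end driver.

## Synthetic cohorts

The generator's job is a two-class cohort with *known* directed
connectivity at the scale of the target study design: 35 subjects per
class by default, 5-minute 19-channel recordings at 256 Hz (150 two-second
segments each); reduced sizes are used in tests where noted.

* **Backbone.** All subjects share a stable sparse MVAR(3) backbone:
  AR(3) self-dynamics (0.4, −0.15, 0.05) per channel and 20 random lag-1
  couplings oriented from higher to lower channel index. The acyclic
  orientation makes the companion eigenvalues equal to those of the
  per-channel self-terms, so stability is inherited by construction (and
  still checked).
* **Class effect.** AUD-like subjects receive additional coupling entries.
  For the band-localized default (`gamma_effect_config`), two source
  channels (O2, O1) get AR(2) self-dynamics with poles of radius 0.96 at
  57 Hz and 66 Hz, and the effect adds first-differenced couplings
  (+0.15 at lag 1, −0.15 at lag 2) O2→F3 and O1→F4. Localization comes
  from both factors: the resonance puts a deep dip in the source column's
  PDC denominator near f₀, and the differencing high-passes the coupling
  numerator. Against the analytic oracle the class difference in band-PDC
  is ≥ ~0.24 on the gamma bands and ≤ ~0.11 below them; parameters were
  fixed from that oracle profile (two resonances cover the 17-band gamma
  range more evenly than one).
* **Subject variability and noise.** Each subject's effect couplings and
  diagonal self-terms are jittered with N(0, 0.02²); jitter draws that
  destabilize a model are retried a bounded number of times, then reported
  with the subject index. Recordings add white sensor noise of 0.5 µV sd
  on top of unit-variance innovations. A 1 000-sample burn-in removes the
  zero-state transient.
* **Determinism.** Per-subject random streams are spawned from the config
  seed via `SeedSequence`, so a config identifies a cohort exactly;
  subjects are simulated in lock-step batches (batched matmuls over one
  time loop), which changes speed and memory but not the output.

What the generator does **not** emulate: 1/f background spectra, alpha
peaks, eye-blink/EMG artifacts, volume conduction, or non-stationarity.
Passing tests therefore demonstrate correctness of the estimation and
decision machinery on MVAR-class signals, not clinical performance.

## Feature selection

Each of the 324 directed electrode pairs is tested with a two-group
one-way ANOVA on segment-level values (pooled across the chosen band set),
and pairs with raw p < α are kept — deliberately without multiple-testing
correction, since the thresholded-raw-p workflow is the procedure being
reproduced; the selection's type-I behaviour is instead characterized
explicitly (null-cohort keep fraction matches the binomial interval around
α). Zero-variance features get p = 1 by convention. The grouping unit is
the segment; `by_subject=True` averages within subject first for
leakage-aware analyses. Selection is monotone in α by construction.

## Classification

SVMs (Gaussian RBF, polynomial degree 2–4, or linear) run on standardized
features. The Gaussian `kernel_scale` σ maps to sklearn's `gamma = 1/σ²`.
Hyperparameters are found by a seeded sequential model-based optimizer:
one Gaussian-process surrogate (Matérn 5/2 + white noise) per kernel arm
over log₁₀-scaled parameters (box constraint 10⁻³–10³, Gaussian scale
10⁻²–10²), expected-improvement acquisition over random candidate pools,
default budget 30 evaluations, all against a fixed cross-validation split
so configurations are compared on identical folds.

Evaluation is repeated stratified k-fold cross-validation (default 5×5).
Confusion counts and the pooled decision-score ROC come from the first
repeat, where every row is held out exactly once (so TP+TN+FP+FN equals
the row count); accuracy is reported mean ± sd over repeats. The positive
class is AUD-like. The operating point maximizes Youden's J = TPR − FPR.
The default split stratifies over segments, mirroring the segment-level
protocol of the study design this emulates; `split="subject"`
(StratifiedGroupKFold) is provided and recommended when subject-level
generalization is the question — the suite asserts that the subject split
is the harder one on cohorts with subject jitter.

## Numerical and scale choices

* Batched per-segment OLS uses normal equations (`solve` on XᵀX); it is
  verified bit-compatible with the per-segment `lstsq` path, which remains
  the fallback (and names the offending segment on rank deficiency).
* Stability is the companion-matrix spectral radius (< 1); simulation and
  analytic PDC refuse unstable models.
* Repeated-run studies use reduced problem sizes chosen as the package's
  own trade-off between statistical resolution and runtime: the band-sweep
  localization study runs 100 cohorts of 10 subjects/class × 15 segments
  over 16 swept bands with a fixed Gaussian SVM (per-band hyperparameter
  search is irrelevant to the ranking property and would dominate cost);
  the study-scale recovery check uses 20 subjects/class × 150 segments.
* t-SNE uses exact gradients (Barnes–Hut in 3-D is unreliable on
  near-duplicate inputs at this sklearn version) with PCA initialization,
  falling back to random initialization for degenerate constant inputs.

## Known limitations

* PDC is estimated per segment independently; no time-varying MVAR,
  generalized/renormalized PDC, or DTF variants.
* Additive sensor noise biases MVAR estimates (errors-in-variables); the
  default 0.5 µV sd is small relative to signal variance, and the bias is
  shared by both classes, but absolute PDC levels are slightly shrunk.
* ANOVA p-values across the 324 pairs are correlated through the shared
  column normalization; calibration checks use a binomial reference, which
  is adequate at the tested effect and cohort sizes but not exact.
* EDF files can be read (via the optional `mne` extra) but cohorts are
  written as delimited text + JSON manifest; EDF writing is not supported.
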