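# Methods

## Pipeline model

The analysis treats a fluorescence image purely as three per-channel
intensity distributions. All spatial structure is discarded after
thresholding: two fronds with the same per-channel DCV histograms are
identical to every statistic in the package. This matches the method's
intent — the discriminating signal is a spectral shift of the
fluorescence response, not a morphological change — and is what makes a
geometrically crude synthetic frond a valid test subject.

### Thresholding

Manual thresholding removes DCV codes `[0, cutoff)`; "remove the first
10 DCV" therefore drops codes 0–9 and keeps 10–255. The default preset is
cutoff 10 applied per channel, the setting used for all frond analyses.
The configurable grid {0, 5, 10, 15, 20, 25} covers steps of 5 up to 10%
of the 256 available codes.

Automatic thresholding is Otsu's criterion: an exhaustive sweep of
t ∈ [0, 255] maximizing the between-class variance w₀w₁(μ₀ − μ₁)² of the
split {v < t} vs {v ≥ t}, ties broken toward the smallest t. Pixels
strictly below the argmax are discarded (the 0-class of the binarized
image). Two consequences of the tie rule are worth knowing:

- On a histogram with an empty gap between background and foreground the
  between-class variance is exactly constant across the gap, so the
  returned threshold sits at the *left edge* of the gap, not mid-gap.
  Retention is unaffected (the gap is empty either way).
- In per-channel mode the three channels are swept independently and
  generally land on different cutoffs; no shared mask is imposed.

A degenerate histogram (fewer than two occupied bins) has no meaningful
split and raises rather than returning an arbitrary value.

### Abundance curves

Curves are stored as fractions summing to 1 (±1e-9); "percent" is a
display-time scaling. After manual thresholding at cutoff c the support
is every bin in [c, 255] including zero-count bins — so all curves built
under one threshold spec share a support — while the removed bins are
dropped entirely rather than kept as structural zeros. Keeping them
would let the empty background region dominate DTW alignment, which is
precisely the artifact thresholding exists to remove. Curves from
different threshold specs refuse to combine.

### Distances

The density difference 1 − Σ min(x, y) is symmetric, bounded in [0, 1],
and zero exactly on identical curves (values below 1e-12, pure float
round-off from the normalization, are snapped to 0).

DTW is evaluated by the standard forward dynamic program with steps
(advance i, advance j, advance both), endpoints anchored, local cost
|x_i − y_j|; the accumulation loop is numba-compiled because a full
experiment evaluates thousands of 246×246 alignments. No band or slope
constraint is applied. Path-length normalization (divide by n + m − 1)
is available but off by default: the raw alignment distance is the
quantity the 3σ envelope is calibrated on, and normalization only
rescales both sides of that comparison. Two-color DTW runs the same
program with a Euclidean local cost over the paired abundance 2-vectors
(L1 available); the joint-vector formulation was chosen over combining
two single-channel DTWs because it lets a correlated shift in both
channels accumulate in one alignment.

An important property of anchored DTW on these curves: a pure horizontal
translation of a hump on a zero baseline is almost free, because the
warp aligns hump to hump and matches the flat regions at zero cost. DTW
responds strongly to *shape* changes — peak height, width — and only
weakly to pure shifts. The synthetic dose model below is designed with
this in mind.

### Detection

Per tray, metric and channel (or pair), the control images (negative
time offsets) are scored leave-one-out: each control's mean distance to
the remaining controls. The envelope is the sample mean ± 3 × sample
standard deviation (n − 1 denominator) of those values. Every sample —
controls included, reported at their negative offsets — is then scored
as its mean distance to all of the tray's controls and flagged iff the
value falls strictly outside the closed envelope; a value exactly on a
bound does not deviate. The mean over controls is the default
aggregation (minimum available); it is the least surprising single
number and is what the leave-one-out calibration also uses, so sample
and control scores are directly comparable. Trays with fewer than two
controls are skipped with a logged error.

## Synthetic data

The generator reproduces the statistical features the pipeline relies
on, and nothing else:

- background: truncated normal, mean 3 DCV, sd 2 — the near-zero spike a
  black oxidized-aluminum sheet produces;
- frond: an elongated ellipse with two branch lobes, ~25% of a 96×128
  frame; visual realism is explicitly not a goal since only the DCV
  distributions matter;
- foreground intensities: per-channel normals clipped to [0, 255], means
  (R 150, G 60, B 45), sds (25, 15, 12) — red-dominant, as chlorophyll
  emission is captured in the red band;
- biological variability: each frond jitters its channel means by a
  N(0, 3 DCV) draw, which is what gives the control population a
  non-degenerate envelope;
- dose response: blue-channel only by default. The effect level is
  (1 + log₁₀ dose)/3 — doses 1/10/100 nmol/cm² map to 1/3, 2/3, 1 —
  times a transient decay of 1.0/0.1/0.03 at 0/24/48 h after dosing.
  The level scales both a mean shift (up to `dose_shift_max` DCV) and a
  fractional sd widening (`dose_sd_gain`). The widening models
  heterogeneous quenching across the frond: cells absorb unequal Cu, so
  the intensity distribution broadens and its peak drops as it shifts.
  Without it, anchored DTW would warp away most of a pure shift (see
  above) and the generator would misrepresent what a real spectral
  response looks like to this statistic.

Presets: `null` (no effect), `weak` (shift 25, widening 0.3), `strong`
(shift 90, widening 1.0). All draws are keyed by (seed, sample_id) via a
CRC mix, so any single image is reproducible without generating the rest
of the experiment.

The default design is the study layout — 3 trays × 10 partitions, one
pre-dose control sampling per partition (offsets cycling −8/−16/−24 h)
plus samplings at 0, 24 and 48 h — i.e. 120 single-frond images of which
30 are controls. The synthetic chemistry generator draws per-mg
chlorophyll lognormally around 3.3 µg/mL·mg⁻¹ with an a/b ratio
lognormal around 1.5, depresses the ratio at time 0 proportionally to
the dose level, inverts the quantification equations to emit consistent
absorbances, and adds dose-proportional dry-weight Cu with lognormal
noise on a background of ~0.25 nmol/g.

What passing tests on this generator do *not* show: robustness to
non-uniform backgrounds, multiple objects per frame, specular
reflections, autofluorescence of debris, or camera nonlinearity — real
images have all of these and the study handled them by controlled
acquisition, not by the statistics tested here.

## Chemistry

The quantification coefficients satisfy the exact identity
Chl a+b ≡ Chl a + Chl b (7.12 = 12.00 − 4.88, 17.67 = 20.78 − 3.11),
which the packaged table obeys row-wise to printed rounding (max
residual 0.001, tolerance 0.002). Negative concentrations from
near-detection-limit absorbances are flagged, never clamped. The a/b
ratio is reported as undefined when Chl b ≤ 0.

The packaged chlorophyll table carries the published per-mg values and
the published a/b-ratio column verbatim, *plus* a recomputed
`ab_ratio_recomputed = chl_a_per_mg / chl_b_per_mg`. The two disagree
for most rows in the source table; the package keeps both side by side
and takes no position on which the original figures used. Likewise the
SET table's `cu_ww`/`cu_dw` columns are stored exactly as printed with
the unit ambiguity (nmol/g vs mg/kg is not attributed per column in the
source) left to the caller; `cu_content` itself always computes both
unit systems explicitly, converting at 63.546 g/mol.

## Numerical and scale choices

- Grayscale uses BT.601 weights (0.299, 0.587, 0.114), round-half-up;
  the transform is not defined by the method, so the most common 8-bit
  convention was adopted.
- Inputs deeper than 8 bits are linearly rescaled to [0, 255] with a
  logged warning rather than rejected; the DCV arithmetic assumes 256
  codes.
- Problem sizes: synthetic images are 96×128. At this size a full
  120-image experiment with all nine metric/channel combinations
  (≈ 3,300 DTW alignments on 246-bin curves) completes in ~10 s, and the
  per-bin sampling noise of a ~3,000-pixel foreground is small enough
  that the 3σ envelope is driven by the modeled biological jitter rather
  than by counting noise — the regime the real data is in.
- The calibration checks use the full default design (1080 scored
  records under the null) and fixed seeds; the null flag rate (~2.6%)
  sits where a 3σ rule with a 10-control estimated envelope is expected
  to, well under 5%.

## Known limitations

- The cuvette workflow (imaging chlorophyll extracts) is supported only
  as a `sample_type` label; no cuvette-specific geometry is generated.
- The pipeline deliberately does not estimate contamination *level* from
  distance magnitude — the statistic saturates and the method is
  validated only as a detector of recent dosing events.
- Contour/mask-based segmentation of multiple objects is out of scope;
  thresholding assumes one frond on a uniform dark background.
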