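# Methods

This note records the models, conventions and numerical choices behind
each stage of the package, and what the synthetic-data tests do and do
not establish about real data.

## Poly-proline tract scanning

A tract is a **maximal** run of consecutive proline residues with
length ≥ `min_tract_len`. The default threshold is 3, the run length at
which ribosome stalling becomes eIF5A-dependent; it is configurable
(≥ 2) because published PPT catalogues do not always state their
threshold. Matching is case-insensitive. Any non-proline character —
including the ambiguity codes X/B/Z/U and the stop symbol `*` — breaks
a run: ambiguity codes are not proline and must not be allowed to
bridge two sub-threshold runs into a reported tract. Coordinates are
0-based half-open. Sub-runs of a longer run are never reported.

Per-protein profiles summarise tract count, longest tract, and total
prolines in tracts (isolated prolines do not count). Ranking of a gene
set uses total prolines in tracts as the primary key; the tie-break
chain (longest tract, then tract count, then identifier) is fixed so
that ranks are total, dense and reproducible. Only the primary key is
scientifically motivated; the remaining keys exist for determinism.

## Enrichment statistics

Carrier status (≥ 1 tract vs none) against gene-set membership forms a
2×2 table whose background is the complement of the gene set among the
profiled proteins, so the four cells partition the proteome.

* **Chi-square**: uncorrected Pearson, df = 1. No Yates continuity
  correction is applied — on the reference carrier counts the corrected
  statistic would be ≈ 7.39 while the uncorrected one is 7.64, the
  published value, which pins the convention. The p-value uses the
  closed form `erfc(sqrt(chi2/2))`, exact for one degree of freedom.
* **Odds ratio**: cross-product ad/bc with the Wald (Woolf) interval on
  the log scale, z = 1.959964. All four cells must be positive; no
  continuity adjustment (e.g. Haldane +0.5) is offered, because the
  interval convention would silently change.
* Sampling-zero margins raise errors naming the degenerate margin
  rather than returning NaN.

The implementation computes the statistic from the closed form; the
test suite cross-checks it against an independent expected-count oracle
and `scipy.stats.chi2_contingency(correction=False)`.

## Blot normalization and group comparison

Per lane, `ab_ratio = (Tab/mean Tab)/(Cab/mean Cab)`, with means over
all lanes of **one blot** — each blot is its own normalization unit and
blots are never pooled, which makes the ratio invariant to whole-channel
exposure changes. For hypusination the hypusine signal is normalized to
total eIF5A (the only hypusine-carrying protein), so the ratio reads as
the hypusinated fraction up to the blot-mean scaling. Signals must be
positive: background subtraction and band quantification are upstream
of this package.

Group comparison is the unpaired **Student** t-test (pooled variance),
two-sided; the unequal-variance Welch variant is available behind a
flag but not the default, since pooled variance is the common default
of the acquisition software such analyses typically use. Degenerate
zero-variance inputs: equal means give (t = 0, p = 1); unequal means
raise, as no finite statistic exists.

qPCR expression is `2^-(CT_target − CT_reference)` (relative
quantification against a reference gene, no calibrator sample, i.e.
not the ΔΔCT design).

## Polysome trace segmentation

The absorbance trace is smoothed with a centred moving average
(default window 9 samples) for peak detection; local maxima are kept if
their prominence exceeds 5 % of the smoothed trace's amplitude **and**
their width at half prominence exceeds twice the smoothing window.
Both filters matter: after averaging over *w* samples, noise remains
correlated on scale *w*, so noise excursions can pass a pure prominence
test; requiring features to outlast the smoothing scale removes them.
The window default of 9 (rather than a smaller value) keeps residual
noise prominence well below the 5 % threshold at noise levels up to a
few per cent of the monosome peak height, which is where usable traces
live; both parameters are exposed.

Labels are positional by default — first three peaks 40S, 60S, 80S,
all later peaks `polysome_k` — with a manual override because gradient
layouts vary (free-RNA region, halfmers, missing subunit peaks).

Regions span valley to valley: boundaries are the minima of the
(anchor-)smoothed trace between adjacent peaks plus the trace ends.
Ties on a flat valley floor are resolved on the heavier-smoothed
signal, which lands the boundary inside the plateau instead of at a
peak's base. Each region's baseline is the straight line joining the
smoothed trace values at its boundaries; the area is the trapezoidal
integral of (smoothed signal − baseline) clipped at zero. Three
numerical choices deserve note:

* **Baseline anchors from a smoothed signal** (window 2·w+1): anchoring
  the chord to single raw samples lets one noisy point tilt the whole
  baseline of a region.
* **Integrating the smoothed signal**: a unit-mass moving average
  preserves area, while clipping the *raw* signal at zero rectifies
  noise into a systematic positive bias that is worst for small regions
  (the 60S peak).
* **Clipping at zero** tolerates noisy valleys dipping below the chord.

P/M uses the 80S area alone as the monosome denominator (not
40S+60S+80S). The 60S/80S ratio is area-based. Ratios whose regions are
absent are NaN, not errors.

This convention is parameter-light and reproducible but not a
deconvolution: overlapping peaks exchange tail mass across valleys, and
the chord baseline removes any peak mass lying under the valley level.
On well-resolved peaks the residual error is below 1 %; heavily
overlapping peaks (valley elevation a substantial fraction of peak
height) will be under-integrated, and curve fitting would be needed
instead.

## Synthetic data

* **Proteome**: two classes (gene set, background) with per-class
  carrier probabilities; carriers receive 1 + Poisson(0.7) tracts with
  lengths 3 + (geometric(q = 0.55) − 1), giving a heavy right tail
  (longest tracts ≈ 9–12). Defaults mirror the human analysis scale
  (685 vs 17 981 proteins, carrier rates 0.289/0.242); sequence lengths
  are uniform on 120–600 residues. Non-tract segments are built from
  the 19 non-proline amino acids plus isolated sub-threshold prolines
  placed so that no accidental run can reach the scan threshold and no
  planted tract can be extended; the planted truth table is therefore
  exact, and the scanner is required to reproduce it residue-perfectly.
  The generator does not model realistic amino-acid composition,
  homology, or length–proline correlations — recovery tests validate
  the scanning and counting machinery, not biological realism.
* **Trace**: sum of Gaussians on a linear baseline with additive
  Gaussian noise scaled to the 80S peak height. Default layout: 40S,
  60S, 80S at positions 25/35/45 and four polysome peaks at 57/68/79/90
  (span 0–100, 800 samples), widths 1.2–1.8, true areas
  1.0/1.5/4.0/4.0/3.0/2.0/1.0 — a true P/M of 2.5 and 60S/80S of
  0.375, with peaks resolved as in a usable fractionator run. Specs
  with centres closer than one peak width trigger a merge warning.
* **Blot**: lane signal = group mean × lognormal lane loading
  (σ = 0.2) × lognormal measurement error (σ = 0.05); the control
  antibody shares the lane loading. Defaults: six lanes per group,
  true mutant/WT ratio 0.4 — a strong hypusination-type deficit at
  typical replicate counts.
* **CT table**: reference CT ≈ 20 with SD 0.15 per well; the target CT
  offsets by −log2(true expression).

All generators are pure functions of their spec (seed included).

## Problem sizes used in validation

The validation suite runs the scanner/oracle comparison on ~1100 random
sequences at thresholds 2–6; the synthetic round trip on a 2000-gene
proteome with planted carrier rates 0.5/0.25 (recovery within 3
binomial SE); type-I calibration on 200 null tables (n = 2000 per
class) and 1000 null t-test pairs (n = 3, 5 % ± 2 % rejection);
trace-ratio recovery on 50 seeded traces at 3 % noise (≥ 90 % of traces
within 10 % of truth; in practice 50/50); and blot-deficit recovery on
100 replicate blots. These sizes make the whole suite run in seconds
while keeping Monte-Carlo standard errors comfortably inside the
asserted tolerances.

## Known limitations

* The scanner operates on protein sequences only; DNA-level scanning
  and isoform handling are out of scope.
* The enrichment module fixes the single-gene-set, chi-square + Wald
  convention; no Fisher exact test, multiple-testing machinery, or
  covariate modelling.
* Trace segmentation does not deconvolve overlapping peaks or detect
  halfmers.
* Blot quantification starts from extracted band intensities; image
  densitometry is not modelled.
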