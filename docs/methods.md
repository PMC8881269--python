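# Methods

This note documents the models, defaults and numerical choices behind
`tetrascreen`: what the synthetic-data generator emulates, how cells are
classified and wells normalized, and how the confirmatory and downstream
statistics are computed. It also records which features of real screen data
the generator deliberately does not model.

## Synthetic screen generator

### Population model

A well's population is a categorical distribution over seven states: the
six ploidy/cell-cycle classes — 2CG1, 2CS, 4CG2 (mononucleated diploid
compartment), 4CG1, 4CS, 8CG2 (binucleated tetraploid compartment) — plus a
FUCCI-negative state for cells expressing neither sensor. The default
baseline emulates a population ~24 h after transient cytokinesis-failure
induction:

| state | 2CG1 | 2CS | 4CG2 | 4CG1 | 4CS | 8CG2 | FUCCI− |
|---|---|---|---|---|---|---|---|
| probability | 0.12 | 0.12 | 0.06 | 0.30 | 0.23 | 0.12 | 0.05 |

giving 65% binucleated tetraploids and 30% diploids — inside the 60–70% /
30–40% window such treatments produce — with most cells of either ploidy
cycling. The within-compartment G1/S/G2 split (≈46/35/19%) reflects an
actively cycling population. The FUCCI-negative fraction (5%) is a modelling
choice; real screens report only that such cells exist and are excluded.

### Knockdown effects

A knockdown effect is a single scalar `e` added to the joint log-odds of
the proliferating-tetraploid classes {4CS, 8CG2} against everything else:
their probabilities are multiplied by `exp(e)` and the vector renormalized.
This encodes the screened "TP53-like" phenotype — more tetraploids entering
S and reaching G2 — with one knob; `e = 0` is the exact identity, `e → ∞`
concentrates all mass on the two classes in proportion to their baseline.
The default planted effect is `e = +1.5`, which moves the 4CS+8CG2
abundance from 0.35 to ≈0.71; both TP53 and KIFC1 positive-control wells
carry the same reference effect, R-LUC wells carry zero.

### Plate effects

Each plate draws i.i.d. lognormal factors (SD 0.05 by default) *per class*,
which multiply the class probabilities before renormalization. A scalar
factor common to all classes would cancel exactly under renormalization, so
per-class factors are what make plate effects observable and per-plate
normalization necessary. Ground truth records the factor vector per plate.

### Intensity model

Integrated intensities per cell are lognormal around class-determined
medians:

- **DAPI**: median = content × anchor (default anchor 1000 a.u. for a 2C
  nucleus), with 2C→1×, 4C→2×, 8C→4×; S-phase classes draw their content
  uniformly between the flanking anchors (2CS in (1,2), 4CS in (2,4)).
  Lognormal CV 0.12 per nucleus — typical for integrated nuclear
  intensities. Binucleated cells are emitted as one record with
  `n_nuclei = 2` and the two per-nucleus draws summed (their total DNA
  content is what the classifier needs), which also gives tetraploid
  classes √2-reduced relative noise, as summing two independent nuclei
  does in real measurements.
- **FUCCI**: "on" median 500, "off" median 25 (20× separation keeps the
  on/off gates learnable), CV 0.25. G1 classes express the G1 sensor; S and
  G2 classes the G2 sensor; 25% of S-phase cells additionally retain the G1
  sensor (the Cdt1 reporter persists into early S); FUCCI-negative cells
  express neither.
- A per-well multiplicative factor scales all three channels jointly
  (staining/illumination variation); classification is invariant to it.

Reproducibility: one master seed; every well derives an independent RNG
stream from a SHA-256 hash of (plate, well), so output is bit-identical for
a fixed seed and independent of simulation order.

### Rendered fields

`render_field` draws each cell as a uniform disc (radius 8 px by default);
binucleated cells as two discs separated by `binucleate_gap` (default 2 px,
within the default merge radius of the quantifier; 0 renders tangent lobes
that form a single connected component). The scaled integrated intensity is
spread over the disc pixels with exact integer allocation, so channel sums
reproduce the record up to quantization of the total. Background is
constant (default 100) with optional Gaussian noise. Cells are placed by
seeded rejection sampling with a clearance margin so distinct cells are
never merged by the gap-based grouping.

**Not modelled**: point-spread functions, shading/vignetting, focus drift,
cell debris and clumps, mitotic figures, multi-generation lineage dynamics,
cell death. Tests passing on these fields show the measurement chain is
correct, not that segmentation would survive arbitrary real-microscopy
artefacts.

## Image quantification

Segmentation is global-threshold based: subtract the image median (robust
background when foreground is sparse), threshold with Otsu's method
(configurable hook), label 8-connected components, drop objects below
`min_area` (30 px). Nuclei pairs whose boundary gap (minimal pixel-centre
distance − 1) is at most `max_gap_px` (3) are merged greedily
nearest-pair-first into cell-level objects, each object merging with at
most one partner — so a binucleated tetraploid contributes one measurement
with summed DNA content, and three mutually close nuclei produce one pair
plus a singleton, never a triple. Integrated intensities are
background-subtracted (channel median) sums over object pixels, in floating
point.

## Classification

### Gating windows

With relative content `c = dapi / anchor`, the default windows are
symmetric ±0.25 bands around the 2C and 4C anchors with S-regions between:
2C G1 [0.75, 1.25]; diploid S (1.25, 1.75); 4C [1.75, 2.25]; tetraploid S
(2.25, 3.5); 8C G2 [3.5, 4.5]. G1-sensor-only cells in the 2C/4C windows
are 2CG1/4CG1; G2-sensor cells below the 4C window are 2CS, in the 4C
window 4CG2 (or 4CS when both sensors are on — a both-positive cell at 4C
is a tetraploid in early S, at the accepted risk of mislabelling the
occasional early-S diploid G2 doublet), above it 4CS, and 8CG2 in the 8C
window. Cells with no FUCCI signal are **excluded**; cells whose content
fits no window for their state are **other**. Both are counted for QC and
never enter abundances. All boundaries and thresholds live in a YAML-round-
trippable `GatingConfig`; they are design choices in relative-content
units, not biological constants.

### Anchor estimation

The 2C anchor is located on the kernel-smoothed histogram of log DAPI among
G1-sensor-only cells as the *lowest-content substantial mode* (≥20% of the
tallest peak). Taking the leftmost substantial peak rather than the global
mode matters because in a tetraploid-heavy population the tallest G1 peak
is the 4C one. Anchors are estimated per well; a well falls back to the
pooled plate anchor when it has fewer than 50 FUCCI-positive cells *or*
when its own estimate deviates more than 1.5× from the plate anchor —
staining varies by tens of percent, not two-fold, so a large deviation
marks a failed estimate (e.g. a strong knockdown depleting the diploid G1
peak), not real variation.

### FUCCI thresholds

Per plate, each sensor's on/off threshold is the Otsu split of the
log-intensity distribution (a valley surrogate for the bimodal on/off
mixture); absolute overrides are available. Because both the anchor and the
thresholds are estimated from the data, classification is invariant to a
common rescaling of all intensities.

### Accuracy and its limits

On cells whose S-phase content is drawn in the *gate cores* — at least two
log-noise SDs inside the S-window boundaries (geometric midpoint where a
window is narrower than four SDs) — classification against generator truth
is exact at zero noise and ≈96% at the default CV 0.12, with confusions
confined to adjacent content windows. Accuracy is computed over cells
assigned to one of the six classes, since excluded/other cells never enter
abundances. When S-phase content spans its full biological range instead,
accuracy drops to ≈85%: cells generated within ±1σ of a gate boundary are
intrinsically ambiguous (e.g. a diploid G2 cell at exactly 2× content
leaks ≈29% across the ±12.5% 4C window at 12% CV). That is a property of
gate-based classification of a continuum, not an implementation defect, and
it motivates the robust plate-level normalization downstream: boundary
leakage is common to all wells of a plate and cancels in the Z\*-score.

## Screen statistics

Per plate and class, `z* = (a − median)/(1.4826·MAD)` with median and MAD
over included library wells only: control wells are scored against the
library distribution but never contribute to it (they would bias the null),
and QC-flagged wells (fewer than 100 classified cells, empty, or no anchor)
are excluded entirely. The 1.4826 consistency constant puts z\* on an
SD-comparable scale under normality; a raw-MAD mode is available. A class
with zero MAD yields flagged NaN scores, never ±∞, and flagged values
propagate as missing, never as zero.

The default gene composite is the mean of z\*(4CS) and z\*(8CG2) — the
direct encoding of "more proliferating tetraploids" — per replicate;
single-class and max composites are selectable. Primary calling uses the
union rule (above threshold in ≥1 replicate) by default, trading false
positives for a lower false-negative rate, with intersection and mean rules
available; the high-confidence call uses the replicate-mean score, by
default against a cut of median + 6 scaled MADs of the per-well R-LUC
composite distribution (`negative_control_cut`), or a fixed cut (e.g. 10).

## Dunnett confirmation

Genes are confirmed against the pooled R-LUC wells of their plate-copy
family with the classical homoscedastic Dunnett test. The adjusted p-value
P(max_j T_j ≥ t_i) under the equicorrelated multivariate-t null is
evaluated two ways:

- **integration** (default for k ≤ 50): the probability conditioned on the
  pooled-SD variable U = s/σ and the control-mean normal Z is a product of
  univariate normal CDFs; the two nuisance dimensions are integrated with
  160-point Gauss–Legendre rules on [−8.5σ, +8.5σ] for Z and the 1e-12
  chi-tail-truncated range for U, with analytic weight densities. The
  integrand is entire, so convergence is spectral: the k = 1 case
  reproduces the one-sided two-sample t-test p-value to ~1e-12, and results
  match an independent implementation (scipy's Dunnett, randomized-QMC) to
  its own noise level.
- **Monte Carlo** (k > 50 or on request): seeded direct simulation of the
  max-T null with the binomial standard error reported per p-value.

One-sided "greater" is the default (the screen confirms *improvement* of
tetraploid proliferation); two-sided is available. Confirmation requires
adjusted p strictly below α = 0.1 *and* a positive mean difference.
Degenerate inputs (zero pooled variance, fewer than two observations per
group) raise instead of returning misleading values.

## Flow gating and fold change

Events are gated on relative DNA content (anchor = lowest substantial mode
of the log-DAPI density), EdU (log-Otsu threshold) and cyclin B: EdU+
events are diploid S in (0.75, 2.25] and tetraploid S in (2.25, 4.5); EdU−
events are diploid G1 at ~1×, tetraploid G2/M at ~4×, and at ~2× the
cyclin-B split resolves tetraploid G1 (low) from diploid G2/M (high, pooled
into the diploid S/G2/M category) — this is the analytic purpose of the
cyclin-B stain in the assay. Without a cyclin-B column those events are
labelled "other" with a warning. The proliferating-tetraploid fraction is
(4C_S + 8C_G2)/(4C_G1 + 4C_S + 8C_G2) and the fold change is the
treated/control ratio of that fraction; an EdU-only numerator variant is
available, as the figure-level definition in published screens is rarely
spelled out.

## Proteomics statistics

Missing log-intensities are imputed per sample from
Normal(mean − 1.8·SD, (0.3·SD)²) — the conventional down-shifted normal for
left-censored label-free data. The moderated statistic is
`d = Δmean/(s0 + se_pooled)` with s0 = 0.1 by default; s0 = 0 reduces d
exactly to the Student t statistic.

Significance is set by label permutation: for each candidate cutoff on the
observed |d|, the estimated FDR is the mean over permutations of the
permuted exceedance count divided by the observed count, and the smallest
cutoff with estimated FDR ≤ the target defines the significant set.
Permutations equivalent to the observed labelling (identity and group swap)
are always excluded, and the mean-count convention is the default because
the median collapses to zero at extreme cutoffs when the number of distinct
assignments is small (20 for 3 vs 3), which would call the top-ranked
protein "significant" in over a third of pure-noise matrices; with the mean
convention the null rejection rate is bounded by the permutation
discreteness (1/10 at 3 vs 3, ≈0.03 at 4 vs 4) while strong planted effects
remain detected. The median convention remains available for comparison.
At least 20 distinct assignments are required; below that the test refuses
and recommends exact enumeration.

## Problem sizes used in the shipped checks

The end-to-end recovery check simulates 2,000 genes × 2 replicates at 500
cells/well (≈2.1M cells, 12 plates) with 2% planted hits at e = +1.5;
classifier checks use 20,000-cell wells; Dunnett null calibration uses
2,000 families of 374 genes × 4 replicates against 16 controls; FDR null
calibration uses 200 matrices of 150 proteins × 8 samples. These sizes give
sub-percent Monte-Carlo error on every reported rate while keeping the full
suite and the acceptance script each under a minute of CPU.

## Known limitations

- The generator draws cells i.i.d. within a well; it does not model
  spatial effects (edge wells, gradients), well-to-well carry-over, or
  cell-count variation beyond the configured per-well count.
- Segmentation handles pair-merging only; three or more touching nuclei
  and watershed splitting of truly overlapping nuclei are out of scope.
- The Dunnett implementation assumes homoscedasticity (technical
  replicates); a heteroscedastic (Dunnett-T3-style) variant is a future
  option.
- Gate boundaries are configuration, not estimates; a misplaced anchor
  shifts every class assignment in a well, which is why the anchor has both
  a pooling and a plausibility fallback.
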