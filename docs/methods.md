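# Methods

## Scene model

A scene is a set of fields of view, each a multi-channel 3D stack
(channels `dna`, `intron`, `exon`) plus a 16-bit label mask. Cells are
spheroids (default 4.0 µm lateral × 3.0 µm axial radius) on a jittered grid
(9 µm pitch, ±0.4 µm jitter; the geometry refuses configurations whose
spheroids could overlap), with a concentric nuclear spheroid at 60 % of the
cell radius. Cell centres sit exactly on a z-plane centre so that each
cell's "mid-plane" is well defined; everything else (dot positions, locus
positions) is continuous in all three coordinates.

Each cell carries one or two homologous loci inside the nucleus (within
80 % of the nuclear radius). With probability `pairing_prob[stage]` the two
alleles are colocalized — rendered as a single punctum whose label is the
*sum* of both alleles' amplitudes, true distance 0. Otherwise the alleles
are displaced symmetrically about a random nuclear point along an isotropic
direction, with 3D distance drawn from a truncated normal (default mean
1.5 µm, sd 0.5 µm, floor 0.5 µm; the floor keeps unpaired foci optically
resolvable, since the violin-style distance distributions this emulates
have essentially no mass below it). With probability `sister_split_prob`
an allele resolves as two sister sub-foci 0.3–0.6 µm apart, each carrying
half the allele's label — the S-phase multi-focus pattern used to test the
exclusion rules.

Per-allele label: DNA-channel amplitude `dna_amplitude` and intron-channel
amplitude `nascent_rate[stage]`, each with unit-mean lognormal variation
(CV 0.15); unpaired alleles' nascent output is multiplied by
`suppression_factor` (1.0 = pairing-independent transcription).

Cytoplasmic mRNA dots (exon channel) follow a homogeneous spatial Poisson
process in the cytoplasm (cell minus nucleus), calibrated per plane slab so
that the expected number of dots whose nearest plane is the mid-plane equals
`mrna_rate[stage]` — the quantity the mid-plane scoring estimates.
Contamination dots emulating signal from adjacent somatic cells sit on a
thin shell just inside the cell surface at rate `contamination_rate`; they
are flagged separately in the ground truth. Defaults (GSC 12 dots/plane
declining ≈2-fold to 6 at the 2–4-cell stage, 2 contamination dots/cell)
were chosen so that the fold change matches the wild-type expression
decline while single-molecule dots remain sparse enough that overlapping
(multi-molecule-looking) dots are rare, a stated property of the real data
this emulates.

### Optics and noise

Spots are separable anisotropic Gaussians integrated exactly over voxel
extents (error-function quadrature, ±6σ support), so a fully interior spot
adds exactly its amplitude to the grid. Default PSF σ = 0.08 µm lateral /
0.25 µm axial — the scale of an Airyscan-processed 63×/NA 1.4 confocal
(lateral FWHM ≈ 0.19 µm, axial ≈ 0.6 µm) — on 0.1 µm pixels with a 0.5 µm
z-step. Noise is a constant background (20 a.u.), optional Poisson shot
noise on signal + background, and Gaussian read noise (σ = 3 a.u.),
clamped at zero.

Deliberately **not** modelled: lateral defocus blur (an out-of-focus dot is
dimmer but not wider here), spherical aberration, bleaching, chromatic
shift, nuclear texture, segmentation errors (masks are emitted directly
rather than derived from a nuclear stain). Consequently, passing tests
demonstrate that the measurement operators are correct and unbiased under
the stated statistical structure; they do not certify performance against
aberrated real-world optics or imperfect segmentation.

### Determinism

One seed drives a scene. Sub-streams are derived per cell as
`default_rng([seed, field_index, cell_index])`, with separate layout and
noise streams per field; identical config + seed reproduces stacks and
tables bit for bit. The pipeline derives per-stage seeds by CRC-32 of
`"<seed>:<stage>"`.

## Detection and measurement

**Spot detection** runs on the anisotropy-corrected grid: a scale-matched
difference-of-Gaussians band-pass (σ vs 1.6σ, in voxel units per axis),
thresholded at `median + k·1.4826·MAD` of the filtered volume (default
k = 6; at the default noise this holds the pure-noise false-positive rate
below 0.01 per nucleus), local maxima with a minimum-separation rule
(default 0.12 µm lateral, one plane axial; ties broken toward the brightest,
then lowest (z, y, x) index). Peaks closer than the separation limit merge
— which *is* the operational definition of a paired (single-punctum)
signal. Sub-voxel centroids are intensity-weighted means over a small
window around the peak. Detections are assigned to the cell whose mask
contains the centroid, tolerating a one-voxel rim (a dot hugging the cell
surface can peak one voxel outside the rasterized mask).

**Intensity integration** sums a fixed lateral box (±4 lateral σ) over one
to three consecutive z-planes: the brightest plane, plus neighbours whose
background-subtracted in-box peak is ≥ 15 % of the brightest plane's.
The 15 % cut is matched to the axial PSF/z-step ratio: with σz = 0.25 µm
and 0.5 µm steps a plane-centred spot puts ~23 % of its peak on each
neighbour, so a higher cut would integrate a single plane and lose ~30 % of
the amplitude, while 15 % keeps worst-case recovery above 95 %. Background
is the median of a 2-voxel lateral annulus around the box on the same
planes, subtracted per voxel; negative totals are floored at zero with a QC
flag, and spans touching the stack border are flagged but still measured.

**Mid-plane dot counting** is per-plane 2D detection with a focus
criterion: a dot is scored on the mid-plane when it is a lateral local
maximum above threshold there *and* no brighter axial ghost exists — i.e.
no neighbouring-plane value within one pixel that is both higher and itself
a lateral peak (the tail of a laterally offset dot on another plane must
not veto a genuine in-focus dot). This mirrors how a human scores a single
confocal section and, unlike full 3D detection, does not let dots on other
planes absorb mid-plane dots. Every detected dot contributes exactly 1
regardless of brightness. **Whole-cell counting** uses full 3D detection,
whose axial merging makes one molecule spanning several planes count once.

## Pairing classification and intensities

After dropping intensity-outlier puncta — outside `[median/k, median·k]`
(default k = 3) of the cohort stratified by stage and focus-count class,
disabled below 10 measurements — a cell is *paired* with distance 0 at one
focus; *unpaired* at two foci with `D = √(x² + z²)`, `x` the lateral
centroid separation and `z` the plane-index difference times the z-step;
*excluded* otherwise (reasons: `no_signal`, `ambiguous_three_foci`,
`too_many_foci`). Exactly three foci are excluded by default because the
pattern is indistinguishable from an S-phase sister-chromatid split; the
`keep` policy instead scores the two brightest foci as the allele pair.
Centroid positions (not brightest pixels) define `x`; `z` is quantized to
whole planes, so axial distance components carry ±½ z-step quantization.

Per-punctum intensities are divided by the mean punctum intensity of three
(two if only two exist) seeded-randomly chosen *paired* CySCs in the same
field; per-allele values halve paired puncta. The paired/unpaired analysis
reports per-punctum and per-allele means, their ratios, and seeded
percentile-bootstrap 95 % CIs (2,000 resamples).

## Expression statistics

The silencing index is the **ratio of stage means** (not the mean of
per-cell ratios — cells are not paired across stages), with a percentile
bootstrap CI resampling cells within each stage. Cells are pooled across
fields; per-replicate grouping can be added upstream by filtering the counts
table. Group comparisons use Welch's unequal-variance two-tailed t-test
(the robust choice when variances track means, as Poisson-like counts do),
with the Šidák closed form `1 − (1 − p)^m` for families of comparisons
against a control; Šidák is used uniformly where step-down procedures
appear in common practice because it is closed-form, conservative and
reproducible across languages. Degenerate convention: two zero-variance
groups compare at p = 1 when their means are equal, p = 0 otherwise.
Quantiles use linear interpolation throughout. The copy-number check fits
per-cell counts against gene dosage by OLS (slope/intercept standard errors
from the cell-level fit) and reports R² of the per-dosage means against the
fitted line.

## Validation suite sizes and known limitations

The validation protocols run at ~120–200 gonialblasts for intensity ratios,
200 cells/stage for silencing indices, 250 cells for the hemizygote
single-focus check, 60 cells per dosage level for linearity, and 1,000
replicates for the family-wise-error simulation — sizes at which bootstrap
CIs are a few percent wide while a full run stays within minutes on one CPU.

Known limitations:

- At the densest default dot load (GSC, 12 dots/plane) optical crowding
  merges ~3–5 % of mid-plane dots, so SIs against a sparser stage read
  ~3–5 % below the generator fold change; the validation tolerance for SI
  recovery is 10 % of the true fold change.
- Axial inter-allele distance components are quantized to whole z-planes,
  as in single-plane scoring practice; sub-resolution separations are
  reported as 0 (paired), never estimated.
- Sister sub-foci below the lateral resolution limit (or stacked axially
  within one z-step) merge into their parent punctum, slightly inflating
  single-focus fractions in split-bearing scenes.
- The contamination confound is geometric only (surface shell); it does not
  model intensity differences between germline and somatic dots.
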