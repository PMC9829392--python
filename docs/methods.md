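# Methods

`padlockrca` implements the computational half of a padlock-probe /
rolling-circle-amplification (RCA) co-detection assay for miRNA and mRNA
in plant tissue: the design and validation of the oligo set, planning of
multiplexed imaging panels, and per-cell quantification of the RCA dot
signals, tested end to end against a synthetic scene generator with known
ground truth.

## Probe architecture

For a mature miRNA of length L (warn outside 20–21 nt), the detection
probe is a DNA oligo of L + 30 bases: the 5' region of length L is the
perfect antiparallel complement of the miRNA, with locked-nucleic-acid
(LNA) bases at positions 2, 4, 6, 8 and 10 from the 5' end, and the 3'
30 bases are a linker generated to be unique against the target
transcriptome. "Match" is implemented as complementarity throughout: a
probe hybridizes its target, it does not copy it. This convention is also
what maps a target mismatch at positions 11–19 onto the probe's 5' LNA
region (target position p pairs probe position L + 1 − p), where a single
mismatch abolishes ligation-competent binding.

The padlock probe is an 80-base 5'-phosphorylated oligo laid out as
15-base 5' arm + 20-base detection site + 30-base backbone + 15-base
3' arm. Given a 30-base template (the probe linker, or a cDNA window for
the mRNA assay), the two arms are chosen so that reading the circularized
padlock across the ligation junction (3' arm then 5' arm) gives the
reverse complement of the template; the nick falls exactly between
template positions 15 and 16 with zero gap. The segment order between the
arms (detection site before backbone) and the midpoint nick are
conventions — the chemistry constrains only the segment lengths and the
arm complementarities — and the validator enforces self-consistency, so
either convention would validate.

The detection oligo equals the detection site in circle sense. RCA copies
the circle into a tandem-repeat single strand that is the complement of
the circle, so a circle-sense 20-mer is complementary to every repeat of
the product. The five-step validator checks, in order: (I) probe–miRNA
complementarity, (II) full contiguous arm annealing on the linker,
(III) a ligatable zero-gap nick (perfect junction-flanking base pairs),
(IV) the simulated RCA product is the tandem reverse complement of the
circle, and (V) the detection oligo occurs in circle sense (rotation-safe
search in the doubled repeat unit). Every possible single-base
substitution in linker, arms, or detection oligo trips at least one step
(verified exhaustively, 240 mutants).

## Linker/backbone generation and uniqueness screening

Random 20/30-mers are drawn constructively: a base composition is sampled
uniformly from all compositions with GC fraction in [0.50, 0.60] and each
base count within length/4 ± length/20 (6–9 of each base for a 30-mer),
then shuffled; candidates with homopolymer runs > 3, self-complementary
stems > 3 bases (minimum loop 3), or any canonical k-mer shared with the
transcriptome index are rejected and redrawn. All thresholds live in
`DesignConstraints`. Failure after `max_attempts` raises with
per-constraint failure counts.

Uniqueness is a canonical k-mer set over the transcriptome with k = 15 by
default — the padlock arm length, since an off-target needs a full-arm
perfect match to seed ligation. Canonicalization (lexicographic min of a
k-mer and its reverse complement) collapses strands, the conservative
choice. The hit threshold defaults to 0 and is configurable; no
alignment-based search is attempted.

## Thermodynamics

Duplex Tm is a unified nearest-neighbor computation (SantaLucia-type
parameter set, entropic monovalent-salt correction) at 0.75 M Na+ (the
NaCl of 5× SSC) and 0.1 µM strands. LNA bases add a configurable
+2.0 °C each — a first-order treatment chosen over LNA-specific
nearest-neighbor tables for transparency; the increment is a
`ThermoParams` field and can be recalibrated or zeroed. The downstream
contract is deliberately simple and exact: the recommended hybridization
temperature is always Tm − 10 °C. Hairpin screening reports the longest
Watson-Crick stem foldable with a loop ≥ 3 nt (O(n²) dynamic program,
oracle-tested against exhaustive search); it is a screen, not a
free-energy folding.

## Mismatch-signal predictor

`predict_mismatch_signal` encodes the calibrated discrimination profile
of the probe on a 20-nt target: position 0 (no mismatch) is the
reference (score 1.0); positions 2–10 score 0.9 down to 0.1 linearly
(classes HIGH ≥ 0.7 > MODERATE ≥ 0.3 > LOW > 0); positions 11–19 —
the probe's LNA region — give no signal (score 0); terminal positions 1
and 20 are reported UNTESTED rather than extrapolated. The scores are an
ordinal calibration: only their ordering and the zero region are asserted
anywhere.

## mRNA assay

The mRNA design places a 25-nt LNA primer (same LNA pattern) as close to
the transcript 3' end as its GC bound (0.30–0.70) allows, then scans
5'-ward — beyond a 10-nt spacer — for the 3'-most 30-base window with GC
in [0.40, 0.60] and zero canonical k-mer hits in the leave-one-out index
(transcriptome minus the target transcript; the caller supplies this
index, the CLI builds it). The padlock is built against the cDNA sense of
the window, so its arms read across the junction as the transcript
substring exactly. Reverse-transcription reachability is enforced as
window-end < primer-start.

## Panel planning

Capacity is fluorophores × cycles (default 4 × 5 = 20). Assignment is a
greedy cycle-major fill in stable input order; miRNA/mRNA pairs that must
be co-imaged are placed first, each into the earliest cycle with two free
slots, and an unplaceable pair raises rather than being silently split.
Fluorophore labels are opaque; no spectral or signal-degradation model.

## Synthetic scenes

`simulate_section` emulates a leaf cross-section on a 16-bit monochrome
camera: cells are a Lloyd-relaxed (2 iterations) Voronoi tessellation of
uniform random centers; walls are the dilated label boundaries, rendered
bright only in the wall (autofluorescence) channel; per cell and signal
channel the dot count is Poisson(λ) and dot centers are uniform over the
cell interior kept 4 px clear of the wall (RCPs are cytoplasmic); dots
are 2-D Gaussians (σ 1.2 px, peak 8000 counts over a 200-count
background); Poisson shot noise then Gaussian read noise (σ 30) are
applied last. Defaults describe the high signal-to-noise regime the assay
produces; the two-group preset renders a "wild-type-like" scene (channel
1 λ = 2, channel 2 λ = 10) and an "overexpressor-like" scene with the
rates swapped, giving opposite per-channel orderings. λ values are
scenario parameters, not measurements.

What the simulator deliberately omits: realistic point-spread functions
(dots are isotropic Gaussians), tissue autofluorescence structure inside
cells, uneven illumination, cell-size/shape families beyond Voronoi
polygons, z-structure, and chromatic registration error. Passing the
recovery tests therefore shows the pipeline is correct on well-formed
bright-dot images, not that it is robust to every real-tissue artifact.

## Quantification pipeline

Cell segmentation (wall channel): Gaussian smooth (σ 1.0) → Otsu
threshold → morphological closing (radius 2) → wall mask; cells are
4-connected components of the non-wall region with border-touching and
< 100 px components removed, relabeled canonically by centroid row-major
order so output is bit-identical across runs. A wall-free image yields an
empty mask with a warning.

Spot calling is per-object ellipse-fit adaptive thresholding: candidate
objects are connected components above a robust floor (median + 5 scaled
MADs of the image); each object's own intensity levels (capped at 64
quantiles) are swept descending, and every component lineage — tracked by
its brightest pixel, which is stable until lineages merge — is scored at
each level where its area is within [4, 400] px by the ellipse-fit score:
the Jaccard overlap between the component and the equal-area ellipse
sharing its centroid, orientation and second moments (single pixel 1.0 by
convention; exactly collinear components 0.0, as no 2-D ellipse exists).
Second moments include the 1/12 per-pixel variance of the unit pixel. The
lineage is emitted at its best-scoring threshold if that score reaches
0.7, ties breaking toward the lower threshold (the larger spot);
overlapping accepted components are resolved by keeping the higher score.
None of these defaults comes from the original study (its pipeline
parameters are not published); all are configurable and logged.

Dots are assigned to cells by centroid containment: a centroid on
wall/background gets cell id 0 and is excluded from per-cell counts but
reported, so per-cell counts plus unassigned always equal the number of
calls. Group comparison of per-cell counts is a Welch unequal-variance
t-test by default, or a permutation test on the mean difference that
enumerates all label assignments exhaustively when there are ≤ 50,000 of
them and otherwise uses seeded Monte Carlo with the add-one estimator
(so a group compared against itself gives p = 1 exactly under
enumeration).

Scoring against simulator truth matches detections to true dots by
optimal assignment gated at 2 px and maps segmented to true cells by
majority overlap. At the 50-cell, λ = 8 high-SNR preset the pipeline
reaches recall 0.95, precision 1.0, and 97% of cells within ±1 of the
true count (seed-fixed values the acceptance test recomputes); residual
misses are genuinely merged dot pairs. Test scenes use 384–512 px images
with 25–50 cells, sizes at which every statistic asserted is already
stable.

## Numerical and degenerate-input choices

Probabilities and scores are plain floats; all randomness flows through
`numpy.random.default_rng` seeds, and every design, scene, and table is
byte-reproducible from its seed. Degenerate cases are defined, not
special-cased downstream: empty FASTA → empty list; transcripts shorter
than k are skipped with a warning; a uniform image → zero cells/spots;
zero-variance group comparison → t = 0, p = 1. Coordinates in all CSV
outputs are 0-based pixel centers (x = column, y = row), stated in each
file header; all sequence coordinates in reports are 1-based inclusive.

## Known limitations

No alignment-based off-target search; no mismatch ΔΔG thermodynamics (the
mismatch predictor is ordinal, calibrated to one probe family); no
LNA-specific nearest-neighbor parameters; the detection-oligo/fluorophore
assignment carries no spectral cross-talk model; the quantifier processes
channels independently and does not register sequential imaging cycles;
and the cited per-object thresholding family admits variants (area-ratio
ellipse scores, different sweep granularities) — the variant implemented
here is fixed, documented above, and oracle-tested.
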