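# Methods

This note documents the models, parameter choices and numerical conventions
behind `minidomain`, and what the synthetic experiments do and do not show
about real data.

## Coordinates and fragment classes

All intervals are 0-based half-open in memory and BED-style on disk.  A
fragment's midpoint is `start + length // 2` (integer; even lengths round
down).  The sub-nucleosomal class is `length < 120` strictly — 120 bp sits
safely below the ~147 bp octamer footprint while keeping partially unwrapped
nucleosome footprints.  The "all fragments" view deliberately retains the
short minority: at genome scale it is a good approximation of mark-bearing
nucleosome coverage because short fragments are a few percent of a library.
A `nucleosomal_only` view (`length >= threshold`) exists for analyses where
that approximation breaks down (see *Quantifying knockdown effects*).

## Synthetic libraries

The generator emulates the release geometry of antibody-tethered MNase:

- **Nucleosomal fragments**: lengths from a truncated normal,
  mean 185, sd 25, clipped to [147, 250] bp (sampled by inverse CDF, so
  libraries are bit-reproducible from the seed).  Midpoints are uniform
  within their source interval.
- **Element fragments**: truncated normal lengths, mean 90, sd 20, clipped
  to [50, 130] bp; midpoints uniform within the element footprint.  Note the
  upper tail (120–130 bp) intentionally exceeds the 120 bp analysis cutoff:
  the footprint class and the analysis threshold do not coincide exactly, as
  in the assay.
- **Phased nucleosomes**: each element optionally carries two nucleosomal
  hotspots at center ± 120 bp (±30 bp jitter), expected count half the
  element rate each.  They scale with the *domain* effect factor, not the
  element factor — they are mark-carrying nucleosomes released through the
  antibody, not TF footprints.
- **Counts** are Poisson around configured per-kb (domains, background) or
  per-library (elements) rates.  Background nucleosomal fragments are laid
  down outside planted domains only (a domain's rate replaces, not adds to,
  background); background short fragments are genome-wide.
- **Condition effects** are multiplicative on rates, so percent-change
  readouts equal the planted factors directly.
- **Determinism**: each (condition, replicate, feature) tuple draws from its
  own child stream derived from the global seed via CRC-keyed SeedSequences,
  so any subset of libraries regenerates byte-identically in any order.

### The fixture

`dhd_fixture()` plants, on one 5.4 Mb chromosome:

| feature | interval / rate | rationale |
|---|---|---|
| mini-domain | 5,312,015–5,317,465 (5450 bp), 300 frags/kb | width and 3′ end as published; 5′ end derived as end − 5450 because the printed 5′ coordinate is internally inconsistent (flagged in the manifest); the high rate encodes its standout density in the size-vs-density scatter |
| control domain | 5,100,000–5,140,000 (40 kb), 60 frags/kb | a typical broad domain, 3× background, with border *and* internal elements for classification contrast |
| border elements | 92 bp and 148 bp footprints at the published spans (5,312,120–5,312,212 and 5,317,300–5,317,448), 120 expected short fragments each | the mini-domain's two borders, no internal elements |
| background | 20 nucleosomal + 0.5 short fragments/kb | keeps short fragments a small minority (~3 %) and domains a small library fraction, so per-million normalization stays nearly neutral under knockdowns |
| replicates | 3 per condition | biological triplicates |

Conditions encode the reported effect regimes: global domain scales 0.65,
0.80 and 0.95 (−35 %/−20 %/−5 %), element scale 0.37 (−63 %) for the three
broadly acting knockdowns; one condition spares domains globally but halves
only the mini-domain border elements; one raises the mini-domain alone by
1.30 while leaving elements intact.  Rates were fixed once from an a-priori
error budget (Poisson noise of pooled triplicate counts against the ±5-point
recovery band) and define the study conditions for every test.

**What the generator does not model**: sequence content and mappability,
fragment-length/position coupling, chromatin accessibility gradients,
pericentric signal, cell-type mixtures, replicate-specific batch effects.
Passing recovery tests therefore demonstrate correctness of the analysis
under the stated release model, not robustness to artifacts of real
libraries.

## Coverage

Bin value = (fragment bases overlapping the bin) / bin_size, full paired-end
extension, so `sum(values) * bin_size` equals total fragment bases exactly
(the conservation invariant).  The last, possibly partial bin also divides
by the nominal bin size.  Normalization modes: raw, or per-million
fragments; pipeline default is downsampling all samples to common depth
first.

## Peak calling

Short-fragment midpoints are pooled in 10 bp bins.  Expected count per bin:
λ = max(genome-wide mean, centered 5 kb mean, centered 10 kb mean), windows
truncated at chromosome ends — the dynamic local-background idea of
conventional Poisson peak callers, made explicit and oracle-checkable.  A
bin is significant when the upper-tail Poisson probability of its observed
count is below 10⁻⁴ (raw p-value, no multiple-testing correction, matching
the procedure this reimplements).  No shift model is estimated (paired-end
midpoints are exact) and duplicates are retained.  Significant bins merge
across gaps ≤ 30 bp and peaks narrower than 50 bp are dropped; both
constants are exposed — they are chosen so a tandem footprint a few bp apart
stays one peak while single noisy bins (10 bp) can never pass the width
floor.  Summit = center of the maximum-pileup bin, leftmost on ties.  Score
= −log₁₀ of the best bin p-value.

Reproducible peaks are replicate 1's peaks that overlap (≥ 1 bp) a peak in
every other replicate; replicate 1's coordinates are reported.

## Domain segmentation

On a coarsely binned track (default 500 bp; must be ≤ 1 kb): enriched ⇔
value ≥ 2 × median of nonzero bins; runs merge across gaps ≤ 2 kb; domains
narrower than 3 kb (the bottom of the observed size range) are discarded.
The nonzero-bin median is robust both to the silent majority of the genome
and to the heavy right tail from pericentric-like signal; the mean is not.
Bin size matters: at 25 bp, Poisson noise puts several percent of background
bins above twice the median and the 2 kb gap rule chains them into spurious
megadomains; at 500 bp the noise exceedance rate is ~10⁻⁴, isolated
single-bin exceedances fall to the width floor, and boundary resolution is
one bin.  Domain density = (sum of bin values × bin size) / width.

Very dense domains blur one extra bin outward because fragment extension
spills ~half a fragment length past the true edge; consumers of segmented
borders must treat them as accurate to ±1 bin.  For that reason the pipeline
classifies peak summits with a border tolerance of 500 bp (the base slack —
"at the border" is not quantified in the source procedure) **plus one
segmentation bin**.  `classify_peaks` itself defaults to the base 500 bp for
use with exactly known borders.

## Architecture

Flank ratio: log₂((Σ 3′ + 1) / (Σ 5′ + 1)) of per-base track values over
(summit, summit + 1 kb] and [summit − 1 kb, summit); the pseudocount keeps
sparse tracks finite and makes the empty case exactly 0.  5′/3′ refer to
genome-coordinate orientation, not transcript strand.  Classification labels
are mutually exclusive and exhaustive; the lower edge wins when a summit is
within slack of both edges of a very narrow domain.  The V-plot counts each
fragment once, at (midpoint − nearest summit, length), within ±1 kb and
lengths ≤ 300 bp.

## Quantifying knockdown effects

Region counts are midpoint-in-region (additive across adjacent regions, and
invariant under fragment order), per-million normalized, with percent change
= 100 × (KD − control)/control against the designated control sample.

Domain-level contrasts in the analysis scripts and recovery tests are
computed on the **nucleosomal fragment class**.  Domain signal means
mark-carrying nucleosome coverage; all-fragment counting approximates it
well at genome scale, but inside a 5 kb fixture domain the element-derived
fragments are ~13 % of counts and carry their own, much larger planted
effect, which would contaminate the contrast.  Element-level contrasts use
the short-fragment class within element footprints.

Meta-domain profiles rescale each domain body to 100 bins by linear
interpolation of per-base coverage and keep ±3 kb flanks at native 100 bp
bins; domains narrower than 100 bp are skipped with a warning.

## Cut&Run-qPCR

Fold enrichment = 2^(Ct_MNase(locus) − Ct_CutRun(locus)) /
2^(Ct_MNase(ref) − Ct_CutRun(ref)), technical duplicates averaged on the Ct
scale.  The double normalization cancels locus-specific input abundance
(via the whole-MNase digestion without antibody) and assay-wide efficiency
offsets (via the mark-depleted reference locus, which scores exactly 1).
The quantity is invariant under adding any constant to all Ct values.
One-way ANOVA across conditions is deliberately left to standard statistics
packages.

## Motif scanning

Exact IUPAC consensus matching on both strands; minus-strand hits are
located by matching the reverse-complemented motif on the forward sequence
and reported at forward coordinates.  Coincident strand-symmetric matches of
palindromic motifs are counted separately — for a palindromic tandem such as
`TATCGATATCGATA` this is the only convention that yields four matches, whose
union span is the 14 bp functional element.  No PWM scoring: the hits being
reproduced are perfect consensus matches, so p-value-scored scanning would
add a model without adding information.

## Problem sizes

Tests and analysis scripts run the fixture at full depth (~115 k fragments
per library, 5.4 Mb genome) with 20-seed repetition for the stochastic
recovery claims and 1000-seed repetition for the Poisson concentration
bound on a 20 kb toy spec; oracle-equivalence checks run on ≤ 100 kb genomes
and 10 kb sequences where exhaustive scans are cheap.  These sizes were
chosen so the whole suite completes in a couple of minutes while keeping
every statistical claim at the stated confidence.

## Known limitations

- Segmentation is single-track thresholding; no HMM, no input correction,
  no replicate-aware joint segmentation (a reproducibility intersection of
  per-replicate domain calls stands in for it).
- The local-λ windows (5/10 kb) follow the convention of the tool whose
  contract is reimplemented; they are configurable but not estimated from
  the data.
- Border classification is distance-based only; it does not use flank-ratio
  evidence, though both are reported side by side.
- Percent-change readouts inherit a small compression bias from per-million
  normalization when a condition shifts a non-negligible library fraction
  (≲ 2 points under the fixture's conditions; quantified in the error
  budget, not corrected).
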