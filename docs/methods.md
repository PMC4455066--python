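# Methods

## Coordinate model

All coordinates are 0-based half-open internally; GFF3 input (1-based
closed) is converted at the boundary and written back losslessly. TSS and
TTS are strand-relative: for a reverse-strand gene the TSS is the span's
last base. Every "upstream"/"downstream" and every binned frame in the
package is expressed in the gene's (or intron's) own 5'→3' direction, so
forward and reverse features are treated symmetrically; the test suite
checks this with coordinate-mirror invariants.

bedGraph pairs (one file per strand) are expanded into dense per-base
arrays; overlapping intervals are rejected rather than summed, because a
coverage track is expected to partition its covered positions and silent
summation would hide malformed input.

## CUT classes and gene selection

CUT classes are defined purely by position relative to annotated genes:
PROMPT = `[TSS − w, TSS)` on the opposite strand, AS = the gene body on the
opposite strand, 3'IGT = `[TTS, TTS + w)` on the gene's strand, clipped at
chromosome ends. The window `w` defaults to 500 bp: the vicinity of the TSS
is not a sharply defined quantity, and 500 bp keeps the whole window
intergenic for every gene passing the 600-bp gap filter. It is a parameter,
not a constant.

Composite-profile gene selection requires strand-relative intergenic gaps of
≥ 600 bp on the 3' side and ≥ 100 bp on the 5' side for the sense analysis,
and the swap of the two for the AS analysis; comparisons are inclusive
("at least"). Gaps are measured to the nearest gene boundary on *either*
strand by default, since any neighbour — sense or antisense — contaminates a
flank window; a `same_strand_only` option implements the laxer convention,
because which convention the original gene counts used is not derivable
from the published numbers without the original annotation.

## Composite (metagene) profiles

Each selected gene contributes one row: 10 5'-flank positions, 15 equal
body bins, 10 3'-flank positions (35 columns). Probe centers are assigned
to real-valued bin boundaries; a center exactly on a boundary joins the
downstream (3') bin — any consistent rule gives the same column averages,
and the brute-force oracle test pins this one. Flank positions take the
`flank_probes` nearest probes on the profile's orientation strand beyond
the TSS/TTS (with per-base input, `probe_pitch_bp`-wide windows instead:
10 × 80 bp = 800 bp, the span of ten same-strand probes of a 40-bp
alternating design). Sense rows use the gene's strand, AS rows the
opposite. The analysis plots the 5' flank for AS profiles and the 3' flank
for sense profiles; both are computed so the full 35-column table is always
available.

Column averaging is the arithmetic mean of log₂ ratios over rows with data
— the log₂ of the geometric mean of the ratios. Missing values are never
imputed; a bin without probes simply contributes nothing to its column.

Expression profiles are then anchored: the offset is the grand mean of the
sense profile's body-bin columns (flanks excluded) and is subtracted from
every column of both the sense and AS profiles. The rationale is that a
mutant accumulating antisense and intergenic RNA inflates the global
scaling of a two-channel comparison, shifting apparent sense levels; the
correction is a single global constant, so it must be applied to both
strands. Subtracting the profile-level grand mean makes the post-condition
(sense body mean exactly 0) hold identically. RIP (IP/input) profiles
receive no anchoring — an IP/input ratio has a meaningful zero — and keep
negative values, which report under-enrichment.

## Intron surveillance

**Normalisation.** Each coverage dataset is scaled so that the median over
intronless ORFs of each gene's median per-base sense coverage equals 100.
The median-of-medians is insensitive to expression outliers, and scaling by
`100 / median` makes the operation exact and idempotent.

**Filtering.** Introns are kept when 20 ≤ length ≤ 400 bp (inclusive), the
parent is an ORF, and the expression proxy — median WT sense coverage over
the two 20-bp flanking-exon windows — is inside the percentile band.
Percentile exclusion is rank-based: the `floor(p/100 × N)` lowest and
highest proxies are dropped, ties broken by intron id. Only the resulting
counts, not the convention, are fixed by the published analysis, so the
convention is documented and deterministic.

**Ranking.** Score = (mean mutant intronic coverage − mean WT intronic
coverage) / (mean *mutant* flank-exon coverage); the denominator is the
mutant strain's expression because that is the strain in which the intronic
excess is measured. The upper quartile is `ceil(N/4)` of the ranked introns
— the only rounding consistent with 3,935 ranked → 984 selected. Introns
with zero mutant flank coverage cannot be scored and are dropped with a
warning.

**Meta-intron profile.** 40 equal bins over the intron (fractional-width
when the intron is shorter than 40 bp, length-weighted means) plus one
column per 20-bp flanking-exon window, sense strand only, strand-relative
order. Each intron contributes log₂(mean coverage) per column; zero means
are replaced by a pseudocount (default 1.0 on the normalised scale, i.e. 1 %
of the intronless median) before the log, and only then — so uniform
coverage of 100 yields exactly log₂ 100 in every column.

**Junction quantification.** Spliced (S) reads are gapped reads whose gap
matches the intron span *exactly*; a gapped read overlapping but not
matching the intron is counted separately as mis-spliced rather than being
silently absorbed into either class. Unspliced (US) reads are contiguous
reads overlapping both the intron and an adjacent flank window; contiguous
reads fully inside the intron are informative but boundary-ambiguous and
are reported as a third class. Every intron-informative read lands in
exactly one class (a conservation property the tests enforce). US/S ratios
are normalised to the wild-type ratio when WT reads are supplied, mirroring
how gel-based US/S quantification is reported; the normalisation cancels
the geometric constants (read length, transcript length) that relate
retention probability to read counts, which is why the normalised ratio
estimates the retention odds ratio.

**Diagnostic.** Three geometric-mean mutant/WT fold-changes — selected
intron spans, their flank exons, intronless gene bodies — separate two
mechanisms: stabilised unspliced pre-mRNAs raise intronic and exonic
coverage together while intronless genes are untouched; a pure splicing
defect raises only the intronic signal. Verdicts are assigned with a log₂
tolerance τ (default 0.5): "no change" when all three folds are within τ of
1; "splicing defect" when the intron fold exceeds the exon fold by more
than τ; "stabilization" when introns are elevated, exon and intron folds
agree within τ and intronless genes are flat; "ambiguous" otherwise.

## Interactome

A protein identification is non-significant when its iBAQ is below 50,000
or it has zero spectral counts (both bounds as stated: 50,000 itself
passes). Significant proteins are expressed as 100 × iBAQ / bait iBAQ;
replicates sharing a purification id are averaged on the percentage scale
before tiering (black ≥ 2.5 %, grey ≥ 0.5 %, white below; lower bounds
inclusive). Complex-level abundance is the arithmetic mean over subunits
with absent subunits contributing 0.

Submodules are inferred by exact equality of presence vectors
(presence = tier ≠ white, so a significant protein under 0.5 % of the bait
counts as absent) across purifications. Exact matching is the strictest
machine-checkable version of grouping proteins that appear and disappear
together across deletion backgrounds; a Hamming-distance tolerance
(`max_hamming`) is available but off by default, since on noisy data it can
chain distinct modules together.

## Synthetic data

The generators produce data with the statistical structure the analyses
assume, not sequence-level realism:

* **Toy genome** — non-overlapping genes (1–3 kb) with intergenic gaps of
  1.2–2 kb, so that every gene passes both selection criteria and 500-bp
  CUT windows stay intergenic; adjacent genes' CUT windows never collide on
  a strand by construction. Intron lengths are log-normal with median
  ~60 bp clipped to [20, 400] — the short-intron distribution
  characteristic of fission yeast, and the reason most intron-overlapping
  reads span a boundary rather than sitting inside the intron.
* **Signals** — per-gene baselines are log-normal (median 100, log-sd 1),
  giving the percentile filters spread to act on; CUT intervals get a WT
  baseline of 5 % of the mean gene baseline (detectable but low); intronic
  positions get baseline × retention; the mutant is WT × class fold-change
  with i.i.d. per-base log-normal noise (log₂-sd `noise_sd`, geometric mean
  1, so composite plateaus are unbiased estimates of log₂ fold-changes).
  Default retentions are 5 % (WT) and 15 % (mutant): a 3× increase, the
  magnitude reported for surveillance mutants.
* **Probes** — strand-alternating 40-bp windows; a probe's value is
  log₂(mutant/WT) of its window's mean on its strand, with a pseudocount
  only when a channel's mean is zero.
* **Reads** — each read picks a gene, draws per-intron Bernoulli retention,
  and is placed uniformly on the resulting transcript; reads crossing a
  spliced junction become gapped reads whose gap equals the intron exactly.
  Reads that would span two junctions are resampled (they cannot be
  represented as a single-gap read and are vanishingly rare at 50-bp reads).
* **Purifications** — bait fixed at iBAQ 10⁸, members at bait × baseline
  fraction × log-normal noise, deleted submodules at 0, ~20 contaminants
  under the 50,000 floor.

What the generators deliberately omit: alignment artefacts, GC/fragment
bias, probe melting-temperature effects, dye bias, cross-hybridisation and
overlapping transcription units. Passing parameter-recovery tests therefore
demonstrates that the analysis machinery is correct and unbiased under its
own model assumptions — not that it is robust to every artefact of real
arrays or libraries.

All generators are pure functions of their inputs and a seed; sub-generators
derive independent streams from the seed so adding one does not perturb the
others.

## Problem sizes and numerical choices

Tests and the acceptance script use 200-gene genomes (≈ 0.7 Mb), 40-bp
probes, 5,000–10,000 reads and 10-protein complexes — sizes at which every
stochastic check (binomial agreement within 3 standard errors, plateau
recovery within ±0.3 log₂) has comfortable power while the full suite runs
in seconds. Ties anywhere (bin boundaries, ranking scores, percentile
ranks) are broken deterministically, so identical inputs and seeds always
produce identical outputs, which the CLI determinism test verifies
byte-for-byte.

## Known limitations

* Annotation-relative CUT classes cannot discover unannotated transcription
  units; segmentation-based CUT calling is out of scope.
* The published gene and intron counts (993/1,569 selected genes, 3,935
  filtered introns) depend on the original annotation releases and array
  layout and are not reproducible from the rules alone; only the
  conventions (inclusive thresholds, ⌈N/4⌉ = 984 of 3,935) are.
* Junction quantification requires reads already expressed as genomic
  segments; alignment itself (and hence alignment error) is outside the
  package.
* The submodule inference assumes presence/absence is binary per
  purification; partial dissociation shows up as "ambiguous" extra groups
  rather than fractional membership.
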