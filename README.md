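# nexsurv

Analysis toolkit for nuclear-exosome RNA surveillance in fission yeast.

The nuclear exosome degrades cryptic unstable transcripts (CUTs) — short-lived
non-coding RNAs from promoters, antisense strands and 3' intergenic regions —
and, through its targeting complexes (MTREC/NURS and the Mtl1–Ctr1–Nrl1
module), also removes unspliced pre-mRNAs. Characterising these pathways
genome-wide relies on a small set of recurring computational analyses, which
this package implements as a tested, reusable library plus a `nexsurv`
command-line pipeline:

* **CUT classification** — annotation-relative intervals for the three CUT
  classes: PROMPTs (window *w* upstream of the TSS on the antisense strand),
  antisense (AS) transcripts (gene body, opposite strand) and 3'IGTs (window
  *w* downstream of the TTS, sense strand); gene selection by strand-relative
  intergenic gaps (≥ 600 bp on one side, ≥ 100 bp on the other) so flank
  windows measure intergenic signal.
* **Composite (metagene) profiles** — each selected gene is mapped to 10
  flank positions + 15 equal body bins + 10 flank positions (800 bp flanks at
  80-bp same-strand probe pitch); per column the log₂ ratios (mutant/WT or
  IP/input) are averaged arithmetically, i.e. as the geometric mean of the
  ratios. Expression profiles anchor the mean sense gene-body level at 0 on
  the log₂ scale; RIP (IP/input) profiles are left unnormalised with negative
  (under-enrichment) values retained.
* **Intron surveillance** — coverage tracks are scaled so the median
  intronless-gene coverage is 100; introns are filtered (ORF-only, 20–400 bp,
  10/10 % expression-percentile exclusion on the 20-bp flanking-exon proxy),
  scored as (mean mutant − mean WT intronic coverage) / (mean mutant
  flank-exon coverage), and the upper quartile (⌈N/4⌉, e.g. 3,935 → 984) is
  profiled in a 40-bin meta-intron frame. Junction-level quantification
  counts spliced reads (gap exactly matching the intron) against unspliced
  reads (contiguous, spanning an exon–intron boundary) and reports US/S
  ratios normalised to wild type. A diagnostic separates pre-mRNA
  *stabilization* (introns and exons rise together, intronless genes flat)
  from a pure *splicing defect* (only introns rise).
* **Interactome mapping** — iBAQ tables are filtered (non-significant when
  iBAQ < 50,000 or zero spectral counts), normalised to percent of the bait,
  tiered (black ≥ 2.5 %, grey ≥ 0.5 %, white below), and proteins are grouped
  into submodules by their presence pattern across deletion-background
  purifications.
* **Synthetic data** — generators for toy genomes, strand-specific WT/mutant
  coverage with configurable class fold-changes and intron-retention
  fractions, 40-bp alternating-strand tiling probes, gapped/contiguous reads
  and purification tables, so the full pipeline runs without any download.

## Worked example

Simulate a 200-gene genome in which the mutant accumulates PROMPTs 8-fold,
AS transcripts 4-fold and 3'IGTs 2-fold, and triples intron retention
(5 % → 15 %), then recover those effect sizes:

```python
from nexsurv import synthetic_data as sd
from nexsurv.metagene_profiles import expression_composite
from nexsurv.intron_surveillance import (normalize_coverage, filter_introns,
    rank_and_select_introns, intron_composite, stabilization_diagnostic)

ann = sd.make_toy_genome(200, seed=11)
effect = sd.EffectProfile(
    fold_changes={"PROMPT": 8.0, "AS": 4.0, "IGT3": 2.0},
    intron_retention_wt=0.05, intron_retention_mut=0.15,
    noise_sd=0.2, seed=11)
wt, mut = sd.simulate_signals(ann, effect)

_, ratios = sd.simulate_probe_ratios(ann, wt, mut)
res = expression_composite(ann, ratios)

flank = ["5'flank-%d" % k for k in range(2, 7)]
body = ["bin%d" % b for b in range(2, 15)]
print(f"genes selected (sense/AS): {len(res['genes_sense'])}/{len(res['genes_as'])}")
print(f"AS 5'-flank plateau: {res['antisense'][flank].mean():.2f} log2")
print(f"AS gene-body mean:   {res['antisense'][body].mean():.2f} log2")

wt_n, mut_n = normalize_coverage(wt, ann), normalize_coverage(mut, ann)
kept = filter_introns(ann, wt_n)
selected = rank_and_select_introns(kept, ann, wt_n, mut_n).selected_ids
pw = intron_composite(selected, ann, wt_n)
pm = intron_composite(selected, ann, mut_n)
bins = [c for c in pw.index if c.startswith("bin")]
print(f"introns filtered/selected: {len(kept)}/{len(selected)}")
print(f"meta-intron elevation: {float((pm - pw)[bins].mean()):.2f} log2")
report = stabilization_diagnostic(wt_n, mut_n, selected, ann)
print(f"diagnostic: {report.verdict} (intron x{report.intron_fold:.2f}, "
      f"exon x{report.exon_fold:.2f}, intronless x{report.intronless_fold:.2f})")
```

prints:

```
genes selected (sense/AS): 200/200
AS 5'-flank plateau: 2.96 log2
AS gene-body mean:   1.97 log2
introns filtered/selected: 141/36
meta-intron elevation: 1.61 log2
diagnostic: splicing defect (intron x3.06, exon x0.99, intronless x1.01)
```

The AS-profile 5'-flank plateau reads back log₂ 8 ≈ 3.0 (the PROMPT
fold-change), the AS body log₂ 4 = 2.0, and the meta-intron elevation
log₂ 3 ≈ 1.58 (the retention increase). Because only intronic coverage rose
while flanking exons and intronless genes stayed flat, the diagnostic calls
a splicing defect rather than whole-pre-mRNA stabilization.

The same pipeline runs from the shell on generated files:

```sh
nexsurv simulate --out run/ --seed 11
nexsurv profile  --annotation run/annotation.gff3 --probes run/probes.tsv --out run/
nexsurv introns  --annotation run/annotation.gff3 \
    --wt-fwd run/wt_fwd.bedgraph --wt-rev run/wt_rev.bedgraph \
    --mut-fwd run/mut_fwd.bedgraph --mut-rev run/mut_rev.bedgraph --out run/
nexsurv interactome --manifest run/purifications.tsv --out run/
```

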