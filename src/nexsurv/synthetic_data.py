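"""Synthetic genomes, signals, probes, reads and purification tables.

The generators emulate the statistical structure the downstream analyses
assume, so the whole pipeline is exercisable without any external dataset:

* a toy genome of non-overlapping genes separated by intergenic gaps wide
  enough for flank-based analyses, a configurable fraction carrying introns;
* strand-specific per-base coverage for a wild-type and a mutant strain, in
  which CUT classes (PROMPTs, antisense transcripts, 3'IGTs) accumulate by
  configurable fold-changes and introns are retained at configurable
  fractions;
* tiling probes alternating strands at fixed resolution, carrying
  log2(mutant/WT) ratios;
* reads that are gapped (spliced) or contiguous (retained) across introns;
* bait-normalised purification tables with submodule structure across
  deletion backgrounds.

Every generator is a pure function of its inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nexsurv.cut_classification import classify_cut_intervals
from nexsurv.genome_model import (
    FORWARD,
    REVERSE,
    STRANDS,
    Gene,
    GenomeAnnotation,
    ProbeSet,
    Read,
    ReadSet,
    StrandedSignal,
    make_intron,
)

CLASSES = ("mRNA", "meiotic_mRNA", "PROMPT", "AS", "IGT3")


@dataclass(frozen=True)
class EffectProfile:
    """Genotype effect on each transcript class, plus splicing behaviour.

    ``fold_changes`` maps each transcript class to its mutant/WT abundance
    ratio.  ``intron_retention_wt`` / ``intron_retention_mut`` are the
    probabilities that a transcript copy retains a given intron in the two
    strains; their ratio sets the intronic-coverage elevation the meta-intron
    profile should recover.  ``noise_sd`` is the standard deviation of the
    multiplicative log2 noise applied to the mutant signal.
    """

    fold_changes: dict[str, float] = field(
        default_factory=lambda: {"mRNA": 1.0, "meiotic_mRNA": 1.0,
                                 "PROMPT": 1.0, "AS": 1.0, "IGT3": 1.0})
    intron_retention_wt: float = 0.05
    intron_retention_mut: float = 0.15
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, fc in self.fold_changes.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown transcript class {cls!r}")
            if fc < 0:
                raise ValueError(f"fold-change for {cls} must be >= 0")
        for p in (self.intron_retention_wt, self.intron_retention_mut):
            if not 0.0 <= p <= 1.0:
                raise ValueError("retention fractions must lie in [0, 1]")

    def fold(self, cls: str) -> float:
        return self.fold_changes.get(cls, 1.0)


@dataclass(frozen=True)
class ComplexSpec:
    """Ground-truth composition of a protein complex for iBAQ emulation.

    ``submodules`` are disjoint named protein groups; the bait belongs to
    exactly one of them.  ``baseline_abundance`` gives each protein's
    expected iBAQ as a fraction of the bait.  Each named background deletes
    a set of submodules.  Contaminants are added below the significance
    floor so the filter has something to remove.
    """

    submodules: dict[str, tuple[str, ...]]
    bait: str
    baseline_abundance: dict[str, float]
    backgrounds: dict[str, tuple[str, ...]] = field(default_factory=dict)
    contaminant_count: int = 20
    contaminant_abundance_range: tuple[float, float] = (1_000.0, 40_000.0)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        bait_homes = 0
        for name, members in self.submodules.items():
            for m in members:
                if m in seen:
                    raise ValueError(f"protein {m} in more than one submodule")
                seen.add(m)
            if self.bait in members:
                bait_homes += 1
        if bait_homes != 1:
            raise ValueError("bait must belong to exactly one submodule")

    @property
    def proteins(self) -> list[str]:
        return [m for members in self.submodules.values() for m in members]


def default_complex_spec() -> ComplexSpec:
    """A four-submodule complex resembling the MTREC organisation: a
    Mtl1-Red1 core, a Red5-Pab2-Rmn1 module, a Ctr1-Nrl1 module and an
    Ars2-cap-binding module, with one deletion background per non-core
    module plus one removing two modules."""
    return ComplexSpec(
        submodules={
            "core": ("Mtl1", "Red1"),
            "red5_module": ("Red5", "Pab2", "Rmn1"),
            "ctr1_module": ("Ctr1", "Nrl1"),
            "ars2_module": ("Ars2", "Cbc1", "Cbc2"),
        },
        bait="Mtl1",
        baseline_abundance={
            "Mtl1": 1.0, "Red1": 0.8,
            "Red5": 0.12, "Pab2": 0.10, "Rmn1": 0.08,
            "Ctr1": 0.05, "Nrl1": 0.04,
            "Ars2": 0.015, "Cbc1": 0.012, "Cbc2": 0.010,
        },
        backgrounds={
            "red5_del": ("red5_module",),
            "ctr1_del": ("ctr1_module",),
            "ars2_del": ("ars2_module",),
            "red5_ctr1_del": ("red5_module", "ctr1_module"),
        },
    )


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

def make_toy_genome(n_genes: int,
                    seed: int = 0,
                    intron_rate: float = 0.5,
                    gene_length_range: tuple[int, int] = (1_000, 3_000),
                    gap_range: tuple[int, int] = (1_200, 2_000),
                    intron_length_range: tuple[int, int] = (20, 400),
                    meiotic_fraction: float = 0.05,
                    chrom: str = "chrI",
                    chrom_length: int | None = None,
                    exon_flank_bp: int = 20) -> GenomeAnnotation:
    """Lay out ``n_genes`` non-overlapping genes with random strands.

    Intergenic gaps are drawn from ``gap_range``; with the defaults every
    gene satisfies both the sense (600/100 bp) and antisense (100/600 bp)
    intergenic selection criteria, and 500-bp CUT windows stay intergenic.
    A fraction ``intron_rate`` of genes carries 1-3 introns.  Intron lengths
    follow the short-skewed distribution characteristic of fission yeast
    (log-normal, median ~60 bp) clipped to ``intron_length_range``.
    Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    genes: list[Gene] = []
    introns = []
    cursor = int(rng.integers(gap_range[0], gap_range[1] + 1))
    for k in range(n_genes):
        length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        gene = Gene(id=f"g{k:04d}", chrom=chrom, strand=strand,
                    start=cursor, end=cursor + length,
                    is_orf=True,
                    in_mmi1_regulon=bool(rng.random() < meiotic_fraction))
        genes.append(gene)
        if rng.random() < intron_rate:
            n_int = int(rng.integers(1, 4))
            # end margins and inter-intron exons keep flank windows exonic
            margin, spacer = 100, 60
            for attempt in range(20):
                lengths = np.clip(
                    np.round(rng.lognormal(np.log(60.0), 0.45, size=n_int)),
                    intron_length_range[0], intron_length_range[1]).astype(int)
                needed = margin * 2 + int(lengths.sum()) + spacer * (n_int - 1)
                if needed <= length:
                    break
                n_int = max(1, n_int - 1)
            else:
                n_int = 0
                lengths = np.array([], dtype=int)
            if n_int:
                slack = length - (margin * 2 + int(lengths.sum()) + spacer * (n_int - 1))
                cuts = np.sort(rng.integers(0, slack + 1, size=n_int))
                pos = gene.start + margin
                prev_cut = 0
                for j, ilen in enumerate(lengths):
                    pos += int(cuts[j] - prev_cut)
                    prev_cut = int(cuts[j])
                    introns.append(make_intron(f"{gene.id}.i{j + 1}", gene,
                                               pos, pos + int(ilen), exon_flank_bp))
                    pos += int(ilen) + spacer
        cursor += length + int(rng.integers(gap_range[0], gap_range[1] + 1))
    total = cursor
    if chrom_length is not None:
        if chrom_length < total:
            raise ValueError(
                f"chromosome length {chrom_length} too short for layout ({total} bp)")
        total = chrom_length
    return GenomeAnnotation(chromosomes={chrom: total}, genes=genes, introns=introns)


# ---------------------------------------------------------------------------
# stranded signals
# ---------------------------------------------------------------------------

def simulate_signals(annotation: GenomeAnnotation,
                     effect: EffectProfile,
                     w_bp: int = 500,
                     baseline_mean: float = 100.0,
                     baseline_log_sd: float = 1.0,
                     cut_baseline_frac: float = 0.05,
                     ) -> tuple[StrandedSignal, StrandedSignal]:
    """Paint WT and mutant strand-specific coverage over a toy genome.

    Each gene draws a log-normal baseline abundance (median ``baseline_mean``,
    log-sd ``baseline_log_sd``); exonic sense positions receive the baseline
    and intronic positions baseline x retention.  Each CUT interval (PROMPT /
    AS / 3'IGT geometry with window ``w_bp``) receives a low WT baseline of
    ``cut_baseline_frac`` x the mean gene baseline.  The mutant signal is the
    WT signal times the class fold-change, with i.i.d. per-base multiplicative
    noise of log2-sd ``noise_sd``.  Deterministic given ``effect.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(effect.seed, spawn_key=(1,)))
    wt = StrandedSignal.zeros(annotation, mode="coverage")
    mut = StrandedSignal.zeros(annotation, mode="coverage")
    baselines = {g.id: float(rng.lognormal(np.log(baseline_mean), baseline_log_sd))
                 for g in annotation.genes}
    introns_by_gene: dict[str, list] = {}
    for i in annotation.introns:
        introns_by_gene.setdefault(i.parent_gene, []).append(i)

    for g in annotation.genes:
        b = baselines[g.id]
        cls = "meiotic_mRNA" if g.in_mmi1_regulon else "mRNA"
        fold = effect.fold(cls)
        wt.values[g.chrom][g.strand][g.start:g.end] = b
        mut.values[g.chrom][g.strand][g.start:g.end] = b * fold
        for i in introns_by_gene.get(g.id, []):
            wt.values[g.chrom][g.strand][i.start:i.end] = b * effect.intron_retention_wt
            mut.values[g.chrom][g.strand][i.start:i.end] = (
                b * fold * effect.intron_retention_mut)

    cut_base = cut_baseline_frac * float(np.mean(list(baselines.values())))
    class_map = classify_cut_intervals(annotation, w_bp=w_bp)
    for cls in ("PROMPT", "AS", "IGT3"):
        fold = effect.fold(cls)
        for chrom, strand, (s, e) in class_map.intervals_of_class(cls):
            wt.values[chrom][strand][s:e] = cut_base
            mut.values[chrom][strand][s:e] = cut_base * fold

    if effect.noise_sd > 0:
        for chrom, per_strand in mut.values.items():
            for strand in STRANDS:
                arr = per_strand[strand]
                noise = np.exp2(rng.normal(0.0, effect.noise_sd, size=arr.size))
                per_strand[strand] = arr * noise
    return wt, mut


def simulate_probe_ratios(annotation: GenomeAnnotation,
                          wt: StrandedSignal,
                          mut: StrandedSignal,
                          probe_resolution: int = 40,
                          pseudocount: float = 1.0,
                          ) -> tuple[ProbeSet, StrandedSignal]:
    """Tile each chromosome with strand-alternating probes carrying
    log2(mutant/WT) of the mean per-base signal in each probe's window.

    Probe ``k`` covers ``[k*r, (k+1)*r)`` with its center at ``k*r + r//2``,
    on the forward strand for even ``k``.  Windows whose mean is zero use
    ``pseudocount`` in place of the zero before taking the ratio.
    """
    probes: dict[str, list[tuple[int, str]]] = {}
    values: dict[str, dict[str, list[float]]] = {}
    for chrom, length in annotation.chromosomes.items():
        plist: list[tuple[int, str]] = []
        vals = {FORWARD: [], REVERSE: []}
        for k in range(length // probe_resolution):
            s, e = k * probe_resolution, (k + 1) * probe_resolution
            strand = FORWARD if k % 2 == 0 else REVERSE
            w = float(wt.values[chrom][strand][s:e].mean())
            m = float(mut.values[chrom][strand][s:e].mean())
            w = w if w > 0 else pseudocount
            m = m if m > 0 else pseudocount
            plist.append((s + probe_resolution // 2, strand))
            vals[strand].append(np.log2(m / w))
        probes[chrom] = plist
        values[chrom] = vals
    pset = ProbeSet(probes=probes, resolution=probe_resolution)
    sig = StrandedSignal(
        values={c: {s: np.array(v, dtype=float) for s, v in d.items()}
                for c, d in values.items()},
        mode="log2_ratio", probes=pset)
    return pset, sig


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _transcript_blocks(gene: Gene, introns, retained: np.ndarray
                       ) -> list[tuple[int, int]]:
    """Genomic blocks of one transcript copy, excluding spliced introns."""
    blocks: list[tuple[int, int]] = []
    pos = gene.start
    for keep, i in zip(retained, introns):
        if not keep:
            if i.start > pos:
                blocks.append((pos, i.start))
            pos = i.end
    if gene.end > pos:
        blocks.append((pos, gene.end))
    return blocks


def simulate_reads(annotation: GenomeAnnotation,
                   effect: EffectProfile,
                   n_reads: int,
                   read_length: int = 50,
                   seed: int = 0,
                   retention: float | None = None) -> ReadSet:
    """Sample sense-strand reads from transcript copies of random genes.

    Each copy retains each of its gene's introns independently with
    probability ``retention`` (default: the profile's mutant retention).
    Reads from spliced copies that cross a junction become gapped reads whose
    gap equals the intron span exactly; reads from retained copies are
    contiguous.  Deterministic given ``seed``.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    p = effect.intron_retention_mut if retention is None else retention
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    introns_by_gene: dict[str, list] = {}
    for i in annotation.introns:
        introns_by_gene.setdefault(i.parent_gene, []).append(i)
    for gid in introns_by_gene:
        introns_by_gene[gid].sort(key=lambda i: i.start)

    # error only when no gene's mature transcript can accommodate a read
    longest_mature = max(
        g.length - sum(i.length for i in introns_by_gene.get(g.id, []))
        for g in annotation.genes)
    if read_length > longest_mature:
        raise ValueError(f"read_length {read_length} exceeds every transcript")

    reads: list[Read] = []
    genes = annotation.genes
    while len(reads) < n_reads:
        g = genes[int(rng.integers(len(genes)))]
        gi = introns_by_gene.get(g.id, [])
        retained = rng.random(len(gi)) < p
        blocks = _transcript_blocks(g, gi, retained)
        total = sum(e - s for s, e in blocks)
        if total < read_length:
            continue
        for _attempt in range(100):
            start = int(rng.integers(0, total - read_length + 1))
            segs: list[tuple[int, int]] = []
            remaining, offset = read_length, start
            for bs, be in blocks:
                blen = be - bs
                if offset >= blen:
                    offset -= blen
                    continue
                take = min(remaining, blen - offset)
                segs.append((bs + offset, bs + offset + take))
                remaining -= take
                offset = 0
                if remaining == 0:
                    break
            if len(segs) <= 2:
                # merge abutting segments produced by retained introns
                merged = [segs[0]]
                for s, e in segs[1:]:
                    if s == merged[-1][1]:
                        merged[-1] = (merged[-1][0], e)
                    else:
                        merged.append((s, e))
                reads.append(Read(chrom=g.chrom, strand=g.strand,
                                  segments=tuple(merged)))
                break
    return ReadSet(reads=reads)


# ---------------------------------------------------------------------------
# purification tables
# ---------------------------------------------------------------------------

def simulate_ibaq_table(spec: ComplexSpec,
                        background: str = "wild_type",
                        seed: int = 0,
                        bait_ibaq: float = 1e8,
                        noise_sd: float = 0.0) -> pd.DataFrame:
    """Emulate one purification: an iBAQ / spectral-count table.

    Proteins of submodules removed by ``background`` are absent (iBAQ 0,
    zero spectral counts); the rest receive
    ``bait_ibaq x baseline_abundance x lognormal noise``; the bait itself is
    noise-free so percent-of-bait is anchored at 100.  Contaminants are
    added below the significance floor.

    Returns a DataFrame with columns (protein, ibaq, spectral_counts) and
    ``attrs`` carrying the bait, background and purification id.
    """
    if background != "wild_type" and background not in spec.backgrounds:
        raise ValueError(f"unknown background {background!r}")
    removed: set[str] = set()
    for sub in spec.backgrounds.get(background, ()):
        removed.update(spec.submodules[sub])
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    rows = []
    for prot in spec.proteins:
        if prot in removed:
            rows.append((prot, 0.0, 0))
            continue
        if prot == spec.bait:
            ibaq = bait_ibaq
        else:
            ibaq = (bait_ibaq * spec.baseline_abundance.get(prot, 0.0)
                    * float(rng.lognormal(0.0, noise_sd * np.log(2))))
        sc = max(1, int(round(ibaq / 1e5)))
        rows.append((prot, ibaq, sc))
    lo, hi = spec.contaminant_abundance_range
    for k in range(spec.contaminant_count):
        ibaq = float(rng.uniform(lo, hi))
        sc = int(rng.integers(0, 3))
        rows.append((f"CONT{k:03d}", ibaq, sc))
    df = pd.DataFrame(rows, columns=["protein", "ibaq", "spectral_counts"])
    df.attrs["bait"] = spec.bait
    df.attrs["background"] = background
    df.attrs["purification"] = f"{spec.bait}_{background}"
    return df
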