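import numpy as np
import pytest

from nexsurv.genome_model import (
    FORWARD,
    REVERSE,
    Gene,
    GenomeAnnotation,
    StrandedSignal,
    make_intron,
)
from nexsurv import synthetic_data as sd


def build_annotation(genes, introns=(), chrom_len=100_000, chrom="chrI"):
    """Hand-rolled annotation: genes as (id, strand, start, end[, is_orf]),
    introns as (id, gene_id, start, end)."""
    gene_objs = []
    for spec in genes:
        gid, strand, start, end = spec[:4]
        is_orf = spec[4] if len(spec) > 4 else True
        gene_objs.append(Gene(id=gid, chrom=chrom, strand=strand,
                              start=start, end=end, is_orf=is_orf))
    by_id = {g.id: g for g in gene_objs}
    intron_objs = [make_intron(iid, by_id[gid], s, e) for iid, gid, s, e in introns]
    return GenomeAnnotation(chromosomes={chrom: chrom_len}, genes=gene_objs,
                            introns=intron_objs)


def constant_signal(annotation, value=0.0, mode="log2_ratio"):
    sig = StrandedSignal.zeros(annotation, mode="log2_ratio")
    for chrom in sig.values:
        for strand in sig.values[chrom]:
            sig.values[chrom][strand][:] = value
    return StrandedSignal(values=sig.values, mode=mode)


@pytest.fixture
def single_intron_annotation():
    """One forward gene with one 100-bp intron, plus an intronless gene."""
    return build_annotation(
        genes=[("gA", FORWARD, 1000, 3000), ("gB", REVERSE, 5000, 7000)],
        introns=[("gA.i1", "gA", 1800, 1900)],
        chrom_len=10_000)


@pytest.fixture(scope="session")
def recovery_instance():
    """The standard parameter-recovery setting: 200 genes, noise_sd 0.2,
    class fold-changes 8 (PROMPT) / 4 (AS) / 2 (3'IGT), WT/mutant intron
    retention 0.05 / 0.15."""
    ann = sd.make_toy_genome(200, seed=11, intron_rate=0.5)
    effect = sd.EffectProfile(
        fold_changes={"mRNA": 1.0, "meiotic_mRNA": 1.0,
                      "PROMPT": 8.0, "AS": 4.0, "IGT3": 2.0},
        intron_retention_wt=0.05, intron_retention_mut=0.15,
        noise_sd=0.2, seed=11)
    wt, mut = sd.simulate_signals(ann, effect)
    return ann, effect, wt, mut
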