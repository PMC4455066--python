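"""Splicing-surveillance analyses: meta-intron profiles and junction counts.

The workflow mirrors the genome-wide characterisation of a mutant that
stabilises unspliced pre-mRNAs:

1. coverage tracks are normalised so the median intronless-gene coverage is
   100 in every dataset, making strains comparable;
2. introns are filtered (ORF-only, 20-400 bp, expression-percentile band on
   the flanking-exon proxy) and ranked by the mutant-vs-WT increase of mean
   intronic coverage normalised to the mutant's flanking-exon expression;
   the upper quartile is selected;
3. each selected intron is mapped to a 40-bin frame plus 20-bp exonic flank
   columns and averaged geometrically (mean of log2 values) per column;
4. read-level spliced/unspliced quantification: a gapped read whose gap
   matches the intron exactly is spliced (S); a contiguous read overlapping
   both the intron and an adjacent exonic flank is unspliced (US); the US/S
   ratio is reported, optionally normalised to WT;
5. a stabilization-vs-splicing-defect diagnostic compares intronic, exonic
   and intronless fold-changes: a stabilised pre-mRNA raises intronic and
   exonic coverage together while intronless genes are unaffected, whereas
   a pure splicing defect raises only the intronic signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nexsurv.genome_model import (
    GenomeAnnotation,
    Intron,
    Read,
    ReadSet,
    StrandedSignal,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntronFilter:
    """Intron inclusion rules for the meta-intron analysis.

    The expression proxy of an intron is the median WT sense coverage over
    its two flanking exonic windows; introns in the lowest ``low_pct`` % or
    highest ``high_pct`` % of that proxy are excluded, as are introns
    outside ``[min_len_bp, max_len_bp]`` (inclusive) or in non-ORF genes
    when ``orf_only``.
    """

    min_len_bp: int = 20
    max_len_bp: int = 400
    orf_only: bool = True
    low_pct: float = 10.0
    high_pct: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.low_pct + self.high_pct < 100:
            raise ValueError("percentile exclusions must satisfy 0 <= low+high < 100")
        if self.min_len_bp > self.max_len_bp:
            raise ValueError("min_len_bp must be <= max_len_bp")


@dataclass
class IntronRanking:
    """Scored introns with the upper quartile flagged.

    score = (mean mutant intronic coverage - mean WT intronic coverage)
            / (mean mutant flank-exon coverage);
    the top ceil(N/4) by descending score are selected (ties broken by id).
    """

    table: pd.DataFrame  # columns: intron_id, score, selected
    dropped: list[str] = field(default_factory=list)

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "intron_id"])


# ---------------------------------------------------------------------------
# normalisation and filtering
# ---------------------------------------------------------------------------

def intronless_gene_medians(signal: StrandedSignal,
                            annotation: GenomeAnnotation) -> pd.Series:
    """Median per-base sense coverage of every intronless ORF."""
    meds = {}
    for g in annotation.intronless_genes(orf_only=True):
        arr = signal.values[g.chrom][g.strand][g.start:g.end]
        meds[g.id] = float(np.median(arr))
    return pd.Series(meds)


def normalize_coverage(signal: StrandedSignal,
                       annotation: GenomeAnnotation) -> StrandedSignal:
    """Scale a coverage track so the median intronless-gene coverage is 100.

    The per-gene statistic is the median per-base sense coverage over each
    intronless ORF; the whole signal is multiplied by
    ``100 / median(statistics)``.  Idempotent, and exact: recomputing the
    median statistic afterwards yields 100.
    """
    if signal.mode != "coverage":
        raise ValueError("normalize_coverage expects a coverage-mode signal")
    meds = intronless_gene_medians(signal, annotation)
    if meds.empty:
        raise ValueError("annotation has no intronless ORFs")
    m = float(meds.median())
    if m <= 0:
        raise ValueError("median intronless coverage is zero; cannot normalize")
    return signal.scaled(100.0 / m)


def flank_proxy(intron: Intron, annotation: GenomeAnnotation,
                wt: StrandedSignal) -> float:
    """Median WT sense coverage over the two flanking exonic windows."""
    g = annotation.genes_by_id[intron.parent_gene]
    vals = np.concatenate([
        wt.values[g.chrom][g.strand][s:e]
        for s, e in (intron.flank_exon_5, intron.flank_exon_3)])
    return float(np.median(vals))


def filter_introns(annotation: GenomeAnnotation, wt_coverage: StrandedSignal,
                   flt: IntronFilter | None = None) -> list[str]:
    """Intron ids passing length, ORF and expression-percentile filters.

    The percentile exclusion is rank-based: the ``floor(low_pct/100 * N)``
    lowest and ``floor(high_pct/100 * N)`` highest proxies are dropped
    (ties broken by intron id for determinism).
    """
    flt = flt or IntronFilter()
    by_id = annotation.genes_by_id
    kept = []
    for i in annotation.introns:
        if not flt.min_len_bp <= i.length <= flt.max_len_bp:
            continue
        if flt.orf_only and not by_id[i.parent_gene].is_orf:
            continue
        kept.append(i)
    if not kept:
        return []
    proxies = {i.id: flank_proxy(i, annotation, wt_coverage) for i in kept}
    order = sorted(proxies, key=lambda iid: (proxies[iid], iid))
    n = len(order)
    lo = math.floor(flt.low_pct / 100.0 * n)
    hi = math.floor(flt.high_pct / 100.0 * n)
    surviving = set(order[lo:n - hi] if hi else order[lo:])
    return [i.id for i in kept if i.id in surviving]


def rank_and_select_introns(intron_ids: list[str], annotation: GenomeAnnotation,
                            wt: StrandedSignal, mut: StrandedSignal) -> IntronRanking:
    """Score, rank and select the upper quartile of introns.

    Introns whose mutant flank-exon coverage is zero cannot be scored and
    are dropped with a warning.  The selected count is ``ceil(N/4)`` of the
    ranked introns.
    """
    by_intron = {i.id: i for i in annotation.introns}
    by_gene = annotation.genes_by_id
    rows, dropped = [], []
    for iid in intron_ids:
        i = by_intron[iid]
        g = by_gene[i.parent_gene]
        arr_mut = mut.values[g.chrom][g.strand]
        arr_wt = wt.values[g.chrom][g.strand]
        flank_mut = np.concatenate([arr_mut[s:e] for s, e in
                                    (i.flank_exon_5, i.flank_exon_3)])
        denom = float(flank_mut.mean())
        if denom == 0:
            dropped.append(iid)
            logger.warning("intron %s dropped: zero mutant flank coverage", iid)
            continue
        score = (float(arr_mut[i.start:i.end].mean())
                 - float(arr_wt[i.start:i.end].mean())) / denom
        rows.append((iid, score))
    df = pd.DataFrame(rows, columns=["intron_id", "score"])
    df = df.sort_values(["score", "intron_id"],
                        ascending=[False, True]).reset_index(drop=True)
    df["selected"] = select_upper_quartile(df["score"].to_numpy())
    return IntronRanking(table=df, dropped=dropped)


def select_upper_quartile_count(n: int) -> int:
    """The number of introns the upper-quartile rule keeps out of ``n``."""
    return math.ceil(n / 4) if n > 0 else 0


def select_upper_quartile(scores: np.ndarray) -> np.ndarray:
    """Boolean mask flagging the upper quartile of ``scores``.

    The ``ceil(N/4)`` highest scores are selected — the only rounding
    consistent with selecting 984 out of 3,935 ranked introns.  Ties are
    broken by original order.
    """
    scores = np.asarray(scores, dtype=float)
    n_sel = select_upper_quartile_count(scores.size)
    order = np.argsort(-scores, kind="stable")
    mask = np.zeros(scores.size, dtype=bool)
    mask[order[:n_sel]] = True
    return mask


# ---------------------------------------------------------------------------
# meta-intron composite
# ---------------------------------------------------------------------------

def intron_composite(intron_ids: list[str], annotation: GenomeAnnotation,
                     signal: StrandedSignal, n_bins: int = 40,
                     pseudocount: float = 1.0) -> pd.Series:
    """Meta-intron profile: 40 bins over the intron plus one column per
    20-bp exonic flank, strand-relative 5'->3', sense strand only.

    Each intron contributes log2(mean coverage) per column (zero means are
    replaced by ``pseudocount`` before the log); columns are averaged over
    introns — the log2 of the geometric mean of the coverages.
    """
    if not intron_ids:
        raise ValueError("empty intron list")
    by_intron = {i.id: i for i in annotation.introns}
    by_gene = annotation.genes_by_id
    labels = ["exon5"] + [f"bin{b}" for b in range(1, n_bins + 1)] + ["exon3"]
    rows = []
    for iid in intron_ids:
        i = by_intron[iid]
        g = by_gene[i.parent_gene]
        arr = signal.values[g.chrom][g.strand]

        def mean_of(s: float, e: float) -> float:
            # fractional bins: length-weighted mean over the covered bases
            lo, hi = int(math.floor(s)), int(math.ceil(e))
            w = np.minimum(np.arange(lo, hi) + 1, e) - np.maximum(np.arange(lo, hi), s)
            return float(np.average(arr[lo:hi], weights=w))

        edges = np.linspace(i.start, i.end, n_bins + 1)
        bins = [mean_of(edges[b], edges[b + 1]) for b in range(n_bins)]
        f5 = float(arr[slice(*i.flank_exon_5)].mean())
        f3 = float(arr[slice(*i.flank_exon_3)].mean())
        row = [f5] + bins + [f3]
        if g.strand == "-":
            row = [f5] + bins[::-1] + [f3]  # mirror bins into the 5'->3' frame
        vals = np.array(row, dtype=float)
        vals[vals <= 0] = pseudocount
        rows.append(np.log2(vals))
    return pd.Series(np.mean(rows, axis=0), index=labels)


# ---------------------------------------------------------------------------
# read-level quantification
# ---------------------------------------------------------------------------

def _overlaps(seg: tuple[int, int], iv: tuple[int, int]) -> bool:
    return seg[0] < iv[1] and iv[0] < seg[1]


def _is_spliced_for(read: Read, intron: Intron) -> bool:
    return read.is_gapped and read.gap == intron.span


def boundary_span_fraction(reads: ReadSet, introns: list[Intron],
                           annotation: GenomeAnnotation) -> float:
    """Among contiguous reads overlapping an intron, the fraction that also
    cross into an adjacent exonic flank (i.e. span an exon-intron boundary).

    Gapped reads are splicing products and are excluded entirely.  Returns
    NaN when no contiguous read overlaps any intron.
    """
    by_gene = annotation.genes_by_id
    n_overlap = n_boundary = 0
    for read in reads:
        if read.is_gapped:
            continue
        for seg in read.segments:
            for i in introns:
                g = by_gene[i.parent_gene]
                if g.chrom != read.chrom or g.strand != read.strand:
                    continue
                if _overlaps(seg, i.span):
                    n_overlap += 1
                    if (_overlaps(seg, i.flank_exon_5)
                            or _overlaps(seg, i.flank_exon_3)):
                        n_boundary += 1
                    break
            else:
                continue
            break
    if n_overlap == 0:
        return float("nan")
    return n_boundary / n_overlap


@dataclass
class SplicingCounts:
    """Junction-level counts for one intron.

    ``spliced`` (S): gapped reads whose gap equals the intron span exactly.
    ``unspliced`` (US): contiguous reads overlapping both the intron and an
    adjacent exonic flank.  ``intron_internal``: contiguous reads fully
    inside the intron.  ``mis_spliced``: gapped reads whose gap overlaps the
    intron without matching it.  ``us_over_s`` is NaN when S = 0;
    ``ratio_vs_wt`` = (US/S)_sample / (US/S)_WT when a WT read set is given.
    """

    spliced: int
    unspliced: int
    intron_internal: int
    mis_spliced: int
    us_over_s: float
    ratio_vs_wt: float | None = None


def _count_for_intron(reads: ReadSet, intron: Intron, chrom: str,
                      strand: str) -> tuple[int, int, int, int]:
    s = us = internal = mis = 0
    for read in reads:
        if read.chrom != chrom or read.strand != strand:
            continue
        if read.is_gapped:
            if read.gap == intron.span:
                s += 1
            elif _overlaps(read.gap, intron.span):
                mis += 1
            continue
        seg = read.segments[0]
        if not _overlaps(seg, intron.span):
            continue
        if (_overlaps(seg, intron.flank_exon_5)
                or _overlaps(seg, intron.flank_exon_3)):
            us += 1
        else:
            internal += 1
    return s, us, internal, mis


def quantify_splicing(reads: ReadSet, intron: Intron,
                      annotation: GenomeAnnotation,
                      wt_reads: ReadSet | None = None) -> SplicingCounts:
    """Count spliced vs unspliced reads for one intron; see
    :class:`SplicingCounts` for the definitions.

    Every intron-informative read is counted as exactly one of
    {spliced, unspliced, intron-internal, mis-spliced}.
    """
    g = annotation.genes_by_id[intron.parent_gene]
    s, us, internal, mis = _count_for_intron(reads, intron, g.chrom, g.strand)
    ratio = us / s if s > 0 else float("nan")
    norm = None
    if wt_reads is not None:
        ws, wus, _, _ = _count_for_intron(wt_reads, intron, g.chrom, g.strand)
        wt_ratio = wus / ws if ws > 0 else float("nan")
        norm = ratio / wt_ratio if wt_ratio and not math.isnan(wt_ratio) else float("nan")
    return SplicingCounts(spliced=s, unspliced=us, intron_internal=internal,
                          mis_spliced=mis, us_over_s=ratio, ratio_vs_wt=norm)


# ---------------------------------------------------------------------------
# stabilization-vs-splicing diagnostic
# ---------------------------------------------------------------------------

@dataclass
class StabilizationReport:
    """Geometric-mean mut/WT fold-changes of the three diagnostic categories
    (linear scale) and the verdict derived from them."""

    intron_fold: float
    exon_fold: float
    intronless_fold: float
    verdict: str
    tau_log2: float


def _geo_fold(pairs: list[tuple[float, float]], pseudocount: float = 1.0) -> float:
    logs = []
    for w, m in pairs:
        w = w if w > 0 else pseudocount
        m = m if m > 0 else pseudocount
        logs.append(np.log2(m / w))
    return float(2 ** np.mean(logs))


def stabilization_diagnostic(wt: StrandedSignal, mut: StrandedSignal,
                             intron_ids: list[str],
                             annotation: GenomeAnnotation,
                             tau_log2: float = 0.5,
                             pseudocount: float = 1.0) -> StabilizationReport:
    """Distinguish pre-mRNA stabilization from a pure splicing defect.

    Computes geometric-mean mut/WT fold-changes over (a) selected intron
    spans, (b) their flanking exonic windows, (c) intronless gene bodies.
    Verdicts (all comparisons on the log2 scale with tolerance ``tau_log2``):

    * "no change" — all three folds within tau of 1;
    * "stabilization" — introns elevated, exon fold within tau of the intron
      fold and intronless genes unaffected (unspliced transcripts are
      stabilised whole, so exons rise with introns);
    * "splicing defect" — intron fold exceeds exon fold by more than tau
      (only the intron accumulates);
    * "ambiguous" otherwise.
    """
    if not intron_ids:
        raise ValueError("empty intron list")
    by_intron = {i.id: i for i in annotation.introns}
    by_gene = annotation.genes_by_id
    intron_pairs, exon_pairs = [], []
    for iid in intron_ids:
        i = by_intron[iid]
        g = by_gene[i.parent_gene]
        aw, am = wt.values[g.chrom][g.strand], mut.values[g.chrom][g.strand]
        intron_pairs.append((float(aw[i.start:i.end].mean()),
                             float(am[i.start:i.end].mean())))
        for s, e in (i.flank_exon_5, i.flank_exon_3):
            exon_pairs.append((float(aw[s:e].mean()), float(am[s:e].mean())))
    intronless = annotation.intronless_genes(orf_only=True)
    if not intronless:
        raise ValueError("no intronless genes for the control category")
    less_pairs = [(float(wt.values[g.chrom][g.strand][g.start:g.end].mean()),
                   float(mut.values[g.chrom][g.strand][g.start:g.end].mean()))
                  for g in intronless]
    fi = _geo_fold(intron_pairs, pseudocount)
    fe = _geo_fold(exon_pairs, pseudocount)
    fl = _geo_fold(less_pairs, pseudocount)
    li, le, ll = np.log2([fi, fe, fl])
    if abs(li) <= tau_log2 and abs(le) <= tau_log2 and abs(ll) <= tau_log2:
        verdict = "no change"
    elif li - le > tau_log2:
        verdict = "splicing defect"
    elif li > tau_log2 and abs(li - le) <= tau_log2 and abs(ll) <= tau_log2:
        verdict = "stabilization"
    else:
        verdict = "ambiguous"
    return StabilizationReport(intron_fold=fi, exon_fold=fe, intronless_fold=fl,
                               verdict=verdict, tau_log2=tau_log2)
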