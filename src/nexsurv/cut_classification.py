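"""Annotation-relative CUT classes and composite-profile gene selection.

Three classes of cryptic unstable transcripts are defined purely by position
relative to annotated genes:

* PROMPT — promoter upstream transcript: a window of ``w_bp`` upstream of the
  TSS on the strand opposite the gene;
* AS — antisense transcript: the gene body on the opposite strand;
* 3'IGT — 3' intergenic transcript: a window of ``w_bp`` downstream of the
  TTS on the gene's own strand.

Gene selection for composite profiles requires a minimum intergenic gap on
each strand-relative side, so that flank windows measure intergenic signal
rather than a neighbouring gene.
"""

from __future__ import annotations

from dataclasses import dataclass

from nexsurv.genome_model import FORWARD, GenomeAnnotation, opposite


@dataclass(frozen=True)
class ClassIntervals:
    """The three CUT-class intervals associated with one gene."""

    gene_id: str
    chrom: str
    prompt: tuple[int, int]
    prompt_strand: str
    antisense: tuple[int, int]
    antisense_strand: str
    igt3: tuple[int, int]
    igt3_strand: str


@dataclass
class TranscriptClassMap:
    """Per-gene CUT-class intervals for a whole annotation."""

    w_bp: int
    by_gene: dict[str, ClassIntervals]

    def intervals_of_class(self, cls: str) -> list[tuple[str, str, tuple[int, int]]]:
        """All ``(chrom, strand, interval)`` for class ``cls`` in
        {"PROMPT", "AS", "IGT3"}, skipping empty (fully clipped) windows."""
        out = []
        for ci in self.by_gene.values():
            iv, strand = {
                "PROMPT": (ci.prompt, ci.prompt_strand),
                "AS": (ci.antisense, ci.antisense_strand),
                "IGT3": (ci.igt3, ci.igt3_strand),
            }[cls]
            if iv[1] > iv[0]:
                out.append((ci.chrom, strand, iv))
        return out


@dataclass(frozen=True)
class SelectionCriteria:
    """Minimum strand-relative intergenic gaps required of a profiled gene.

    The sense-profile analysis uses (600, 100): at least 600 bp free of other
    genes downstream (3') and 100 bp upstream (5').  The antisense analysis
    swaps the two.  Comparisons are inclusive (gap >= threshold passes).
    """

    min_gap_3prime_bp: int = 600
    min_gap_5prime_bp: int = 100

    def __post_init__(self) -> None:
        if self.min_gap_3prime_bp < 0 or self.min_gap_5prime_bp < 0:
            raise ValueError("gap thresholds must be >= 0")


SENSE_CRITERIA = SelectionCriteria(min_gap_3prime_bp=600, min_gap_5prime_bp=100)
ANTISENSE_CRITERIA = SelectionCriteria(min_gap_3prime_bp=100, min_gap_5prime_bp=600)


def _clip(iv: tuple[int, int], chrom_len: int) -> tuple[int, int]:
    return (max(0, iv[0]), min(chrom_len, iv[1]))


def classify_cut_intervals(annotation: GenomeAnnotation, w_bp: int = 500) -> TranscriptClassMap:
    """Derive PROMPT / AS / 3'IGT intervals for every gene.

    For a forward gene ``[s, e)``: PROMPT = reverse-strand ``[s - w, s)``,
    AS = reverse-strand ``[s, e)``, 3'IGT = forward-strand ``[e, e + w)``;
    mirrored for reverse genes.  Windows are clipped to chromosome bounds.
    """
    by_gene: dict[str, ClassIntervals] = {}
    for g in annotation.genes:
        n = annotation.chromosomes[g.chrom]
        if g.strand == FORWARD:
            prompt = _clip((g.start - w_bp, g.start), n)
            igt3 = _clip((g.end, g.end + w_bp), n)
        else:
            prompt = _clip((g.end, g.end + w_bp), n)
            igt3 = _clip((g.start - w_bp, g.start), n)
        by_gene[g.id] = ClassIntervals(
            gene_id=g.id, chrom=g.chrom,
            prompt=prompt, prompt_strand=opposite(g.strand),
            antisense=(g.start, g.end), antisense_strand=opposite(g.strand),
            igt3=igt3, igt3_strand=g.strand)
    return TranscriptClassMap(w_bp=w_bp, by_gene=by_gene)


def intergenic_gaps(annotation: GenomeAnnotation, gene_id: str,
                    same_strand_only: bool = False) -> tuple[int, int]:
    """Strand-relative (5' gap, 3' gap) to the nearest neighbouring gene.

    The gap is the distance from the gene boundary to the nearest boundary of
    any other gene (by default on either strand; optionally only the same
    strand).  An overlapping neighbour yields gap 0; with no neighbour the
    gap extends to the chromosome end.
    """
    g = annotation.gene(gene_id)
    chrom_len = annotation.chromosomes[g.chrom]
    left_gap = g.start  # distance to chromosome start if no neighbour
    right_gap = chrom_len - g.end
    for other in annotation.genes:
        if other.id == g.id or other.chrom != g.chrom:
            continue
        if same_strand_only and other.strand != g.strand:
            continue
        if other.end <= g.start:
            left_gap = min(left_gap, g.start - other.end)
        elif other.start >= g.end:
            right_gap = min(right_gap, other.start - g.end)
        else:  # overlap
            if other.start < g.start:
                left_gap = 0
            if other.end > g.end:
                right_gap = 0
            if g.start <= other.start and other.end <= g.end:
                left_gap = right_gap = 0
    if g.strand == FORWARD:
        return left_gap, right_gap
    return right_gap, left_gap


def select_genes(annotation: GenomeAnnotation, criteria: SelectionCriteria,
                 same_strand_only: bool = False) -> list[str]:
    """Gene ids whose strand-relative intergenic gaps meet the criteria.

    Thresholds are inclusive: a gene with a 3' gap of exactly
    ``min_gap_3prime_bp`` passes.
    """
    selected = []
    for g in annotation.genes:
        gap5, gap3 = intergenic_gaps(annotation, g.id, same_strand_only)
        if gap3 >= criteria.min_gap_3prime_bp and gap5 >= criteria.min_gap_5prime_bp:
            selected.append(g.id)
    return selected


def write_class_bed(class_map: TranscriptClassMap, annotation: GenomeAnnotation,
                    path: str) -> None:
    """Write class intervals as BED6 with name ``geneid:class``."""
    with open(path, "w") as fh:
        for gid, ci in class_map.by_gene.items():
            for cls, iv, strand in (("PROMPT", ci.prompt, ci.prompt_strand),
                                    ("AS", ci.antisense, ci.antisense_strand),
                                    ("IGT3", ci.igt3, ci.igt3_strand)):
                if iv[1] > iv[0]:
                    fh.write(f"{ci.chrom}\t{iv[0]}\t{iv[1]}\t{gid}:{cls}\t0\t{strand}\n")
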