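"""Domain types, coordinate conventions and format I/O shared by all stages.

Conventions
-----------
* All coordinates are 0-based half-open internally.  GFF3 (1-based closed) is
  converted at the boundary; BED and bedGraph are already half-open.
* "Upstream"/"downstream", TSS and TTS are strand-relative: for a forward
  gene with span ``[s, e)`` the TSS is ``s`` and the TTS is ``e - 1``; for a
  reverse gene the TSS is ``e - 1`` and the TTS is ``s``.
* Strands are the strings ``"+"`` and ``"-"``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


class SignalError(ValueError):
    """Raised for malformed or out-of-bounds signal input."""


def opposite(strand: str) -> str:
    if strand not in STRANDS:
        raise ValueError(f"invalid strand {strand!r}")
    return REVERSE if strand == FORWARD else FORWARD


@dataclass(frozen=True)
class Gene:
    """A gene with a strand-aware span ``[start, end)``."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    is_orf: bool = True
    in_mmi1_regulon: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"gene {self.id}: end {self.end} <= start {self.start}")
        if self.strand not in STRANDS:
            raise AnnotationError(f"gene {self.id}: invalid strand {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == FORWARD else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == FORWARD else self.start


@dataclass(frozen=True)
class Intron:
    """An intron inside a parent gene, with abutting exonic flank windows.

    ``flank_exon_5`` / ``flank_exon_3`` are strand-relative: the 5' flank is
    the exonic window immediately upstream of the intron in the direction of
    transcription.  Both windows have width ``exon_flank_bp`` (clipped only
    if the parent gene is too short, which the constructor rejects).
    """

    id: str
    parent_gene: str
    start: int
    end: int
    flank_exon_5: tuple[int, int]
    flank_exon_3: tuple[int, int]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"intron {self.id}: empty span")
        left = self.flank_exon_5 if self.flank_exon_5[1] == self.start else self.flank_exon_3
        right = self.flank_exon_3 if left is self.flank_exon_5 else self.flank_exon_5
        if left[1] != self.start or right[0] != self.end:
            raise AnnotationError(f"intron {self.id}: flank windows must abut the intron span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def make_intron(id: str, parent: Gene, start: int, end: int, exon_flank_bp: int = 20) -> Intron:
    """Build an :class:`Intron` with strand-relative flank windows of the given width."""
    left = (start - exon_flank_bp, start)
    right = (end, end + exon_flank_bp)
    if parent.strand == FORWARD:
        f5, f3 = left, right
    else:
        f5, f3 = right, left
    return Intron(id=id, parent_gene=parent.id, start=start, end=end,
                  flank_exon_5=f5, flank_exon_3=f3)


@dataclass
class GenomeAnnotation:
    """Genes and introns on named chromosomes; the coordinate backbone.

    Invariants checked on construction: gene spans lie within their
    chromosome, gene ids are unique, and every intron lies strictly inside
    its parent gene's span.
    """

    chromosomes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)
    introns: list[Intron] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise AnnotationError(f"duplicate gene id {g.id}")
            seen.add(g.id)
            if g.chrom not in self.chromosomes:
                raise AnnotationError(f"gene {g.id}: unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > self.chromosomes[g.chrom]:
                raise AnnotationError(
                    f"gene {g.id} span [{g.start},{g.end}) outside chromosome "
                    f"{g.chrom} of length {self.chromosomes[g.chrom]}")
        by_id = {g.id: g for g in self.genes}
        for i in self.introns:
            parent = by_id.get(i.parent_gene)
            if parent is None:
                raise AnnotationError(f"intron {i.id}: unknown parent gene {i.parent_gene}")
            if not (parent.start < i.start and i.end < parent.end):
                raise AnnotationError(
                    f"intron {i.id} [{i.start},{i.end}) not strictly inside "
                    f"parent {parent.id} [{parent.start},{parent.end})")

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def genes_by_id(self) -> dict[str, Gene]:
        return {g.id: g for g in self.genes}

    def introns_of(self, gene_id: str) -> list[Intron]:
        return [i for i in self.introns if i.parent_gene == gene_id]

    def intronless_genes(self, orf_only: bool = True) -> list[Gene]:
        with_introns = {i.parent_gene for i in self.introns}
        out = [g for g in self.genes if g.id not in with_introns]
        if orf_only:
            out = [g for g in out if g.is_orf]
        return out


@dataclass
class ProbeSet:
    """Ordered tiling probes per chromosome, alternating strands.

    ``probes[chrom]`` is a list of ``(center_bp, strand)`` in genomic order.
    Consecutive probes alternate strands, so same-strand probes sit
    ``2 * resolution`` apart.
    """

    probes: dict[str, list[tuple[int, str]]]
    resolution: int

    def centers_on(self, chrom: str, strand: str) -> np.ndarray:
        return np.array([c for c, s in self.probes.get(chrom, []) if s == strand], dtype=int)


@dataclass
class StrandedSignal:
    """Per-base (or per-probe) values on both strands of every chromosome.

    ``values[chrom][strand]`` is a dense float array.  In per-base form its
    length equals the chromosome length; in probe form it is aligned with
    ``probes.centers_on(chrom, strand)``.  ``mode`` is ``"coverage"``
    (non-negative) or ``"log2_ratio"`` (signed).
    """

    values: dict[str, dict[str, np.ndarray]]
    mode: str
    probes: ProbeSet | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("coverage", "log2_ratio"):
            raise SignalError(f"invalid mode {self.mode!r}")
        if self.mode == "coverage":
            for chrom, per_strand in self.values.items():
                for strand, arr in per_strand.items():
                    if np.any(arr < 0):
                        raise SignalError(f"negative coverage on {chrom}{strand}")

    @property
    def is_probe_mode(self) -> bool:
        return self.probes is not None

    def array(self, chrom: str, strand: str) -> np.ndarray:
        return self.values[chrom][strand]

    def copy(self) -> "StrandedSignal":
        return StrandedSignal(
            values={c: {s: a.copy() for s, a in d.items()} for c, d in self.values.items()},
            mode=self.mode, probes=self.probes)

    def scaled(self, factor: float) -> "StrandedSignal":
        return StrandedSignal(
            values={c: {s: a * factor for s, a in d.items()} for c, d in self.values.items()},
            mode=self.mode, probes=self.probes)

    @classmethod
    def zeros(cls, annotation: GenomeAnnotation, mode: str = "coverage") -> "StrandedSignal":
        return cls(
            values={c: {s: np.zeros(n, dtype=float) for s in STRANDS}
                    for c, n in annotation.chromosomes.items()},
            mode=mode)


@dataclass(frozen=True)
class Read:
    """A read as one contiguous segment or two gap-separated segments.

    A two-segment read models a spliced (gapped) alignment; the gap is the
    genomic interval between ``segments[0][1]`` and ``segments[1][0]``.
    """

    chrom: str
    strand: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.segments) <= 2:
            raise ValueError("a read has one or two segments")
        for s, e in self.segments:
            if e <= s:
                raise ValueError("empty read segment")
        if len(self.segments) == 2 and self.segments[1][0] <= self.segments[0][1]:
            raise ValueError("gapped read segments must be ordered with gap length > 0")

    @property
    def is_gapped(self) -> bool:
        return len(self.segments) == 2

    @property
    def gap(self) -> tuple[int, int] | None:
        if not self.is_gapped:
            return None
        return (self.segments[0][1], self.segments[1][0])


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def _read_gff3(path: str, exon_flank_bp: int) -> GenomeAnnotation:
    import gffutils

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise AnnotationError(f"{path}: malformed GFF3 record at line {lineno}")
    db = gffutils.create_db(path, dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")

    chromosomes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                chromosomes[parts[1]] = int(parts[3])

    genes: list[Gene] = []
    for f in db.features_of_type("gene"):
        attrs = f.attributes
        biotype = (attrs.get("biotype") or ["protein_coding"])[0]
        genes.append(Gene(
            id=f.id, chrom=f.seqid, strand=f.strand,
            start=f.start - 1, end=f.end,  # 1-based closed -> 0-based half-open
            is_orf=(biotype == "protein_coding"),
            in_mmi1_regulon=(attrs.get("mmi1_regulon") or ["0"])[0] == "1",
        ))
    by_id = {g.id: g for g in genes}
    if not chromosomes:
        # fall back to the maximal annotated extent
        for g in genes:
            chromosomes[g.chrom] = max(chromosomes.get(g.chrom, 0), g.end)

    def parent_gene_of(f) -> str:
        pid = (f.attributes.get("Parent") or [None])[0]
        if pid is None:
            raise AnnotationError(f"feature {f.id} has no Parent")
        if pid in by_id:
            return pid
        # parent may be a transcript; climb one level
        tr = db[pid]
        gid = (tr.attributes.get("Parent") or [None])[0]
        if gid not in by_id:
            raise AnnotationError(f"cannot resolve parent gene of feature {f.id}")
        return gid

    introns: list[Intron] = []
    explicit = list(db.features_of_type("intron"))
    if explicit:
        for n, f in enumerate(explicit):
            gid = parent_gene_of(f)
            introns.append(make_intron(f.id or f"{gid}.i{n}", by_id[gid],
                                       f.start - 1, f.end, exon_flank_bp))
    else:
        # derive introns as gaps between exons of the same parent
        exons_by_gene: dict[str, list[tuple[int, int]]] = {}
        for f in db.features_of_type("exon"):
            gid = parent_gene_of(f)
            g = by_id[gid]
            if f.start - 1 < g.start or f.end > g.end:
                raise AnnotationError(
                    f"exon [{f.start - 1},{f.end}) outside gene {gid} span "
                    f"[{g.start},{g.end})")
            exons_by_gene.setdefault(gid, []).append((f.start - 1, f.end))
        for gid, exons in exons_by_gene.items():
            exons.sort()
            for n, ((_, e1), (s2, _)) in enumerate(zip(exons, exons[1:]), 1):
                if s2 < e1:
                    raise AnnotationError(f"overlapping exons in gene {gid}")
                if s2 > e1:
                    introns.append(make_intron(f"{gid}.i{n}", by_id[gid], e1, s2,
                                               exon_flank_bp))
    return GenomeAnnotation(chromosomes=chromosomes, genes=genes, introns=introns)


def _read_bed(path: str) -> GenomeAnnotation:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise AnnotationError(f"{path}: cannot parse BED: {exc}") from exc
    if df["strand"].isna().any():
        bad = int(df.index[df["strand"].isna()][0]) + 1
        raise AnnotationError(f"{path}: malformed BED6 record at line {bad}")
    genes = [Gene(id=str(r.name_), chrom=str(r.chrom), strand=str(r.strand),
                  start=int(r.start), end=int(r.end))
             for r in df.rename(columns={"name": "name_"}).itertuples()]
    chromosomes: dict[str, int] = {}
    for g in genes:
        chromosomes[g.chrom] = max(chromosomes.get(g.chrom, 0), g.end)
    return GenomeAnnotation(chromosomes=chromosomes, genes=genes, introns=[])


def read_annotation(path: str, exon_flank_bp: int = 20) -> GenomeAnnotation:
    """Read a GFF3 or BED6 annotation into a validated :class:`GenomeAnnotation`.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    Introns come from explicit ``intron`` features when present, otherwise
    they are derived as gaps between ``exon`` features of the same parent.
    """
    if path.endswith((".bed", ".bed6")):
        return _read_bed(path)
    return _read_gff3(path, exon_flank_bp)


def write_annotation(annotation: GenomeAnnotation, path: str) -> None:
    """Write a GFF3 file that :func:`read_annotation` round-trips exactly."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in annotation.genes:
            biotype = "protein_coding" if g.is_orf else "ncRNA"
            attrs = f"ID={g.id};biotype={biotype}"
            if g.in_mmi1_regulon:
                attrs += ";mmi1_regulon=1"
            fh.write("\t".join([g.chrom, "nexsurv", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")
        by_id = annotation.genes_by_id
        for i in annotation.introns:
            g = by_id[i.parent_gene]
            attrs = f"ID={i.id};Parent={i.parent_gene}"
            fh.write("\t".join([g.chrom, "nexsurv", "intron", str(i.start + 1),
                                str(i.end), ".", g.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# signal I/O
# ---------------------------------------------------------------------------

def _paint_bedgraph(path: str, arrs: dict[str, np.ndarray],
                    chromosomes: dict[str, int]) -> None:
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"], comment="#")
    except pd.errors.EmptyDataError:
        return
    covered: dict[str, np.ndarray] = {c: np.zeros(n, dtype=bool)
                                      for c, n in chromosomes.items()}
    for r in df.itertuples():
        chrom, start, end, value = str(r.chrom), int(r.start), int(r.end), float(r.value)
        if chrom not in chromosomes:
            raise SignalError(f"{path}: unknown chromosome {chrom}")
        if start < 0 or end > chromosomes[chrom] or end <= start:
            raise SignalError(
                f"{path}: interval {chrom}:{start}-{end} outside chromosome "
                f"of length {chromosomes[chrom]}")
        if covered[chrom][start:end].any():
            raise SignalError(f"{path}: overlapping intervals at {chrom}:{start}-{end}")
        covered[chrom][start:end] = True
        arrs[chrom][start:end] = value


def read_stranded_signal(path_fwd: str, path_rev: str,
                         annotation: GenomeAnnotation,
                         mode: str = "coverage") -> StrandedSignal:
    """Read a bedGraph pair (forward, reverse) into dense per-base arrays.

    Positions not covered by any interval are 0.  Overlapping intervals are
    rejected: input tracks are expected to partition the covered positions.
    """
    sig = StrandedSignal.zeros(annotation, mode="log2_ratio")
    _paint_bedgraph(path_fwd, {c: d[FORWARD] for c, d in sig.values.items()},
                    annotation.chromosomes)
    _paint_bedgraph(path_rev, {c: d[REVERSE] for c, d in sig.values.items()},
                    annotation.chromosomes)
    return StrandedSignal(values=sig.values, mode=mode)


def write_stranded_signal(signal: StrandedSignal, path_fwd: str, path_rev: str) -> None:
    """Write per-base arrays as a bedGraph pair (runs of equal value merged)."""
    for strand, path in ((FORWARD, path_fwd), (REVERSE, path_rev)):
        with open(path, "w") as fh:
            for chrom, per_strand in signal.values.items():
                arr = per_strand[strand]
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [arr.size]])
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_probe_table(path: str) -> tuple[ProbeSet, StrandedSignal]:
    """Read a tab-delimited probe table (chrom, center, strand, value)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "center", "strand", "value"], header=0)
    probes: dict[str, list[tuple[int, str]]] = {}
    values: dict[str, dict[str, list[float]]] = {}
    for r in df.itertuples():
        probes.setdefault(str(r.chrom), []).append((int(r.center), str(r.strand)))
        values.setdefault(str(r.chrom), {FORWARD: [], REVERSE: []})[str(r.strand)].append(float(r.value))
    centers = probes[next(iter(probes))] if probes else []
    res = centers[1][0] - centers[0][0] if len(centers) > 1 else 0
    pset = ProbeSet(probes=probes, resolution=res)
    sig = StrandedSignal(
        values={c: {s: np.array(v, dtype=float) for s, v in d.items()}
                for c, d in values.items()},
        mode="log2_ratio", probes=pset)
    return pset, sig


def write_probe_table(pset: ProbeSet, signal: StrandedSignal, path_or_buf) -> None:
    rows = []
    for chrom, plist in pset.probes.items():
        idx = {FORWARD: 0, REVERSE: 0}
        for center, strand in plist:
            v = signal.values[chrom][strand][idx[strand]]
            idx[strand] += 1
            rows.append((chrom, center, strand, v))
    df = pd.DataFrame(rows, columns=["chrom", "center", "strand", "value"])
    df.to_csv(path_or_buf, sep="\t", index=False)


# ---------------------------------------------------------------------------
# read-set I/O
# ---------------------------------------------------------------------------

def read_read_table(path: str) -> ReadSet:
    """Read a tab-delimited read table:
    chrom, strand, seg1_start, seg1_end[, seg2_start, seg2_end]."""
    reads: list[Read] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, strand = parts[0], parts[1]
            coords = [int(x) for x in parts[2:] if x != ""]
            segs = tuple((coords[i], coords[i + 1]) for i in range(0, len(coords), 2))
            reads.append(Read(chrom=chrom, strand=strand, segments=segs))
    return ReadSet(reads=reads)


def write_read_table(reads: ReadSet, path_or_buf) -> None:
    buf = path_or_buf if isinstance(path_or_buf, io.TextIOBase) else open(path_or_buf, "w")
    try:
        for r in reads:
            coords = "\t".join(f"{s}\t{e}" for s, e in r.segments)
            buf.write(f"{r.chrom}\t{r.strand}\t{coords}\n")
    finally:
        if buf is not path_or_buf:
            buf.close()


# ---------------------------------------------------------------------------
# signal statistics
# ---------------------------------------------------------------------------

def mean_signal(signal: StrandedSignal, chrom: str, strand: str,
                interval: tuple[int, int]) -> float:
    """Arithmetic mean of the signal over ``[start, end)`` on one strand.

    In probe mode the mean is over probes whose centers fall in the interval;
    NaN is returned when no probe does.
    """
    start, end = interval
    if end <= start:
        raise SignalError(f"empty interval [{start},{end})")
    if signal.is_probe_mode:
        centers = signal.probes.centers_on(chrom, strand)
        vals = signal.values[chrom][strand]
        mask = (centers >= start) & (centers < end)
        if not mask.any():
            return float("nan")
        return float(vals[mask].mean())
    arr = signal.values[chrom][strand]
    if start < 0 or end > arr.size:
        raise SignalError(f"interval [{start},{end}) outside chromosome {chrom}")
    return float(arr[start:end].mean())
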