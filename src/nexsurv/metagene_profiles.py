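"""Composite (metagene) expression and RIP-enrichment profiles.

Selected genes are each mapped to a common coordinate frame: ``flank_probes``
positions upstream of the TSS, ``n_bins`` equal body bins, and
``flank_probes`` positions downstream of the TTS, all strand-relative
5'->3'.  Each row holds log2 ratios (mutant/WT or IP/input); columns are
averaged arithmetically on the log2 scale, i.e. as the geometric mean of the
underlying ratios, and plotted on a log2 scale.

Expression profiles are normalised so the mean sense gene-body signal sits
at 0 on the log2 scale, compensating the global-scaling artefact introduced
when antisense and intergenic transcripts accumulate in a mutant; RIP
(IP/input) profiles receive no such normalisation, and their negative
(under-enrichment) values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nexsurv.cut_classification import SelectionCriteria, select_genes
from nexsurv.genome_model import FORWARD, Gene, GenomeAnnotation, StrandedSignal, opposite


@dataclass(frozen=True)
class ProfileConfig:
    """Geometry of composite profiles.

    ``probe_pitch_bp`` is the same-strand probe spacing (2 x the 40-bp
    alternating design resolution); ``flank_probes`` x ``probe_pitch_bp``
    gives the 800-bp flank of the standard analysis.  ``exon_flank_bp`` is
    the exonic window width used by the meta-intron profiles.
    """

    n_bins: int = 15
    flank_probes: int = 10
    probe_pitch_bp: int = 80
    exon_flank_bp: int = 20
    clamp_negative_for_plot: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.flank_probes < 0:
            raise ValueError("flank_probes must be >= 0")

    @property
    def column_labels(self) -> list[str]:
        up = [f"5'flank{-k}" for k in range(self.flank_probes, 0, -1)]
        body = [f"bin{b}" for b in range(1, self.n_bins + 1)]
        down = [f"3'flank+{k}" for k in range(1, self.flank_probes + 1)]
        return up + body + down

    @property
    def body_labels(self) -> list[str]:
        return [f"bin{b}" for b in range(1, self.n_bins + 1)]


@dataclass
class CompositeMatrix:
    """Genes x positions matrix of log2 ratios behind a composite plot."""

    data: pd.DataFrame  # index: gene ids; columns: ProfileConfig.column_labels
    orientation: str  # "sense" or "antisense"

    def __post_init__(self) -> None:
        if self.orientation not in ("sense", "antisense"):
            raise ValueError(f"invalid orientation {self.orientation!r}")


def _positions_and_values(signal: StrandedSignal, chrom: str, strand: str,
                          pitch_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-strand sample positions and log2 values: probe centers in probe
    mode, per-base positions otherwise."""
    if signal.is_probe_mode:
        return signal.probes.centers_on(chrom, strand), signal.values[chrom][strand]
    arr = signal.values[chrom][strand]
    return np.arange(arr.size), arr


def bin_gene_row(gene: Gene, signal: StrandedSignal, config: ProfileConfig,
                 orientation: str) -> pd.Series:
    """One composite-matrix row for one gene.

    The gene body is split into ``n_bins`` equal real-valued intervals in
    strand-relative 5'->3' order; each bin value is the mean of the log2
    ratios whose probe centers fall inside it on the orientation strand
    (the gene's strand for ``sense``, the opposite for ``antisense``).
    Flank columns take the ``flank_probes`` nearest orientation-strand
    probes beyond the TSS (5' flank) and TTS (3' flank).  Bins or flank
    positions with no probe are missing (NaN).
    """
    if orientation not in ("sense", "antisense"):
        raise ValueError(f"invalid orientation {orientation!r}")
    strand = gene.strand if orientation == "sense" else opposite(gene.strand)
    pos, vals = _positions_and_values(signal, gene.chrom, strand, config.probe_pitch_bp)

    # body bins: real-valued boundaries; a probe at a boundary joins the
    # downstream (3') bin
    edges = np.linspace(gene.start, gene.end, config.n_bins + 1)
    body_mask = (pos >= gene.start) & (pos < gene.end)
    body = np.full(config.n_bins, np.nan)
    if body_mask.any():
        bpos, bvals = pos[body_mask], vals[body_mask]
        if gene.strand == FORWARD:
            frame = bpos - gene.start
        else:
            frame = gene.end - 1 - bpos  # mirror into the 5'->3' frame
        width = gene.length / config.n_bins
        idx = np.minimum((frame / width).astype(int), config.n_bins - 1)
        for b in range(config.n_bins):
            sel = idx == b
            if sel.any():
                body[b] = bvals[sel].mean()

    def flank(side: str) -> np.ndarray:
        out = np.full(config.flank_probes, np.nan)
        if config.flank_probes == 0:
            return out
        upstream = (side == "5p") == (gene.strand == FORWARD)
        if signal.is_probe_mode:
            if upstream:
                mask = pos < gene.start
                order = np.argsort(gene.start - pos[mask])  # nearest first
            else:
                mask = pos >= gene.end
                order = np.argsort(pos[mask] - gene.end)
            fvals = vals[mask][order][:config.flank_probes]
            # nearest-first -> fill from the gene-proximal end
            out[:fvals.size] = fvals
        else:
            span = config.flank_probes * config.probe_pitch_bp
            arr = signal.values[gene.chrom][strand]
            for k in range(config.flank_probes):
                if upstream:
                    s = gene.start - (k + 1) * config.probe_pitch_bp
                    e = gene.start - k * config.probe_pitch_bp
                else:
                    s = gene.end + k * config.probe_pitch_bp
                    e = gene.end + (k + 1) * config.probe_pitch_bp
                s, e = max(0, s), min(arr.size, e)
                if e > s:
                    out[k] = arr[s:e].mean()
        return out

    f5 = flank("5p")[::-1]  # proximal-last so columns read 5'->3'
    f3 = flank("3p")
    row = np.concatenate([f5, body, f3])
    return pd.Series(row, index=config.column_labels, name=gene.id)


def build_matrix(annotation: GenomeAnnotation, signal: StrandedSignal,
                 config: ProfileConfig, orientation: str,
                 gene_ids: list[str]) -> CompositeMatrix:
    by_id = annotation.genes_by_id
    rows = [bin_gene_row(by_id[gid], signal, config, orientation) for gid in gene_ids]
    data = pd.DataFrame(rows) if rows else pd.DataFrame(columns=config.column_labels)
    return CompositeMatrix(data=data, orientation=orientation)


def composite_average(matrix: CompositeMatrix) -> pd.Series:
    """Column-wise mean of log2 values over rows with data in that column
    (the log2 of the geometric mean of the ratios).  Columns missing in
    every row stay missing."""
    if matrix.data.empty:
        raise ValueError("empty composite matrix")
    return matrix.data.mean(axis=0, skipna=True)


def normalize_to_wt(sense_profile: pd.Series, as_profile: pd.Series,
                    sense_matrix: CompositeMatrix | None = None,
                    body_labels: list[str] | None = None
                    ) -> tuple[pd.Series, pd.Series, float]:
    """Anchor the mean sense gene-body expression at 0 on the log2 scale.

    The offset is the grand mean of the sense profile's body-bin columns
    (flanks excluded) and is subtracted from every column of both the sense
    and antisense profiles — a global array-scaling correction, so it
    applies to both strands equally.  Returns (sense, antisense, offset).
    """
    if body_labels is None:
        body_labels = [c for c in sense_profile.index if str(c).startswith("bin")]
    body = sense_profile[body_labels]
    if body.isna().all():
        raise ValueError("sense gene-body columns are all missing")
    offset = float(body.mean(skipna=True))
    return sense_profile - offset, as_profile - offset, offset


def clamp_for_plot(profile: pd.Series) -> pd.Series:
    """Plot-ready variant: negative values dropped (only positive values are
    shown on expression composite plots)."""
    out = profile.copy()
    out[out < 0] = np.nan
    return out


def expression_composite(annotation: GenomeAnnotation,
                         ratio_signal: StrandedSignal,
                         config: ProfileConfig | None = None,
                         criteria_sense: SelectionCriteria | None = None,
                         criteria_as: SelectionCriteria | None = None,
                         ) -> dict:
    """The full expression-composite pipeline on a log2(mutant/WT) signal.

    Selects genes per orientation, builds both matrices, averages each
    column and anchors the sense body at WT level.  Returns a dict with the
    normalised profiles, plot-ready (negative-clamped) variants, matrices,
    the offset and the selected gene lists.
    """
    config = config or ProfileConfig()
    criteria_sense = criteria_sense or SelectionCriteria(600, 100)
    criteria_as = criteria_as or SelectionCriteria(100, 600)
    genes_sense = select_genes(annotation, criteria_sense)
    genes_as = select_genes(annotation, criteria_as)
    if not genes_sense or not genes_as:
        raise ValueError("no genes pass the selection criteria")
    m_sense = build_matrix(annotation, ratio_signal, config, "sense", genes_sense)
    m_as = build_matrix(annotation, ratio_signal, config, "antisense", genes_as)
    p_sense = composite_average(m_sense)
    p_as = composite_average(m_as)
    p_sense, p_as, offset = normalize_to_wt(p_sense, p_as, m_sense,
                                            config.body_labels)
    return {
        "sense": p_sense,
        "antisense": p_as,
        "sense_plot": clamp_for_plot(p_sense),
        "antisense_plot": clamp_for_plot(p_as),
        "sense_matrix": m_sense,
        "antisense_matrix": m_as,
        "offset": offset,
        "genes_sense": genes_sense,
        "genes_as": genes_as,
    }


def rip_composite(annotation: GenomeAnnotation,
                  ip_over_input_signal: StrandedSignal,
                  config: ProfileConfig | None = None,
                  criteria_sense: SelectionCriteria | None = None,
                  criteria_as: SelectionCriteria | None = None) -> dict:
    """RIP-enrichment composite on a log2(IP/input) signal.

    Same machinery as :func:`expression_composite` but with no WT
    normalisation and no clamping: under-enrichment (negative values) is
    part of the result.
    """
    config = config or ProfileConfig()
    criteria_sense = criteria_sense or SelectionCriteria(600, 100)
    criteria_as = criteria_as or SelectionCriteria(100, 600)
    genes_sense = select_genes(annotation, criteria_sense)
    genes_as = select_genes(annotation, criteria_as)
    if not genes_sense or not genes_as:
        raise ValueError("no genes pass the selection criteria")
    m_sense = build_matrix(annotation, ip_over_input_signal, config, "sense", genes_sense)
    m_as = build_matrix(annotation, ip_over_input_signal, config, "antisense", genes_as)
    return {
        "sense": composite_average(m_sense),
        "antisense": composite_average(m_as),
        "sense_matrix": m_sense,
        "antisense_matrix": m_as,
        "genes_sense": genes_sense,
        "genes_as": genes_as,
    }


def regulon_report(annotation: GenomeAnnotation, gene_ids: list[str],
                   signal: StrandedSignal) -> pd.Series:
    """Per-gene mean sense log2 value over the gene body (the per-gene
    numbers behind regulon heat strips).  Genes with no overlapping signal
    are missing."""
    if not gene_ids:
        raise ValueError("empty gene list")
    by_id = annotation.genes_by_id
    out = {}
    for gid in gene_ids:
        if gid not in by_id:
            raise KeyError(f"unknown gene id {gid}")
        g = by_id[gid]
        pos, vals = _positions_and_values(signal, g.chrom, g.strand, 0)
        mask = (pos >= g.start) & (pos < g.end)
        out[gid] = float(vals[mask].mean()) if mask.any() else np.nan
    return pd.Series(out)


def profile_table(sense: pd.Series, antisense: pd.Series,
                  n_sense: int, n_as: int) -> pd.DataFrame:
    """Tab-delimited-ready composite table: one row per column position."""
    return pd.DataFrame({
        "position": sense.index,
        "sense": sense.values,
        "antisense": antisense.reindex(sense.index).values,
        "n_genes_sense": n_sense,
        "n_genes_antisense": n_as,
    })


def plot_composite(sense: pd.Series, antisense: pd.Series, path: str,
                   title: str = "") -> None:
    """Mirrored-axis composite plot: sense above, antisense mirrored below."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    x = np.arange(len(sense))
    ax1.plot(x, sense.values, lw=1.5)
    ax1.set_ylabel("sense log2")
    ax1.axhline(0, color="grey", lw=0.5)
    ax2.plot(x, antisense.reindex(sense.index).values, lw=1.5)
    ax2.invert_yaxis()
    ax2.set_ylabel("antisense log2 (mirrored)")
    ax2.axhline(0, color="grey", lw=0.5)
    ax2.set_xticks(x[::5])
    ax2.set_xticklabels(list(sense.index[::5]), rotation=90, fontsize=6)
    if title:
        ax1.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
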