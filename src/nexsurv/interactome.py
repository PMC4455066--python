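"""iBAQ-based interactome post-processing.

Label-free quantification of affinity purifications: each co-purifying
protein's iBAQ intensity is expressed as a percentage of the bait protein
and binned into abundance tiers (black >= 2.5 %, grey >= 0.5 %, white
otherwise).  A protein is non-significant when its iBAQ is below 50,000 or
it has zero spectral counts.  Comparing presence patterns across
purifications in deletion backgrounds partitions the complex into
submodules: proteins that come and go together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

IBAQ_SIGNIFICANCE_FLOOR = 50_000.0
TIER_BLACK_MIN = 2.5  # percent of bait
TIER_GREY_MIN = 0.5


@dataclass(frozen=True)
class AbundanceTier:
    """Tier thresholds in percent-of-bait units."""

    black_min: float = TIER_BLACK_MIN
    grey_min: float = TIER_GREY_MIN

    def __post_init__(self) -> None:
        if not self.black_min > self.grey_min > 0:
            raise ValueError("thresholds must satisfy black_min > grey_min > 0")

    def classify(self, percentage: float) -> str:
        if percentage >= self.black_min:
            return "black"
        if percentage >= self.grey_min:
            return "grey"
        return "white"


def significance_filter(table: pd.DataFrame,
                        ibaq_floor: float = IBAQ_SIGNIFICANCE_FLOOR) -> pd.DataFrame:
    """Drop non-significant identifications: iBAQ < floor or zero spectral
    counts.  The input table needs columns (protein, ibaq, spectral_counts);
    ``attrs`` are preserved."""
    keep = (table["ibaq"] >= ibaq_floor) & (table["spectral_counts"] > 0)
    out = table.loc[keep].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out


def percent_of_bait(table: pd.DataFrame, bait: str | None = None,
                    ibaq_floor: float = IBAQ_SIGNIFICANCE_FLOOR) -> pd.Series:
    """iBAQ of each significant protein as a percentage of the bait's.

    The bait maps to exactly 100.  Proteins filtered out (or absent) do not
    appear; callers treating absence as 0 should reindex.  Raises if the
    bait itself fails the significance filter.
    """
    bait = bait or table.attrs.get("bait")
    if bait is None:
        raise ValueError("bait id required (argument or table.attrs['bait'])")
    sig = significance_filter(table, ibaq_floor)
    sig = sig.set_index("protein")
    if bait not in sig.index:
        raise ValueError(f"bait {bait!r} is non-significant or absent")
    return 100.0 * sig["ibaq"] / float(sig.loc[bait, "ibaq"])


def tier(percentage: float, thresholds: AbundanceTier | None = None) -> str:
    """Abundance tier of a percent-of-bait value: black >= 2.5, grey >= 0.5,
    white below.  Both lower bounds are inclusive."""
    return (thresholds or AbundanceTier()).classify(percentage)


def complex_abundance(percentages: pd.Series, member_ids: list[str]) -> float:
    """Mean percent-of-bait over a complex's subunits, with absent members
    contributing 0 (e.g. the 12-subunit nuclear exosome reported as one
    averaged abundance)."""
    if not member_ids:
        raise ValueError("empty member list")
    return float(percentages.reindex(member_ids).fillna(0.0).mean())


def tier_matrix(tables: list[pd.DataFrame],
                thresholds: AbundanceTier | None = None,
                average_replicates: bool = True) -> pd.DataFrame:
    """Proteins x purifications matrix of tier labels.

    Replicate tables sharing a purification id have their percent-of-bait
    values averaged before tiering.  Rows are all proteins significant in at
    least one purification; absence is tiered white.
    """
    thresholds = thresholds or AbundanceTier()
    pct_by_purif: dict[str, list[pd.Series]] = {}
    for t in tables:
        pid = t.attrs.get("purification") or t.attrs.get("bait")
        pct_by_purif.setdefault(pid, []).append(percent_of_bait(t))
    cols = {}
    for pid, reps in pct_by_purif.items():
        if average_replicates and len(reps) > 1:
            cols[pid] = pd.concat(reps, axis=1).fillna(0.0).mean(axis=1)
        else:
            cols[pid] = reps[0]
    pct = pd.DataFrame(cols).fillna(0.0)
    return pct.map(thresholds.classify)


def infer_submodules(tiers: pd.DataFrame,
                     max_hamming: int = 0) -> dict[tuple[bool, ...], list[str]]:
    """Group proteins by their presence pattern across purifications.

    Presence = tier != white (a significant protein under 0.5 % of the bait
    is treated as absent, like the white tier).  Proteins sharing an
    identical presence vector form one submodule; ``max_hamming`` > 0
    merges groups whose vectors differ in at most that many purifications.
    Proteins absent everywhere are not grouped.
    """
    if tiers.shape[1] < 2:
        logger.warning("single purification: submodule grouping is by presence only")
    presence = tiers != "white"
    groups: dict[tuple[bool, ...], list[str]] = {}
    for prot, row in presence.iterrows():
        vec = tuple(bool(v) for v in row)
        if not any(vec):
            continue
        groups.setdefault(vec, []).append(prot)
    if max_hamming > 0:
        merged: dict[tuple[bool, ...], list[str]] = {}
        for vec in sorted(groups, reverse=True):
            for mvec in merged:
                if sum(a != b for a, b in zip(vec, mvec)) <= max_hamming:
                    merged[mvec].extend(groups[vec])
                    break
            else:
                merged[vec] = list(groups[vec])
        groups = merged
    return groups


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_ibaq_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_ibaq_table(path: str, bait: str | None = None,
                    background: str | None = None,
                    purification: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"protein", "ibaq", "spectral_counts"}
    if not expected <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    if bait:
        df.attrs["bait"] = bait
    if background:
        df.attrs["background"] = background
    df.attrs["purification"] = purification or f"{bait}_{background}"
    return df


def write_tier_matrix(tiers: pd.DataFrame, path: str) -> None:
    tiers.rename_axis("protein").to_csv(path, sep="\t")


def write_submodules(groups: dict[tuple[bool, ...], list[str]],
                     purification_ids: list[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("submodule\tpresence_vector\tproteins\n")
        for k, (vec, prots) in enumerate(sorted(groups.items(), reverse=True), 1):
            pattern = "".join("1" if v else "0" for v in vec)
            fh.write(f"M{k}\t{pattern}\t{','.join(sorted(prots))}\n")
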