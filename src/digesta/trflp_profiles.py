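"""T-RFLP peak processing: background filtering, normalisation, binning.

Electropherogram exports (one row per sized fluorescent peak: sample,
fragment size in bp, height, area) are turned into relative-abundance
terminal-fragment profiles that can be compared across samples:

1. background filtering removes peaks below a gene-specific size floor
   (70 bp for the cel5 marker, 50 bp for cel48) and peaks contributing
   less than 1 % of the total raw peak area,
2. normalisation divides each surviving area by the post-filter total, and
3. binning clusters fractional sizes across samples into integer T-RF bins
   so the same ribotype lines up across lanes.

The size floor and share floor are applied independently (a peak is
dropped if it fails either); the conjunctive reading - drop only peaks
failing both - is available via ``combine="and"``.  Shares for the 1 %
rule are always measured against the pre-filter total: "background" is a
property of the raw trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRFProfile",
    "SIZE_FLOORS",
    "MIN_SHARE",
    "CALIBRATION_RANGE",
    "filter_background",
    "relative_abundance",
    "make_profile",
    "bin_trfs",
    "profile_turnover",
]

#: Gene-specific minimum T-RF size (bp) retained after digestion of the
#: cel5 and cel48 marker amplicons.
SIZE_FLOORS = {"cel5": 70.0, "cel48": 50.0}

#: Minimum share of the raw total peak area for a peak to count as signal.
MIN_SHARE = 0.01

#: Calibration range of the GS ROX 500 internal size standard; peaks
#: cannot be sized reliably outside it.
CALIBRATION_RANGE = (50.0, 500.0)


@dataclass
class TRFProfile:
    """Filtered, normalised T-RF abundance vector for one sample."""

    sample_id: str
    gene: str
    sizes: np.ndarray  # bp, may be fractional before binning
    abundances: np.ndarray  # fractions summing to 1 when non-empty

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.sizes.shape != self.abundances.shape:
            raise ValueError("sizes and abundances must have equal length")
        if self.abundances.size and abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    @property
    def empty(self) -> bool:
        return self.sizes.size == 0


def _size_floor(gene: str, size_floor: float | None) -> float:
    if size_floor is not None:
        return float(size_floor)
    try:
        return SIZE_FLOORS[gene]
    except KeyError:
        raise ValueError(f"unknown gene context {gene!r}; pass size_floor explicitly") from None


def filter_background(
    peaks: pd.DataFrame,
    gene: str,
    *,
    min_share: float = MIN_SHARE,
    size_floor: float | None = None,
    combine: str = "or",
) -> pd.DataFrame:
    """Remove background peaks from a sized peak table.

    ``peaks`` needs ``size_bp`` and ``area`` columns.  With the default
    ``combine="or"`` a peak is excluded if its size is below the gene
    floor, or (independently) its share of the raw total area is below
    ``min_share``; ``combine="and"`` excludes only peaks failing both.
    Peaks outside the size-standard calibration range are always dropped.
    An empty table passes through unchanged.
    """
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")
    floor = _size_floor(gene, size_floor)
    if peaks.empty:
        return peaks.copy()
    if np.any(peaks["area"].to_numpy(dtype=float) < 0):
        raise ValueError("peak areas must be non-negative")
    total = float(peaks["area"].sum())
    size = peaks["size_bp"].to_numpy(dtype=float)
    share = peaks["area"].to_numpy(dtype=float) / total if total > 0 else np.zeros(len(peaks))
    small = size < floor
    faint = share < min_share
    drop = (small | faint) if combine == "or" else (small & faint)
    drop |= (size < CALIBRATION_RANGE[0]) | (size > CALIBRATION_RANGE[1])
    return peaks.loc[~drop].copy()


def relative_abundance(
    peaks: pd.DataFrame, *, sample_id: str = "", gene: str = ""
) -> TRFProfile:
    """Normalise a (filtered) peak table to a relative-abundance profile.

    Each area is divided by the post-filter total so the reported
    percentages sum to 100 %.  An all-filtered table yields an empty
    profile (callers should treat this as a flagged condition).
    """
    if not sample_id and "sample" in peaks.columns and peaks["sample"].nunique() == 1:
        sample_id = str(peaks["sample"].iloc[0])
    if peaks.empty:
        return TRFProfile(sample_id, gene, np.array([]), np.array([]))
    areas = peaks["area"].to_numpy(dtype=float)
    total = areas.sum()
    if total <= 0:
        return TRFProfile(sample_id, gene, np.array([]), np.array([]))
    return TRFProfile(sample_id, gene, peaks["size_bp"].to_numpy(dtype=float), areas / total)


def make_profile(
    peaks: pd.DataFrame,
    gene: str,
    *,
    sample_id: str = "",
    min_share: float = MIN_SHARE,
    size_floor: float | None = None,
    combine: str = "or",
) -> TRFProfile:
    """Filter then normalise: the full per-sample pipeline in one call."""
    kept = filter_background(peaks, gene, min_share=min_share, size_floor=size_floor, combine=combine)
    return relative_abundance(kept, sample_id=sample_id, gene=gene)


def bin_trfs(profiles: Sequence[TRFProfile], tolerance: float = 1.0) -> pd.DataFrame:
    """Cluster fractional T-RF sizes across samples into integer bins.

    Greedy clustering seeded by descending total abundance: the heaviest
    unassigned peak opens a bin and captures every unassigned peak within
    ``tolerance`` bp; the bin label is the abundance-weighted mean size
    rounded to an integer.  Returns a T-RF x sample matrix whose non-empty
    columns each sum to 1.
    """
    genes = {p.gene for p in profiles}
    if len(genes) > 1:
        raise ValueError(f"profiles mix gene contexts: {sorted(genes)}")
    records = []  # (size, abundance, sample)
    for p in profiles:
        for s, a in zip(p.sizes, p.abundances):
            records.append([float(s), float(a), p.sample_id])
    samples = [p.sample_id for p in profiles]
    if not records:
        return pd.DataFrame(columns=samples, dtype=float)
    rec = pd.DataFrame(records, columns=["size", "abundance", "sample"])
    # total abundance per unique size drives the greedy seeding order
    totals = rec.groupby("size")["abundance"].sum().sort_values(ascending=False)
    assigned = pd.Series(False, index=rec.index)
    bins: dict[int, pd.Series] = {}
    for seed_size in totals.index:
        mask = (~assigned) & (np.abs(rec["size"] - seed_size) <= tolerance)
        if not mask.any():
            continue
        members = rec.loc[mask]
        label = int(round(np.average(members["size"], weights=members["abundance"])
                          if members["abundance"].sum() > 0 else members["size"].mean()))
        col = members.groupby("sample")["abundance"].sum()
        bins[label] = bins[label].add(col, fill_value=0.0) if label in bins else col
        assigned[mask] = True
    matrix = pd.DataFrame(bins).T.reindex(columns=samples).fillna(0.0).sort_index()
    matrix.index.name = "trf_bp"
    return matrix


def profile_turnover(start: pd.Series, end: pd.Series) -> pd.Series:
    """Signed per-T-RF abundance change (end - start) over the union axis.

    Inputs are binned abundance vectors (e.g. columns of :func:`bin_trfs`
    output) indexed by T-RF.  For two complete profiles the changes sum to
    zero: abundance lost by some T-RFs is gained by others.
    """
    start = pd.Series(start, dtype=float)
    end = pd.Series(end, dtype=float)
    idx = start.index.union(end.index)
    return end.reindex(idx, fill_value=0.0) - start.reindex(idx, fill_value=0.0)
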