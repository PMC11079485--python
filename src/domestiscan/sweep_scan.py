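"""Candidate selective-sweep calling from window statistics.

Windows whose F_ST *and* ROD both exceed their empirical top-5%
thresholds (nearest-rank quantile, strict inequality) are selected,
overlapping or book-ended selected windows are merged into regions, and
annotated genes overlapping each region are attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomicInterval

__all__ = [
    "SweepRegion",
    "empirical_threshold",
    "select_sweep_windows",
    "merge_windows",
    "genes_in_regions",
]


@dataclass
class SweepRegion:
    """A merged run of selected windows with overlapping genes attached."""

    interval: GenomicInterval
    n_windows: int
    max_fst: float
    max_rod: float
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError("region must contain at least one window")


def empirical_threshold(values: Sequence[float] | np.ndarray, upper_tail: float = 0.05) -> float:
    """Nearest-rank upper-tail cut point of the defined values.

    The threshold is the value at ascending rank ``ceil((1 - upper_tail) *
    n)``; downstream selection keeps values *strictly greater* than it, so
    at most ``upper_tail`` of the defined values can be selected.  NaNs
    (undefined windows) are excluded; fewer than 20 defined values is an
    error.  ``upper_tail >= 1`` degenerates to ``-inf`` (select all).
    """
    v = np.asarray(values, dtype=float)
    v = np.sort(v[~np.isnan(v)])
    if upper_tail >= 1.0:
        return float("-inf")
    if len(v) == 0:
        raise ValueError("all values undefined")
    if len(v) < 20:
        raise ValueError(f"need >= 20 defined values, got {len(v)}")
    rank = math.ceil((1.0 - upper_tail) * len(v))  # 1-based order statistic
    return float(v[rank - 1])


def select_sweep_windows(
    stats: pd.DataFrame, fst_threshold: float, rod_threshold: float
) -> pd.DataFrame:
    """Windows with ``fst > fst_threshold`` and ``rod > rod_threshold``.

    Both statistics must be defined (non-NaN); this is the intersection of
    the two upper-tail selections.
    """
    if not (np.isfinite(fst_threshold) or fst_threshold == -np.inf) or not (
        np.isfinite(rod_threshold) or rod_threshold == -np.inf
    ):
        raise ValueError("thresholds must be finite (or -inf for select-all)")
    mask = (stats["fst"] > fst_threshold) & (stats["rod"] > rod_threshold)
    mask &= stats["fst"].notna() & stats["rod"].notna()
    return stats.loc[mask].reset_index(drop=True)


def merge_windows(selected: pd.DataFrame) -> list[SweepRegion]:
    """Merge overlapping or book-ended same-chromosome windows into regions.

    Region F_ST/ROD are member maxima; output is sorted by (chrom, start)
    and non-overlapping.  Merging is idempotent.
    """
    if len(selected) == 0:
        return []
    df = selected.sort_values(["chrom", "start"]).reset_index(drop=True)
    regions: list[SweepRegion] = []
    cur: dict | None = None
    for row in df.itertuples(index=False):
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.start <= cur["end"]  # overlap or book-ended
        ):
            cur["end"] = max(cur["end"], row.end)
            cur["n"] += 1
            cur["fst"] = max(cur["fst"], row.fst)
            cur["rod"] = max(cur["rod"], row.rod)
        else:
            if cur is not None:
                regions.append(_close(cur))
            cur = {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "n": 1,
                "fst": row.fst,
                "rod": row.rod,
            }
    if cur is not None:
        regions.append(_close(cur))
    return regions


def _close(cur: dict) -> SweepRegion:
    return SweepRegion(
        interval=GenomicInterval(cur["chrom"], int(cur["start"]), int(cur["end"])),
        n_windows=cur["n"],
        max_fst=float(cur["fst"]),
        max_rod=float(cur["rod"]),
    )


def genes_in_regions(
    regions: Sequence[SweepRegion], genes: Iterable[GeneModel]
) -> tuple[list[SweepRegion], list[str]]:
    """Attach genes overlapping each region by >= 1 bp; also return the
    deduplicated, sorted flat gene list.

    Gene coordinates (1-based inclusive) are compared as the half-open
    interval ``[start - 1, end)``.
    """
    flat: set[str] = set()
    for region in regions:
        hits = [
            g.gene_id for g in genes if g.interval().overlaps(region.interval)
        ]
        region.genes = sorted(hits)
        flat.update(hits)
    return list(regions), sorted(flat)


def regions_to_frame(regions: Sequence[SweepRegion]) -> pd.DataFrame:
    """Tabular view of regions (BED-style coordinates)."""
    return pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in regions],
            "start": [r.interval.start for r in regions],
            "end": [r.interval.end for r in regions],
            "n_windows": [r.n_windows for r in regions],
            "max_fst": [r.max_fst for r in regions],
            "max_rod": [r.max_rod for r in regions],
            "genes": [",".join(r.genes) for r in regions],
        }
    )
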