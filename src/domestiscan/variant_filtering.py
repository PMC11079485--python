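"""The SNP quality funnel: hard INFO-field filters, a MAF / call-rate
filter, and windowed LD pruning.

The hard filter is the GATK-style disjunction
``QD < 2.0 || MQ < 40.0 || FS > 60.0 || SOR > 3.0 || MQRankSum < -12.5 ||
ReadPosRankSum < -8.0``: a site is dropped if *any* rule fires, and a site
lacking a given annotation is never dropped by that rule (GATK convention
for missing annotations).  LD pruning mirrors PLINK's
``--indep-pairwise 50 10 0.2``: within sliding windows of 50 SNPs
advancing by 10, offending pairs (r^2 above threshold) lose their
lower-MAF member until no pair remains above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import MISSING, GenotypeMatrix
from .ld_analysis import pairwise_r2

__all__ = [
    "HardFilterThresholds",
    "LdPruneParams",
    "apply_hard_filters",
    "filter_maf_callrate",
    "site_maf",
    "ld_prune",
]


@dataclass(frozen=True)
class HardFilterThresholds:
    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    sor_max: float = 3.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")

    def rules(self) -> list[tuple[str, str, float]]:
        """(INFO key, direction, threshold); 'lt' fails when value < thr."""
        return [
            ("QD", "lt", self.qd_min),
            ("MQ", "lt", self.mq_min),
            ("FS", "gt", self.fs_max),
            ("SOR", "gt", self.sor_max),
            ("MQRankSum", "lt", self.mqranksum_min),
            ("ReadPosRankSum", "lt", self.readposranksum_min),
        ]


@dataclass(frozen=True)
class LdPruneParams:
    """PLINK-style ``--indep-pairwise`` parameters (counts of SNPs)."""

    window_snps: int = 50
    step_snps: int = 10
    r2_max: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.step_snps <= self.window_snps):
            raise ValueError("require 0 < step_snps <= window_snps")
        if not (0.0 <= self.r2_max <= 1.0):
            raise ValueError("require 0 <= r2_max <= 1")


def apply_hard_filters(
    gm: GenotypeMatrix, thresholds: HardFilterThresholds = HardFilterThresholds()
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop sites failing any hard-filter rule; report removals per rule.

    A site with a missing annotation for some rule is not removed by that
    rule.  Removal counts attribute a site to every rule it fails.
    """
    if gm.site_annotations is None:
        raise ValueError("genotype matrix has no site annotations (read with keep_info)")
    fail_any = np.zeros(gm.n_sites, dtype=bool)
    removed_per_rule: dict[str, int] = {}
    for key, direction, thr in thresholds.rules():
        values = gm.site_annotations.get(key)
        if values is None:
            removed_per_rule[key] = 0
            continue
        present = ~np.isnan(values)
        fails = present & (values < thr if direction == "lt" else values > thr)
        removed_per_rule[key] = int(fails.sum())
        fail_any |= fails
    return gm.take_sites(np.flatnonzero(~fail_any)), removed_per_rule


def site_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site minor allele frequency over called alleles (nan if none)."""
    called = gm.dosage != MISSING
    alt = np.where(called, gm.dosage, 0).sum(axis=1)
    n_alleles = 2 * called.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_alleles > 0, alt / n_alleles, np.nan)
    return np.minimum(p, 1.0 - p)


def filter_maf_callrate(
    gm: GenotypeMatrix, maf_min: float = 0.01, call_rate_min: float = 0.9
) -> GenotypeMatrix:
    """Keep sites with MAF strictly above ``maf_min`` and genotype call rate
    at least ``call_rate_min``.

    MAF uses called alleles only; sites with zero called genotypes are
    removed.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    maf = site_maf(gm)
    call_rate = (gm.dosage != MISSING).sum(axis=1) / gm.n_samples
    keep = np.nan_to_num(maf, nan=-1.0) > maf_min
    keep &= call_rate >= call_rate_min
    return gm.take_sites(np.flatnonzero(keep))


def ld_prune(
    gm: GenotypeMatrix, params: LdPruneParams = LdPruneParams()
) -> np.ndarray:
    """Greedy windowed LD pruning; returns kept site indices (sorted).

    Within each sliding window of ``window_snps`` consecutive sites
    (advancing by ``step_snps``, per chromosome), while some kept pair has
    r^2 above ``r2_max`` the lower-MAF member of the first offending pair
    (scanning in position order) is removed; ties remove the site at the
    larger position.  The postcondition — no within-window kept pair above
    threshold — is directly assertable on the output.
    """
    maf = site_maf(gm)
    keep = np.ones(gm.n_sites, dtype=bool)
    for c in np.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        # windows slide over the *surviving* sites, and removals shift later
        # windows, so passes repeat until a full sweep removes nothing; this
        # makes the no-pair-above-threshold postcondition hold on the output
        while True:
            live = idx[keep[idx]]
            removed = False
            start = 0
            while True:
                window = live[start : start + params.window_snps]
                if len(window) >= 2:
                    removed |= _prune_window(gm, window, keep, maf, params.r2_max)
                if start + params.window_snps >= len(live):
                    break
                start += params.step_snps
            if not removed:
                break
    return np.flatnonzero(keep)


def _prune_window(
    gm: GenotypeMatrix,
    window: np.ndarray,
    keep: np.ndarray,
    maf: np.ndarray,
    r2_max: float,
) -> bool:
    any_removed = False
    changed = True
    while changed:
        changed = False
        live = window[keep[window]]
        for ii in range(len(live) - 1):
            for jj in range(ii + 1, len(live)):
                si, sj = live[ii], live[jj]
                r2 = pairwise_r2(gm.dosage[si], gm.dosage[sj])
                if np.isnan(r2) or r2 <= r2_max:
                    continue
                # drop the lower-MAF member; tie -> larger position
                if maf[si] < maf[sj]:
                    keep[si] = False
                elif maf[sj] < maf[si]:
                    keep[sj] = False
                else:
                    keep[sj] = False
                changed = True
                any_removed = True
                break
            if changed:
                break
    return any_removed
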