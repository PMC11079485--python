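"""Molecular evolution of allele pairs: Nei-Gojobori (1986) Ka/Ks with
Jukes-Cantor correction, selection-class assignment, and differential
allele expression (DEA/EEA) calling.

The NG86 estimator counts, per codon, the fraction of the three possible
changes at each position that are synonymous (averaged over the two
sequences), resolves observed multi-position codon differences by
averaging over all equally weighted mutational pathways (pathways passing
through a stop codon are excluded), and corrects the proportions with the
Jukes-Cantor formula ``d = -(3/4) ln(1 - 4p/3)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "CodingPair",
    "ng86_ka_ks",
    "classify_selection",
    "classify_dea",
    "selection_summary",
    "synonymous_fraction",
]

_TABLE = unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"


@dataclass(frozen=True)
class CodingPair:
    """Two aligned in-frame CDS and their substitution-rate estimates."""

    pair_id: str
    cds_a: str
    cds_b: str
    ka: float = float("nan")
    ks: float = float("nan")
    ratio: float = float("nan")


def _validate_cds(seq: str, name: str) -> str:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
    for i in range(0, len(seq) - 3, 3):  # terminal stop permitted
        if seq[i : i + 3] in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon at {i}")
    return seq


def synonymous_fraction(codon: str) -> float:
    """Number of synonymous *sites* in a codon (0..3).

    Each position contributes the fraction of its three possible changes
    that preserve the amino acid; changes creating a stop codon count as
    nonsynonymous.
    """
    if codon in STOP_CODONS:
        raise ValueError("stop codon has no synonymous-site count")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
    return s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) difference counts over all
    equally weighted mutational pathways; None if every pathway passes
    through a stop codon."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_valid = 0
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                ok = False
                break
            if nxt in STOP_CODONS:  # endpoint is a (terminal) stop
                nonsyn += 1.0
            elif GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        if ok:
            syn_total += syn
            nonsyn_total += nonsyn
            n_valid += 1
    if n_valid == 0:
        return None
    return syn_total / n_valid, nonsyn_total / n_valid


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_ka_ks(cds_a: str, cds_b: str) -> tuple[float, float, float]:
    """NG86 (Ka, Ks, Ka/Ks) for one aligned in-frame CDS pair.

    Codons containing non-ACGT characters in either sequence are skipped
    pairwise, as are codon pairs whose every mutational pathway crosses a
    stop codon.  ``nan`` marks an undefined Ks (p_s >= 3/4), Ka, or ratio
    (Ks = 0 or undefined).
    """
    a = _validate_cds(cds_a, "cds_a")
    b = _validate_cds(cds_b, "cds_b")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    S = 0.0
    n_codons_used = 0
    syn_diff = 0.0
    nonsyn_diff = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue  # aligned terminal stop contributes no sites
        counts = _pathway_counts(ca, cb)
        if counts is None:
            continue
        S += (synonymous_fraction(ca) + synonymous_fraction(cb)) / 2.0
        n_codons_used += 1
        syn_diff += counts[0]
        nonsyn_diff += counts[1]
    if n_codons_used == 0:
        return float("nan"), float("nan"), float("nan")
    N = 3.0 * n_codons_used - S
    ps = syn_diff / S if S > 0 else float("nan")
    pn = nonsyn_diff / N if N > 0 else float("nan")
    ks = _jukes_cantor(ps) if not math.isnan(ps) else float("nan")
    ka = _jukes_cantor(pn) if not math.isnan(pn) else float("nan")
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        ratio = float("nan")
    else:
        ratio = ka / ks
    return ka, ks, ratio


def classify_selection(ratio: float) -> str:
    """Selection class from Ka/Ks: ``< 0.1`` purifying, ``> 1`` positive,
    in between (inclusive) intermediate; ``nan`` -> undefined."""
    if isinstance(ratio, float) and math.isnan(ratio):
        return "undefined"
    if ratio < 0:
        raise ValueError("Ka/Ks cannot be negative")
    if ratio < 0.1:
        return "purifying"
    if ratio > 1.0:
        return "positive"
    return "intermediate"


def classify_dea(
    expr_pairs: pd.DataFrame,
    lfc_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Label allele pairs DEA/EEA from per-stage expression.

    Expects columns ``pair_id, stage, expr_a, expr_b`` (normalized,
    non-negative).  Per stage, ``log2fc = log2((expr_a + c)/(expr_b + c))``
    with pseudocount ``c``; a pair is DEA iff *any* stage reaches
    ``|log2fc| >= lfc_threshold`` (inclusive), else EEA.  Returns one row
    per pair with ``max_abs_log2fc`` and ``label``.
    """
    required = {"pair_id", "stage", "expr_a", "expr_b"}
    if not required.issubset(expr_pairs.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    if (expr_pairs["expr_a"] < 0).any() or (expr_pairs["expr_b"] < 0).any():
        raise ValueError("negative expression value")
    df = expr_pairs.copy()
    df["log2fc"] = np.log2(
        (df["expr_a"] + pseudocount) / (df["expr_b"] + pseudocount)
    )
    per_pair = (
        df.groupby("pair_id", sort=True)["log2fc"]
        .agg(lambda x: float(np.max(np.abs(x))))
        .rename("max_abs_log2fc")
        .reset_index()
    )
    per_pair["label"] = np.where(
        per_pair["max_abs_log2fc"] >= lfc_threshold, "DEA", "EEA"
    )
    return per_pair


def selection_summary(labels: Iterable[str]) -> dict[str, float]:
    """Percentage of pairs per selection class.

    ``100 * count / total`` at full precision, over the four classes
    (absent classes report 0.0).  Percentages sum to 100.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no labels")
    classes = ("purifying", "intermediate", "positive", "undefined")
    unknown = set(labels) - set(classes)
    if unknown:
        raise ValueError(f"unknown selection classes: {sorted(unknown)}")
    total = len(labels)
    return {c: 100.0 * labels.count(c) / total for c in classes}
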