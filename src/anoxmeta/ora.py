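"""PageMan-style over-representation analysis of functional bins.

For each functional category (bin, at every level of the hierarchy) and
each direction (up- or down-regulated gene set, tested separately), a
two-sided Fisher exact test compares the bin's share of the DE set with
its share of the background.  The p-value is converted to a signed
z-score, z = Phi^-1(1 - p/2), positive for over-representation of the bin
in the DE set and negative for under-representation; |z| > 1.96
corresponds to p < 0.05 and flags significance.

The background is the set of genes that survived the detection filter in
the study at hand — enrichment is judged relative to what was measurable.
"""
from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .data import BinAnnotation, ValidationError
from .diffexpr import ContrastResults

__all__ = ["fisher_bin_test", "p_to_signed_z", "run_ora", "overrepresented_bins"]

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 1.96


def fisher_bin_test(k: int, K: int, n: int, N: int) -> float:
    """Two-sided Fisher exact probability for a bin membership table.

    ``k`` DE genes in the bin, ``K`` background genes in the bin, ``n`` DE
    genes total, ``N`` background genes total; the 2x2 table is
    ``[[k, n-k], [K-k, N-K-n+k]]`` and the two-sided p sums the
    hypergeometric probabilities of all tables (same margins) no more
    probable than the observed one.
    """
    for label, val in (("k", k), ("K", K), ("n", n), ("N", N)):
        if val < 0 or val != int(val):
            raise ValidationError(f"count {label}={val} must be a non-negative integer")
    if K > N:
        raise ValidationError(f"impossible table: K={K} exceeds N={N}")
    if n > N:
        raise ValidationError(f"impossible table: n={n} exceeds N={N}")
    if k > min(K, n):
        raise ValidationError(f"impossible table: k={k} exceeds min(K={K}, n={n})")
    if n - k > N - K:
        raise ValidationError(
            f"impossible table: n-k={n - k} DE genes outside the bin exceed N-K={N - K}"
        )
    if n == 0 or N == 0:
        return 1.0
    table = [[k, n - k], [K - k, N - K - n + k]]
    return float(min(1.0, stats.fisher_exact(table, alternative="two-sided")[1]))


def p_to_signed_z(p: float, over: bool) -> float:
    """Map a two-sided probability to a signed z-score.

    ``z = Phi^-1(1 - p/2)``, positive when the bin is over-represented and
    negative when under-represented; p = 1 maps to z = 0.
    """
    if p <= 0:
        raise ValidationError(f"p must be positive, got {p}")
    if p > 1:
        raise ValidationError(f"p must be <= 1, got {p}")
    z = float(stats.norm.isf(p / 2.0))
    if z == 0.0:  # p = 1: the observed table is the mode, no deviation
        return 0.0
    return z if over else -z


def run_ora(
    de_calls: ContrastResults,
    bins: BinAnnotation,
    background: Iterable[str],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    bonferroni: bool = False,
    contrast_name: str | None = None,
) -> pd.DataFrame:
    """Directional bin enrichment for one called contrast.

    Emits one row per (bin with >= 1 background member) x direction, with
    counts, the Fisher probability, the signed z and a significance flag.
    Genes count toward every ancestor of their bins.  With ``bonferroni``
    the probability is Bonferroni-adjusted across bins before the z
    conversion (off by default; the 1.96 rule alone is the standard here).
    """
    bg = set(background)
    if not bg:
        raise ValidationError("background gene set is empty")
    if len(bins) == 0:
        raise ValidationError("bin annotation is empty")
    sets = {"up": de_calls.up_genes(), "down": de_calls.down_genes()}
    for direction, genes in sets.items():
        stray = genes - bg
        if stray:
            raise ValidationError(
                f"{direction} DE set contains genes outside the background, e.g. "
                f"{sorted(stray)[:5]}"
            )
    if not (sets["up"] or sets["down"]):
        logger.warning(
            "empty DE set for contrast '%s': all z-scores will be 0",
            contrast_name or de_calls.name,
        )
    N = len(bg)
    tested = [
        (b, len(bins.bin_members(b) & bg))
        for b in bins.bins
        if len(bins.bin_members(b) & bg) > 0
    ]
    m = len(tested)
    rows = []
    for direction, de_set in sets.items():
        n = len(de_set)
        for b, K in tested:
            k = len(bins.bin_members(b) & de_set)
            p = fisher_bin_test(k, K, n, N)
            if bonferroni:
                p = min(1.0, p * m)
            if n == 0 or k * N == K * n:
                z = 0.0
            else:
                z = p_to_signed_z(p, over=(k * N > K * n))
            rows.append(
                {
                    "contrast": contrast_name or de_calls.name,
                    "direction": direction,
                    "bin": b,
                    "bin_name": bins.name_of(b),
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p": p,
                    "z": z,
                    "significant": abs(z) > z_threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contrast", "direction", "bin", "bin_name",
            "k", "K", "n", "N", "p", "z", "significant",
        ],
    )


def overrepresented_bins(
    ora_table: pd.DataFrame,
    direction: str,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    contrast: str | None = None,
) -> set[str]:
    """Bins significantly over-represented (z above +threshold) in the
    given direction's gene set, optionally within one contrast."""
    t = ora_table[ora_table["direction"] == direction]
    if contrast is not None:
        t = t[t["contrast"] == contrast]
    return set(t.loc[t["z"] > z_threshold, "bin"])
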