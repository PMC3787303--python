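"""Independent brute-force reimplementations used only as test oracles.

Deliberately naive: plain set algebra and exact rational arithmetic,
written without reference to the package implementations they check.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """Two-sided Fisher probability by exact enumeration of all tables
    with the same margins: sum hypergeometric P(X=x) over x with
    P(X=x) <= P(X=k)."""
    if n == 0 or N == 0:
        return Fraction(1)
    denom = comb(N, n)
    def pmf(x: int) -> Fraction:
        return Fraction(comb(K, x) * comb(N - K, n - x), denom)
    obs = pmf(k)
    lo, hi = max(0, n + K - N), min(n, K)
    return sum((pmf(x) for x in range(lo, hi + 1) if pmf(x) <= obs), Fraction(0))


def brute_conserved(per_study_bins: list[set[str]]) -> set[str]:
    out = set(per_study_bins[0])
    for s in per_study_bins[1:]:
        out &= s
    return out


def brute_condition_specific(target: set, coreq: set, excluded: list[set]) -> set:
    union_excluded = set()
    for e in excluded:
        union_excluded = union_excluded | e
    return (target & coreq) - union_excluded


def brute_species_classify(count_a: int, count_b: int, k_a: int, k_b: int) -> str:
    if count_a >= k_a and count_b == 0:
        return "a_only"
    if count_b >= k_b and count_a == 0:
        return "b_only"
    if count_a > 0 and count_b > 0:
        return "both"
    return "neither"


def brute_overlap(lowox_calls: list[dict], abiotic_calls: list[dict], mode: str):
    """Count matrix from per-contrast {gene: call} dicts."""
    mat = []
    for lc in lowox_calls:
        row = []
        for ac in abiotic_calls:
            if mode == "any_direction":
                l = {g for g, c in lc.items() if c in ("up", "down")}
                a = {g for g, c in ac.items() if c in ("up", "down")}
                row.append(len(l & a))
            else:
                n = 0
                for g, c in lc.items():
                    if c in ("up", "down") and ac.get(g) == c:
                        n += 1
                row.append(n)
        mat.append(row)
    return mat


def brute_markers(
    contrast_tables: list[dict],
    fold_min: float,
    k_min: int,
    abiotic_up: set[str],
    exclude: bool,
) -> set[str]:
    """contrast_tables: per contrast {gene: (call, linear_fold)}."""
    count: dict[str, int] = {}
    for table in contrast_tables:
        for g, (call, fold) in table.items():
            if call == "up" and fold > fold_min:
                count[g] = count.get(g, 0) + 1
    markers = {g for g, c in count.items() if c >= k_min}
    if exclude:
        markers -= abiotic_up
    return markers
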