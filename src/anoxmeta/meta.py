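"""Cross-study consensus rules: conserved, condition-specific and
species-specific categories, stress-overlap counts, and marker genes.

These operations consume per-contrast enrichment tables (from
:mod:`anoxmeta.ora`) and called contrast results (from
:mod:`anoxmeta.diffexpr`) grouped into study sets, and apply the
set-logic rules that summarize a compendium:

* conserved categories — over-represented in the same direction in every
  study of a set, with the step intervals where each study responded;
* condition-specific categories — over-represented in a target and a
  co-required comparison while absent from every excluded comparison;
* species consensus — per-bin classification into species-A-only,
  species-B-only, both or neither, using k-of-n quorums per species
  (a bin is species-specific only when the other species never shows it);
* overlap counts — sizes of DE-set intersections between low-oxygen and
  abiotic-stress comparisons;
* marker genes — genes induced above a large fold cutoff (50-fold by
  default) in a quorum of comparisons, optionally excluding genes
  up-regulated under any abiotic stress.

Throughout, "over-represented in a direction" means an enrichment row for
that direction's gene set with z above +threshold; significant
under-representation does not count.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import ValidationError
from .diffexpr import ContrastResults
from .ora import DEFAULT_Z_THRESHOLD

__all__ = [
    "StudyMember",
    "StudySet",
    "conserved_categories",
    "condition_specific_categories",
    "species_consensus",
    "classify_counts",
    "overlap_counts",
    "find_marker_genes",
]


@dataclass
class StudyMember:
    """One comparison of a study set: its contrast name plus the tables
    the consensus rules need (either may be omitted when unused)."""

    study_id: str
    contrast_name: str
    ora: pd.DataFrame | None = None
    de: ContrastResults | None = None


@dataclass
class StudySet:
    """A labelled collection of comparisons, e.g. 'rice low-oxygen'."""

    label: str
    members: list[StudyMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.contrast_name for m in self.members]
        if len(names) != len(set(names)):
            raise ValidationError(
                f"study set '{self.label}' has duplicate contrast names: {names}"
            )

    def __len__(self) -> int:
        return len(self.members)

    @property
    def contrast_names(self) -> list[str]:
        return [m.contrast_name for m in self.members]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _over_bins(
    ora: pd.DataFrame, direction: str, z_threshold: float, contrast: str | None = None
) -> set[str]:
    t = ora[ora["direction"] == direction]
    if contrast is not None:
        t = t[t["contrast"] == contrast]
    return set(t.loc[t["z"] > z_threshold, "bin"])


def _contrast_order(ora: pd.DataFrame) -> list[str]:
    seen: dict[str, None] = {}
    for c in ora["contrast"]:
        seen.setdefault(c, None)
    return list(seen)


# ---------------------------------------------------------------------------
# conserved categories (germination trio style)
# ---------------------------------------------------------------------------

def conserved_categories(
    ora_tables: Sequence[pd.DataFrame],
    direction: str,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    timing_pair: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Bins over-represented in ``direction`` in every table.

    Each table holds one study's enrichment rows across its (possibly
    step-wise) contrasts; a bin qualifies when every study shows it in at
    least one contrast.  The result carries, per study, the list of
    contrast names and step-interval indices where the bin responded, and
    ``timing_match`` — whether the two studies named by ``timing_pair``
    (indices into ``ora_tables``) share a responding interval index.
    """
    if len(ora_tables) < 2:
        raise ValidationError("need at least two enrichment tables for a consensus")
    per_study_over = [_over_bins(t, direction, z_threshold) for t in ora_tables]
    common = set.intersection(*per_study_over) if per_study_over else set()
    orders = [_contrast_order(t) for t in ora_tables]
    rows = []
    for b in sorted(common):
        row: dict = {"bin": b, "direction": direction}
        interval_sets: list[set[int]] = []
        for i, (t, order) in enumerate(zip(ora_tables, orders)):
            hits = [
                c for c in order if b in _over_bins(t, direction, z_threshold, contrast=c)
            ]
            idx = {order.index(c) for c in hits}
            interval_sets.append(idx)
            row[f"study{i}_contrasts"] = ";".join(hits)
            row[f"study{i}_intervals"] = ";".join(str(j) for j in sorted(idx))
        if timing_pair is not None:
            i, j = timing_pair
            row["timing_match"] = bool(interval_sets[i] & interval_sets[j])
        else:
            row["timing_match"] = pd.NA
        rows.append(row)
    cols = ["bin", "direction"]
    for i in range(len(ora_tables)):
        cols += [f"study{i}_contrasts", f"study{i}_intervals"]
    cols.append("timing_match")
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# condition-specific categories
# ---------------------------------------------------------------------------

def condition_specific_categories(
    target_ora: pd.DataFrame,
    corequired_ora: pd.DataFrame,
    excluded_ora: Sequence[pd.DataFrame],
    direction: str,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> set[str]:
    """Bins over-represented in the target AND the co-required comparison
    while over-represented in NONE of the excluded ones (same direction):
    (T ∩ C) \\ ∪E."""
    target = _over_bins(target_ora, direction, z_threshold)
    coreq = _over_bins(corequired_ora, direction, z_threshold)
    excluded: set[str] = set()
    for t in excluded_ora:
        excluded |= _over_bins(t, direction, z_threshold)
    return (target & coreq) - excluded


# ---------------------------------------------------------------------------
# species consensus
# ---------------------------------------------------------------------------

def classify_counts(count_a: int, count_b: int, k_a: int, k_b: int) -> str:
    """Classify one bin from its per-species significant-comparison counts.

    ``a_only`` needs the k_a quorum in species A and zero hits in B;
    ``b_only`` symmetric; ``both`` needs at least one hit per species;
    anything else is ``neither``.
    """
    if count_a >= k_a and count_b == 0:
        return "a_only"
    if count_b >= k_b and count_a == 0:
        return "b_only"
    if count_a >= 1 and count_b >= 1:
        return "both"
    return "neither"


def species_consensus(
    set_a: StudySet,
    set_b: StudySet,
    k_a: int = 3,
    k_b: int = 4,
    directions: Sequence[str] = ("up", "down"),
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Per-bin, per-direction classification {a_only, b_only, both, neither}.

    ``k_a``/``k_b`` are the species-specific quorums (3-of-4 and 4-of-5 by
    default, matching four comparisons in one species and five in the
    other).
    """
    if k_a > len(set_a) or k_b > len(set_b):
        raise ValidationError(
            f"quorum exceeds set size: k_a={k_a} vs {len(set_a)}, k_b={k_b} vs {len(set_b)}"
        )
    rows = []
    for direction in directions:
        bins_a = [
            _over_bins(m.ora, direction, z_threshold) if m.ora is not None else set()
            for m in set_a.members
        ]
        bins_b = [
            _over_bins(m.ora, direction, z_threshold) if m.ora is not None else set()
            for m in set_b.members
        ]
        universe = set().union(*bins_a, *bins_b) if (bins_a or bins_b) else set()
        for b in sorted(universe):
            ca = sum(b in s for s in bins_a)
            cb = sum(b in s for s in bins_b)
            rows.append(
                {
                    "bin": b,
                    "direction": direction,
                    "count_a": ca,
                    "count_b": cb,
                    "classification": classify_counts(ca, cb, k_a, k_b),
                }
            )
    return pd.DataFrame(
        rows, columns=["bin", "direction", "count_a", "count_b", "classification"]
    )


# ---------------------------------------------------------------------------
# overlap counts
# ---------------------------------------------------------------------------

def overlap_counts(
    lowox: StudySet, abiotic: StudySet, mode: str = "any_direction"
) -> pd.DataFrame:
    """Count matrix of shared DE genes, low-oxygen contrasts x stresses.

    ``any_direction`` intersects the full DE sets; ``matched`` counts only
    genes called in the same direction in both comparisons.  Contrast
    orientation is assumed applied upstream, so "up" always means the
    response to the stress.
    """
    if mode not in ("any_direction", "matched"):
        raise ValidationError("mode must be 'any_direction' or 'matched'")
    mat = np.zeros((len(lowox), len(abiotic)), dtype=int)
    for i, lm in enumerate(lowox.members):
        if lm.de is None:
            raise ValidationError(f"member '{lm.contrast_name}' lacks contrast results")
        for j, am in enumerate(abiotic.members):
            if am.de is None:
                raise ValidationError(f"member '{am.contrast_name}' lacks contrast results")
            if mode == "any_direction":
                mat[i, j] = len(lm.de.de_genes() & am.de.de_genes())
            else:
                mat[i, j] = len(lm.de.up_genes() & am.de.up_genes()) + len(
                    lm.de.down_genes() & am.de.down_genes()
                )
    return pd.DataFrame(mat, index=lowox.contrast_names, columns=abiotic.contrast_names)


# ---------------------------------------------------------------------------
# marker genes
# ---------------------------------------------------------------------------

def find_marker_genes(
    lowox: StudySet,
    fold_min: float = 50.0,
    k_min: int = 2,
    abiotic: StudySet | None = None,
    exclude_abiotic_up: bool = True,
) -> pd.DataFrame:
    """Strongly induced low-oxygen marker genes.

    A marker is called up with linear fold > ``fold_min`` in at least
    ``k_min`` of the set's comparisons; with ``exclude_abiotic_up`` any
    gene called up in any abiotic comparison is removed.  Output columns:
    gene, species (the set label), n_passing, max_fold, abiotic_up;
    sorted by n_passing then max_fold, descending.
    """
    lfc_min = np.log2(fold_min)
    passing: dict[str, list[float]] = {}
    for m in lowox.members:
        if m.de is None:
            raise ValidationError(f"member '{m.contrast_name}' lacks contrast results")
        t = m.de.table
        hit = t.index[(t["call"] == "up") & (t["log2fc"] > lfc_min)]
        for g in hit:
            passing.setdefault(g, []).append(float(2.0 ** t.at[g, "log2fc"]))
    abiotic_up: set[str] = set()
    if abiotic is not None:
        for m in abiotic.members:
            if m.de is None:
                raise ValidationError(f"member '{m.contrast_name}' lacks contrast results")
            abiotic_up |= m.de.up_genes()
    rows = []
    for g, folds in passing.items():
        if len(folds) < k_min:
            continue
        is_abiotic_up = g in abiotic_up
        if exclude_abiotic_up and is_abiotic_up:
            continue
        rows.append(
            {
                "gene": g,
                "species": lowox.label,
                "n_passing": len(folds),
                "max_fold": max(folds),
                "abiotic_up": is_abiotic_up,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "species", "n_passing", "max_fold", "abiotic_up"])
    if not df.empty:
        df = df.sort_values(
            ["n_passing", "max_fold", "gene"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return df
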