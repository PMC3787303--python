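"""Core containers: expression studies, detection calls, functional bins.

The pipeline operates on already-normalized log2 expression matrices
(genes x samples) with a replicated two-or-more condition design, optional
MAS5-style present/marginal/absent detection calls, and a MapMan-style
hierarchical functional-category ("bin") annotation in which a gene's
membership in a bin implies membership in every ancestor bin.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a structural contract (duplicate ids, misaligned
    dimensions, non-finite values, inconsistent design)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending cell."""


PRESENCE_POLICIES = ("any_sample", "all_samples", "all_reps_of_any_condition")

#: cell codes for detection calls
PRESENT, MARGINAL, ABSENT = "present", "marginal", "absent"
_CALL_CODES = {"P": PRESENT, "M": MARGINAL, "A": ABSENT}
_CODE_OF = {v: k for k, v in _CALL_CODES.items()}


@dataclass
class ExpressionStudy:
    """A replicated, normalized (log2) expression matrix plus its design.

    Parameters
    ----------
    study_id : str
        Label for the study (used in contrast provenance).
    values : pandas.DataFrame
        genes x samples matrix of log2 normalized intensities.
    design : pandas.DataFrame
        Indexed by sample id, with columns ``condition`` (label),
        ``timepoint`` (ordinal rank within a series, nullable) and
        ``replicate`` (index within condition).
    """

    study_id: str
    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        v, d = self.values, self.design
        dup = v.index[v.index.duplicated()].tolist()
        if dup:
            raise ValidationError(
                f"duplicate gene id(s) in study '{self.study_id}': {sorted(set(dup))}"
            )
        dup_s = v.columns[v.columns.duplicated()].tolist()
        if dup_s:
            raise ValidationError(f"duplicate sample id(s): {sorted(set(dup_s))}")
        for col in ("condition", "replicate"):
            if col not in d.columns:
                raise ValidationError(f"design table lacks required column '{col}'")
        d = d.copy()
        if "timepoint" not in d.columns:
            d["timepoint"] = pd.array([pd.NA] * len(d), dtype="Int64")
        else:
            d["timepoint"] = pd.array(
                pd.to_numeric(d["timepoint"], errors="coerce"), dtype="Int64"
            )
        self.design = d
        missing = [s for s in v.columns if s not in d.index]
        if missing:
            raise ValidationError(f"samples in matrix but not in design: {missing}")
        extra = [s for s in d.index if s not in v.columns]
        if extra:
            raise ValidationError(f"samples in design but not in matrix: {extra}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene '{v.index[bad[0]]}', "
                f"sample '{v.columns[bad[1]]}'"
            )
        # keep design in matrix sample order
        self.design = d.loc[list(v.columns)]

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.design["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        mask = self.design["condition"] == condition
        return list(self.design.index[mask])

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionStudy":
        """Restrict to ``genes``, preserving this study's gene order."""
        keep = set(genes)
        order = [g for g in self.values.index if g in keep]
        return ExpressionStudy(self.study_id, self.values.loc[order], self.design.copy())

    def equals(self, other: "ExpressionStudy") -> bool:
        return (
            self.study_id == other.study_id
            and self.values.equals(other.values)
            and self.design[["condition", "timepoint", "replicate"]].equals(
                other.design[["condition", "timepoint", "replicate"]]
            )
        )


@dataclass
class PresenceCalls:
    """MAS5-style detection verdicts aligned to an :class:`ExpressionStudy`.

    ``calls`` holds one of ``present|marginal|absent`` per (gene, sample);
    ``detection_p`` the corresponding detection p-value.  A cell is called
    present when its detection p-value is below the detection alpha
    (0.05 by default upstream of this container).
    """

    calls: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        c, p = self.calls, self.detection_p
        if list(c.index) != list(p.index) or list(c.columns) != list(p.columns):
            raise ValidationError("calls and detection_p are not aligned")
        bad = set(np.unique(c.to_numpy().astype(str))) - {PRESENT, MARGINAL, ABSENT}
        if bad:
            raise ValidationError(f"unknown call value(s): {sorted(bad)}")
        arr = p.to_numpy(dtype=float)
        if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
            raise ValidationError("detection p-values must lie in [0, 1]")

    @classmethod
    def from_detection_p(cls, detection_p: pd.DataFrame, alpha: float = 0.05) -> "PresenceCalls":
        """Derive calls from detection p-values: present iff p < alpha."""
        calls = detection_p.map(lambda q: PRESENT if q < alpha else ABSENT)
        return cls(calls=calls, detection_p=detection_p)

    def check_aligned(self, study: ExpressionStudy) -> None:
        if list(self.calls.index) != study.gene_ids or list(self.calls.columns) != study.sample_ids:
            raise ValidationError(
                "presence calls are not aligned to the study "
                f"({self.calls.shape} vs {study.values.shape})"
            )

    def present_mask(self) -> pd.DataFrame:
        """Boolean genes x samples mask; marginal counts as not-present."""
        return self.calls == PRESENT


def apply_presence_filter(
    study: ExpressionStudy,
    calls: PresenceCalls,
    policy: str = "all_reps_of_any_condition",
) -> ExpressionStudy:
    """Drop genes that were not reliably detected.

    Policies
    --------
    ``any_sample``
        keep a gene called present in at least one sample;
    ``all_samples``
        present in every sample;
    ``all_reps_of_any_condition``
        present in every replicate of at least one condition (default: the
        least biased toward either side of a contrast).
    """
    if policy not in PRESENCE_POLICIES:
        raise ValidationError(f"unknown presence policy '{policy}'; one of {PRESENCE_POLICIES}")
    calls.check_aligned(study)
    present = calls.present_mask().to_numpy(dtype=bool)
    if policy == "any_sample":
        keep = present.any(axis=1)
    elif policy == "all_samples":
        keep = present.all(axis=1)
    else:
        keep = np.zeros(study.n_genes, dtype=bool)
        for cond in study.conditions:
            cols = [study.sample_ids.index(s) for s in study.samples_for(cond)]
            keep |= present[:, cols].all(axis=1)
    kept = [g for g, k in zip(study.gene_ids, keep) if k]
    return study.subset_genes(kept)


# ---------------------------------------------------------------------------
# Hierarchical functional-category annotation
# ---------------------------------------------------------------------------

def bin_ancestors(path: str) -> list[str]:
    """Proper ancestors of a dotted bin path, nearest first.

    >>> bin_ancestors("10.2.1")
    ['10.2', '10']
    """
    parts = _split_bin_path(path)
    return [".".join(parts[:i]) for i in range(len(parts) - 1, 0, -1)]


def _split_bin_path(path: str) -> list[str]:
    parts = str(path).split(".")
    if any(p.strip() == "" for p in parts):
        raise ParseError(f"malformed bin path '{path}' (empty segment)")
    return parts


class BinAnnotation:
    """Hierarchical gene -> functional-bin membership (MapMan style).

    Bins are dotted paths ("10.2.1"); membership of a gene in a bin implies
    membership in every ancestor bin, which :meth:`bin_members` materializes.
    """

    def __init__(
        self,
        bin_names: Mapping[str, str] | None = None,
        membership: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        names = dict(bin_names or {})
        members: dict[str, set[str]] = {g: set(bins) for g, bins in (membership or {}).items()}
        # validate paths and add implied ancestors to the tree
        all_paths = set(names)
        for bins in members.values():
            all_paths.update(bins)
        for path in list(all_paths):
            for anc in bin_ancestors(path):
                if anc not in names:
                    names.setdefault(anc, anc)
            names.setdefault(path, names.get(path, path))
        self.bin_names: dict[str, str] = names
        self.membership: dict[str, set[str]] = {g: set(b) for g, b in members.items() if b}

    @property
    def bins(self) -> list[str]:
        """All bin paths (including implied ancestors), sorted."""
        return sorted(self.bin_names)

    @property
    def genes(self) -> set[str]:
        return set(self.membership)

    def bins_for_gene(self, gene: str, with_ancestors: bool = True) -> set[str]:
        direct = self.membership.get(gene, set())
        if not with_ancestors:
            return set(direct)
        out = set(direct)
        for b in direct:
            out.update(bin_ancestors(b))
        return out

    @cached_property
    def _members_closure(self) -> dict[str, frozenset[str]]:
        acc: dict[str, set[str]] = {b: set() for b in self.bin_names}
        for gene, bins in self.membership.items():
            for b in bins:
                acc[b].add(gene)
                for anc in bin_ancestors(b):
                    acc[anc].add(gene)
        return {b: frozenset(g) for b, g in acc.items()}

    def bin_members(self, bin_path: str) -> frozenset[str]:
        """Genes in ``bin_path`` or any of its descendants."""
        try:
            return self._members_closure[bin_path]
        except KeyError:
            raise KeyError(f"unknown bin '{bin_path}'") from None

    def name_of(self, bin_path: str) -> str:
        return self.bin_names.get(bin_path, bin_path)

    def __len__(self) -> int:
        return len(self.bin_names)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinAnnotation)
            and self.bin_names == other.bin_names
            and self.membership == other.membership
        )
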