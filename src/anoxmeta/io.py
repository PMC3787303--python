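"""Tab-separated readers and writers for every pipeline input and output.

Dialect: tab-separated, UTF-8, "." decimal, no quoting.  Expression
matrices carry sample ids in the header row and gene ids in the first
column (the first header cell is ignored on read).  Detection calls are
accepted either as a single combined file with ``P:0.003``-style
``call:p`` cells or as two parallel files (letter calls + p-values).
"""
from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .data import (
    _CALL_CODES,
    _CODE_OF,
    BinAnnotation,
    ExpressionStudy,
    ParseError,
    PresenceCalls,
    ValidationError,
)


def _read_tsv(path: str, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise ParseError(f"could not parse '{path}': {exc}") from exc


def _to_numeric_matrix(df: pd.DataFrame, path: str) -> pd.DataFrame:
    try:
        # astype goes through float(), which parses correctly rounded
        return df.astype(float)
    except (TypeError, ValueError):
        num = df.apply(pd.to_numeric, errors="coerce")
        bad = num.isna().to_numpy()
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"non-numeric cell in '{path}' at row '{df.index[r]}', column '{df.columns[c]}': "
            f"'{df.iat[r, c]}'"
        ) from None


def read_expression_study(
    matrix_path: str,
    design_path: str,
    study_id: str | None = None,
    linear_scale: bool = False,
    log_floor: float = 1.0,
) -> ExpressionStudy:
    """Read a genes x samples matrix TSV plus its sample-design TSV.

    ``linear_scale=True`` declares linear-intensity input and triggers a
    log2 transform after flooring values at ``log_floor`` (guards zeros).
    Gene and sample order is preserved from the files.
    """
    raw = _read_tsv(matrix_path, index_col=0)
    dup = raw.index[raw.index.duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate gene id(s) in '{matrix_path}': {sorted(set(dup))}")
    values = _to_numeric_matrix(raw, matrix_path)
    if linear_scale:
        values = np.log2(values.clip(lower=log_floor))
    design = _read_tsv(design_path)
    for col in ("sample", "condition", "replicate"):
        if col not in design.columns:
            raise ValidationError(f"design file '{design_path}' lacks column '{col}'")
    design = design.set_index("sample")
    design["replicate"] = pd.to_numeric(design["replicate"]).astype(int)
    if "timepoint" in design.columns:
        design["timepoint"] = pd.array(
            [int(t) if str(t).strip() not in ("", "NA", "nan") else pd.NA for t in design["timepoint"]],
            dtype="Int64",
        )
    if study_id is None:
        study_id = os.path.splitext(os.path.basename(matrix_path))[0]
    return ExpressionStudy(study_id=study_id, values=values, design=design)


def write_expression_study(study: ExpressionStudy, matrix_path: str, design_path: str) -> None:
    out = study.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    d = study.design.copy()
    d.index.name = "sample"
    cols = ["condition", "timepoint", "replicate"]
    d[cols].to_csv(design_path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Detection calls
# ---------------------------------------------------------------------------

def read_presence_calls(path: str, p_path: str | None = None) -> PresenceCalls:
    """Read detection calls.

    With only ``path``: combined cells like ``P:0.003`` (call letter, colon,
    detection p).  With ``p_path``: ``path`` holds letter calls (P/M/A) and
    ``p_path`` the parallel numeric detection p-values.
    """
    raw = _read_tsv(path, index_col=0)
    if p_path is not None:
        codes = raw
        pvals = _to_numeric_matrix(_read_tsv(p_path, index_col=0), p_path)
    else:
        codes = raw.copy()
        pvals = raw.copy()
        for col in raw.columns:
            split = raw[col].str.split(":", n=1, expand=True)
            if split.shape[1] != 2 or split.isna().any().any():
                bad = raw[col][split.isna().any(axis=1)] if split.shape[1] == 2 else raw[col]
                raise ParseError(
                    f"malformed call cell in '{path}' column '{col}': "
                    f"expected 'P:0.003' style, got '{bad.iloc[0]}'"
                )
            codes[col] = split[0]
            pvals[col] = split[1]
        pvals = _to_numeric_matrix(pvals, path)
    unknown = set(np.unique(codes.to_numpy().astype(str))) - set(_CALL_CODES)
    if unknown:
        raise ParseError(f"unknown call code(s) in '{path}': {sorted(unknown)}")
    calls = codes.map(_CALL_CODES.get)
    return PresenceCalls(calls=calls, detection_p=pvals)


def write_presence_calls(calls: PresenceCalls, path: str) -> None:
    """Write combined ``P:0.003``-style call cells."""
    code = calls.calls.map(_CODE_OF.get)
    p = calls.detection_p
    combined = code + ":" + p.map(lambda q: format(q, "g"))
    combined.index.name = "gene_id"
    combined.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Functional-bin annotation
# ---------------------------------------------------------------------------

def read_bin_annotation(path: str) -> BinAnnotation:
    """Read a MapMan-style TSV with columns bin_path, bin_name, gene_id.

    Rows with an empty gene_id define a bin without members.  Duplicate
    (gene, bin) rows are deduplicated; all implied ancestor bins are added.
    """
    df = _read_tsv(path)
    if df.empty and list(df.columns) in ([], ["bin_path", "bin_name", "gene_id"]):
        return BinAnnotation()
    for col in ("bin_path", "bin_name", "gene_id"):
        if col not in df.columns:
            raise ParseError(f"bin annotation '{path}' lacks column '{col}'")
    names: dict[str, str] = {}
    membership: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        bpath = str(row["bin_path"]).strip()
        names.setdefault(bpath, str(row["bin_name"]).strip() or bpath)
        gene = str(row["gene_id"]).strip()
        if gene:
            membership.setdefault(gene, set()).add(bpath)
    return BinAnnotation(bin_names=names, membership=membership)


def write_bin_annotation(bins: BinAnnotation, path: str) -> None:
    rows = []
    for gene in sorted(bins.membership):
        for b in sorted(bins.membership[gene]):
            rows.append((b, bins.name_of(b), gene))
    member_bins = {r[0] for r in rows}
    for b in sorted(bins.bin_names):
        if b not in member_bins:
            rows.append((b, bins.name_of(b), ""))
    pd.DataFrame(rows, columns=["bin_path", "bin_name", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )
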