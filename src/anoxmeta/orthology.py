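"""Cross-species ortholog maps and projection of contrast results.

Ortholog relations arrive as two independent pair tables — one from a
sequence-similarity resource, one Inparanoid-style — and are combined by
union: a pair supported by either source (or both) is accepted.  The map
is many-to-many and direction-agnostic; similarity percentages are
carried as annotation only, never as a filter.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ValidationError
from .diffexpr import ContrastResults

__all__ = [
    "OrthologTable",
    "OrthologMap",
    "union_orthologs",
    "map_genes",
    "project_contrasts",
    "read_ortholog_table",
    "write_ortholog_map",
]

PROVENANCES = ("similarity", "inparanoid", "both")


@dataclass(frozen=True)
class OrthologTable:
    """One evidence source of cross-species gene pairs."""

    species_a: str
    species_b: str
    source: str  # "similarity" or "inparanoid"
    pairs: tuple[tuple[str, str, float | None], ...]  # (gene_a, gene_b, pct_identity)

    def __post_init__(self) -> None:
        if self.source not in ("similarity", "inparanoid"):
            raise ValidationError(
                f"source must be 'similarity' or 'inparanoid', got '{self.source}'"
            )
        object.__setattr__(
            self,
            "pairs",
            tuple((a, b, None if pct is None else float(pct)) for a, b, pct in self.pairs),
        )

    def pair_keys(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.pairs}


@dataclass
class OrthologMap:
    """Many-to-many cross-species pairs with evidence provenance.

    ``pairs`` maps (gene_a, gene_b) to a dict with ``provenance`` in
    {similarity, inparanoid, both} and optional ``pct_identity``.
    """

    species_a: str
    species_b: str
    pairs: dict[tuple[str, str], dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def provenance_counts(self) -> dict[str, int]:
        out = {p: 0 for p in PROVENANCES}
        for meta in self.pairs.values():
            out[meta["provenance"]] += 1
        return out

    def orthologs_of(self, gene: str, species: str | None = None) -> set[str]:
        """Partners of ``gene``; ``species`` names the side the gene is on
        (defaults to searching both sides, consistent either way)."""
        out: set[str] = set()
        if species in (None, self.species_a):
            out |= {b for (a, b) in self.pairs if a == gene}
        if species in (None, self.species_b):
            out |= {a for (a, b) in self.pairs if b == gene}
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_a": a,
                "gene_b": b,
                "provenance": meta["provenance"],
                "pct_identity": meta.get("pct_identity"),
            }
            for (a, b), meta in sorted(self.pairs.items())
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "provenance", "pct_identity"])


def union_orthologs(source_sim: OrthologTable, source_inp: OrthologTable) -> OrthologMap:
    """Union the two evidence sources: a pair found by one or both methods
    is an ortholog pair; provenance records which source(s) supplied it."""
    if (source_sim.species_a, source_sim.species_b) != (
        source_inp.species_a,
        source_inp.species_b,
    ):
        raise ValidationError(
            "inconsistent species labels: "
            f"({source_sim.species_a}, {source_sim.species_b}) vs "
            f"({source_inp.species_a}, {source_inp.species_b})"
        )
    sim_keys = source_sim.pair_keys()
    inp_keys = source_inp.pair_keys()
    pct: dict[tuple[str, str], float | None] = {}
    for a, b, val in (*source_inp.pairs, *source_sim.pairs):  # similarity pct wins
        if val is not None or (a, b) not in pct:
            pct[(a, b)] = val
    pairs: dict[tuple[str, str], dict] = {}
    for key in sim_keys | inp_keys:
        if key in sim_keys and key in inp_keys:
            prov = "both"
        elif key in sim_keys:
            prov = "similarity"
        else:
            prov = "inparanoid"
        pairs[key] = {"provenance": prov, "pct_identity": pct.get(key)}
    return OrthologMap(source_sim.species_a, source_sim.species_b, pairs)


def map_genes(
    genes: Iterable[str], omap: OrthologMap, species: str | None = None
) -> dict[str, set[str]]:
    """Map each gene to its (possibly empty) ortholog set; one-to-many is
    preserved in full and genes absent from the map get an empty set."""
    return {g: omap.orthologs_of(g, species=species) for g in genes}


def project_contrasts(
    genes: Iterable[str],
    omap: OrthologMap,
    foreign_results: Sequence[ContrastResults] | Mapping[str, ContrastResults],
    species: str | None = None,
) -> pd.DataFrame:
    """Expression of the orthologs of ``genes`` in the partner species.

    One row per (source gene, ortholog) with the ortholog's log2fc and
    call in every foreign contrast.  Orthologs absent from a foreign
    result are reported as ``not_detected`` — distinct from ``ns``.
    """
    if isinstance(foreign_results, Mapping):
        named = list(foreign_results.items())
    else:
        named = [(r.name, r) for r in foreign_results]
    rows = []
    for gene in genes:
        for orth in sorted(omap.orthologs_of(gene, species=species)):
            row: dict = {"source_gene": gene, "ortholog": orth}
            for cname, res in named:
                if orth in res.table.index:
                    row[f"{cname}:log2fc"] = float(res.table.at[orth, "log2fc"])
                    call = res.table.at[orth, "call"]
                    row[f"{cname}:call"] = call if isinstance(call, str) else "ns"
                else:
                    row[f"{cname}:log2fc"] = np.nan
                    row[f"{cname}:call"] = "not_detected"
            rows.append(row)
    cols = ["source_gene", "ortholog"]
    for cname, _ in named:
        cols += [f"{cname}:log2fc", f"{cname}:call"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

def read_ortholog_table(
    path: str, species_a: str, species_b: str, source: str
) -> OrthologTable:
    """Read a pair table TSV with columns gene_a, gene_b and optional
    pct_identity."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise ValidationError(f"ortholog table '{path}' lacks column '{col}'")
    pairs = []
    for _, row in df.iterrows():
        pct = row.get("pct_identity", "")
        pairs.append(
            (row["gene_a"], row["gene_b"], float(pct) if str(pct).strip() else None)
        )
    return OrthologTable(species_a, species_b, source, tuple(pairs))


def write_ortholog_table(table: OrthologTable, path: str) -> None:
    pd.DataFrame(
        [(a, b, "" if pct is None else format(pct, "g")) for a, b, pct in table.pairs],
        columns=["gene_a", "gene_b", "pct_identity"],
    ).to_csv(path, sep="\t", index=False)


def write_ortholog_map(omap: OrthologMap, path: str) -> None:
    """Write the unioned map; the provenance column is mandatory output."""
    omap.to_frame().to_csv(path, sep="\t", index=False, na_rep="")
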