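"""End-to-end orchestration: detection filter -> regularized DE -> PPDE ->
calls -> enrichment -> consensus/markers/overlap.

These helpers connect the stage modules for the common designs (a set of
treatment-vs-control contrasts per species); each stage remains usable on
its own.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .data import BinAnnotation, ExpressionStudy, PresenceCalls, apply_presence_filter
from .diffexpr import (
    ContrastResults,
    ContrastSpec,
    CyberT,
    CyberTParams,
    Thresholds,
)
from .meta import (
    StudyMember,
    StudySet,
    find_marker_genes,
    overlap_counts,
    species_consensus,
)
from .ora import run_ora
from .orthology import OrthologMap, union_orthologs
from .synthetic import SpeciesPairFixture

__all__ = [
    "run_contrast",
    "contrasts_vs_control",
    "build_study_set",
    "SpeciesPairResults",
    "run_species_pair",
]


def run_contrast(
    study: ExpressionStudy,
    spec: ContrastSpec,
    params: CyberTParams | None = None,
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
) -> ContrastResults:
    """Fit the regularized t, attach PPDE and apply the three-part call."""
    return CyberT(study, spec, params).fit().add_ppde(seed=seed).with_calls(thresholds)


def contrasts_vs_control(
    study: ExpressionStudy,
    conditions: Sequence[str],
    control: str = "control",
    orientation: int = 1,
) -> list[ContrastSpec]:
    """One spec per condition, each against the shared control group."""
    ctrl = tuple(study.samples_for(control))
    return [
        ContrastSpec(
            study_id=study.study_id,
            name=f"{cond} v {control}",
            group_a=ctrl,
            group_b=tuple(study.samples_for(cond)),
            orientation=orientation,
        )
        for cond in conditions
    ]


def build_study_set(
    label: str,
    study: ExpressionStudy,
    specs: Sequence[ContrastSpec],
    bins: BinAnnotation | None = None,
    params: CyberTParams | None = None,
    thresholds: Thresholds = Thresholds(),
    z_threshold: float = 1.96,
    seed: int = 0,
) -> StudySet:
    """Run DE (and enrichment, when ``bins`` is given) for every spec."""
    members = []
    background = study.gene_ids
    for spec in specs:
        de = run_contrast(study, spec, params, thresholds, seed=seed)
        ora = (
            run_ora(de, bins, background, z_threshold=z_threshold, contrast_name=spec.name)
            if bins is not None
            else None
        )
        members.append(
            StudyMember(study_id=study.study_id, contrast_name=spec.name, ora=ora, de=de)
        )
    return StudySet(label=label, members=members)


@dataclass
class SpeciesPairResults:
    """All cross-species outputs for one two-species compendium."""

    lowox_a: StudySet
    lowox_b: StudySet
    abiotic_a: StudySet
    abiotic_b: StudySet
    ortholog_map: OrthologMap
    consensus: pd.DataFrame
    markers_a: pd.DataFrame
    markers_b: pd.DataFrame
    overlap_a: pd.DataFrame
    overlap_b: pd.DataFrame
    overlap_a_matched: pd.DataFrame
    overlap_b_matched: pd.DataFrame


def run_species_pair(
    fixture: SpeciesPairFixture,
    params: CyberTParams | None = None,
    thresholds: Thresholds = Thresholds(),
    presence_policy: str = "all_reps_of_any_condition",
    z_threshold: float = 1.96,
    consensus_k_a: int = 3,
    consensus_k_b: int = 4,
    marker_fold: float = 50.0,
    marker_k_a: int = 2,
    marker_k_b: int = 3,
    exclude_abiotic_up_a: bool = True,
    exclude_abiotic_up_b: bool = False,
    seed: int = 0,
) -> SpeciesPairResults:
    """The full cross-species chain on a two-species fixture.

    Defaults mirror the compendium conventions: species-specific quorums
    3-of-4 / 4-of-5; marker rule >50-fold in >=2 comparisons with abiotic
    exclusion for species A, >=3 without exclusion for species B.
    """
    study_a = apply_presence_filter(fixture.study_a, fixture.calls_a, presence_policy)
    study_b = apply_presence_filter(fixture.study_b, fixture.calls_b, presence_policy)

    def sets_for(study, lowox_conds, bins, label):
        low = build_study_set(
            f"{label} low-oxygen",
            study,
            contrasts_vs_control(study, lowox_conds),
            bins=bins,
            params=params,
            thresholds=thresholds,
            z_threshold=z_threshold,
            seed=seed,
        )
        abi = build_study_set(
            f"{label} abiotic",
            study,
            contrasts_vs_control(study, fixture.abiotic_conditions),
            bins=None,
            params=params,
            thresholds=thresholds,
            seed=seed,
        )
        return low, abi

    lowox_a, abiotic_a = sets_for(
        study_a, fixture.lowox_conditions_a, fixture.bins_a, fixture.species_a
    )
    lowox_b, abiotic_b = sets_for(
        study_b, fixture.lowox_conditions_b, fixture.bins_b, fixture.species_b
    )

    consensus = species_consensus(
        lowox_a, lowox_b, k_a=consensus_k_a, k_b=consensus_k_b, z_threshold=z_threshold
    )
    markers_a = find_marker_genes(
        lowox_a, fold_min=marker_fold, k_min=marker_k_a,
        abiotic=abiotic_a, exclude_abiotic_up=exclude_abiotic_up_a,
    )
    markers_b = find_marker_genes(
        lowox_b, fold_min=marker_fold, k_min=marker_k_b,
        abiotic=abiotic_b, exclude_abiotic_up=exclude_abiotic_up_b,
    )
    omap = union_orthologs(fixture.similarity_table, fixture.inparanoid_table)
    return SpeciesPairResults(
        lowox_a=lowox_a,
        lowox_b=lowox_b,
        abiotic_a=abiotic_a,
        abiotic_b=abiotic_b,
        ortholog_map=omap,
        consensus=consensus,
        markers_a=markers_a,
        markers_b=markers_b,
        overlap_a=overlap_counts(lowox_a, abiotic_a, "any_direction"),
        overlap_b=overlap_counts(lowox_b, abiotic_b, "any_direction"),
        overlap_a_matched=overlap_counts(lowox_a, abiotic_a, "matched"),
        overlap_b_matched=overlap_counts(lowox_b, abiotic_b, "matched"),
    )
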