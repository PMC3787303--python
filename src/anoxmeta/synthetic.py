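"""Synthetic expression studies with machine-readable planted truth.

Generates the study designs the pipeline is exercised on, without any
download: single replicated contrasts, step-wise time courses, and a
two-species compendium with ortholog tables.  All values are log2-scale
Gaussian around per-gene baselines (emulating variance-stabilized array
data): replicate value = baseline + condition effect + N(0, noise_sd).
Planted differential genes, enriched bins, ortholog conservation classes
and marker genes are recorded in a :class:`SyntheticTruth` so every
downstream stage can be scored against ground truth.

Every generator is bit-for-bit reproducible from its seed; sub-streams
are split off a single :class:`numpy.random.SeedSequence`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ABSENT, PRESENT, BinAnnotation, ExpressionStudy, PresenceCalls, ValidationError
from .orthology import OrthologTable

__all__ = [
    "SyntheticTruth",
    "SpeciesPairFixture",
    "generate_study",
    "generate_timecourse",
    "generate_species_pair",
    "write_species_pair_fixture",
]


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator.

    planted_de maps contrast name (prefixed ``species:`` in the
    two-species setting) to {gene: true log2 effect}; planted_bins maps
    contrast name to {bin path: planted enrichment fraction};
    ortholog_classes maps ``"gene_a|gene_b"`` to a conservation class;
    planted_markers maps species label to the genes planted as low-oxygen
    markers; planted_bin_classes records the species-consensus label each
    planted bin should receive.
    """

    seed: int
    planted_de: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_bins: dict[str, dict[str, float]] = field(default_factory=dict)
    ortholog_classes: dict[str, str] = field(default_factory=dict)
    planted_markers: dict[str, list[str]] = field(default_factory=dict)
    planted_bin_classes: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


ORTHOLOG_CLASSES = ("conserved_up", "conserved_down", "divergent", "opposite", "unrelated")


def _baselines(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    return rng.normal(mean, sd, size=n)


def _presence(
    rng: np.random.Generator,
    gene_ids: Sequence[str],
    sample_ids: Sequence[str],
    absent_fraction: float,
    alpha: float = 0.05,
) -> PresenceCalls:
    shape = (len(gene_ids), len(sample_ids))
    p = rng.uniform(1e-4, alpha * 0.8, size=shape)
    if absent_fraction > 0:
        absent = rng.random(shape) < absent_fraction
        p = np.where(absent, rng.uniform(alpha * 1.2, 0.9, size=shape), p)
    pdf = pd.DataFrame(p, index=list(gene_ids), columns=list(sample_ids))
    calls = pdf.map(lambda q: PRESENT if q < alpha else ABSENT)
    return PresenceCalls(calls=calls, detection_p=pdf)


def _assemble_study(
    rng: np.random.Generator,
    study_id: str,
    gene_ids: Sequence[str],
    conditions: Sequence[str],
    n_reps: int,
    baselines: np.ndarray,
    effects: np.ndarray,  # genes x conditions
    noise_sd: float,
    timepoints: Mapping[str, int] | None = None,
) -> ExpressionStudy:
    cols, data, design_rows = [], [], []
    for ci, cond in enumerate(conditions):
        for r in range(1, n_reps + 1):
            sample = f"{cond}_r{r}"
            cols.append(sample)
            data.append(
                baselines + effects[:, ci] + rng.normal(0.0, noise_sd, size=len(gene_ids))
            )
            design_rows.append(
                {
                    "sample": sample,
                    "condition": cond,
                    "timepoint": (timepoints or {}).get(cond, pd.NA),
                    "replicate": r,
                }
            )
    values = pd.DataFrame(np.column_stack(data), index=list(gene_ids), columns=cols)
    design = pd.DataFrame(design_rows).set_index("sample")
    design["timepoint"] = pd.array(design["timepoint"], dtype="Int64")
    return ExpressionStudy(study_id=study_id, values=values, design=design)


# ---------------------------------------------------------------------------
# single study
# ---------------------------------------------------------------------------

def generate_study(
    n_genes: int = 2000,
    conditions: Sequence[str] = ("control", "treatment"),
    n_reps: int = 3,
    de_fraction: float = 0.1,
    effect_range: tuple[float, float] = (1.0, 6.0),
    noise_sd: float = 0.25,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
    absent_fraction: float = 0.05,
    seed: int = 0,
    study_id: str = "synthetic",
) -> tuple[ExpressionStudy, PresenceCalls, SyntheticTruth]:
    """One replicated multi-condition study with planted DE genes.

    Exactly ``round(n_genes * de_fraction)`` genes are planted; each gets
    an independent effect per non-reference condition with magnitude
    uniform in ``effect_range`` (log2) and random sign.  The first
    condition is the unperturbed reference.  Detection calls are present
    everywhere except a random ``absent_fraction`` of cells.
    """
    if not (0 <= de_fraction <= 1):
        raise ValidationError(f"de_fraction must lie in [0, 1], got {de_fraction}")
    if len(conditions) < 2:
        raise ValidationError("need a reference plus at least one perturbed condition")
    ss = np.random.SeedSequence(seed)
    r_base, r_fx, r_noise, r_pres = [np.random.default_rng(s) for s in ss.spawn(4)]
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    baselines = _baselines(r_base, n_genes, baseline_mean, baseline_sd)
    n_de = int(round(n_genes * de_fraction))
    planted_idx = r_fx.choice(n_genes, size=n_de, replace=False)
    effects = np.zeros((n_genes, len(conditions)))
    truth = SyntheticTruth(seed=seed)
    ref = conditions[0]
    for ci, cond in enumerate(conditions[1:], start=1):
        mag = r_fx.uniform(effect_range[0], effect_range[1], size=n_de)
        sign = r_fx.choice([-1.0, 1.0], size=n_de)
        effects[planted_idx, ci] = mag * sign
        truth.planted_de[f"{cond} v {ref}"] = {
            gene_ids[g]: float(effects[g, ci]) for g in sorted(planted_idx)
        }
    study = _assemble_study(
        r_noise, study_id, gene_ids, conditions, n_reps, baselines, effects, noise_sd
    )
    calls = _presence(r_pres, gene_ids, study.sample_ids, absent_fraction)
    return study, calls, truth


# ---------------------------------------------------------------------------
# step-wise time course
# ---------------------------------------------------------------------------

def generate_timecourse(
    n_genes: int = 1000,
    timepoints: int = 4,
    n_reps: int = 3,
    step_responders: Mapping[int, Mapping[str, float]] | None = None,
    noise_sd: float = 0.25,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
    seed: int = 0,
    study_id: str = "synthetic_timecourse",
) -> tuple[ExpressionStudy, SyntheticTruth]:
    """A germination-style time course with planted step responders.

    ``step_responders`` maps an interval index i (1..timepoints-1, the
    step from t_{i-1} to t_i) to {gene_id: log2 effect}; a planted gene
    shifts at its interval and stays flat otherwise, so its cumulative
    profile is a single step.  Conditions are named ``t0..t{k-1}`` with
    matching timepoint ranks.
    """
    if timepoints < 2:
        raise ValidationError("need at least 2 timepoints")
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    steps = np.zeros((n_genes, timepoints))
    truth = SyntheticTruth(seed=seed)
    for interval, genes in (step_responders or {}).items():
        if not (1 <= interval <= timepoints - 1):
            raise ValidationError(
                f"interval {interval} out of range 1..{timepoints - 1}"
            )
        for g, eff in genes.items():
            if g not in gene_pos:
                raise ValidationError(f"planted gene '{g}' not in study")
            steps[gene_pos[g], interval] += float(eff)
        truth.planted_de[f"t{interval} v t{interval - 1}"] = {
            g: float(eff) for g, eff in genes.items()
        }
    effects = np.cumsum(steps, axis=1)
    ss = np.random.SeedSequence(seed)
    r_base, r_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    baselines = _baselines(r_base, n_genes, baseline_mean, baseline_sd)
    conds = [f"t{i}" for i in range(timepoints)]
    study = _assemble_study(
        r_noise,
        study_id,
        gene_ids,
        conds,
        n_reps,
        baselines,
        effects,
        noise_sd,
        timepoints={c: i for i, c in enumerate(conds)},
    )
    return study, truth


# ---------------------------------------------------------------------------
# two-species compendium
# ---------------------------------------------------------------------------

#: reserved gene-index blocks of the two-species fixture
_BIN_BLOCKS = {  # bin path -> (start, size, n_enriched)
    "90.1": (400, 50, 30),
    "90.2": (450, 50, 30),
    "91.1": (500, 50, 30),
    "91.2": (550, 50, 30),
}
_BIN_NAMES = {
    "90": "planted processes",
    "90.1": "conserved process 1",
    "90.2": "conserved process 2",
    "91": "species-specific processes",
    "91.1": "species A specific process",
    "91.2": "species B specific process",
}
_MARKER_BLOCK = 600  # marker/decoy genes live at 600..609
_BACKGROUND_START = 650  # background responders drawn from here on

ABIOTIC_CONDITIONS = ("cold", "drought", "salt", "heat")


@dataclass
class SpeciesPairFixture:
    """Everything the cross-species pipeline consumes, plus the truth."""

    species_a: str
    species_b: str
    study_a: ExpressionStudy
    study_b: ExpressionStudy
    calls_a: PresenceCalls
    calls_b: PresenceCalls
    bins_a: BinAnnotation
    bins_b: BinAnnotation
    similarity_table: OrthologTable
    inparanoid_table: OrthologTable
    truth: SyntheticTruth
    lowox_conditions_a: tuple[str, ...] = ()
    lowox_conditions_b: tuple[str, ...] = ()
    abiotic_conditions: tuple[str, ...] = ABIOTIC_CONDITIONS


def _random_bins(
    rng: np.random.Generator, gene_ids: Sequence[str], n_bins: int
) -> tuple[dict[str, str], dict[str, set[str]]]:
    """Two-level random hierarchy: sizes log-uniform 10..200."""
    names: dict[str, str] = {}
    membership: dict[str, set[str]] = {}
    n_top = max(1, n_bins // 2)
    for i in range(n_bins):
        top = 1 + (i % n_top)
        child = 1 + (i // n_top)
        path = f"{top}.{child}"
        names.setdefault(str(top), f"process group {top}")
        names[path] = f"random category {path}"
        size = int(round(10 ** rng.uniform(1.0, np.log10(200))))
        for g in rng.choice(len(gene_ids), size=min(size, len(gene_ids)), replace=False):
            membership.setdefault(gene_ids[g], set()).add(path)
    return names, membership


def _species_effects(
    rng: np.random.Generator,
    n_genes: int,
    lowox: Sequence[str],
    abiotic: Sequence[str],
    background_de_fraction: float,
    effect_range: tuple[float, float],
) -> tuple[np.ndarray, list[str]]:
    """Zero effect matrix plus background responders in every contrast.

    Background genes are drawn from the unreserved block so planted roles
    stay clean; each contrast gets its own random responders.
    """
    conditions = ["control", *lowox, *abiotic]
    effects = np.zeros((n_genes, len(conditions)))
    pool = np.arange(_BACKGROUND_START, n_genes)
    n_bg = int(round(n_genes * background_de_fraction))
    for ci in range(1, len(conditions)):
        idx = rng.choice(pool, size=n_bg, replace=False)
        mag = rng.uniform(effect_range[0], effect_range[1], size=n_bg)
        sign = rng.choice([-1.0, 1.0], size=n_bg)
        effects[idx, ci] = mag * sign
    return effects, conditions


def generate_species_pair(
    n_genes: int = 2000,
    n_reps: int = 3,
    n_lowox_a: int = 4,
    n_lowox_b: int = 5,
    n_ortholog_pairs: int = 300,
    class_mix: Mapping[str, float] | None = None,
    background_de_fraction: float = 0.02,
    effect_range: tuple[float, float] = (1.0, 6.0),
    conserved_effect_range: tuple[float, float] = (1.5, 3.0),
    marker_log2_effect: float = 6.5,
    noise_sd: float = 0.25,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
    n_random_bins: int = 26,
    seed: int = 0,
    species_a: str = "rice",
    species_b: str = "arabidopsis",
) -> SpeciesPairFixture:
    """A two-species low-oxygen compendium with planted consensus truth.

    Species A carries ``n_lowox_a`` low-oxygen comparisons (vs control)
    plus four abiotic-stress comparisons; species B likewise with
    ``n_lowox_b``.  Planted structure, all recorded in the truth:

    * ortholog pairs with classes drawn from ``class_mix`` — conserved
      pairs respond with the same sign in both species, opposite pairs
      with opposite signs, divergent pairs in species A only;
    * two conserved enriched bins (up in every low-oxygen comparison of
      both species), one species-A-only bin (up in 3 of the 4 A
      comparisons, never in B) and one species-B-only bin (up in 4 of the
      5 B comparisons, never in A);
    * marker genes induced ``marker_log2_effect`` log2 (~90-fold) in a
      quorum of low-oxygen comparisons, plus decoys: one also induced
      under an abiotic stress (rice-rule exclusion), one below the
      50-fold cutoff, one missing the quorum;
    * each ortholog source table holds ~80% of the pair set (independent
      draws; every pair is in at least one source), so the union rule is
      exercised.
    """
    if class_mix is None:
        class_mix = {
            "conserved_up": 0.25,
            "conserved_down": 0.15,
            "divergent": 0.20,
            "opposite": 0.10,
            "unrelated": 0.30,
        }
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValidationError("class_mix proportions must sum to 1")
    if n_genes < _BACKGROUND_START + 200:
        raise ValidationError(f"n_genes must be >= {_BACKGROUND_START + 200}")
    if n_ortholog_pairs > 350:
        raise ValidationError("n_ortholog_pairs is capped at 350 by the reserved layout")
    if n_lowox_a < 4 or n_lowox_b < 4:
        raise ValidationError("need >= 4 low-oxygen comparisons per species")

    ss = np.random.SeedSequence(seed)
    (r_class, r_fx_a, r_fx_b, r_bins_a, r_bins_b, r_src,
     r_noise_a, r_noise_b, r_pres_a, r_pres_b) = [
        np.random.default_rng(s) for s in ss.spawn(10)
    ]

    genes_a = [f"osg{i:04d}" for i in range(n_genes)]
    genes_b = [f"atg{i:04d}" for i in range(n_genes)]
    lowox_a = tuple(f"anoxia{i}" for i in range(1, n_lowox_a + 1))
    lowox_b = tuple(f"hypoxia{i}" for i in range(1, n_lowox_b + 1))

    eff_a, conds_a = _species_effects(
        r_fx_a, n_genes, lowox_a, ABIOTIC_CONDITIONS, background_de_fraction, effect_range
    )
    eff_b, conds_b = _species_effects(
        r_fx_b, n_genes, lowox_b, ABIOTIC_CONDITIONS, background_de_fraction, effect_range
    )
    ci_a = {c: i for i, c in enumerate(conds_a)}
    ci_b = {c: i for i, c in enumerate(conds_b)}
    truth = SyntheticTruth(seed=seed)

    # ---- ortholog pairs and their conservation classes -----------------------
    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes])
    assignment = r_class.choice(len(classes), size=n_ortholog_pairs, p=probs)
    pair_list: list[tuple[str, str]] = []
    lo, hi = conserved_effect_range
    for i, ai in enumerate(assignment):
        cls = classes[ai]
        ga, gb = genes_a[i], genes_b[i]
        pair_list.append((ga, gb))
        truth.ortholog_classes[f"{ga}|{gb}"] = cls
        mag_a, mag_b = r_class.uniform(lo, hi, size=2)
        if cls == "conserved_up":
            sa, sb = mag_a, mag_b
        elif cls == "conserved_down":
            sa, sb = -mag_a, -mag_b
        elif cls == "opposite":
            sa, sb = mag_a, -mag_b
        elif cls == "divergent":
            sa = mag_a * r_class.choice([-1.0, 1.0])
            sb = 0.0
        else:
            sa = sb = 0.0
        for c in lowox_a:
            eff_a[i, ci_a[c]] += sa
        for c in lowox_b:
            eff_b[i, ci_b[c]] += sb
    # a few extra cross pairs make the relation many-to-many
    for j in range(5):
        ga, gb = genes_a[j], genes_b[j + 100]
        pair_list.append((ga, gb))
        truth.ortholog_classes[f"{ga}|{gb}"] = "unrelated"

    # ---- planted enriched bins ----------------------------------------------
    planted_in: dict[str, tuple[list[str], list[str]]] = {
        # bin -> (A conditions, B conditions)
        "90.1": (list(lowox_a), list(lowox_b)),
        "90.2": (list(lowox_a), list(lowox_b)),
        "91.1": (list(lowox_a[:3]), []),
        "91.2": ([], list(lowox_b[:4])),
    }
    truth.planted_bin_classes = {"90.1": "both", "90.2": "both", "91.1": "a_only", "91.2": "b_only"}
    for bpath, (conds_in_a, conds_in_b) in planted_in.items():
        start, size, n_enriched = _BIN_BLOCKS[bpath]
        frac = n_enriched / size
        for cond in conds_in_a:
            effs = r_fx_a.uniform(lo, hi, size=n_enriched)
            eff_a[start : start + n_enriched, ci_a[cond]] += effs
            truth.planted_bins.setdefault(f"{species_a}:{cond} v control", {})[bpath] = frac
        for cond in conds_in_b:
            effs = r_fx_b.uniform(lo, hi, size=n_enriched)
            eff_b[start : start + n_enriched, ci_b[cond]] += effs
            truth.planted_bins.setdefault(f"{species_b}:{cond} v control", {})[bpath] = frac

    # ---- marker genes and decoys --------------------------------------------
    m = _MARKER_BLOCK
    a_marker_conds = list(lowox_a[:3])
    b_marker_conds = list(lowox_b[:4])
    for gi in (m, m + 1, m + 2):  # true A markers
        for c in a_marker_conds:
            eff_a[gi, ci_a[c]] = marker_log2_effect
    for c in a_marker_conds:  # decoy: also induced under salt -> excluded
        eff_a[m + 3, ci_a[c]] = marker_log2_effect
    eff_a[m + 3, ci_a["salt"]] = 2.0
    for c in lowox_a:  # decoy: strong but below the 50-fold cutoff
        eff_a[m + 4, ci_a[c]] = 5.2
    for gi in (m, m + 1):  # true B markers
        for c in b_marker_conds:
            eff_b[gi, ci_b[c]] = marker_log2_effect
    for c in list(lowox_b[:2]):  # decoy: misses the 3-of-5 quorum
        eff_b[m + 2, ci_b[c]] = marker_log2_effect
    truth.planted_markers = {
        species_a: [genes_a[m], genes_a[m + 1], genes_a[m + 2]],
        species_b: [genes_b[m], genes_b[m + 1]],
    }

    # ---- record planted DE (all non-zero planted effects) --------------------
    for species, genes, eff, conds, cidx in (
        (species_a, genes_a, eff_a, conds_a, ci_a),
        (species_b, genes_b, eff_b, conds_b, ci_b),
    ):
        for cond in conds[1:]:
            nz = np.nonzero(eff[:, cidx[cond]])[0]
            truth.planted_de[f"{species}:{cond} v control"] = {
                genes[g]: float(eff[g, cidx[cond]]) for g in nz
            }

    # ---- bin annotations ------------------------------------------------------
    def build_bins(rng: np.random.Generator, genes: Sequence[str]) -> BinAnnotation:
        names, membership = _random_bins(rng, genes, n_random_bins)
        names.update(_BIN_NAMES)
        for bpath, (start, size, _) in _BIN_BLOCKS.items():
            for g in genes[start : start + size]:
                membership.setdefault(g, set()).add(bpath)
        return BinAnnotation(bin_names=names, membership=membership)

    bins_a = build_bins(r_bins_a, genes_a)
    bins_b = build_bins(r_bins_b, genes_b)

    # ---- ortholog source tables (~80% subsets whose union covers all) --------
    sim_pairs, inp_pairs = [], []
    for ga, gb in pair_list:
        bucket = r_src.choice(3, p=[0.6, 0.2, 0.2])  # both / sim only / inp only
        pct = float(np.round(r_src.uniform(40, 95), 1))
        if bucket in (0, 1):
            sim_pairs.append((ga, gb, pct))
        if bucket in (0, 2):
            inp_pairs.append((ga, gb, None))
    sim_table = OrthologTable(species_a, species_b, "similarity", tuple(sim_pairs))
    inp_table = OrthologTable(species_a, species_b, "inparanoid", tuple(inp_pairs))

    # ---- assemble matrices ----------------------------------------------------
    base_a = _baselines(r_noise_a, n_genes, baseline_mean, baseline_sd)
    base_b = _baselines(r_noise_b, n_genes, baseline_mean, baseline_sd)
    study_a = _assemble_study(
        r_noise_a, species_a, genes_a, conds_a, n_reps, base_a, eff_a, noise_sd
    )
    study_b = _assemble_study(
        r_noise_b, species_b, genes_b, conds_b, n_reps, base_b, eff_b, noise_sd
    )
    calls_a = _presence(r_pres_a, genes_a, study_a.sample_ids, absent_fraction=0.0)
    calls_b = _presence(r_pres_b, genes_b, study_b.sample_ids, absent_fraction=0.0)

    return SpeciesPairFixture(
        species_a=species_a,
        species_b=species_b,
        study_a=study_a,
        study_b=study_b,
        calls_a=calls_a,
        calls_b=calls_b,
        bins_a=bins_a,
        bins_b=bins_b,
        similarity_table=sim_table,
        inparanoid_table=inp_table,
        truth=truth,
        lowox_conditions_a=lowox_a,
        lowox_conditions_b=lowox_b,
    )


def write_species_pair_fixture(fixture: SpeciesPairFixture, outdir: str) -> dict[str, str]:
    """Write the full fixture as the TSV dialects :mod:`anoxmeta.io` reads,
    plus ``truth.json``; returns the path of every file written."""
    import os

    from .io import (
        write_bin_annotation,
        write_expression_study,
        write_presence_calls,
    )
    from .orthology import write_ortholog_table

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    for tag, study, calls, bins in (
        ("a", fixture.study_a, fixture.calls_a, fixture.bins_a),
        ("b", fixture.study_b, fixture.calls_b, fixture.bins_b),
    ):
        write_expression_study(study, p(f"study_{tag}_matrix.tsv"), p(f"study_{tag}_design.tsv"))
        write_presence_calls(calls, p(f"study_{tag}_calls.tsv"))
        write_bin_annotation(bins, p(f"bins_{tag}.tsv"))
    write_ortholog_table(fixture.similarity_table, p("orthologs_similarity.tsv"))
    write_ortholog_table(fixture.inparanoid_table, p("orthologs_inparanoid.tsv"))
    fixture.truth.to_json(p("truth.json"))
    meta = {
        "species_a": fixture.species_a,
        "species_b": fixture.species_b,
        "lowox_conditions_a": list(fixture.lowox_conditions_a),
        "lowox_conditions_b": list(fixture.lowox_conditions_b),
        "abiotic_conditions": list(fixture.abiotic_conditions),
    }
    with open(p("fixture.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    return paths
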