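"""Consensus set-logic: conserved/specific/species categories, overlaps,
markers — each checked against naive brute-force reimplementations."""
import itertools

import numpy as np
import pandas as pd
import pytest

import anoxmeta as am
from anoxmeta.diffexpr import ContrastResults, ContrastSpec, CyberTParams
from anoxmeta.meta import StudyMember, StudySet, classify_counts

from _oracles import (
    brute_condition_specific,
    brute_conserved,
    brute_markers,
    brute_overlap,
    brute_species_classify,
)


def _ora_table(sig: dict[str, set[str]], direction="up", all_bins=None) -> pd.DataFrame:
    """Build an enrichment table from {contrast: set of significant bins}."""
    rows = []
    for contrast, bins in sig.items():
        universe = all_bins if all_bins is not None else bins
        for b in universe:
            is_sig = b in bins
            rows.append(
                {
                    "contrast": contrast,
                    "direction": direction,
                    "bin": b,
                    "bin_name": b,
                    "k": 0, "K": 1, "n": 1, "N": 10,
                    "p": 0.001 if is_sig else 0.9,
                    "z": 3.0 if is_sig else 0.1,
                    "significant": is_sig,
                }
            )
    return pd.DataFrame(rows)


def _de_member(name: str, calls: dict[str, str], log2fc: dict[str, float] | None = None):
    genes = list(calls)
    frame = pd.DataFrame(
        {
            "log2fc": [(log2fc or {}).get(g, 2.0 if calls[g] == "up" else -2.0)
                       for g in genes],
            "t": 0.0,
            "p": 0.01,
            "ppde": 0.99,
            "call": pd.array([calls[g] for g in genes], dtype=object),
        },
        index=genes,
    )
    spec = ContrastSpec("s", name, ("a1", "a2"), ("b1", "b2"))
    return StudyMember("s", name, de=ContrastResults(spec, CyberTParams(), frame))


class TestConservedCategories:
    def test_identical_single_bin_tables(self):
        tables = [_ora_table({"c1": {"10.2"}}) for _ in range(3)]
        got = am.conserved_categories(tables, "up")
        assert list(got["bin"]) == ["10.2"]

    def test_bin_missing_from_one_study_is_excluded(self):
        tables = [
            _ora_table({"c1": {"10.2"}}),
            _ora_table({"c1": {"10.2"}}),
            _ora_table({"c1": set()}, all_bins={"10.2"}),
        ]
        assert am.conserved_categories(tables, "up").empty

    def test_planted_shared_interval_sets_timing_match(self):
        # three step-wise studies; studies 1 and 2 share interval index 1
        t0 = _ora_table({"s0_c0": set(), "s0_c1": {"9.1"}, "s0_c2": set()}, all_bins={"9.1"})
        t1 = _ora_table({"s1_c0": set(), "s1_c1": {"9.1"}, "s1_c2": set()}, all_bins={"9.1"})
        t2 = _ora_table({"s2_c0": {"9.1"}, "s2_c1": set(), "s2_c2": set()}, all_bins={"9.1"})
        got = am.conserved_categories([t0, t1, t2], "up", timing_pair=(1, 2))
        assert got.iloc[0]["timing_match"] == False  # noqa: E712 (1@1 vs 2@0)
        got = am.conserved_categories([t0, t1, t2], "up", timing_pair=(0, 1))
        assert got.iloc[0]["timing_match"] == True  # noqa: E712

    def test_under_representation_does_not_count_as_conserved(self):
        t = _ora_table({"c1": {"8.1"}})
        t.loc[:, "z"] = -3.0  # significant but under-represented
        assert am.conserved_categories([t, t], "up").empty

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(0)
        bins = [f"{i}.1" for i in range(1, 7)]
        for _ in range(200):
            per_study = [
                {b for b in bins if rng.random() < 0.4} for _ in range(3)
            ]
            tables = [
                _ora_table({"c": s}, all_bins=set(bins)) for s in per_study
            ]
            got = set(am.conserved_categories(tables, "up")["bin"])
            assert got == brute_conserved(per_study)


class TestConditionSpecific:
    def test_fig2_rule_examples(self):
        target = _ora_table({"AvN": {"10.2", "3.1"}})
        coreq = _ora_table({"step": {"10.2", "3.1", "5.5"}})
        excl = [_ora_table({"aer": {"3.1"}})]
        got = am.condition_specific_categories(target, coreq, excl, "up")
        assert got == {"10.2"}

    def test_bin_significant_everywhere_is_dropped(self):
        t = _ora_table({"c": {"1.1"}})
        assert am.condition_specific_categories(t, t, [t], "up") == set()

    def test_random_instances_match_set_algebra(self):
        rng = np.random.default_rng(1)
        bins = [f"{i}.1" for i in range(1, 9)]
        for _ in range(200):
            draw = lambda: {b for b in bins if rng.random() < 0.35}
            target, coreq = draw(), draw()
            excluded = [draw() for _ in range(rng.integers(0, 4))]
            got = am.condition_specific_categories(
                _ora_table({"t": target}, all_bins=set(bins)),
                _ora_table({"c": coreq}, all_bins=set(bins)),
                [_ora_table({"e": e}, all_bins=set(bins)) for e in excluded],
                "up",
            )
            assert got == brute_condition_specific(target, coreq, excluded)


class TestSpeciesConsensus:
    def test_rice_specific_rule_example(self):
        # significant up in 3 of 4 A comparisons, never in B -> a_only
        set_a = StudySet("rice", [
            StudyMember("a", f"c{i}", ora=_ora_table({f"c{i}": {"7.2"} if i < 3 else set()},
                                                     all_bins={"7.2"}))
            for i in range(4)
        ])
        set_b = StudySet("arabidopsis", [
            StudyMember("b", f"c{i}", ora=_ora_table({f"c{i}": set()}, all_bins={"7.2"}))
            for i in range(5)
        ])
        got = am.species_consensus(set_a, set_b, k_a=3, k_b=4)
        row = got[(got["bin"] == "7.2") & (got["direction"] == "up")].iloc[0]
        assert row["classification"] == "a_only"
        assert (row["count_a"], row["count_b"]) == (3, 0)

    def test_everywhere_significant_is_both(self):
        set_a = StudySet("A", [
            StudyMember("a", f"c{i}", ora=_ora_table({f"c{i}": {"1.1"}})) for i in range(4)
        ])
        set_b = StudySet("B", [
            StudyMember("b", f"c{i}", ora=_ora_table({f"c{i}": {"1.1"}})) for i in range(5)
        ])
        got = am.species_consensus(set_a, set_b)
        assert set(got["classification"]) == {"both"}

    def test_exhaustive_truth_table(self):
        for ca, cb in itertools.product(range(5), range(6)):
            assert classify_counts(ca, cb, 3, 4) == brute_species_classify(ca, cb, 3, 4)

    def test_classification_is_stable_under_member_permutation(self):
        rng = np.random.default_rng(2)
        bins = {"1.1", "2.2", "3.3"}
        members_a = [
            StudyMember("a", f"c{i}", ora=_ora_table(
                {f"c{i}": {b for b in bins if rng.random() < 0.5}}, all_bins=bins))
            for i in range(4)
        ]
        members_b = [
            StudyMember("b", f"c{i}", ora=_ora_table(
                {f"c{i}": {b for b in bins if rng.random() < 0.5}}, all_bins=bins))
            for i in range(5)
        ]
        base = am.species_consensus(StudySet("A", members_a), StudySet("B", members_b))
        perm = am.species_consensus(
            StudySet("A", members_a[::-1]), StudySet("B", members_b[::-1])
        )
        key = ["bin", "direction"]
        assert base.sort_values(key).reset_index(drop=True).equals(
            perm.sort_values(key).reset_index(drop=True)
        )

    def test_quorum_larger_than_set_is_an_error(self):
        s = StudySet("A", [StudyMember("a", "c0", ora=_ora_table({"c0": set()}))])
        with pytest.raises(am.ValidationError, match="quorum"):
            am.species_consensus(s, s, k_a=2, k_b=1)


class TestOverlapCounts:
    def test_disjoint_and_identical_sets(self):
        a = StudySet("low", [_de_member("l1", {"g1": "up", "g2": "down", "g3": "ns"})])
        b_disjoint = StudySet("abi", [_de_member("a1", {"g3": "up", "g4": "down"})])
        b_same = StudySet("abi", [_de_member("a1", {"g1": "up", "g2": "down"})])
        assert am.overlap_counts(a, b_disjoint).iloc[0, 0] == 0
        assert am.overlap_counts(a, b_same).iloc[0, 0] == 2

    def test_matched_mode_requires_same_direction(self):
        a = StudySet("low", [_de_member("l1", {"g1": "up", "g2": "down"})])
        b = StudySet("abi", [_de_member("a1", {"g1": "down", "g2": "down"})])
        assert am.overlap_counts(a, b, "any_direction").iloc[0, 0] == 2
        assert am.overlap_counts(a, b, "matched").iloc[0, 0] == 1

    def test_random_instances_match_brute_force_in_both_modes(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(15)]
        for _ in range(200):
            def rand_calls():
                return {g: rng.choice(["up", "down", "ns"]) for g in genes}
            low = [rand_calls() for _ in range(2)]
            abi = [rand_calls() for _ in range(3)]
            lset = StudySet("low", [_de_member(f"l{i}", c) for i, c in enumerate(low)])
            aset = StudySet("abi", [_de_member(f"a{i}", c) for i, c in enumerate(abi)])
            for mode in ("any_direction", "matched"):
                got = am.overlap_counts(lset, aset, mode).to_numpy().tolist()
                assert got == brute_overlap(low, abi, mode)


class TestMarkerGenes:
    @staticmethod
    def _lowox(per_contrast: list[dict[str, float]]):
        """per_contrast: {gene: log2fc}; every listed gene is called up."""
        members = []
        for i, fc in enumerate(per_contrast):
            calls = {g: "up" for g in fc}
            calls.update({"filler": "ns"})
            members.append(_de_member(f"c{i}", calls, log2fc=fc))
        return StudySet("rice", members)

    def test_rice_rule_recovers_marker(self):
        lf = np.log2(60)
        lowox = self._lowox([{"m": lf}, {"m": lf}, {}, {}])
        got = am.find_marker_genes(lowox, fold_min=50, k_min=2)
        assert list(got["gene"]) == ["m"]
        assert got.iloc[0]["n_passing"] == 2
        assert got.iloc[0]["max_fold"] == pytest.approx(60.0)

    def test_abiotic_up_gene_is_excluded_when_exclusion_on(self):
        lf = np.log2(60)
        lowox = self._lowox([{"m": lf}, {"m": lf}, {}, {}])
        abiotic = StudySet("rice abiotic", [_de_member("salt", {"m": "up"},
                                                       log2fc={"m": np.log2(3)})])
        on = am.find_marker_genes(lowox, 50, 2, abiotic, exclude_abiotic_up=True)
        off = am.find_marker_genes(lowox, 50, 2, abiotic, exclude_abiotic_up=False)
        assert on.empty
        assert list(off["gene"]) == ["m"] and bool(off.iloc[0]["abiotic_up"])

    def test_gene_below_fold_cutoff_is_not_a_marker(self):
        lf = np.log2(49)
        lowox = self._lowox([{"m": lf}] * 4)
        assert am.find_marker_genes(lowox, fold_min=50, k_min=2).empty

    def test_degenerate_parameters_reduce_to_union_of_up_calls(self):
        rng = np.random.default_rng(4)
        per_contrast = [
            {f"g{j}": float(rng.uniform(1.01, 8)) for j in rng.integers(0, 20, size=6)}
            for _ in range(3)
        ]
        lowox = self._lowox(per_contrast)
        got = set(am.find_marker_genes(lowox, fold_min=2, k_min=1,
                                       exclude_abiotic_up=False)["gene"])
        union_up = set().union(*[set(fc) for fc in per_contrast])
        assert got == union_up

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(12)]
        for _ in range(200):
            tables = []
            for _c in range(4):
                t = {}
                for g in genes:
                    call = rng.choice(["up", "ns"], p=[0.4, 0.6])
                    fold = float(rng.uniform(1, 120))
                    t[g] = (call, fold)
                tables.append(t)
            abiotic_up = {g for g in genes if rng.random() < 0.3}
            exclude = bool(rng.random() < 0.5)
            lowox = StudySet("low", [
                _de_member(f"c{i}", {g: v[0] for g, v in t.items()},
                           log2fc={g: np.log2(v[1]) for g, v in t.items()})
                for i, t in enumerate(tables)
            ])
            abi = StudySet("abi", [_de_member(
                "stress", {g: ("up" if g in abiotic_up else "ns") for g in genes})])
            got = set(am.find_marker_genes(lowox, 50, 2, abi, exclude)["gene"])
            want = brute_markers(tables, 50, 2, abiotic_up, exclude)
            assert got == want


class TestStudySet:
    def test_duplicate_contrast_names_are_an_error(self):
        m = _de_member("c1", {"g": "ns"})
        with pytest.raises(am.ValidationError, match="duplicate"):
            StudySet("s", [m, m])
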