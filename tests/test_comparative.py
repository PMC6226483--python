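"""Comparative statistics: HD, P score, complexity, core, CS shapes."""

import random

import pytest

from pathrecon.annotation import EnzymeAnnotation
from pathrecon.comparative import (
    build_complexity_table,
    coexistence,
    complexity_report,
    conserved_core,
    cs_distribution,
    enzyme_reaction_graph,
    hamming_distance,
    hd_matrix,
    overall_coexistence,
    p_score,
    p_score_matrix,
    scores_to_long,
)

from conftest import make_pathway, make_reaction


def _chain(species, ids, subs=("CAL",), shared_ec=None):
    reactions = [
        make_reaction(rid, ecs=(shared_ec or f"1.1.1.{i + 1}",), subs=subs)
        for i, rid in enumerate(ids)
    ]
    return make_pathway(species, reactions)


class TestHammingDistance:
    def test_identical_pathways_zero(self):
        q = _chain("q", ["R1", "R2", "R3"])
        assert hamming_distance(coexistence(q, _chain("t", ["R1", "R2", "R3"]), "CAL")) == 0.0

    def test_one_missing_of_four(self):
        q = _chain("q", ["R1", "R2", "R3", "R4"])
        t = _chain("t", ["R1", "R2", "R3"])
        m = coexistence(q, t, "CAL")
        assert sum(flag for _, flag in m.a) == 1
        assert hamming_distance(m) == pytest.approx(0.25)

    def test_disjoint_pathways_one(self):
        q = _chain("q", ["R1", "R2"])
        t = _chain("t", ["R8", "R9"])
        assert hamming_distance(coexistence(q, t, "CAL")) == 1.0

    def test_non_enzymatic_reactions_excluded(self):
        q = make_pathway(
            "q",
            [
                make_reaction("R1", ecs=("1.1.1.1",), subs=("CAL",)),
                make_reaction("R2", ecs=(), subs=("CAL",), rtype="spontaneous"),
                make_reaction("R3", ecs=("3.3.3.3",), subs=("CAL",), rtype="orphan"),
            ],
        )
        m = coexistence(q, _chain("t", ["R1"]), "CAL")
        assert m.b == 1

    def test_empty_sub_metabolism_errors(self):
        q = _chain("q", ["R1"], subs=("CAL",))
        with pytest.raises(ValueError):
            coexistence(q, q, "NUC")

    def test_oracle_1000_random_toys(self):
        """HD agrees with brute-force set counting on 1,000 random toy
        pathways of <= 10 reactions, and stays within [0, 1]."""
        rng = random.Random(42)
        universe = [f"R{i}" for i in range(10)]
        for _ in range(1000):
            q_ids = rng.sample(universe, rng.randint(1, 10))
            t_ids = set(rng.sample(universe, rng.randint(0, 10)))
            q = _chain("q", q_ids)
            t = _chain("t", sorted(t_ids)) if t_ids else make_pathway("t", [])
            hd = hamming_distance(coexistence(q, t, "CAL"))
            expect = sum(1 for r in q_ids if r not in t_ids) / len(q_ids)
            assert hd == pytest.approx(expect)
            assert 0.0 <= hd <= 1.0

    def test_overall_pools_deduplicated(self):
        q = make_pathway(
            "q",
            [
                make_reaction("R1", ecs=("1.1.1.1",), subs=("CAL", "SUC")),
                make_reaction("R2", ecs=("2.2.2.2",), subs=("SUC",)),
            ],
        )
        t = _chain("t", ["R1"])
        m = overall_coexistence(q, t)
        assert m.b == 2  # R1 counted once despite two memberships
        assert hamming_distance(m) == pytest.approx(0.5)

    def test_matrix_layout(self, small_scenario, small_result):
        hd = small_result.hd
        assert list(hd.columns) == list(small_scenario.template_pathways)
        assert hd.index[-1] == "overall"
        assert ((hd >= 0) & (hd <= 1)).all().all()


def _ann(protein, ec, supporters):
    return EnzymeAnnotation(protein, ec, supporting_templates=set(supporters))


class TestPScore:
    def _table(self, annotations, sub_reactions):
        p = make_pathway("q", sub_reactions)
        return build_complexity_table(annotations, p, species=["a", "b"]), p

    def test_full_support_is_one(self):
        anns = [_ann(f"p{i}", "1.1.1.1", {"a"}) for i in range(3)]
        table, _ = self._table(anns, [make_reaction("R1", ecs=("1.1.1.1",))])
        assert p_score(table, "CAL", "a") == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # 2 ECs: (c=2 of C=4) and (c=1 of C=2) -> (0.5 + 0.5) / 2 = 0.5
        anns = (
            [_ann(f"p{i}", "1.1.1.1", {"a"}) for i in range(2)]
            + [_ann(f"p{i + 2}", "1.1.1.1", {"b"}) for i in range(2)]
            + [_ann("p9", "2.2.2.2", {"a"}), _ann("p10", "2.2.2.2", {"b"})]
        )
        table, _ = self._table(
            anns,
            [make_reaction("R1", ecs=("1.1.1.1",)), make_reaction("R2", ecs=("2.2.2.2",))],
        )
        assert p_score(table, "CAL", "a") == pytest.approx(0.5)

    def test_unsupporting_species_zero(self):
        anns = [_ann("p1", "1.1.1.1", {"a"})]
        table, _ = self._table(anns, [make_reaction("R1", ecs=("1.1.1.1",))])
        assert p_score(table, "CAL", "b") == 0.0

    def test_orphan_ec_counts_in_denominator(self):
        anns = [_ann("p1", "1.1.1.1", {"a"})]
        table, _ = self._table(
            anns,
            [
                make_reaction("R1", ecs=("1.1.1.1",)),
                make_reaction("R2", ecs=("9.9.9.9",), rtype="orphan"),
            ],
        )
        assert p_score(table, "CAL", "a") == pytest.approx(0.5)

    def test_oracle_1000_random_toys(self):
        """P agrees with a brute-force double loop on random toy tables
        with <= 6 ECs, and is monotone non-decreasing in any c_l."""
        rng = random.Random(7)
        for _ in range(1000):
            n_ec = rng.randint(1, 6)
            ecs = [f"1.1.1.{i + 1}" for i in range(n_ec)]
            anns = []
            p_count = 0
            for ec in ecs:
                for _ in range(rng.randint(0, 4)):
                    p_count += 1
                    supporters = {
                        k for k in ("a", "b") if rng.random() < 0.6
                    } or {"a"}
                    anns.append(_ann(f"p{p_count}", ec, supporters))
            reactions = [make_reaction(f"R{i}", ecs=(ec,)) for i, ec in enumerate(ecs)]
            pathway = make_pathway("q", reactions)
            table = build_complexity_table(anns, pathway, species=["a", "b"])
            for k in ("a", "b"):
                got = p_score(table, "CAL", k)
                total = 0.0
                for ec in ecs:
                    cpe = sum(a.ec == ec for a in anns)
                    c_l = sum(a.ec == ec and k in a.supporting_templates for a in anns)
                    if cpe:
                        total += c_l / cpe
                expect = total / len(ecs)
                assert got == pytest.approx(expect)
                assert 0.0 <= got <= 1.0
            # monotonicity: adding support for species a never lowers P
            unsupported = [a for a in anns if "a" not in a.supporting_templates]
            if unsupported:
                before = p_score(table, "CAL", "a")
                unsupported[0].supporting_templates.add("a")
                table2 = build_complexity_table(anns, pathway, species=["a", "b"])
                assert p_score(table2, "CAL", "a") >= before

    def test_matrix_bounds(self, small_result):
        assert ((small_result.p_scores >= 0) & (small_result.p_scores <= 1)).all().all()


class TestComplexityReport:
    def test_bucket_shares_and_max(self):
        anns = []
        # 3 ECs with 1 protein, 1 EC with 28 proteins
        for i in range(3):
            anns.append(_ann(f"p{i}", f"1.1.1.{i + 1}", {"a"}))
        anns += [_ann(f"q{i}", "2.4.1.12", {"a"}) for i in range(28)]
        reactions = [make_reaction(f"R{i}", ecs=(f"1.1.1.{i + 1}",)) for i in range(3)]
        reactions.append(make_reaction("R9", ecs=("2.4.1.12",), subs=("CEL",)))
        p = make_pathway("q", reactions)
        rep = complexity_report(build_complexity_table(anns, p), p)
        assert rep["max_c_pe"] == 28
        assert rep["n_le5"] == 3 and rep["n_gt10"] == 1
        assert rep["share_le5_pct"] == pytest.approx(75.0)

    def test_all_singletons_mean_one(self):
        anns = [_ann(f"p{i}", f"1.1.1.{i + 1}", {"a"}) for i in range(4)]
        p = make_pathway(
            "q", [make_reaction(f"R{i}", ecs=(f"1.1.1.{i + 1}",)) for i in range(4)]
        )
        rep = complexity_report(build_complexity_table(anns, p), p)
        assert all(v == 1.0 for v in rep["per_sub_mean"].values())
        assert rep["carbohydrate_group"]["mean_pooled_ecs"] == 1.0

    def test_group_mean_identity_when_balanced(self):
        # equal EC counts per sub-metabolism: pooled mean equals the
        # mean of per-sub means (guards against silent averaging bugs)
        anns = [
            _ann("p1", "1.1.1.1", {"a"}), _ann("p2", "1.1.1.1", {"a"}),
            _ann("p3", "2.2.2.2", {"a"}),
        ]
        p = make_pathway(
            "q",
            [
                make_reaction("R1", ecs=("1.1.1.1",), subs=("CAL",)),
                make_reaction("R2", ecs=("2.2.2.2",), subs=("STA",)),
            ],
        )
        rep = complexity_report(build_complexity_table(anns, p), p)
        g = rep["carbohydrate_group"]
        assert g["mean_pooled_ecs"] == pytest.approx(g["mean_of_sub_means"])


class TestEnzymeReactionGraph:
    def test_relation_classes(self):
        p = make_pathway(
            "q",
            [
                make_reaction("R1", ecs=("1.1.1.1",), subs=("CAL",)),
                make_reaction("R2", ecs=("2.2.2.2",), subs=("CAL",)),
                make_reaction("R3", ecs=("2.2.2.2",), subs=("CAL",)),
                make_reaction("R4", ecs=("3.3.3.3",), subs=("CAL",)),
                make_reaction("R5", ecs=("3.3.3.3",), subs=("SUC",)),
                make_reaction("R6", ecs=("4.4.4.4", "5.5.5.5"), subs=("SUC",)),
            ],
        )
        rep = enzyme_reaction_graph(p)
        assert rep["relation_class"]["1.1.1.1"] == "1:1"
        assert rep["relation_class"]["2.2.2.2"] == "1:many"
        assert rep["relation_class"]["3.3.3.3"] == "cross-pathway"
        assert rep["relation_class"]["4.4.4.4"] == "many:1"
        assert rep["multi_reaction_ecs"] == ["2.2.2.2", "3.3.3.3"]
        assert rep["multi_reaction_share_pct"] == pytest.approx(100 * 2 / 5)

    def test_all_degree_one_no_multi(self):
        p = make_pathway(
            "q", [make_reaction(f"R{i}", ecs=(f"1.1.1.{i + 1}",)) for i in range(3)]
        )
        rep = enzyme_reaction_graph(p)
        assert rep["multi_reaction_ecs"] == []
        assert rep["graph"].number_of_edges() == 3


class TestConservedCore:
    def test_identical_single_template_full_core(self):
        q = _chain("q", ["R1", "R2"])
        core = conserved_core(q, {"t": _chain("t", ["R1", "R2"])})
        assert core["n_core_reactions"] == 2
        assert core["core_share_pct"] == 100.0

    def test_core_is_intersection_over_all_templates(self):
        q = _chain("q", ["R1", "R2", "R3", "R4"])
        templates = {
            "t1": _chain("t1", ["R1", "R2", "R3"]),
            "t2": _chain("t2", ["R1", "R2", "R4"]),
        }
        core = conserved_core(q, templates)
        assert core["core_reactions"] == ["R1", "R2"]
        assert core["core_share_pct"] == pytest.approx(50.0)

    def test_core_antitone_in_templates(self):
        q = _chain("q", ["R1", "R2", "R3", "R4"])
        t1 = {"t1": _chain("t1", ["R1", "R2", "R3"])}
        t2 = {**t1, "t2": _chain("t2", ["R2", "R3"])}
        assert (
            conserved_core(q, t2)["n_core_reactions"]
            <= conserved_core(q, t1)["n_core_reactions"]
        )

    def test_species_specific_annotations_listed(self):
        q = _chain("q", ["R1"])
        anns = [_ann("p1", "2.7.9.2", {"maize"}), _ann("p2", "1.1.1.1", {"a", "b"})]
        core = conserved_core(q, {"t": _chain("t", ["R1"])}, anns)
        assert core["species_specific"] == [("2.7.9.2", "maize")]


class TestCSDistribution:
    def _pathway(self):
        return make_pathway("q", [make_reaction("R1", ecs=("1.1.1.1",), subs=("FAT",))])

    def test_all_conserved_symmetric(self):
        anns = [
            EnzymeAnnotation(f"p{i}", "1.1.1.1", supporting_templates={"a"}, cs=1.0)
            for i in range(5)
        ]
        d = cs_distribution(anns, "FAT", self._pathway())
        assert d["median"] == 1.0
        assert d["skewness"] == 0.0
        assert d["shape"] == "symmetric"

    def test_right_skewed_when_mostly_low_supporters(self):
        # moment-based skewness oracle: many CS 1/6 with a long right tail
        cs_values = [1 / 6] * 12 + [2 / 6] * 4 + [5 / 6, 1.0]
        from scipy import stats

        anns = [
            EnzymeAnnotation(f"p{i}", "1.1.1.1", supporting_templates={"a"}, cs=v)
            for i, v in enumerate(cs_values)
        ]
        d = cs_distribution(anns, "FAT", self._pathway())
        assert d["skewness"] == pytest.approx(stats.skew(cs_values, bias=False))
        assert d["skewness"] > 0.5
        assert d["shape"] == "right-skewed"

    def test_single_annotation_median_is_its_cs(self):
        anns = [EnzymeAnnotation("p1", "1.1.1.1", supporting_templates={"a"}, cs=0.5)]
        d = cs_distribution(anns, "FAT", self._pathway())
        assert d["median"] == 0.5 and d["n_proteins"] == 1

    def test_empty_sub_metabolism_errors(self):
        with pytest.raises(ValueError):
            cs_distribution([], "FAT", self._pathway())


def test_scores_long_format(small_result):
    long = scores_to_long(small_result.hd, "hd")
    assert set(long.columns) == {"sub_metabolism", "template", "hd"}
    assert len(long) == small_result.hd.size


def test_pipeline_hd_matches_planted_sharing(small_scenario, small_result):
    """Constructing a template to share a fraction f of a sub-metabolism's
    reactions yields HD = 1 - f exactly."""
    for (j, k), expect in small_scenario.truth.hd.items():
        assert small_result.hd.loc[j, k] == pytest.approx(expect, abs=1e-12)
    for k, expect in small_scenario.truth.hd_overall.items():
        assert small_result.hd.loc["overall", k] == pytest.approx(expect, abs=1e-12)
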