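import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_hypergeom_upper
from scproteo import (
    GeneSetCollection,
    category_tally,
    gsea_enrichment_score,
    gsea_run,
    ora_hypergeometric,
    read_gmt,
    write_gmt,
)


class TestGmt:
    def test_read_two_sets(self, tmp_path):
        f = tmp_path / "x.gmt"
        f.write_text("s1\td1\ta\tb\tc\ns2\td2\ta\tb\tc\td\te\n", encoding="utf-8")
        coll = read_gmt(f)
        assert len(coll) == 2
        assert coll["s2"] == list("abcde")

    def test_duplicate_member_warns(self, tmp_path):
        f = tmp_path / "x.gmt"
        f.write_text("s1\td\ta\tb\ta\n", encoding="utf-8")
        with pytest.warns(UserWarning, match="duplicate member"):
            coll = read_gmt(f)
        assert coll["s1"] == ["a", "b"]

    def test_duplicate_set_name_rejected(self, tmp_path):
        f = tmp_path / "x.gmt"
        f.write_text("s1\td\ta\tb\ns1\td\tc\td\n", encoding="utf-8")
        with pytest.raises(ValueError, match="duplicate set name"):
            read_gmt(f)

    def test_short_line_rejected_with_number(self, tmp_path):
        f = tmp_path / "x.gmt"
        f.write_text("s1\td\ta\nbad\tx\n", encoding="utf-8")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(f)

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            {"s1": ["a", "b"], "s2": ["x", "y", "z"]}, {"s1": "d1", "s2": "d2"}
        )
        f = tmp_path / "x.gmt"
        write_gmt(coll, f)
        back = read_gmt(f)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions


class TestOra:
    def test_worked_example_20_5_10_5(self):
        pop = [f"p{i}" for i in range(20)]
        sets = GeneSetCollection({"T": pop[:5]})
        rec = ora_hypergeometric(pop[:10], pop, sets)[0]
        assert rec.k == 5
        assert rec.p == pytest.approx(0.016254, abs=1e-6)
        assert rec.fold_enrichment == pytest.approx(2.0)

    def test_worked_example_10_2_5_2(self):
        pop = [f"p{i}" for i in range(10)]
        sets = GeneSetCollection({"T": pop[:2]})
        rec = ora_hypergeometric(pop[:5], pop, sets)[0]
        assert rec.p == pytest.approx(56 / 252, abs=1e-6)
        assert rec.p == pytest.approx(0.22222, abs=1e-5)

    def test_k0_tail_is_one(self):
        pop = [f"p{i}" for i in range(10)]
        sets = GeneSetCollection({"T": pop[:3]})
        rec = ora_hypergeometric(pop[5:8], pop, sets)[0]
        assert rec.k == 0
        assert rec.p == 1.0

    def test_study_not_subset_rejected(self):
        pop = ["a", "b"]
        sets = GeneSetCollection({"T": ["a"]})
        with pytest.raises(ValueError, match="zzz"):
            ora_hypergeometric(["a", "zzz"], pop, sets)

    def test_exhaustive_enumeration_oracle(self):
        # for N <= 12: p equals exact enumeration over all C(N, n) draws
        rng = np.random.default_rng(0)
        for N in (6, 9, 12):
            pop = [f"p{i}" for i in range(N)]
            for _ in range(5):
                K = int(rng.integers(1, N))
                n = int(rng.integers(1, N))
                members = list(rng.choice(pop, K, replace=False))
                study = list(rng.choice(pop, n, replace=False))
                k = len(set(members) & set(study))
                # oracle 1: enumerate all study draws of size n
                member_set = set(members)
                hits = 0
                total = 0
                for draw in itertools.combinations(pop, n):
                    total += 1
                    if len(member_set & set(draw)) >= k:
                        hits += 1
                enum_p = hits / total
                # oracle 2: exact pmf summation
                pmf_p = brute_force_hypergeom_upper(N, K, n, k)
                rec = ora_hypergeometric(
                    study, pop, GeneSetCollection({"T": members})
                )[0]
                assert rec.p == pytest.approx(enum_p, abs=1e-12)
                assert rec.p == pytest.approx(pmf_p, abs=1e-12)


class TestEnrichmentScore:
    IDS = ["g1", "g2", "g3", "g4", "g5"]
    SCORES = [3.0, 2.0, 1.0, -1.0, -2.0]

    def test_worked_example(self):
        es, run, le = gsea_enrichment_score(self.IDS, self.SCORES, {"g1", "g3"})
        np.testing.assert_allclose(
            run, [0.75, 0.41667, 0.66667, 0.33333, 0.0], atol=1e-5
        )
        assert es == pytest.approx(0.75)
        assert le == ["g1"]

    def test_negative_extremum(self):
        es, _, le = gsea_enrichment_score(self.IDS, self.SCORES, {"g5"})
        assert es == pytest.approx(-1.0)
        assert le == ["g5"]

    def test_full_set_rejected(self):
        with pytest.raises(ValueError, match="entire ranked list"):
            gsea_enrichment_score(self.IDS, self.SCORES, set(self.IDS))

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            gsea_enrichment_score(self.IDS, self.SCORES, {"zzz"})

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_running_sum_conserves_to_zero(self, data):
        n = data.draw(st.integers(min_value=3, max_value=40))
        ids = [f"g{i}" for i in range(n)]
        scores = data.draw(
            st.lists(
                st.floats(min_value=-50, max_value=50),
                min_size=n,
                max_size=n,
            )
        )
        k = data.draw(st.integers(min_value=1, max_value=n - 1))
        members = set(data.draw(st.permutations(ids))[:k])
        _, run, _ = gsea_enrichment_score(ids, scores, members)
        assert abs(run[-1]) < 1e-9

    def test_weight0_invariant_to_monotone_rescale(self):
        scores = np.array(self.SCORES)
        es1, _, _ = gsea_enrichment_score(self.IDS, scores, {"g2", "g4"}, weight=0)
        es2, _, _ = gsea_enrichment_score(
            self.IDS, np.sign(scores) * np.exp(np.abs(scores)), {"g2", "g4"}, weight=0
        )
        assert es1 == pytest.approx(es2)

    def test_positive_scaling_invariant_any_weight(self):
        for w in (0.5, 1.0, 2.0):
            es1, _, _ = gsea_enrichment_score(
                self.IDS, self.SCORES, {"g1", "g4"}, weight=w
            )
            es2, _, _ = gsea_enrichment_score(
                self.IDS, [7.3 * s for s in self.SCORES], {"g1", "g4"}, weight=w
            )
            assert es1 == pytest.approx(es2)

    def test_es_bounds(self):
        rng = np.random.default_rng(1)
        ids = [f"g{i}" for i in range(100)]
        scores = rng.normal(size=100)
        for _ in range(20):
            members = set(rng.choice(ids, size=int(rng.integers(1, 99)),
                                     replace=False))
            es, _, _ = gsea_enrichment_score(ids, scores, members)
            assert -1.0 <= es <= 1.0


class TestGseaRun:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        ids = [f"g{i}" for i in range(80)]
        scores = rng.normal(size=80)
        sets = GeneSetCollection({"s1": ids[:10], "s2": ids[20:35]})
        r1 = gsea_run(ids, scores, sets, n_perm=100, seed=5)
        r2 = gsea_run(ids, scores, sets, n_perm=100, seed=5)
        assert [(x.es, x.nes, x.p_perm, x.fdr) for x in r1] == [
            (x.es, x.nes, x.p_perm, x.fdr) for x in r2
        ]

    def test_p_range(self):
        rng = np.random.default_rng(2)
        ids = [f"g{i}" for i in range(100)]
        scores = rng.normal(size=100)
        sets = GeneSetCollection(
            {f"s{j}": list(rng.choice(ids, 10, replace=False)) for j in range(5)}
        )
        for r in gsea_run(ids, scores, sets, n_perm=200, seed=1):
            assert 1 / 201 <= r.p_perm <= 1.0
            assert np.sign(r.nes) == np.sign(r.es) or r.es == 0

    def test_low_n_perm_rejected(self):
        sets = GeneSetCollection({"s": ["g1"]})
        with pytest.raises(ValueError, match="n_perm"):
            gsea_run(["g1", "g2"], [1.0, 0.5], sets, n_perm=10, seed=0)


class TestCategoryTally:
    ANN = pd.DataFrame(
        {
            "protein_id": ["p1", "p2", "p3", "p3"],
            "category": ["lysosome", "lysosome", "ER", "lysosome"],
        }
    )

    def test_basic_counts(self):
        tally = category_tally(["p1", "p2", "p3", "p4"], self.ANN)
        d = dict(zip(tally["category"], tally["count"]))
        assert d == {"lysosome": 3, "ER": 1, "unannotated": 1}

    def test_multi_category_fractions_over_assignments(self):
        tally = category_tally(["p3"], self.ANN)
        d = dict(zip(tally["category"], tally["fraction"]))
        assert d["ER"] == pytest.approx(0.5)
        assert d["lysosome"] == pytest.approx(0.5)

    def test_empty_study(self):
        tally = category_tally([], self.ANN)
        assert len(tally) == 0
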