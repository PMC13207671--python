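import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_bh, make_meta, two_group_meta
from scproteo import (
    bh_adjust,
    differential_table,
    group_separation,
    students_t_test,
    zscore_top_k,
)


class TestStudentsT:
    def test_closed_form(self):
        # pooled t evaluated from the textbook formula
        x, y = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        sp2 = ((x.var(ddof=1) * 2) + (y.var(ddof=1) * 2)) / 4
        t_expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        t, p = students_t_test(x, y)
        assert t == pytest.approx(t_expected, abs=1e-10)
        assert t == pytest.approx(-3.67423, abs=1e-5)
        assert p == pytest.approx(0.02131, abs=1e-5)

    def test_identical_samples(self):
        t, p = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        t1, p1 = students_t_test([1.0, 2.0], [5.0, 9.0])
        t2, p2 = students_t_test([5.0, 9.0], [1.0, 2.0])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t, p = students_t_test([2.0, 2.0], [3.0, 3.0])
        assert np.isnan(p)


class TestBhAdjust:
    def test_hand_computed(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    def test_single_identity(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_q_geq_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        assert np.all(bh_adjust(p) >= p)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200)
    )
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], brute_force_bh([0.01, 0.5]))


def _table_fixture(log2fc_values, q_scale=1e-6, n_per_group=3, sigma=1e-3, seed=0):
    """Tiny dataset with tightly controlled per-protein group differences."""
    rng = np.random.default_rng(seed)
    meta = two_group_meta(n_per_group, prefix=("a", "b"))
    n = len(log2fc_values)
    base = np.full((n, n_per_group), 10.0) + rng.normal(0, sigma, (n, n_per_group))
    up = base.mean(axis=1, keepdims=True) + np.asarray(log2fc_values)[:, None] + rng.normal(
        0, sigma, (n, n_per_group)
    )
    df = pd.DataFrame(
        np.hstack([base, up]),
        index=[f"p{i}" for i in range(n)],
        columns=meta.cell_ids,
    )
    return df, meta


class TestDifferentialTable:
    def test_fc_boundary_inclusive(self):
        # group difference exactly log2(1.5): class must be "up"
        df, meta = _table_fixture([np.log2(1.5), 2.0, 0.0] + [0.0] * 20, sigma=1e-4)
        # remove sampling jitter from the means so the boundary is exact
        fc = np.log2(1.5)
        a_cols = [c for c in df.columns if c.startswith("a")]
        b_cols = [c for c in df.columns if c.startswith("b")]
        df.loc["p0", a_cols] = [10.0, 10.0001, 9.9999]
        df.loc["p0", b_cols] = df.loc["p0", a_cols].to_numpy() + fc
        table = differential_table(df, meta).table
        row = table[table["protein_id"] == "p0"].iloc[0]
        assert row["log2fc"] == pytest.approx(fc, abs=1e-12)
        assert row["q"] < 0.05
        assert row["class"] == "up"

    def test_fdr_boundary_strict(self):
        # q exactly at the threshold must stay ns
        df, meta = _table_fixture([1.0, 0.0, 0.0])
        table = differential_table(df, meta, fdr_threshold=1e-300).table
        assert (table["class"] == "ns").all()

    def test_classes_partition(self, clean_dataset):
        m, meta, _ = clean_dataset
        table = differential_table(np.log2(m.data), meta).table
        counts = table["class"].value_counts()
        assert counts.sum() == len(table)
        assert set(counts.index) <= {"up", "down", "ns", "unclassifiable"}

    def test_relabel_swaps_up_down(self, clean_dataset):
        m, meta, _ = clean_dataset
        df = np.log2(m.data)
        t1 = differential_table(df, meta, reference="control")
        t2 = differential_table(df, meta, reference="storage")
        assert sorted(t1.up) == sorted(t2.down)
        assert sorted(t1.down) == sorted(t2.up)
        np.testing.assert_allclose(
            t1.table["log2fc"].values, -t2.table["log2fc"].values, atol=1e-12
        )

    def test_fc_linear_column(self, clean_dataset):
        m, meta, _ = clean_dataset
        table = differential_table(np.log2(m.data), meta).table
        np.testing.assert_allclose(
            table["fc_linear"], np.exp2(table["log2fc"]), rtol=1e-12
        )


class TestZscoreTopK:
    def test_rows_standardized(self, clean_dataset):
        m, meta, _ = clean_dataset
        df = np.log2(m.data)
        table = differential_table(df, meta)
        z, _ = zscore_top_k(df, table, k=20)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_k1_trivial(self, clean_dataset):
        m, meta, _ = clean_dataset
        df = np.log2(m.data)
        table = differential_table(df, meta)
        z, order = zscore_top_k(df, table, k=1)
        assert order == [0]
        assert z.shape[0] == 1

    def test_duplicated_profiles_adjacent(self):
        rng = np.random.default_rng(3)
        meta = two_group_meta(4, prefix=("a", "b"))
        vals = rng.normal(10, 1, (10, 8))
        vals[:, 4:] += rng.normal(0, 0.5, (10, 4))
        vals[7] = vals[2] * 1.5 + 0.3  # same correlation profile as row 2
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(10)],
                          columns=meta.cell_ids)
        table = differential_table(df, meta)
        z, _ = zscore_top_k(df, table, k=10)
        rows = list(z.index)
        assert abs(rows.index("p2") - rows.index("p7")) == 1

    def test_k_too_large_rejected(self, clean_dataset):
        m, meta, _ = clean_dataset
        df = np.log2(m.data)
        table = differential_table(df, meta)
        with pytest.raises(ValueError, match="k="):
            zscore_top_k(df, table, k=10**6)


class TestGroupSeparation:
    def test_null_near_zero(self):
        scores = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            meta = two_group_meta(12, prefix=("a", "b"))
            df = pd.DataFrame(
                rng.normal(10, 1, (300, 24)),
                index=[f"p{i}" for i in range(300)],
                columns=meta.cell_ids,
            )
            scores.append(group_separation(df, meta))
        assert np.mean(np.abs(scores)) < 0.15

    def test_strong_separation(self):
        rng = np.random.default_rng(1)
        meta = two_group_meta(12, prefix=("a", "b"))
        vals = rng.normal(10, 0.5, (2500, 24))
        vals[:1000, 12:] += 1.0  # 1000 planted DEPs at |log2fc| >= 1
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(2500)],
                          columns=meta.cell_ids)
        assert group_separation(df, meta) > 0.5

    def test_replication_near_invariant(self):
        rng = np.random.default_rng(2)
        meta = two_group_meta(6, prefix=("a", "b"))
        vals = rng.normal(10, 0.5, (200, 12))
        vals[:80, 6:] += 1.0
        df = pd.DataFrame(vals, index=[f"p{i}" for i in range(200)],
                          columns=meta.cell_ids)
        s1 = group_separation(df, meta)
        dup = pd.concat(
            [df, df.rename(columns={c: c + "_dup" for c in df.columns})], axis=1
        )
        groups = {c: c[0] for c in dup.columns}
        meta2 = make_meta(groups)
        s2 = group_separation(dup, meta2)
        assert s2 == pytest.approx(s1, abs=0.05)

    def test_degenerate_matrix_rejected(self):
        meta = two_group_meta(2, prefix=("a", "b"))
        df = pd.DataFrame(np.full((5, 4), 3.0), columns=meta.cell_ids)
        with pytest.raises(ValueError, match="zero-variance"):
            group_separation(df, meta)
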