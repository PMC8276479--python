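import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import cnvpd
from cnvpd.models import CopyNumberMatrix, Group, SampleMeta
from cnvpd.popdiff import (
    call_differentiated,
    kruskal_wallis,
    kruskal_wallis_table,
    pairwise_vst_matrix,
    vst,
    vst_thresholds,
)


# ---------------------------------------------------------------- oracles
def brute_variance(xs, ddof=1):
    """Sample variance from first principles (no numpy)."""
    n = len(xs)
    mean = sum(xs) / n
    return sum((x - mean) ** 2 for x in xs) / (n - ddof)


def brute_vst(a, b):
    v_t = brute_variance(list(a) + list(b))
    v_s = (len(a) * brute_variance(a) + len(b) * brute_variance(b)) / (len(a) + len(b))
    if v_t == 0:
        return 0.0
    return min(1.0, max(0.0, (v_t - v_s) / v_t))


def brute_ranks(values):
    """Midranks by explicit pairwise counting."""
    return [
        1
        + sum(1 for y in values if y < x)
        + 0.5 * sum(1 for j, y in enumerate(values) if y == x and j != i)
        for i, x in enumerate(values)
    ]


def brute_kw_h(groups):
    """Tie-corrected H from the rank-sum formula, built on brute_ranks."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = brute_ranks(pooled)
    h, off = 0.0, 0
    for g in groups:
        r = ranks[off : off + len(g)]
        h += len(g) * (sum(r) / len(g) - (n + 1) / 2) ** 2
        off += len(g)
    h *= 12 / (n * (n + 1))
    ties = {}
    for x in pooled:
        ties[x] = ties.get(x, 0) + 1
    corr = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return 0.0 if corr == 0 else h / corr


# ------------------------------------------------------------------ V_ST
class TestVst:
    def test_fully_separated_constants_give_one(self):
        r = vst([2, 2, 2, 2], [4, 4, 4, 4])
        assert r.v_within == 0.0
        assert r.vst == 1.0

    def test_identical_populations_give_zero(self):
        r = vst([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.vst == 0.0
        assert r.vst_raw <= 0.0

    def test_hand_computed_example(self):
        # var_a = var_b = 1, V_S = 1, V_T = 1.1 -> (1.1-1)/1.1
        r = vst([1, 2, 3], [2, 3, 4])
        assert r.v_total == pytest.approx(1.1)
        assert r.v_within == pytest.approx(1.0)
        assert r.vst == pytest.approx(0.1 / 1.1)

    def test_degenerate_total_variance_yields_zero(self):
        r = vst([2, 2], [2, 2])
        assert r.vst == 0.0

    def test_small_populations_rejected(self):
        with pytest.raises(ValueError):
            vst([1.0], [1.0, 2.0])

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        shift=st.floats(-10, 10),
        scale=st.floats(0.1, 10),
    )
    def test_shift_scale_invariance_and_symmetry(self, a, b, shift, scale):
        base = vst(a, b).vst
        shifted = vst([x + shift for x in a], [x + shift for x in b]).vst
        scaled = vst([x * scale for x in a], [x * scale for x in b]).vst
        assert vst(b, a).vst == pytest.approx(base, abs=1e-9)
        assert shifted == pytest.approx(base, abs=1e-6)
        assert scaled == pytest.approx(base, abs=1e-6)


# --------------------------------------------------------- pairwise matrix
def toy_matrix():
    rng = np.random.default_rng(11)
    individuals = [f"I{i}" for i in range(12)]
    metas = [
        SampleMeta(f"I{i}", breed=f"B{i // 3}", group=list(Group)[i // 3])
        for i in range(12)
    ]
    cn = 2.0 + rng.normal(0, 0.3, size=(20, 12))
    cn[0, 3:6] += 4.0  # one locus strongly differentiated in breed B1
    cn = np.clip(cn, 0, None)
    matrix = CopyNumberMatrix(
        cnvr_ids=[f"R{k}" for k in range(20)],
        individual_ids=individuals,
        cn=cn,
        presence=(np.abs(cn - 2.0) > 0.5).astype(np.int8),
    )
    return matrix, metas


class TestPairwiseVst:
    def test_two_breeds_give_one_pair_per_cnvr(self):
        matrix, metas = toy_matrix()
        sub = matrix.subset_individuals([f"I{i}" for i in range(6)])
        long, mean = pairwise_vst_matrix(sub, metas[:6], grouping="breed")
        assert set(zip(long["pop_a"], long["pop_b"])) == {("B0", "B1")}
        assert len(long) == len(sub.cnvr_ids)

    def test_mean_matrix_symmetric_zero_diagonal(self):
        matrix, metas = toy_matrix()
        _, mean = pairwise_vst_matrix(matrix, metas, grouping="breed")
        np.testing.assert_allclose(mean.to_numpy(), mean.to_numpy().T)
        assert np.all(np.diag(mean.to_numpy()) == 0)

    def test_matches_scalar_vst_and_mean_oracle(self):
        matrix, metas = toy_matrix()
        long, mean = pairwise_vst_matrix(matrix, metas, grouping="breed")
        by_breed = {}
        for j, ind in enumerate(matrix.individual_ids):
            breed = next(m.breed for m in metas if m.individual_id == ind)
            by_breed.setdefault(breed, []).append(j)
        for row in long.sample(30, random_state=0).itertuples():
            i = matrix.cnvr_ids.index(row.cnvr_id)
            expected = brute_vst(
                matrix.cn[i, by_breed[row.pop_a]].tolist(),
                matrix.cn[i, by_breed[row.pop_b]].tolist(),
            )
            assert row.vst == pytest.approx(expected, abs=1e-12)
        # mean matrix equals per-pair means computed independently
        for (a, b), grp in long.groupby(["pop_a", "pop_b"]):
            assert mean.loc[a, b] == pytest.approx(grp["vst"].mean())

    def test_differentiated_breed_pair_is_matrix_maximum(self):
        matrix, metas = toy_matrix()
        # B0 drops on loci 0-9 and B1 gains on loci 10-19, so the B0-B1
        # pair is differentiated at twice as many loci as any other pair
        matrix.cn[:10, 0:3] = np.clip(matrix.cn[:10, 0:3] - 1.8, 0, None)
        matrix.cn[10:, 3:6] += 5.0
        _, mean = pairwise_vst_matrix(matrix, metas, grouping="breed")
        vals = mean.where(~np.eye(len(mean), dtype=bool))
        stacked = vals.stack()
        assert set(stacked.idxmax()) == {"B0", "B1"}

    def test_singleton_breeds_excluded(self):
        matrix, metas = toy_matrix()
        metas = list(metas)
        metas[0] = SampleMeta("I0", breed="SOLO", group=Group.EAT)
        long, _ = pairwise_vst_matrix(matrix, metas, grouping="breed")
        assert "SOLO" not in set(long["pop_a"]) | set(long["pop_b"])

    def test_fewer_than_two_populations_rejected(self):
        matrix, metas = toy_matrix()
        metas = [SampleMeta(m.individual_id, "ONE", m.group) for m in metas]
        with pytest.raises(ValueError):
            pairwise_vst_matrix(matrix, metas, grouping="breed")


# --------------------------------------------------------- Kruskal-Wallis
class TestKruskalWallis:
    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [
                rng.choice([0.0, 1.0, 2.0, 2.5, 7.0], size=rng.integers(2, 10))
                for _ in range(k)
            ]
            ours = kruskal_wallis(groups)
            ref = stats.kruskal(*groups)
            assert ours.h_statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matches_brute_force_rank_oracle_small_n(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(4, 9))
            split = int(rng.integers(2, n - 1))
            values = rng.integers(0, 3, size=n).astype(float)
            groups = [values[:split], values[split:]]
            ours = kruskal_wallis(groups)
            assert ours.h_statistic == pytest.approx(
                brute_kw_h([g.tolist() for g in groups]), abs=1e-12
            )

    def test_two_group_example_exact(self):
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.h_statistic == pytest.approx(brute_kw_h([[1, 2], [3, 4]]))
        assert res.df == 1

    def test_all_identical_values(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.h_statistic == 0.0
        assert res.pvalue == 1.0

    def test_table_matches_scalar_calls(self):
        matrix, metas = toy_matrix()
        table = kruskal_wallis_table(matrix, metas)
        by_group = {}
        for j, ind in enumerate(matrix.individual_ids):
            g = next(m.group for m in metas if m.individual_id == ind)
            by_group.setdefault(g, []).append(j)
        for i in (0, 5, 19):
            expected = kruskal_wallis(
                [matrix.cn[i, idx] for g, idx in by_group.items() if g in cnvpd.ANALYSIS_GROUPS]
            )
            assert table.loc[i, "pvalue"] == pytest.approx(expected.pvalue)


# -------------------------------------------------------- dual criterion
class TestCallDifferentiated:
    def make_tables(self, vst_values, kw_pvalues):
        n = len(vst_values)
        vst_long = pd.DataFrame(
            {
                "cnvr_id": [f"R{i}" for i in range(n)],
                "pop_a": "EAT",
                "pop_b": "ASI",
                "v_total": 1.0,
                "v_within": 1.0,
                "vst_raw": vst_values,
                "vst": vst_values,
            }
        )
        kw = pd.DataFrame(
            {
                "cnvr_id": [f"R{i}" for i in range(n)],
                "h_statistic": 1.0,
                "df": 3,
                "pvalue": kw_pvalues,
            }
        )
        return vst_long, kw

    def test_threshold_is_order_statistic_quantile(self):
        rng = np.random.default_rng(1)
        values = rng.random(1000)
        vst_long, kw = self.make_tables(values, np.full(1000, 0.5))
        thr = vst_thresholds(vst_long, (0.99,))[0.99]
        srt = np.sort(values)
        # linear interpolation between order statistics at h = 0.99*(n-1)
        h = 0.99 * (len(values) - 1)
        lo, frac = int(np.floor(h)), h - np.floor(h)
        expected = srt[lo] * (1 - frac) + srt[lo + 1] * frac
        assert thr == pytest.approx(expected, abs=1e-15)

    def test_dual_criterion_requires_both_arms(self):
        values = np.linspace(0, 0.5, 999).tolist() + [0.99]
        # the extreme CNVR fails the KW arm -> not differentiated
        vst_long, kw = self.make_tables(values, [0.5] * 1000)
        table, _ = call_differentiated(vst_long, kw)
        assert not table["differentiated"].any()
        assert table.loc[table["cnvr_id"] == "R999", "vst_top"].item()

        vst_long, kw = self.make_tables(values, [0.5] * 999 + [0.001])
        table, _ = call_differentiated(vst_long, kw)
        called = table.loc[table["differentiated"], "cnvr_id"].tolist()
        assert "R999" in called

    def test_empty_input_gives_empty_output(self):
        table, thresholds = call_differentiated(
            pd.DataFrame(columns=["cnvr_id", "pop_a", "pop_b", "vst"]),
            pd.DataFrame(columns=["cnvr_id", "h_statistic", "df", "pvalue"]),
        )
        assert table.empty
        assert thresholds == {}

    def test_top_pair_classes_attached(self):
        values = [0.1] * 998 + [0.92, 0.99]
        vst_long, kw = self.make_tables(values, [0.001] * 1000)
        table, thr = call_differentiated(vst_long, kw)
        row = table.set_index("cnvr_id").loc["R999"]
        assert "EAT-ASI" in row["top_pairs"]
        assert "EAT-ASI" in row["top01_pairs"]
        row92 = table.set_index("cnvr_id").loc["R998"]
        assert row92["top_pairs"] and not row92["top01_pairs"]
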