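import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from regulonkit.config import PipelineConfig
from regulonkit.core_io import ExpressionMatrix
from regulonkit.expression import (
    build_cems, call_degs, operon_profiles, wilcoxon_signed_rank,
)

from conftest import make_operon


def brute_force_signed_rank_p(diffs):
    """Two-sided p by exhaustive enumeration of all 2^n sign assignments,
    conditioning on the observed |difference| midranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.array(ws)
    n = len(ws)
    lower = (ws <= w_obs + 1e-9).sum() / n
    upper = (ws >= w_obs - 1e-9).sum() / n
    return min(1.0, 2 * min(lower, upper))


class TestWilcoxonSignedRank:
    def test_identical_vectors_degenerate(self):
        w, p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_n8_all_positive_exact(self):
        # all 8 differences positive: W+ is maximal, two-sided p = 2 / 2^8
        w, p = wilcoxon_signed_rank(np.zeros(8), np.arange(1.0, 9.0))
        assert w == 36.0
        assert p == pytest.approx(0.0078125, abs=0)

    def test_n8_one_negative_smallest_magnitude(self):
        treatment = np.array([5, 6, 7, 8, 9, 10, 11, -0.5])
        control = np.zeros(8)
        _, p = wilcoxon_signed_rank(control, treatment)
        assert p == pytest.approx(brute_force_signed_rank_p(treatment), rel=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 8, 10])
    def test_matches_enumeration_random_inputs(self, n, rng):
        for _ in range(25):
            d = np.round(rng.normal(size=n), 2)
            _, p = wilcoxon_signed_rank(np.zeros(n), d)
            assert p == pytest.approx(brute_force_signed_rank_p(d), rel=1e-12)

    def test_matches_enumeration_with_ties(self, rng):
        for _ in range(20):
            d = rng.choice([-2.0, -1.0, 1.0, 2.0, 3.0], size=7)
            _, p = wilcoxon_signed_rank(np.zeros(7), d)
            assert p == pytest.approx(brute_force_signed_rank_p(d), rel=1e-12)

    def test_agrees_with_scipy_exact_when_tie_free(self, rng):
        for _ in range(10):
            d = rng.normal(size=9)
            _, p = wilcoxon_signed_rank(np.zeros(9), d)
            assert p == pytest.approx(
                scipy_wilcoxon(d, method="exact").pvalue, rel=1e-9)

    def test_large_n_normal_approximation_reasonable(self, rng):
        d = rng.normal(0.5, 1.0, size=60)
        _, p = wilcoxon_signed_rank(np.zeros(60), d)
        sp = scipy_wilcoxon(d, correction=True, method="approx").pvalue
        assert p == pytest.approx(sp, rel=1e-6)


def _paired_matrix(values, n_pairs):
    n_genes = values.shape[0]
    cols = [f"c{i}" for i in range(n_pairs)] + [f"t{i}" for i in range(n_pairs)]
    design = pd.DataFrame({
        "sample": cols,
        "condition": ["control"] * n_pairs + ["treatment"] * n_pairs,
        "pair": list(range(n_pairs)) * 2,
    })
    vals = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    return ExpressionMatrix(vals, design)


class TestCallDegs:
    def test_planted_shift_all_recovered(self, config, rng):
        n_pairs, n_shift, n_null = 8, 50, 950
        base = rng.normal(0, 0.5, size=(n_shift + n_null, 2 * n_pairs))
        base[:n_shift, n_pairs:] += 2.0
        expr = _paired_matrix(base, n_pairs)
        degs = call_degs(expr, config)
        shifted = [d for d in degs if int(d.gene_id[1:]) < n_shift]
        assert all(d.direction == "up" for d in shifted)
        # false positives binomial around the achievable alpha (0.0391 at n=8)
        fp = sum(1 for d in degs[n_shift:] if d.direction != "none")
        alpha_eff = 10 / 256  # largest achievable two-sided level below 0.05
        mean, sd = n_null * alpha_eff, np.sqrt(n_null * alpha_eff * (1 - alpha_eff))
        assert fp <= mean + 3 * sd

    def test_all_null_type_i_error_controlled(self, config, rng):
        n_null, n_pairs = 950, 8
        expr = _paired_matrix(rng.normal(size=(n_null, 2 * n_pairs)), n_pairs)
        degs = call_degs(expr, config)
        n_called = sum(1 for d in degs if d.direction != "none")
        alpha_eff = 10 / 256
        mean, sd = n_null * alpha_eff, np.sqrt(n_null * alpha_eff * (1 - alpha_eff))
        assert n_called <= mean + 3 * sd

    def test_empty_matrix(self, config):
        expr = _paired_matrix(np.empty((0, 8)), 4)
        assert call_degs(expr, config) == []

    def test_adjusted_p_reported_and_bounded(self, config, rng):
        expr = _paired_matrix(rng.normal(size=(20, 16)), 8)
        for d in call_degs(expr, config):
            assert 0 <= d.p_value <= 1 and d.p_value <= d.adjusted_p <= 1


class TestOperonProfiles:
    def test_single_gene_operon_equals_gene_profile(self, rng):
        expr = _paired_matrix(rng.normal(size=(3, 8)), 4)
        op = make_operon("op", "+", (1, 5))
        op = op.__class__("op", (op.genes[0].__class__("g0", 1, 5, "+"),), "+")
        prof = operon_profiles(expr, [op])
        assert np.allclose(prof.loc["op"], expr.values.loc["g0"])

    def test_opposite_profiles_average_to_zero(self):
        vals = np.vstack([np.arange(8.0), -np.arange(8.0)])
        expr = _paired_matrix(vals, 4)
        from regulonkit.core_io import Gene, Operon
        op = Operon("op", (Gene("g0", 1, 5, "+"), Gene("g1", 10, 15, "+")), "+")
        prof = operon_profiles(expr, [op])
        assert np.allclose(prof.loc["op"], 0.0)

    def test_matches_brute_force_mean(self, rng):
        from regulonkit.core_io import Gene, Operon
        expr = _paired_matrix(rng.normal(size=(30, 8)), 4)
        ops, gi = [], 0
        for i in range(10):
            k = int(rng.integers(1, 4))
            genes = tuple(Gene(f"g{gi + j}", 10 * (gi + j) + 1, 10 * (gi + j) + 5, "+")
                          for j in range(k))
            gi += k
            ops.append(Operon(f"op{i}", genes, "+"))
        prof = operon_profiles(expr, ops)
        for op in ops:
            expected = np.mean(
                [expr.values.loc[g.locus_tag] for g in op.genes], axis=0)
            assert np.allclose(prof.loc[op.operon_id], expected)

    def test_operon_without_expressed_genes_dropped(self, rng):
        from regulonkit.core_io import Gene, Operon
        expr = _paired_matrix(rng.normal(size=(1, 8)), 4)
        ops = [Operon("present", (Gene("g0", 1, 5, "+"),), "+"),
               Operon("absent", (Gene("missing", 10, 15, "+"),), "+")]
        prof = operon_profiles(expr, ops)
        assert list(prof.index) == ["present"]


def _block_profiles(rng, sizes, scale=50.0, noise=0.1, n_samples=6):
    rows, index, block_of = [], [], {}
    for b, size in enumerate(sizes):
        center = rng.normal(0, scale, size=n_samples)
        for j in range(size):
            oid = f"b{b}_o{j:03d}"
            rows.append(center + rng.normal(0, noise, size=n_samples))
            index.append(oid)
            block_of[oid] = b
    return pd.DataFrame(rows, index=index), block_of


class TestBuildCems:
    def test_planted_blocks_recovered(self, config, rng):
        profiles, block_of = _block_profiles(rng, [10, 10, 10])
        cems, _ = build_cems(profiles, config)
        assert len(cems) == 3
        for cem in cems:
            assert len({block_of[o] for o in cem.operon_ids}) == 1

    def test_oversize_cluster_removed(self, config, rng):
        profiles, _ = _block_profiles(rng, [201] + [2] * 10)
        cems, log = build_cems(profiles, config)
        assert len(log["removed_oversize"]) == 1
        assert len(log["removed_oversize"][0]) == 201
        assert all(c.size <= config.max_cem_size for c in cems)

    def test_identical_pair_forms_module(self, config, rng):
        profiles, _ = _block_profiles(rng, [1] * 12)
        profiles.loc["twin"] = profiles.iloc[0]
        cems, log = build_cems(profiles, config)
        pair = [c for c in cems if profiles.index[0] in c.operon_ids]
        assert pair and pair[0].operon_ids == {profiles.index[0], "twin"}

    def test_row_order_invariance(self, config, rng):
        profiles, _ = _block_profiles(rng, [8, 8, 8])
        shuffled = profiles.sample(frac=1.0, random_state=3)
        a, _ = build_cems(profiles, config)
        b, _ = build_cems(shuffled, config)
        assert [c.operon_ids for c in a] == [c.operon_ids for c in b]

    def test_size_accounting(self, config, rng):
        profiles, _ = _block_profiles(rng, [201, 10, 5, 1, 1, 2])
        cems, log = build_cems(profiles, config)
        total = (sum(c.size for c in cems)
                 + sum(len(m) for m in log["removed_oversize"])
                 + len(log["singletons"]))
        assert total == len(profiles)

    def test_fewer_than_two_operons_rejected(self, config):
        with pytest.raises(ValueError):
            build_cems(pd.DataFrame([[1.0, 2.0]], index=["solo"]), config)
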