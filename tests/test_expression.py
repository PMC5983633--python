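"""TPM normalization, differential-expression calling, and qPCR ratios."""

import numpy as np
import pandas as pd
import pytest

from mirstalk.expression import (CountMatrix, LibraryMeta, QPCRSample,
                                 bh_adjust, comparison_summary, ddct, de_test,
                                 tpm)


def make_matrix(counts: np.ndarray, libraries: list[str],
                depth: int = 1_000_000) -> CountMatrix:
    frame = pd.DataFrame(counts, index=[f"m{i}" for i in range(len(counts))],
                         columns=libraries)
    meta = {lib: LibraryMeta(lib, "stem", "C", i + 1, depth)
            for i, lib in enumerate(libraries)}
    return CountMatrix(frame, meta)


def simulate_counts(rng, n_mirna, libs_per_group, base_mean=200.0,
                    dispersion=0.05, lfc=None):
    """NB counts for a two-group design; ``lfc`` maps row index -> log2FC."""
    n = 1.0 / dispersion
    means = rng.lognormal(np.log(base_mean), 1.0, size=n_mirna)
    cols = []
    for g, group in enumerate(("A", "B")):
        for _ in range(libs_per_group):
            mu = means.copy()
            if g == 1 and lfc:
                for idx, change in lfc.items():
                    mu[idx] *= 2.0 ** change
            cols.append(rng.negative_binomial(n, n / (n + mu)))
    return np.column_stack(cols)


class TestTpm:
    @pytest.mark.parametrize("count,total,expected", [
        (1, 1_000_000, 1.0),
        (250, 10_000_000, 25.0),
        (0, 12345, 0.0),
    ])
    def test_examples(self, count, total, expected):
        assert tpm(count, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tpm(5, 0)

    def test_library_tpm_sums_below_million(self, rng):
        counts = rng.integers(0, 500, size=(50, 4))
        matrix = make_matrix(counts, ["a", "b", "c", "d"], depth=100_000)
        sums = matrix.tpm_matrix().sum(axis=0)
        expected = counts.sum(axis=0) / 100_000 * 1e6
        assert np.allclose(sums, expected)
        assert (sums <= 1e6).all()


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_textbook_step_up_oracle(self):
        pvals = [0.01, 0.02, 0.03, 0.04]
        # independent direct implementation of the step-up formula
        m = len(pvals)
        order = np.argsort(pvals)
        ranked = np.array(pvals)[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(ranked, 1.0)
        assert bh_adjust(pvals) == pytest.approx(expected.tolist())

    def test_bounds_and_monotonicity(self, rng):
        for _ in range(20):
            p = rng.random(50)
            adj = np.array(bh_adjust(p))
            assert ((adj >= p - 1e-12) & (adj <= 1.0)).all()

    def test_permutation_invariance(self, rng):
        p = rng.random(30)
        perm = rng.permutation(30)
        adj = np.array(bh_adjust(p))
        adj_perm = np.array(bh_adjust(p[perm]))
        assert np.allclose(adj[perm], adj_perm)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDeTest:
    def test_identity_groups_give_zero_fc(self, rng):
        half = rng.integers(0, 300, size=(40, 3))
        counts = np.hstack([half, half])
        matrix = make_matrix(counts, ["a1", "a2", "a3", "b1", "b2", "b3"])
        results = de_test(matrix, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert all(r.log2fc == 0 for r in results)
        assert not any(r.significant for r in results)

    def test_swap_negates_log2fc(self, rng):
        counts = simulate_counts(rng, 50, 3, lfc={0: 2.0, 1: -2.0})
        libs = ["a1", "a2", "a3", "b1", "b2", "b3"]
        matrix = make_matrix(counts, libs)
        fwd = de_test(matrix, libs[:3], libs[3:])
        rev = de_test(matrix, libs[3:], libs[:3])
        for f, r in zip(fwd, rev):
            assert f.log2fc == pytest.approx(-r.log2fc)

    def test_group_validation(self, rng):
        counts = rng.integers(1, 100, size=(10, 4))
        matrix = make_matrix(counts, ["a1", "a2", "b1", "b2"])
        with pytest.raises(ValueError):
            de_test(matrix, ["a1", "a2"], ["a2", "b1"])
        with pytest.raises(ValueError):
            de_test(matrix, ["a1"], ["b1", "b2"])

    def test_planted_fourfold_recovery(self):
        rng = np.random.default_rng(1)
        planted = {i: 2.0 for i in range(20)}
        counts = simulate_counts(rng, 200, 3, dispersion=0.05, lfc=planted)
        libs = ["a1", "a2", "a3", "b1", "b2", "b3"]
        matrix = make_matrix(counts, libs)
        results = de_test(matrix, libs[:3], libs[3:])
        called = {int(r.mirna[1:]) for r in results if r.significant}
        tp = len(called & set(planted))
        fp = len(called - set(planted))
        assert tp / len(planted) >= 0.9
        assert fp / max(1, len(called)) <= 0.1
        # estimated effect centred on the planted 4-fold change
        est = [r.log2fc for r in results if int(r.mirna[1:]) in planted]
        assert abs(float(np.mean(est)) - 2.0) <= 0.3

    def test_null_simulation_type_i_control(self):
        rng = np.random.default_rng(2)
        counts = simulate_counts(rng, 1000, 3, dispersion=0.05)
        libs = ["a1", "a2", "a3", "b1", "b2", "b3"]
        matrix = make_matrix(counts, libs)
        results = de_test(matrix, libs[:3], libs[3:])
        fraction = np.mean([r.padj <= 0.05 for r in results])
        assert fraction <= 0.05


class TestComparisonSummary:
    def _result(self, mirna, label, lfc, padj=0.01):
        from mirstalk.expression import DEResult
        return DEResult(mirna, label, lfc, 10, 10 * 2 ** lfc, 0.001, padj)

    def test_identical_sets(self):
        res = {
            "A": [self._result("x", "A", 2.0), self._result("y", "A", -2.0)],
            "B": [self._result("x", "B", 2.0), self._result("y", "B", -2.0)],
        }
        summary = comparison_summary(res)
        assert summary.up_down["A"] == (1, 1)
        assert summary.venn[frozenset({"A", "B"})] == 2
        assert summary.venn[frozenset({"A"})] == 0

    def test_disjoint_sets(self):
        res = {
            "A": [self._result("a", "A", 2.0)],
            "B": [self._result("b", "B", 1.5)],
        }
        summary = comparison_summary(res)
        assert summary.venn[frozenset({"A"})] == 1
        assert summary.venn[frozenset({"B"})] == 1
        assert summary.venn[frozenset({"A", "B"})] == 0

    def test_enumeration_oracle_three_way(self, rng):
        universe = [f"m{i}" for i in range(40)]
        sets = {}
        res = {}
        for label in ("A", "B", "C"):
            members = {m for m in universe if rng.random() < 0.4}
            sets[label] = members
            res[label] = [self._result(m, label, 2.0) for m in members]
        summary = comparison_summary(res)
        for combo, count in summary.venn.items():
            expected = sum(
                1 for m in universe
                if all(m in sets[l] for l in combo)
                and not any(m in sets[l] for l in sets if l not in combo)
            )
            assert count == expected


class TestDdct:
    def test_equal_cts_give_unity(self):
        assert ddct(QPCRSample(20, 20, 20, 20)) == 1.0

    def test_two_cycle_shift(self):
        # ddCt = 2 -> fourfold reduction
        assert ddct(QPCRSample(24, 20, 22, 20)) == 0.25

    def test_negative_shift(self):
        assert ddct(QPCRSample(19, 20, 20, 20)) == 2.0

    def test_missing_ct_rejected(self):
        with pytest.raises(ValueError):
            QPCRSample(20, 20, 20, float("nan"))
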