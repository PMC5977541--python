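"""Feature rankers against exhaustive and analytic oracles."""

import itertools

import numpy as np
import pytest

from nucmorph.ranking import (
    discretize,
    mrmr_rank,
    mutual_information,
    pls_vip_rank,
    ranksum_pvalue,
    ranksum_rank,
    vip_scores,
)


def names(p):
    return [f"f{j}" for j in range(p)]


class TestRanksum:
    def test_perfectly_separating_feature_is_first(self, rng):
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 8))
        X[:, 5] = y  # perfect separation
        assert ranksum_rank(X, y, names(8)).ordered_features[0] == "f5"

    def test_matches_exhaustive_permutation_null(self):
        # every 4/4 labelling of one pooled sample: the p-value must track
        # the exhaustive permutation distribution of the rank statistic
        from scipy.stats import rankdata

        x = np.random.default_rng(3).normal(size=8)
        ranks = rankdata(x)
        combos = list(itertools.combinations(range(8), 4))
        null = np.array([ranks[list(c)].sum() for c in combos])
        mu = null.mean()
        for c in combos:
            a = x[list(c)]
            b = x[[i for i in range(8) if i not in c]]
            p_impl, _ = ranksum_pvalue(a, b)
            p_exact = np.mean(np.abs(null - mu) >= abs(ranks[list(c)].sum() - mu) - 1e-9)
            assert abs(p_impl - p_exact) < 0.02

    def test_identical_features_rank_adjacent_in_catalog_order(self, rng):
        y = np.repeat([0, 1], 10)
        X = rng.normal(size=(20, 5))
        X[:, 1] += y
        X[:, 3] = X[:, 1]
        ordered = ranksum_rank(X, y, names(5)).ordered_features
        assert ordered[:2] == ["f1", "f3"]

    def test_constant_feature_has_p_one(self):
        y = np.repeat([0, 1], 5)
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        result = ranksum_rank(X, y, names(2))
        assert result.scores[result.ordered_features.index("f0")] == 1.0

    def test_invariant_to_monotone_transforms(self, rng):
        y = np.repeat([0, 1], 15)
        X = rng.normal(size=(30, 6)) + y[:, None] * rng.uniform(0, 1, 6)
        a = ranksum_rank(X, y, names(6)).ordered_features
        b = ranksum_rank(np.exp(X), y, names(6)).ordered_features
        assert a == b


class TestVIP:
    def test_vip_identity(self, rng):
        X = rng.normal(size=(60, 12))
        y = (rng.random(60) > 0.5).astype(int)
        y[:5] = 0
        y[-5:] = 1
        vip = vip_scores(X, y)
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)

    def test_single_informative_feature_wins(self):
        hits = 0
        for seed in range(100):
            srng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 100)
            X = srng.normal(size=(200, 20))
            X[:, 7] += 2.0 * y  # 2 sigma effect
            hits += int(np.argmax(vip_scores(X, y)) == 7)
        assert hits >= 95

    def test_duplicated_feature_gets_equal_vip(self, rng):
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 6))
        X[:, 2] += 1.5 * y
        X[:, 5] = X[:, 2]
        vip = vip_scores(X, y)
        assert vip[2] == pytest.approx(vip[5], abs=1e-6)

    def test_too_few_features_rejected(self, rng):
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError):
            pls_vip_rank(rng.normal(size=(20, 1)), y, names(1), n_components=2)


class TestMutualInformation:
    def test_identity_of_balanced_binary(self):
        a = np.repeat([0, 1], 50)
        assert mutual_information(a, a) == pytest.approx(1.0)

    def test_independent_levels_near_zero(self, rng):
        a = rng.integers(0, 3, 10_000)
        b = rng.integers(0, 3, 10_000)
        assert mutual_information(a, b) < 0.01

    def test_symmetry(self, rng):
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 2, 200)
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a))

    def test_discretize_levels(self):
        v = np.array([0.0] * 10 + [100.0] + [-100.0])
        levels = discretize(v)
        assert set(levels) == {-1, 0, 1}
        assert levels[10] == 1 and levels[11] == -1


class TestMRMR:
    def test_first_selection_maximizes_class_mi(self, rng):
        y = np.repeat([0, 1], 25)
        X = rng.normal(size=(50, 6))
        X[:, 4] += 3.0 * y
        for variant in ("MID", "MIQ"):
            result = mrmr_rank(X, y, names(6), variant=variant, k=3)
            assert result.ordered_features[0] == "f4"

    def test_duplicate_of_first_feature_not_second(self, rng):
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 4))
        X[:, 0] += 3.0 * y  # strongest
        X[:, 1] = X[:, 0]  # exact duplicate: maximal redundancy
        X[:, 2] += 1.5 * y  # informative and less redundant
        for variant in ("MID", "MIQ"):
            result = mrmr_rank(X, y, names(4), variant=variant, k=2)
            assert result.ordered_features == ["f0", "f2"]

    @pytest.mark.parametrize("variant", ["MID", "MIQ"])
    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_step_matches_brute_force(self, variant, seed):
        srng = np.random.default_rng(seed)
        p = int(srng.integers(4, 9))
        y = (srng.random(40) > 0.5).astype(int)
        y[:3] = 0
        y[-3:] = 1
        X = srng.normal(size=(40, p))
        X[:, 1] += y
        result = mrmr_rank(X, y, names(p), variant=variant, k=3)
        levels = np.column_stack([discretize(X[:, j]) for j in range(p)])
        relevance = [mutual_information(levels[:, j], y) for j in range(p)]
        chosen = []
        for _ in range(3):
            best, best_score = None, -np.inf
            for j in range(p):
                if j in chosen:
                    continue
                if not chosen:
                    score = relevance[j]
                else:
                    red = np.mean(
                        [mutual_information(levels[:, j], levels[:, s]) for s in chosen]
                    )
                    score = relevance[j] - red if variant == "MID" else relevance[j] / max(red, 1e-12)
                if score > best_score:
                    best, best_score = j, score
            chosen.append(best)
        assert result.ordered_features[:3] == [names(p)[j] for j in chosen]

    def test_invariant_to_affine_transforms(self, rng):
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 5)) + y[:, None] * rng.uniform(0, 2, 5)
        a = mrmr_rank(X, y, names(5), variant="MID").ordered_features
        b = mrmr_rank(3.0 * X + 7.0, y, names(5), variant="MID").ordered_features
        assert a == b

    def test_column_order_invariance(self, rng):
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 5)) + y[:, None] * np.array([0.3, 1.5, 0.1, 0.9, 0.6])
        base = mrmr_rank(X, y, names(5), variant="MIQ", k=3).ordered_features
        perm = [3, 0, 4, 1, 2]
        shuffled = mrmr_rank(
            X[:, perm], y, [f"f{j}" for j in perm], variant="MIQ", k=3
        ).ordered_features
        assert base == shuffled
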