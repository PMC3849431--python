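import numpy as np
import pytest
from scipy import stats

from fishq.agreement import (
    DegenerateInputError,
    PairedScores,
    agreement,
    cohens_kappa,
    crosstab,
    interpret_kappa,
    spearman_rho,
)


def kappa_first_principles(table):
    """Cohen's kappa from the definition, explicit double loop over cells."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    k = t.shape[0]
    p_o = sum(t[i, i] for i in range(k)) / n
    p_e = 0.0
    for i in range(k):
        row = sum(t[i, j] for j in range(k))
        col = sum(t[j, i] for j in range(k))
        p_e += (row / n) * (col / n)
    return (p_o - p_e) / (1.0 - p_e)


def rho_first_principles(x, y):
    """Spearman rho as Pearson on mid-ranks, assembled by hand."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0  # average of ranks i+1..j
            i = j
        return ranks
    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestCohensKappa:
    def test_perfect_diagonal_is_one(self):
        k, _ = cohens_kappa(np.diag([5, 7, 3]))
        assert k == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # p_o = 35/50 = 0.7, p_e = 0.5 -> kappa = 0.4
        k, (lo, hi) = cohens_kappa([[20, 5], [10, 15]])
        assert k == pytest.approx(0.4, abs=1e-12)
        assert -1.0 <= lo < k < hi <= 1.0

    def test_marginal_independence_is_zero(self):
        k, _ = cohens_kappa([[9, 21], [21, 49]])
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_matches_first_principles_on_200_random_tables(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            size = int(rng.integers(2, 6))
            table = rng.integers(0, 20, size=(size, size))
            if table.sum() < 2 or table.trace() == table.sum():
                continue
            expected = kappa_first_principles(table)
            got, _ = cohens_kappa(table)
            assert got == pytest.approx(expected, abs=1e-12)
            checked += 1

    def test_matches_sklearn_cross_check(self):
        """Independent library route: reconstruct rater vectors from the
        table and compare with sklearn's kappa."""
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.integers(0, 4, size=60)
            b = np.where(rng.random(60) < 0.7, a, rng.integers(0, 4, size=60))
            table = crosstab(PairedScores(list(zip(range(60), a, b)))).to_numpy()
            k, _ = cohens_kappa(table)
            assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_invariant_under_joint_category_permutation(self):
        rng = np.random.default_rng(3)
        table = rng.integers(0, 15, size=(4, 4)) + 1
        k0, _ = cohens_kappa(table)
        perm = rng.permutation(4)
        k1, _ = cohens_kappa(table[np.ix_(perm, perm)])
        assert k1 == pytest.approx(k0, abs=1e-12)

    def test_single_category_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            cohens_kappa([[10, 0], [0, 0]])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(np.ones((2, 3)))


def _pairs(x, y):
    return PairedScores(list(zip(range(len(x)), x, y)))


class TestSpearmanRho:
    def test_monotone_increasing_is_one(self):
        rho, _, p, df = spearman_rho(_pairs([1, 2, 3, 4, 5], [10, 20, 30, 40, 50]))
        assert rho == pytest.approx(1.0)
        assert df == 3

    def test_monotone_decreasing_is_minus_one(self):
        rho, *_ = spearman_rho(_pairs([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]))
        assert rho == pytest.approx(-1.0)

    def test_textbook_example(self):
        # d = (0, -1, 1, -1, 1): rho = 1 - 6*4/(5*24) = 0.8
        rho, *_ = spearman_rho(_pairs([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]))
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_matches_midrank_oracle_on_200_tied_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, *_ = spearman_rho(_pairs(x, y))
            assert rho == pytest.approx(rho_first_principles(x, y), abs=1e-12)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=40)
        y = x + rng.normal(scale=0.8, size=40)
        rho, _, p, _ = spearman_rho(_pairs(x, y))
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        rho0, *_ = spearman_rho(_pairs(x, y))
        rho1, *_ = spearman_rho(_pairs(np.exp(x), y**3))
        assert rho1 == pytest.approx(rho0, abs=1e-12)

    def test_ci_ordered_and_within_bounds(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, (lo, hi), p, df = spearman_rho(_pairs(x, y))
        assert -1.0 <= lo <= rho <= hi <= 1.0
        assert 0 < p <= 1.0 and df == 28

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho(_pairs([1, 1, 1, 1], [1, 2, 3, 4]))


class TestInterpretKappa:
    @pytest.mark.parametrize("kappa,band", [
        (0.911, "almost perfect"),
        (0.606, "substantial"),
        (0.703, "substantial"),
        (-0.2, "poor"),
        (0.0, "slight"),
        (0.20, "slight"),
        (0.21, "fair"),
        (0.40, "fair"),
        (0.60, "moderate"),
        (0.80, "substantial"),
        (1.0, "almost perfect"),
    ])
    def test_landis_koch_bands(self, kappa, band):
        assert interpret_kappa(kappa) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)


class TestCrosstab:
    def test_single_category(self):
        tab = crosstab(_pairs(["pos"] * 3, ["pos"] * 3))
        assert tab.to_numpy().tolist() == [[3]]

    def test_two_by_two_layout(self):
        pairs = _pairs(["pos", "pos", "neg"], ["pos", "neg", "neg"])
        tab = crosstab(pairs)
        # rows/cols sorted: neg, pos
        assert tab.to_numpy().tolist() == [[1, 0], [1, 1]]

    def test_cell_sum_equals_item_count(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            n = int(rng.integers(2, 40))
            a = rng.integers(0, 5, size=n)
            b = rng.integers(0, 5, size=n)
            assert crosstab(_pairs(a, b)).to_numpy().sum() == n


class TestAgreementPanel:
    def test_full_panel_on_categorical_scores(self):
        rng = np.random.default_rng(16)
        cats = ["neg", "equivocal", "pos"]
        a = rng.integers(0, 3, size=50)
        b = np.where(rng.random(50) < 0.8, a, rng.integers(0, 3, size=50))
        res = agreement(_pairs([cats[i] for i in a], [cats[i] for i in b]))
        assert -1.0 <= res.kappa <= 1.0
        assert res.interpretation == interpret_kappa(res.kappa)
        assert res.df == 48
        assert "Cohen's kappa" in res.summary()

    def test_missing_ratings_dropped_and_counted(self):
        pairs = PairedScores([
            (1, "pos", "pos"), (2, None, "neg"), (3, "neg", "neg"), (4, "pos", None),
        ])
        assert len(pairs) == 2 and pairs.n_dropped == 2
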