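"""Feature selection: missing-value removal, t-test screening, DEG thresholds, mRMR."""
import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from conftest import make_matrix
from omifuse.exceptions import DegenerateClassError, DomainError, EmptyMatrixError
from omifuse.features import (
    DEGFilterConfig,
    TTestSelectionConfig,
    deg_filter,
    drop_missing_features,
    mrmr_rank,
    ttest_screen,
)


def three_class_matrix(rng, n_per_class=50, n_features=10, shift=None, modality="toy"):
    labels = np.repeat(["LUAD", "control", "LUSC"], n_per_class)
    X = rng.standard_normal((len(labels), n_features))
    if shift:
        for j, (cls, delta) in shift.items():
            X[labels == cls, j] += delta
    return make_matrix(X, labels, modality=modality)


class TestDropMissing:
    def test_columns_with_any_missing_removed(self, rng):
        mm = three_class_matrix(rng, n_per_class=5)
        mm.values.iloc[0, 2] = np.nan
        mm.values.iloc[3, 7] = np.nan
        out = drop_missing_features(mm)
        assert out.n_features == 8
        assert "f2" not in out.feature_names and "f7" not in out.feature_names
        assert out.n_samples == mm.n_samples

    def test_no_missing_is_identity(self, rng):
        mm = three_class_matrix(rng, n_per_class=5)
        out = drop_missing_features(mm)
        assert out.values.equals(mm.values)

    def test_all_missing_errors(self, rng):
        mm = three_class_matrix(rng, n_per_class=5, n_features=2)
        mm.values.iloc[0, :] = np.nan
        with pytest.raises(EmptyMatrixError):
            drop_missing_features(mm)


class TestTTestScreen:
    def test_constant_feature_never_selected(self, rng):
        mm = three_class_matrix(rng, n_per_class=20, n_features=3)
        mm.values.iloc[:, 1] = 5.0
        cfg = TTestSelectionConfig(alpha=1.0, bonferroni=False,
                                   required_comparisons=1, mean_diff_threshold=0.0)
        assert "f1" not in ttest_screen(mm, cfg)

    def test_vacuous_thresholds_select_everything_varying(self, rng):
        mm = three_class_matrix(rng, n_per_class=20, n_features=6)
        cfg = TTestSelectionConfig(alpha=1.0, bonferroni=False,
                                   required_comparisons=1, mean_diff_threshold=0.0)
        assert set(ttest_screen(mm, cfg)) == set(mm.feature_names)

    def test_large_shift_selected_and_matches_direct_t_oracle(self, rng):
        # one feature shifts LUAD by 5 SD; oracle recomputes Welch t by hand
        mm = three_class_matrix(rng, n_per_class=100, n_features=4,
                                shift={0: ("LUAD", 5.0)})
        cfg = TTestSelectionConfig(alpha=0.001, bonferroni=True,
                                   required_comparisons=2, mean_diff_threshold=0.1)
        selected = ttest_screen(mm, cfg)
        assert "f0" in selected

        x = mm.values["f0"]
        luad = x[np.asarray(mm.labels == "LUAD")]
        ctrl = x[np.asarray(mm.labels == "control")]
        t_hand = (luad.mean() - ctrl.mean()) / np.sqrt(
            luad.var(ddof=1) / len(luad) + ctrl.var(ddof=1) / len(ctrl)
        )
        t_scipy = stats.ttest_ind(luad, ctrl, equal_var=False).statistic
        assert t_hand == pytest.approx(t_scipy)
        assert abs(t_hand) > 10  # unambiguously significant even after Bonferroni

    def test_no_bonferroni_selects_superset(self, rng):
        mm = three_class_matrix(rng, n_per_class=30, n_features=40,
                                shift={0: ("LUAD", 1.0), 1: ("LUSC", 0.6)})
        base = dict(alpha=0.05, required_comparisons=1, mean_diff_threshold=0.0)
        with_bonf = set(ttest_screen(mm, TTestSelectionConfig(bonferroni=True, **base)))
        without = set(ttest_screen(mm, TTestSelectionConfig(bonferroni=False, **base)))
        assert with_bonf <= without

    def test_degenerate_class_errors(self):
        mm = make_matrix([[0.0], [1.0], [2.0]], ["LUAD", "control", "LUSC"])
        with pytest.raises(DegenerateClassError):
            ttest_screen(mm, TTestSelectionConfig())

    def test_input_matrix_unmodified(self, rng):
        mm = three_class_matrix(rng, n_per_class=10)
        before = mm.values.copy()
        ttest_screen(mm, TTestSelectionConfig(alpha=0.5, bonferroni=False,
                                              required_comparisons=1))
        assert mm.values.equals(before)


class TestDEGFilter:
    def _expr_matrix(self, rng, means):
        # 3 classes x 30 samples; one feature per configured mean triple
        labels = np.repeat(["LUAD", "control", "LUSC"], 30)
        cols = []
        for m_luad, m_ctrl, m_lusc in means:
            col = np.concatenate([
                rng.normal(m_luad, 0.05 * m_luad, 30),
                rng.normal(m_ctrl, 0.05 * m_ctrl, 30),
                rng.normal(m_lusc, 0.05 * m_lusc, 30),
            ])
            cols.append(np.clip(col, 1e-3, None))
        return make_matrix(np.column_stack(cols), labels)

    def test_eightfold_difference_selected_and_oracle_agrees(self, rng):
        mm = self._expr_matrix(rng, [(8.0, 1.0, 1.0), (2.0, 2.0, 2.0)])
        selected = deg_filter(mm, DEGFilterConfig())
        assert selected == ["f0"]
        # hand-computed oracle for feature 0: LFC and COV
        x = mm.values["f0"]
        means = [x[np.asarray(mm.labels == c)].mean() for c in ("LUAD", "control", "LUSC")]
        lfc = max(abs(np.log2(a / b)) for a, b in itertools.combinations(means, 2))
        cov = x.std(ddof=1) / x.mean()
        assert lfc >= 2.0 and cov <= 2.0

    def test_constant_feature_excluded(self, rng):
        mm = self._expr_matrix(rng, [(8.0, 1.0, 1.0)])
        mm.values["f1"] = 3.0
        assert "f1" not in deg_filter(mm, DEGFilterConfig())

    def test_infinite_lfc_threshold_empty(self, rng):
        mm = self._expr_matrix(rng, [(8.0, 1.0, 1.0)])
        assert deg_filter(mm, DEGFilterConfig(lfc_threshold=np.inf)) == []

    def test_nonpositive_values_domain_error(self, rng):
        mm = self._expr_matrix(rng, [(8.0, 1.0, 1.0)])
        mm.values.iloc[0, 0] = -1.0
        with pytest.raises(DomainError, match="pseudocount"):
            deg_filter(mm, DEGFilterConfig())


def exhaustive_mi(x, y):
    """Counter-based mutual information oracle (nats)."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    return sum(
        (c / n) * np.log((c / n) / ((px[a] / n) * (py[b] / n)))
        for (a, b), c in joint.items()
    )


class TestMRMR:
    def test_informative_feature_ranked_first_vs_exhaustive_mi(self, rng):
        labels = np.repeat(["LUAD", "control", "LUSC"], 60)
        X = rng.standard_normal((180, 3))
        X[labels == "LUAD", 1] += 3.0  # feature 1 is informative
        mm = make_matrix(X, labels)
        ranking = mrmr_rank(mm, k=3)
        assert ranking.feature_names[0] == "f1"
        # oracle: discretize identically and compare relevance by brute force
        from omifuse.features import _discretize

        y = np.searchsorted(["LUAD", "LUSC", "control"], labels)  # any consistent coding
        rels = [exhaustive_mi(tuple(_discretize(X[:, j], 3)), tuple(y)) for j in range(3)]
        assert int(np.argmax(rels)) == 1

    def test_duplicate_penalized_below_independent_weaker_feature(self, rng):
        labels = np.repeat(["LUAD", "control", "LUSC"], 60)
        strong = rng.standard_normal(180)
        strong[labels == "LUAD"] += 3.0
        weak = rng.standard_normal(180)
        weak[labels == "LUSC"] += 1.2
        X = np.column_stack([strong, strong.copy(), weak])
        ranking = mrmr_rank(make_matrix(X, labels), k=3)
        assert ranking.feature_names[0] == "f0"  # strong first (tie broken by order)
        assert ranking.feature_names[1] == "f2"  # duplicate loses to independent weak

    def test_k1_returns_relevance_argmax_only(self, rng):
        labels = np.repeat(["LUAD", "control", "LUSC"], 30)
        X = rng.standard_normal((90, 4))
        X[labels == "control", 2] += 4.0
        ranking = mrmr_rank(make_matrix(X, labels), k=1)
        assert ranking.feature_names == ["f2"]

    def test_k0_empty(self, rng):
        mm = three_class_matrix(rng, n_per_class=10)
        assert mrmr_rank(mm, k=0).feature_names == []

    def test_column_order_invariance(self, rng):
        labels = np.repeat(["LUAD", "control", "LUSC"], 40)
        X = rng.standard_normal((120, 5))
        X[labels == "LUAD", 0] += 2.5
        X[labels == "LUSC", 3] += 1.5
        mm = make_matrix(X, labels)
        perm = [3, 1, 4, 0, 2]
        mm_perm = make_matrix(X[:, perm], labels,
                              feature_names=[f"f{j}" for j in perm])
        assert mrmr_rank(mm, k=3).feature_names == mrmr_rank(mm_perm, k=3).feature_names
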