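"""Leave-one-out core marker selection: worked example, oracle re-checks,
set-algebra properties."""

import numpy as np
import pandas as pd
import pytest

from coremarkers import (
    BinaryLabels,
    CoreMarkerSelector,
    DataError,
    EmptyClassError,
    ExpressionDataset,
    SelectionConfig,
    assess_suitability,
    balance_ratio,
    loo_core_markers,
    simulate_expression,
    SyntheticConfig,
)


def loo_core_oracle(dataset, labels, q):
    """Independent oracle: for every fold, score each gene by an explicit
    all-pairs count in exact rational arithmetic, orient, sort with the
    gene-id tie-break, and intersect the top-q sets."""
    from fractions import Fraction

    lab = labels.to_series().reindex(dataset.sample_ids).to_numpy()
    core = None
    per_fold = {}
    for i, sid in enumerate(dataset.sample_ids):
        keep = np.arange(dataset.n_samples) != i
        y = lab[keep] == "R"
        scored = []
        for g, gid in enumerate(dataset.gene_ids):
            vals = dataset.values[g, keep]
            r, nr = vals[y], vals[~y]
            wins = sum(
                Fraction(2) if a > b else Fraction(1) if a == b else Fraction(0)
                for a in r for b in nr
            )
            auc = wins / (2 * len(r) * len(nr))
            scored.append((-max(auc, 1 - auc), str(gid)))
        top = frozenset(gid for _, gid in sorted(scored)[:q])
        per_fold[str(sid)] = top
        core = top if core is None else core & top
    return core, per_fold


class TestWorkedExample:
    def test_core_set_is_the_two_separating_genes(self, worked_example):
        dataset, labels = worked_example
        with pytest.warns(UserWarning, match="SMALL_N"):
            result = loo_core_markers(dataset, labels, SelectionConfig(q=2))
        assert result.core_genes == {"g1", "g2"}
        assert result.n_core == 2
        assert len(result.per_fold_top) == 6

    def test_matches_exhaustive_fold_enumeration(self, worked_example):
        dataset, labels = worked_example
        with pytest.warns(UserWarning, match="SMALL_N"):
            result = loo_core_markers(dataset, labels, SelectionConfig(q=2))
        oracle_core, oracle_folds = loo_core_oracle(dataset, labels, q=2)
        assert result.core_genes == oracle_core
        assert result.per_fold_top == oracle_folds


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fast_path_matches_independent_reranking(self, seed):
        """The incremental leave-one-out AUC computation must agree
        fold-by-fold with naive re-ranking on tie-rich data."""
        rng = np.random.default_rng(seed)
        values = rng.choice(5, size=(40, 24)).astype(float)  # heavy ties
        dataset = ExpressionDataset(
            np.array([f"g{i + 1:04d}" for i in range(40)]),
            np.array([f"s{j + 1:04d}" for j in range(24)]),
            values,
        )
        lab = np.array(["R"] * 10 + ["NR"] * 14)
        labels = BinaryLabels(dataset.sample_ids, lab)
        with pytest.warns(UserWarning, match="SMALL_N"):
            result = loo_core_markers(dataset, labels, SelectionConfig(q=8))
        oracle_core, oracle_folds = loo_core_oracle(dataset, labels, q=8)
        assert result.per_fold_top == oracle_folds
        assert result.core_genes == oracle_core


class TestProperties:
    @pytest.fixture(scope="class")
    def cohort(self):
        return simulate_expression(
            SyntheticConfig(n_genes=200, n_r=25, n_nr=25, n_markers=5, seed=11)
        )

    def test_core_contained_in_every_fold(self, cohort):
        dataset, labels = cohort
        result = loo_core_markers(dataset, labels)
        for top in result.per_fold_top.values():
            assert result.core_genes <= top

    def test_monotone_in_q(self, cohort):
        """With the deterministic tie-break, per-fold top lists are nested
        in Q, so the core set at Q is a subset of the core set at Q' > Q."""
        dataset, labels = cohort
        previous = None
        for q in (5, 10, 20, 30):
            core = loo_core_markers(dataset, labels, SelectionConfig(q=q)).core_genes
            if previous is not None:
                assert previous <= core
            previous = core

    def test_intersection_antitone_in_folds(self, cohort):
        """Intersecting with any additional top list can only shrink the
        core set."""
        dataset, labels = cohort
        result = loo_core_markers(dataset, labels)
        folds = list(result.per_fold_top.values())
        partial = frozenset.intersection(*folds[:10])
        assert result.core_genes <= partial

    def test_column_order_invariant(self, cohort):
        dataset, labels = cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(dataset.n_samples)
        shuffled = ExpressionDataset(
            dataset.gene_ids, dataset.sample_ids[perm], dataset.values[:, perm]
        )
        a = loo_core_markers(dataset, labels)
        b = loo_core_markers(shuffled, labels)
        assert a.core_genes == b.core_genes
        assert a.per_fold_top == b.per_fold_top

    def test_null_core_well_below_q(self):
        """On pure-noise data the correlated leave-one-out folds still prune
        the boundary genes: the mean core size stays well below Q (the lists
        are far from identical), though far above zero (they are far from
        independent)."""
        sizes = []
        for seed in range(10):
            dataset, labels = simulate_expression(
                SyntheticConfig(n_genes=1000, n_r=30, n_nr=30,
                                n_markers=0, effect_size=0.0, seed=seed)
            )
            sizes.append(loo_core_markers(dataset, labels).n_core)
        assert np.mean(sizes) < 25  # Q = 30


class TestErrorsAndGuards:
    def test_q_at_least_n_rejected(self, worked_example):
        dataset, labels = worked_example
        with pytest.raises(DataError, match="must not exceed the number of cases"):
            loo_core_markers(dataset, labels, SelectionConfig(q=6))

    def test_class_with_single_sample_rejected(self):
        rng = np.random.default_rng(0)
        dataset = ExpressionDataset(
            np.array(["g1", "g2"]),
            np.array([f"s{i}" for i in range(6)]),
            rng.normal(size=(2, 6)),
        )
        labels = BinaryLabels(dataset.sample_ids,
                              np.array(["R"] + ["NR"] * 5))
        with pytest.raises(EmptyClassError, match="retains both"):
            loo_core_markers(dataset, labels, SelectionConfig(q=2))

    def test_small_cohort_warns_but_runs(self, worked_example):
        dataset, labels = worked_example
        with pytest.warns(UserWarning, match="SMALL_N"):
            result = loo_core_markers(dataset, labels, SelectionConfig(q=2))
        assert result.n_core == 2


class TestSuitability:
    def test_report_fields(self, worked_example):
        dataset, labels = worked_example
        with pytest.warns(UserWarning, match="SMALL_N"):
            result = loo_core_markers(dataset, labels, SelectionConfig(q=2))
        report = assess_suitability(result)
        assert report.n_core == 2
        assert not report.suitable  # 2 < default 7
        assert report.n_responders == report.n_nonresponders == 3
        assert set(report.per_fold_sizes.values()) == {2}
        assert report.balance == 0.5

    @pytest.mark.parametrize("n_core, suitable", [(14, True), (2, False), (7, True)])
    def test_threshold_closed_on_the_left(self, n_core, suitable):
        from coremarkers.selection import CoreMarkerResult

        genes = frozenset(f"g{i}" for i in range(n_core))
        result = CoreMarkerResult(
            per_fold_top={"s1": genes},
            core_genes=genes,
            config=SelectionConfig(),
            n_responders=20,
            n_nonresponders=20,
        )
        assert assess_suitability(result).suitable is suitable


class TestBalanceRatio:
    @pytest.mark.parametrize(
        "n_r, n_nr, expected",
        [(116, 6, 6 / 122), (85, 84, 84 / 169), (10, 10, 0.5)],
    )
    def test_catalog_examples(self, n_r, n_nr, expected):
        ids = np.array([f"s{i}" for i in range(n_r + n_nr)])
        labels = BinaryLabels(ids, np.array(["R"] * n_r + ["NR"] * n_nr))
        assert balance_ratio(labels) == pytest.approx(expected)


def test_selector_sklearn_contract():
    """CoreMarkerSelector composes as a sklearn transformer."""
    dataset, labels = simulate_expression(
        SyntheticConfig(n_genes=100, n_r=25, n_nr=25, n_markers=3, seed=5)
    )
    X = pd.DataFrame(dataset.values.T, columns=dataset.gene_ids)
    y = labels.labels
    sel = CoreMarkerSelector(q=10).fit(X, y)
    assert sel.n_core_ == sel.get_support().sum()
    assert sel.transform(X).shape == (50, sel.n_core_)
    assert set(sel.core_genes_) <= set(dataset.gene_ids)
    params = sel.get_params()
    assert params == {"q": 10, "min_core_genes": 7}
    assert CoreMarkerSelector(**params).get_params() == params
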