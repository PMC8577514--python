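"""Repeated-CV stability selection: runs, frequency table, panel rule."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gbmpanel as gp
from gbmpanel.datasets import load_reference_frequencies, reference_frequency_table
from gbmpanel.errors import EmptyPanelError, ValidationError
from tests.conftest import DESK_SELECTION, FAST_BOOSTER

# full column view so a perfectly separating gene is seen by every tree
SMALL_CV = gp.SelectionConfig(
    n_runs=2, n_folds=5, top_k=5, frequency_threshold=2,
    base=dataclasses.replace(FAST_BOOSTER, column_subsample=1.0), seed=4,
)


def _separating_dataset(n_per_class=20, n_noise=29, seed=0):
    """One gene takes a distinct constant value per class; rest is noise."""
    rng = np.random.default_rng(seed)
    classes = ["classical", "mesenchymal", "proneural"]
    labels = [c for c in classes for _ in range(n_per_class)]
    sep = np.array([10.0 * classes.index(c) for c in labels])
    X = rng.normal(5, 1, size=(n_noise, len(labels)))
    matrix = pd.DataFrame(
        np.vstack([sep, X]),
        index=["separator"] + [f"noise_{i}" for i in range(n_noise)],
        columns=[f"s{j}" for j in range(len(labels))],
    )
    return gp.LabeledDataset(
        matrix, pd.Series(labels, index=matrix.columns, name="label")
    )


class TestRunCvOnce:
    def test_perfect_separator_gives_accuracy_one_and_top_rank(self):
        ds = _separating_dataset()
        res = gp.run_cv_once(ds, SMALL_CV, run_seed=11)
        assert res.mean_validation_accuracy == 1.0
        assert res.top_genes[0] == "separator"
        assert len(res.top_genes) == SMALL_CV.top_k

    def test_mean_equals_fold_mean(self):
        res = gp.run_cv_once(_separating_dataset(), SMALL_CV, run_seed=3)
        assert res.mean_validation_accuracy == pytest.approx(
            np.mean(res.per_fold_accuracy)
        )
        assert len(res.per_fold_accuracy) == SMALL_CV.n_folds

    def test_same_run_seed_is_deterministic(self):
        ds = _separating_dataset()
        a = gp.run_cv_once(ds, SMALL_CV, run_seed=17)
        b = gp.run_cv_once(ds, SMALL_CV, run_seed=17)
        assert a == b

    def test_fold_sizes_differ_by_at_most_one(self):
        from gbmpanel.selection import _random_partition

        for stratified in (False, True):
            y = np.array([0] * 13 + [1] * 14 + [2] * 16)
            folds = _random_partition(43, 10, y, 5, stratified)
            sizes = sorted(len(f) for f in folds)
            assert sum(sizes) == 43
            assert sizes[-1] - sizes[0] <= 1
            assert sorted(np.concatenate(folds)) == list(range(43))

    def test_too_few_samples_for_folds_is_rejected(self):
        ds = _separating_dataset(n_per_class=1)
        with pytest.raises(ValidationError, match="n_folds"):
            gp.run_cv_once(ds, SMALL_CV, run_seed=0)


class TestRunRepeatedCv:
    def test_single_run_matches_run_cv_once(self, small_normalized):
        cfg = dataclasses.replace(SMALL_CV, n_runs=1, frequency_threshold=1, top_k=10)
        runs = gp.run_repeated_cv(small_normalized, cfg)
        solo = gp.run_cv_once(
            small_normalized, cfg, gp.derive_seed(cfg.seed, 0), run_index=0
        )
        assert runs == [solo]

    def test_repeated_invocations_are_identical(self, small_normalized):
        cfg = dataclasses.replace(SMALL_CV, n_runs=3, top_k=10, n_folds=3)
        assert gp.run_repeated_cv(small_normalized, cfg) == gp.run_repeated_cv(
            small_normalized, cfg
        )


def _fake_run(i, genes, top_k):
    filler = [f"filler_{i}_{j}" for j in range(top_k - len(genes))]
    return gp.CVRunResult(
        run_index=i,
        mean_validation_accuracy=0.8,
        top_genes=list(genes) + filler,
        per_fold_accuracy=[0.8],
    )


class TestFrequencyTable:
    def test_identical_runs_count_twice(self):
        runs = [_fake_run(i, ["a", "b"], 2) for i in range(2)]
        for r in runs:
            r.top_genes = ["a", "b"]
        table = gp.build_frequency_table(runs)
        assert table.counts.to_dict() == {"a": 2, "b": 2}

    def test_disjoint_runs_count_once(self):
        runs = [_fake_run(0, ["a", "b"], 2), _fake_run(1, ["c", "d"], 2)]
        table = gp.build_frequency_table(runs)
        assert set(table.counts.index) == {"a", "b", "c", "d"}
        assert (table.counts == 1).all()

    def test_conservation_sum_is_runs_times_topk(self, desk_runs):
        table = gp.build_frequency_table(desk_runs)
        assert table.counts.sum() == table.n_runs * table.top_k

    def test_inconsistent_topk_is_rejected(self):
        runs = [_fake_run(0, ["a"], 1), _fake_run(1, ["a", "b"], 2)]
        with pytest.raises(ValidationError, match="top_k"):
            gp.build_frequency_table(runs)

    def test_reference_count_profile_is_reproduced(self):
        """Synthetic run records built to match the published top-5
        frequencies (100/99/92/81/80) count back exactly."""
        ref = load_reference_frequencies().head(5)
        runs = []
        for i in range(100):
            present = [g for g, f in ref.items() if i < f]
            runs.append(_fake_run(i, present, 20))
        table = gp.build_frequency_table(runs)
        for gene, freq in ref.items():
            assert table.counts[gene] == freq
        panel = gp.select_panel(table, threshold=80)
        assert panel.genes == list(ref.index)


class TestSelectPanel:
    def test_published_frequencies_threshold_to_five_genes(self):
        panel = gp.select_panel(reference_frequency_table(), threshold=80)
        assert panel.genes == ["NKAIN1", "UBE2E2", "F13A1", "RNF149", "PLAUR"]

    def test_threshold_zero_selects_every_recorded_gene(self):
        table = gp.build_frequency_table(
            [_fake_run(0, ["a", "b"], 2), _fake_run(1, ["c", "d"], 2)]
        )
        assert set(gp.select_panel(table, threshold=0).genes) == {"a", "b", "c", "d"}

    def test_all_below_threshold_raises_with_max_count(self):
        table = gp.build_frequency_table([_fake_run(0, ["a", "b"], 2)])
        with pytest.raises(EmptyPanelError, match="maximum observed count: 1"):
            gp.select_panel(table, threshold=2)

    @given(st.integers(0, 25))
    def test_raising_threshold_never_enlarges_panel(self, threshold):
        table = reference_frequency_table()
        def size(t):
            try:
                return len(gp.select_panel(table, threshold=t).genes)
            except EmptyPanelError:
                return 0
        assert size(threshold * 4) >= size(threshold * 4 + 1)


class TestSummarizeAccuracy:
    def test_identical_runs(self):
        runs = [_fake_run(0, ["a"], 1), _fake_run(1, ["a"], 1)]
        s = gp.summarize_accuracy(runs)
        assert s == {"mean": 0.8, "sd": 0.0, "min": 0.8, "max": 0.8}

    def test_spread_runs(self):
        runs = [_fake_run(0, ["a"], 1), _fake_run(1, ["a"], 1)]
        runs[0].mean_validation_accuracy = 0.7
        runs[1].mean_validation_accuracy = 0.9
        s = gp.summarize_accuracy(runs)
        assert s["mean"] == pytest.approx(0.8)
        assert s["min"] == 0.7 and s["max"] == 0.9
        assert s["sd"] == pytest.approx(np.std([0.7, 0.9], ddof=1))


class TestDeskScaleProtocol:
    """Study-condition runs: strong planted effect vs null effect."""

    def test_planted_panel_is_recovered(self, desk_cohort, desk_runs):
        table = gp.build_frequency_table(desk_runs)
        panel = gp.select_panel(table, DESK_SELECTION)
        planted = set(desk_cohort.truth.marker_genes())
        assert set(panel.genes) <= planted
        for cls, genes in desk_cohort.truth.markers.items():
            assert set(panel.genes) & set(genes), f"no panel gene for {cls}"

    def test_strong_effect_accuracy_is_high(self, desk_runs):
        assert gp.summarize_accuracy(desk_runs)["mean"] > 0.8

    def test_null_effect_accuracy_is_chance_level(self, null_runs):
        """Without a planted effect, pooled CV accuracy sits inside the 99%
        binomial band around 1/3 (150 predictions per run, 20 runs)."""
        from scipy import stats

        acc = np.mean([r.mean_validation_accuracy for r in null_runs])
        n = 150  # validation predictions per run
        lo = stats.binom.ppf(0.005, n, 1 / 3) / n
        hi = stats.binom.ppf(0.995, n, 1 / 3) / n
        assert lo <= acc <= hi

    def test_null_effect_never_outscores_planted_effect(self, desk_runs, null_runs):
        null_best = max(r.mean_validation_accuracy for r in null_runs)
        strong_worst = min(r.mean_validation_accuracy for r in desk_runs)
        assert null_best < strong_worst
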