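"""Consensus voting, assignment with abstention, per-type summaries."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gbmpanel as gp
from gbmpanel.dataset import ABSTAIN
from gbmpanel.datasets import SUBTYPE_CLASSES, load_mcmaster_votes, mcmaster_vote_table
from gbmpanel.errors import ValidationError
from tests.conftest import DESK_CONSENSUS, FAST_BOOSTER


def _vote_table(rows, classes=SUBTYPE_CLASSES, types=None, n_members=100):
    votes = pd.DataFrame(rows, columns=classes)
    votes.index = [f"s{i}" for i in range(len(rows))]
    stypes = pd.Series(types or ["x"] * len(rows), index=votes.index)
    return gp.VoteTable(votes=votes, sample_types=stypes, n_members=n_members)


class TestAssign:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ((1, 99, 0), "mesenchymal"),
            ((80, 5, 15), "classical"),
            ((79, 21, 0), ABSTAIN),
            ((100, 0, 0), "classical"),
        ],
    )
    def test_published_vote_rows(self, row, expected):
        table = _vote_table([row])
        calls = gp.assign(table, threshold=80).calls
        assert calls["s0"] == expected

    def test_calls_match_published_calls_on_reference_cohort(self):
        df = load_mcmaster_votes()
        table = mcmaster_vote_table()
        assignment = gp.assign(table, threshold=80)
        ours = assignment.calls.replace({ABSTAIN: ""})
        pd.testing.assert_series_equal(
            ours, df["reported_call"], check_names=False
        )

    @given(
        st.tuples(st.integers(0, 100), st.integers(0, 100)).filter(
            lambda t: sum(t) <= 100
        ),
        st.integers(1, 100),
    )
    def test_raising_threshold_never_converts_abstention_to_call(self, ab, threshold):
        a, b = ab
        table = _vote_table([(a, b, 100 - a - b)])
        low = gp.assign(table, threshold=threshold).calls["s0"]
        high = gp.assign(table, threshold=min(threshold + 1, 100)).calls["s0"]
        if low == ABSTAIN:
            assert high == ABSTAIN

    def test_no_ties_possible_above_half_exhaustively(self):
        """For any threshold > n_members/2, at most one class can qualify,
        over all 3-class vote splits of 100 votes."""
        for a, b in itertools.product(range(101), repeat=2):
            if a + b > 100:
                continue
            c = 100 - a - b
            for threshold in range(51, 101):
                assert sum(v >= threshold for v in (a, b, c)) <= 1

    def test_invalid_vote_sums_are_rejected(self):
        table = _vote_table([(50, 10, 10)])
        with pytest.raises(ValidationError, match="sum"):
            gp.assign(table, threshold=80)


class TestSummarizeBySampleType:
    def test_reference_cohort_counts(self):
        table = mcmaster_vote_table()
        assignment = gp.assign(table, threshold=80)
        summary = gp.summarize_by_sample_type(assignment, table)
        assert summary.loc["Patient Tissue", "n_total"] == 11
        assert summary.loc["Patient Tissue", "n_abstained"] == 2
        assert summary.loc["Cell Line", "n_total"] == 13
        assert summary.loc["Cell Line", "n_abstained"] == 2
        assert summary.loc["PDX", "n_total"] == 33
        assert summary.loc["PDX", "n_abstained"] == 4

    def test_all_abstaining_gives_zero_fractions(self):
        table = _vote_table([(40, 30, 30)] * 3, types=["t1", "t2", "t2"])
        summary = gp.summarize_by_sample_type(gp.assign(table, threshold=80), table)
        assert (summary["fraction_classified"] == 0).all()

    def test_single_classified_sample(self):
        table = _vote_table([(90, 5, 5)])
        summary = gp.summarize_by_sample_type(gp.assign(table, threshold=80), table)
        row = summary.loc["x"]
        assert (
            row.n_total,
            row.n_classified,
            row.n_abstained,
            row.fraction_classified,
        ) == (1, 1, 0, 1.0)


class TestEnsemble:
    def test_single_member_votes_are_indicators(self, small_normalized):
        planted = small_normalized.truth.marker_genes()
        train = gp.align_to_panel(small_normalized, planted)
        cfg = gp.ConsensusConfig(
            n_members=1, vote_threshold=1, n_folds_accuracy=3,
            base=FAST_BOOSTER, seed=1,
        )
        ensemble = gp.build_ensemble(train, cfg)
        votes = gp.vote(ensemble, train)
        assert (votes.votes.sum(axis=1) == 1).all()
        assert votes.votes.to_numpy().max() == 1

    def test_identical_members_vote_unanimously(self, small_normalized):
        planted = small_normalized.truth.marker_genes()
        train = gp.align_to_panel(small_normalized, planted)
        cfg = gp.ConsensusConfig(
            n_members=1, vote_threshold=1, n_folds_accuracy=3,
            base=FAST_BOOSTER, seed=1,
        )
        one = gp.build_ensemble(train, cfg)
        clones = gp.Ensemble(
            models=one.models * 5,
            member_accuracies=one.member_accuracies * 5,
            classes=one.classes,
            panel_genes=one.panel_genes,
        )
        votes = gp.vote(clones, train)
        assert (votes.votes.max(axis=1) == 5).all()

    def test_member_accuracy_beats_majority_class(self, small_normalized):
        planted = small_normalized.truth.marker_genes()
        train = gp.align_to_panel(small_normalized, planted)
        cfg = gp.ConsensusConfig(
            n_members=5, vote_threshold=4, n_folds_accuracy=3,
            base=FAST_BOOSTER, seed=6,
        )
        ensemble = gp.build_ensemble(train, cfg)
        majority = train.class_counts().max() / train.n_samples
        assert np.mean(ensemble.member_accuracies) >= majority

    def test_unaligned_query_is_rejected(self, small_normalized):
        planted = small_normalized.truth.marker_genes()
        train = gp.align_to_panel(small_normalized, planted)
        cfg = gp.ConsensusConfig(
            n_members=1, vote_threshold=1, n_folds_accuracy=3,
            base=FAST_BOOSTER, seed=1,
        )
        ensemble = gp.build_ensemble(train, cfg)
        with pytest.raises(ValidationError, match="align"):
            gp.vote(ensemble, small_normalized)

    def test_empty_query_gives_empty_table(self, small_normalized):
        planted = small_normalized.truth.marker_genes()
        train = gp.align_to_panel(small_normalized, planted)
        cfg = gp.ConsensusConfig(
            n_members=1, vote_threshold=1, n_folds_accuracy=3,
            base=FAST_BOOSTER, seed=1,
        )
        ensemble = gp.build_ensemble(train, cfg)
        empty = train.subset(samples=[])
        votes = gp.vote(ensemble, empty)
        assert len(votes.votes) == 0


class TestDeskScaleConsensus:
    """Study-condition checks on the mixed query cohort."""

    def test_vote_conservation(self, desk_query_votes):
        votes, _, _ = desk_query_votes
        assert (votes.votes.sum(axis=1) == votes.n_members).all()

    def test_pure_samples_are_called_correctly(self, desk_query_votes):
        votes, assignment, truth = desk_query_votes
        pure = ~truth.ambiguous
        called = assignment.calls[pure.values] != ABSTAIN
        assert called.mean() >= 0.9
        for sample in called[called].index:
            assert assignment.calls[sample] == truth.labels[sample]

    def test_ambiguous_samples_abstain_more_often(self, desk_query_votes):
        votes, assignment, truth = desk_query_votes
        abstained = assignment.abstained()
        rate_mixed = abstained[truth.ambiguous.values].mean()
        rate_pure = abstained[(~truth.ambiguous).values].mean()
        assert rate_mixed > rate_pure

    def test_ambiguous_samples_get_more_dispersed_votes(self, desk_query_votes):
        votes, _, truth = desk_query_votes
        max_votes = votes.votes.max(axis=1)
        assert (
            max_votes[truth.ambiguous.values].mean()
            < max_votes[(~truth.ambiguous).values].mean()
        )


def test_consensus_config_validation():
    with pytest.raises(ValidationError, match="vote_threshold"):
        gp.ConsensusConfig(n_members=10, vote_threshold=11).validate()
    with pytest.raises(ValidationError, match="n_members"):
        gp.ConsensusConfig(n_members=0).validate()
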