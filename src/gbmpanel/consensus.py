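"""Consensus ensemble prediction with abstention.

The selected gene panel is used to build an ensemble of independently
seeded boosted classifiers.  Each member (i) runs one k-fold CV on the
panel-restricted training data to record its averaged validation accuracy,
and (ii) is refit on all training samples for query prediction.  Members
differ only through their derived random seeds (fold partition, per-tree
column subsampling, monitor split).  Each member casts one hard class vote
per query sample; a subtype is called only when some class collects at
least ``vote_threshold`` of the ``n_members`` votes, otherwise the sample
is left unclassified.

Protocol defaults: 100 members, call threshold 80 votes.  The threshold is
inclusive — a class at exactly 80 of 100 votes is called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import booster
from .booster import BoosterConfig, TrainedModel
from .dataset import ABSTAIN, LabeledDataset, derive_seed
from .errors import ValidationError
from .selection import SelectionConfig, run_cv_once


@dataclass
class ConsensusConfig:
    n_members: int = 100
    vote_threshold: int = 80
    n_folds_accuracy: int = 10
    stratified_folds: bool = False
    base: BoosterConfig = field(default_factory=BoosterConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_members < 1:
            raise ValidationError("n_members must be >= 1")
        if not 0 < self.vote_threshold <= self.n_members:
            raise ValidationError("vote_threshold must be in (0, n_members]")
        if self.n_folds_accuracy < 2:
            raise ValidationError("n_folds_accuracy must be >= 2")
        self.base.validate()


@dataclass
class Ensemble:
    """Refit member models plus the per-member CV accuracy record."""

    models: list[TrainedModel]
    member_accuracies: list[float]
    classes: list[str]
    panel_genes: list[str]

    @property
    def n_members(self) -> int:
        return len(self.models)


@dataclass
class VoteTable:
    """Per-sample per-class vote counts (rows sum to ``n_members``)."""

    votes: pd.DataFrame  # samples × classes, integer counts
    sample_types: pd.Series  # free-text category per sample
    n_members: int

    def validate(self) -> None:
        sums = self.votes.sum(axis=1)
        if not (sums == self.n_members).all():
            bad = sums[sums != self.n_members].index[:5]
            raise ValidationError(
                f"vote counts do not sum to n_members for samples: {list(bad)}"
            )
        if (self.votes.to_numpy() < 0).any():
            raise ValidationError("vote counts must be nonnegative")


@dataclass
class Assignment:
    """Subtype call per sample; :data:`~gbmpanel.dataset.ABSTAIN` when no
    class reached the vote threshold."""

    calls: pd.Series

    def abstained(self) -> pd.Series:
        return self.calls == ABSTAIN


def build_ensemble(train: LabeledDataset, config: ConsensusConfig) -> Ensemble:
    """Build the consensus ensemble on panel-restricted training data.

    ``train`` must already be restricted to the selected panel and
    normalized.  Member m derives its seed from ``(config.seed, m)``; its
    recorded accuracy comes from one k-fold CV, and its query-facing model
    is refit on all training samples with the same seed.
    """
    config.validate()
    sel_cfg = SelectionConfig(
        n_runs=1,
        n_folds=config.n_folds_accuracy,
        top_k=min(1, train.n_genes),
        frequency_threshold=0,
        stratified_folds=config.stratified_folds,
        base=config.base,
        seed=config.seed,
    )
    X = train.matrix.T
    models: list[TrainedModel] = []
    accuracies: list[float] = []
    classes = sorted(train.labels.unique())
    for m in range(config.n_members):
        member_seed = derive_seed(config.seed, m)
        cv = run_cv_once(train, sel_cfg, member_seed, run_index=m)
        accuracies.append(cv.mean_validation_accuracy)
        member_cfg = BoosterConfig(**{**vars(config.base), "seed": member_seed})
        models.append(booster.train(X, train.labels, member_cfg))
    return Ensemble(
        models=models,
        member_accuracies=accuracies,
        classes=classes,
        panel_genes=list(train.matrix.index),
    )


def vote(ensemble: Ensemble, query: LabeledDataset) -> VoteTable:
    """Count, per query sample, the members voting for each class.

    The query must be aligned to the ensemble's panel (same genes, same
    order) and normalized identically to the training data.
    """
    if list(query.matrix.index) != ensemble.panel_genes:
        raise ValidationError(
            "query is not aligned to the ensemble's gene panel; "
            "run align_to_panel first"
        )
    Xq = query.matrix.T
    counts = pd.DataFrame(
        0, index=Xq.index, columns=ensemble.classes, dtype=int
    )
    for model in ensemble.models:
        pred = booster.predict(model, Xq)
        for sample, cls in pred.items():
            counts.at[sample, cls] += 1
    stypes = (
        query.sample_types
        if query.sample_types is not None
        else pd.Series("unknown", index=Xq.index)
    )
    table = VoteTable(votes=counts, sample_types=stypes, n_members=ensemble.n_members)
    table.validate()
    return table


def assign(votes: VoteTable, config: ConsensusConfig | None = None,
           threshold: int | None = None) -> Assignment:
    """Call the class reaching the vote threshold, else abstain.

    With a threshold above ``n_members / 2`` at most one class can qualify;
    below that, ties break toward the higher count then lexicographic
    class order.
    """
    if threshold is None:
        threshold = (config or ConsensusConfig()).vote_threshold
    votes.validate()
    calls = {}
    for sample, row in votes.votes.iterrows():
        qualifying = row[row >= threshold]
        if qualifying.empty:
            calls[sample] = ABSTAIN
        else:
            best = qualifying.sort_index().sort_values(ascending=False, kind="stable")
            calls[sample] = best.index[0]
    return Assignment(
        calls=pd.Series(calls, name="call").reindex(votes.votes.index)
    )


def summarize_by_sample_type(
    assignment: Assignment, votes: VoteTable
) -> pd.DataFrame:
    """Classified / abstained counts per sample-type category.

    Returns one row per sample type with columns ``n_total``,
    ``n_classified``, ``n_abstained``, ``fraction_classified``; rows sorted
    by sample type.
    """
    if not assignment.calls.index.equals(votes.votes.index):
        raise ValidationError("assignment and vote table cover different samples")
    df = pd.DataFrame(
        {
            "sample_type": votes.sample_types,
            "abstained": assignment.abstained(),
        }
    )
    rows = []
    for stype, grp in df.groupby("sample_type", sort=True):
        n_total = len(grp)
        n_abst = int(grp["abstained"].sum())
        rows.append(
            {
                "sample_type": stype,
                "n_total": n_total,
                "n_classified": n_total - n_abst,
                "n_abstained": n_abst,
                "fraction_classified": (n_total - n_abst) / n_total,
            }
        )
    return pd.DataFrame(rows).set_index("sample_type")
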