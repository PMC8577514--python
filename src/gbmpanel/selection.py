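"""Stability selection by repeated k-fold cross-validation.

One *run* is a complete k-fold CV: the samples are randomly partitioned
into k roughly equal folds (optionally stratified by class), one boosted
model is fit per fold on the remaining folds and scored on the held-out
fold, and the run's per-gene importance is the average of the k fold
models' importances.  The run records its averaged validation accuracy and
its ``top_k`` genes by that averaged importance.  Repeating the run many
times with fresh partitions and counting how often each gene enters the
top-k list yields a frequency table; the gene panel is the set of genes
whose count reaches the frequency threshold.

Protocol defaults: 100 runs of 10-fold CV, top 20 genes recorded per run,
panel threshold 80 of 100 appearances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import booster
from .booster import BoosterConfig
from .dataset import LabeledDataset, derive_seed
from .errors import EmptyPanelError, ValidationError


@dataclass
class SelectionConfig:
    n_runs: int = 100
    n_folds: int = 10
    top_k: int = 20
    frequency_threshold: int = 80
    stratified_folds: bool = False
    leaky_monitor: bool = False
    base: BoosterConfig = field(default_factory=BoosterConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ValidationError("n_runs must be >= 1")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if not 0 <= self.frequency_threshold <= self.n_runs:
            raise ValidationError("frequency_threshold must be in [0, n_runs]")
        self.base.validate()


@dataclass
class CVRunResult:
    """One CV run: averaged validation accuracy and its top-k gene list."""

    run_index: int
    mean_validation_accuracy: float
    top_genes: list[str]
    per_fold_accuracy: list[float]


@dataclass
class FrequencyTable:
    """Gene → number of runs in which it entered the top-k list.

    ``counts`` is sorted by count descending, gene id ascending; its sum is
    exactly ``n_runs × top_k``.
    """

    counts: pd.Series
    n_runs: int
    top_k: int


@dataclass
class GenePanel:
    """Thresholded gene selection plus the table that produced it."""

    genes: list[str]
    table: FrequencyTable
    threshold: int

    def __len__(self) -> int:
        return len(self.genes)


def _random_partition(
    n: int, n_folds: int, y: np.ndarray | None, rng_seed: int, stratified: bool
) -> list[np.ndarray]:
    """Fold membership as a list of index arrays, sizes differing by <= 1."""
    if stratified:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
        return [test for _, test in skf.split(np.zeros(n), y)]
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    return [np.sort(a) for a in np.array_split(perm, n_folds)]


def run_cv_once(
    data: LabeledDataset, config: SelectionConfig, run_seed: int, run_index: int = 0
) -> CVRunResult:
    """One complete k-fold CV run on a labeled dataset.

    Features are the dataset's (already normalized) expression values,
    transposed to samples × genes.  Ties in the averaged importance at rank
    ``top_k`` break by gene id ascending, so the recorded list is
    deterministic.
    """
    config.validate()
    if data.n_samples < config.n_folds:
        raise ValidationError(
            f"sample count {data.n_samples} is below n_folds {config.n_folds}"
        )
    if config.top_k > data.n_genes:
        raise ValidationError(
            f"top_k {config.top_k} exceeds gene count {data.n_genes}"
        )
    X = data.matrix.T
    labels = data.labels
    classes = sorted(labels.unique())
    y = np.asarray([classes.index(v) for v in labels])

    folds = _random_partition(
        data.n_samples, config.n_folds, y, run_seed, config.stratified_folds
    )
    importance_sum = pd.Series(0.0, index=data.matrix.index)
    per_fold_acc: list[float] = []
    for f, test_idx in enumerate(folds):
        mask = np.zeros(data.n_samples, dtype=bool)
        mask[test_idx] = True
        if len(set(y[mask])) == 1 and not config.stratified_folds:
            warnings.warn(
                f"fold {f} contains a single class; its accuracy estimate "
                "is degenerate",
                stacklevel=2,
            )
        fold_cfg = BoosterConfig(**{**vars(config.base), "seed": derive_seed(run_seed, f)})
        monitor = (X[mask], labels[mask]) if config.leaky_monitor else None
        model = booster.train(X[~mask], labels[~mask], fold_cfg, monitor=monitor)
        pred = booster.predict(model, X[mask])
        per_fold_acc.append(float((pred.values == labels[mask].values).mean()))
        importance_sum = importance_sum.add(pd.Series(model.importances), fill_value=0.0)

    avg_importance = importance_sum / config.n_folds
    order = sorted(
        avg_importance.index, key=lambda g: (-avg_importance[g], g)
    )
    return CVRunResult(
        run_index=run_index,
        mean_validation_accuracy=float(np.mean(per_fold_acc)),
        top_genes=order[: config.top_k],
        per_fold_accuracy=per_fold_acc,
    )


def run_repeated_cv(
    data: LabeledDataset,
    config: SelectionConfig,
    progress: bool = False,
) -> list[CVRunResult]:
    """The full protocol: ``n_runs`` independent CV runs.

    Run r is seeded deterministically from ``(config.seed, r)``, so the
    result list is independent of execution order and any subset of runs
    can be reproduced in isolation.
    """
    config.validate()
    results = []
    for r in range(config.n_runs):
        res = run_cv_once(data, config, derive_seed(config.seed, r), run_index=r)
        if progress:
            print(
                f"run {r + 1}/{config.n_runs}: "
                f"mean CV accuracy {res.mean_validation_accuracy:.4f}",
                flush=True,
            )
        results.append(res)
    return results


def build_frequency_table(runs: list[CVRunResult]) -> FrequencyTable:
    """Count, per gene, the runs in which it appeared among the top-k."""
    if not runs:
        raise ValidationError("runs must be nonempty")
    top_k = len(runs[0].top_genes)
    for r in runs:
        if len(r.top_genes) != top_k:
            raise ValidationError("runs have inconsistent top_k")
    counts: dict[str, int] = {}
    for r in runs:
        for g in r.top_genes:
            counts[g] = counts.get(g, 0) + 1
    s = pd.Series(counts, dtype=int)
    s = s.sort_index().sort_values(ascending=False, kind="stable")
    s.index.name = "gene_id"
    s.name = "frequency"
    return FrequencyTable(counts=s, n_runs=len(runs), top_k=top_k)


def select_panel(
    table: FrequencyTable, config: SelectionConfig | None = None, threshold: int | None = None
) -> GenePanel:
    """Genes appearing at least ``threshold`` times, count-descending.

    The threshold is inclusive: a gene at exactly the threshold count is
    selected.  Raises :class:`EmptyPanelError` (with the best observed
    count) when nothing qualifies.
    """
    if threshold is None:
        threshold = (config or SelectionConfig()).frequency_threshold
    selected = table.counts[table.counts >= threshold]
    if selected.empty:
        raise EmptyPanelError(threshold, int(table.counts.max()) if len(table.counts) else 0)
    return GenePanel(genes=list(selected.index), table=table, threshold=threshold)


def summarize_accuracy(runs: list[CVRunResult]) -> dict[str, float]:
    """Mean / sample-sd / min / max of the runs' averaged CV accuracies."""
    if not runs:
        raise ValidationError("runs must be nonempty")
    acc = np.array([r.mean_validation_accuracy for r in runs])
    sd = float(acc.std(ddof=1)) if len(acc) > 1 else 0.0
    return {
        "mean": float(acc.mean()),
        "sd": sd,
        "min": float(acc.min()),
        "max": float(acc.max()),
    }
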