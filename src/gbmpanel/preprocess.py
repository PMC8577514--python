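"""Dataset filtering, counts-per-million normalization, panel alignment.

Filtering drops unannotated samples first and then genes with zero counts
in every retained sample, in that order — a gene expressed only in dropped
samples is therefore removed too.  CPM rescales each sample (column) to a
fixed total of one million, optionally followed by a log2(x + pseudocount)
transform; totals are always computed on the full gene set, so panel
alignment must happen *after* normalization (the pipeline driver guards
this ordering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .errors import ValidationError


@dataclass
class NormalizationConfig:
    """CPM settings: fixed 1e6 scale, optional log2 with pseudocount."""

    scale_factor: float = 1e6
    log_transform: bool = True
    pseudocount: float = 1.0

    def validate(self) -> None:
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be > 0")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")


@dataclass
class FilterReport:
    """Counts of samples/genes dropped by :func:`filter_dataset`."""

    n_samples_in: int
    n_samples_dropped: int
    n_genes_in: int
    n_genes_dropped: int

    @property
    def n_samples_kept(self) -> int:
        return self.n_samples_in - self.n_samples_dropped

    @property
    def n_genes_kept(self) -> int:
        return self.n_genes_in - self.n_genes_dropped


def filter_dataset(data: LabeledDataset) -> tuple[LabeledDataset, FilterReport]:
    """Drop unlabeled samples, then genes that are all-zero afterwards.

    Order of the remaining rows and columns is preserved.  Raises
    :class:`ValidationError` if no labeled sample remains.
    """
    keep_samples = data.labeled_mask()
    n_samples_dropped = int((~keep_samples).sum())
    if not keep_samples.any():
        raise ValidationError("no labeled samples")
    sub = data.matrix.loc[:, keep_samples[keep_samples].index]
    keep_genes = (sub != 0).any(axis=1)
    n_genes_dropped = int((~keep_genes).sum())
    filtered = data.subset(
        genes=list(sub.index[keep_genes]),
        samples=list(sub.columns),
    )
    report = FilterReport(
        n_samples_in=data.n_samples,
        n_samples_dropped=n_samples_dropped,
        n_genes_in=data.n_genes,
        n_genes_dropped=n_genes_dropped,
    )
    return filtered, report


def cpm_normalize(
    counts: pd.DataFrame, config: NormalizationConfig | None = None
) -> pd.DataFrame:
    """Counts-per-million: each column rescaled to sum to ``scale_factor``.

    value = raw / column_total × scale_factor, then log2(value + pseudocount)
    when ``log_transform`` is on.  Columns with zero total are an error —
    the normalization is undefined for them — and are named in the message.
    """
    config = config or NormalizationConfig()
    config.validate()
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(
            "cannot CPM-normalize samples with zero total counts: "
            + ", ".join(map(str, zero.index[:10]))
        )
    cpm = counts.div(totals, axis=1) * config.scale_factor
    if config.log_transform:
        cpm = np.log2(cpm + config.pseudocount)
    return cpm


def cpm_normalize_dataset(
    data: LabeledDataset, config: NormalizationConfig | None = None
) -> LabeledDataset:
    """:func:`cpm_normalize` applied to a dataset, metadata carried along."""
    return LabeledDataset(
        cpm_normalize(data.matrix, config),
        data.labels.copy(),
        data.truth,
        data.sample_types,
    )


def align_to_panel(data: LabeledDataset, panel) -> LabeledDataset:
    """Restrict a dataset to the panel's genes, in panel order.

    ``panel`` may be a :class:`~gbmpanel.selection.GenePanel` or a plain
    sequence of gene ids.  Any panel gene missing from the dataset is an
    error (no silent imputation).
    """
    genes = list(getattr(panel, "genes", panel))
    if not genes:
        raise ValidationError("panel is empty")
    missing = [g for g in genes if g not in data.matrix.index]
    if missing:
        raise ValidationError(
            f"panel genes absent from dataset: {', '.join(missing)}"
        )
    return data.subset(genes=genes)
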