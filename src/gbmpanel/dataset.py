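"""Core data containers: expression matrices with per-sample labels.

The unit of work throughout the pipeline is a :class:`LabeledDataset` — a
genes × samples expression table plus one subtype label per sample.  Query
cohorts use the missing-label sentinel :data:`MISSING_LABEL`; simulated
cohorts additionally carry a :class:`CohortTruth` record of the planted
ground truth (marker genes per class, true generating class per sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Label sentinel for samples whose subtype is unknown (query cohorts, or
#: unannotated training samples that the filtering stage drops).
MISSING_LABEL = "NA"

#: Call sentinel emitted when the consensus vote reaches no class threshold.
ABSTAIN = "unclassified"


@dataclass
class CohortTruth:
    """Planted ground truth of a simulated cohort (never seen by models).

    Attributes
    ----------
    markers
        Mapping of class name -> list of gene ids whose expression was
        up-regulated in that class.
    labels
        True generating class per sample.  Ambiguous (mixture) samples are
        recorded as ``"classA+classB"``.
    ambiguous
        Boolean flag per sample; True for samples drawn from a 50/50
        two-class mixture profile.
    """

    markers: dict[str, list[str]]
    labels: pd.Series
    ambiguous: pd.Series

    def marker_genes(self) -> list[str]:
        """All planted marker genes, across classes, without duplicates."""
        seen: dict[str, None] = {}
        for genes in self.markers.values():
            for g in genes:
                seen[g] = None
        return list(seen)


@dataclass
class LabeledDataset:
    """A genes × samples expression matrix with per-sample class labels.

    ``matrix`` rows are genes (index = gene ids), columns are samples
    (columns = sample ids).  ``labels`` is indexed by sample id and may use
    :data:`MISSING_LABEL` for unlabeled samples.
    """

    matrix: pd.DataFrame
    labels: pd.Series
    truth: CohortTruth | None = None
    sample_types: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    # -- contract -----------------------------------------------------------
    def validate(self) -> None:
        if self.matrix.index.has_duplicates:
            raise ValidationError("gene_ids contain duplicates")
        if self.matrix.columns.has_duplicates:
            raise ValidationError("sample_ids contain duplicates")
        if len(self.labels) != self.matrix.shape[1]:
            raise ValidationError(
                f"label vector length {len(self.labels)} does not match "
                f"sample count {self.matrix.shape[1]}"
            )
        if not self.labels.index.equals(self.matrix.columns):
            raise ValidationError("labels index does not match matrix columns")
        if (self.matrix.to_numpy() < 0).any():
            raise ValidationError("matrix contains negative values")

    # -- convenience --------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def labeled_mask(self) -> pd.Series:
        """True for samples carrying a real (non-sentinel) label."""
        return self.labels.notna() & (self.labels != MISSING_LABEL)

    def subset(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "LabeledDataset":
        """Restrict to the given genes and/or samples, preserving order."""
        m = self.matrix
        if genes is not None:
            m = m.loc[list(genes)]
        if samples is not None:
            m = m[list(samples)]
        labels = self.labels.loc[m.columns]
        truth = None
        if self.truth is not None:
            truth = CohortTruth(
                markers={
                    c: [g for g in gs if g in m.index]
                    for c, gs in self.truth.markers.items()
                },
                labels=self.truth.labels.loc[m.columns],
                ambiguous=self.truth.ambiguous.loc[m.columns],
            )
        stypes = None
        if self.sample_types is not None:
            stypes = self.sample_types.loc[m.columns]
        return LabeledDataset(m.copy(), labels.copy(), truth, stypes)

    def class_counts(self) -> pd.Series:
        """Counts of each real label among labeled samples."""
        return self.labels[self.labeled_mask()].value_counts()


# ---------------------------------------------------------------------------
# TSV dialect
#
# matrix.tsv  : first column "gene_id", header row of sample ids
# labels.tsv  : two columns sample_id, label
# truth.tsv   : two columns gene_id, class  (planted markers)
# panel.txt   : one gene id per line; lines starting with '#' are comments
# ---------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    return m


def write_labels(labels: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": labels.index, "label": labels.values})
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ValidationError(
            f"labels file {path} must have columns sample_id, label"
        )
    return pd.Series(df["label"].values, index=df["sample_id"].values, name="label")


def write_truth_markers(markers: Mapping[str, Sequence[str]], path: str | Path) -> None:
    rows = [(g, c) for c, genes in markers.items() for g in genes]
    pd.DataFrame(rows, columns=["gene_id", "class"]).to_csv(path, sep="\t", index=False)


def write_panel(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_panel(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def dataset_from_files(
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
) -> LabeledDataset:
    """Load a dataset from the TSV dialect; missing labels default to NA."""
    matrix = read_matrix(matrix_path)
    if labels_path is not None:
        labels = read_labels(labels_path)
        missing = [s for s in matrix.columns if s not in labels.index]
        if missing:
            raise ValidationError(
                f"labels file lacks entries for samples: {missing[:5]}"
            )
        labels = labels.loc[matrix.columns]
    else:
        labels = pd.Series(MISSING_LABEL, index=matrix.columns, name="label")
    return LabeledDataset(matrix, labels)


def derive_seed(*keys: int) -> int:
    """Deterministically derive a 31-bit integer seed from a key tuple.

    Uses :class:`numpy.random.SeedSequence` so that per-run / per-member
    seeds are reproducible individually and order-independent.
    """
    ss = np.random.SeedSequence(list(keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
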