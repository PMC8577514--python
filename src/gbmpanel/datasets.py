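"""Packaged reference tables for the published five-gene GBM classifier.

Two small TSVs ship with the package:

``mcmaster_votes.tsv``
    The published per-sample consensus vote counts of a 100-member
    five-gene ensemble applied to the 57-sample McMaster GBM cohort
    (11 patient tissues, 13 cell lines, 33 PDX models), with the reported
    subtype calls.  ``treated`` flags PDX models that received radiation,
    chemotherapy, and/or targeted therapy.  Sample ids are synthesized
    here (patient id + sample-type abbreviation + occurrence index) since
    the published table identifies rows by patient only.

``reference_frequencies.tsv``
    The published appearance frequencies of the 20 most frequently
    top-ranked genes across 100 runs of 10-fold CV stability selection on
    the Wang et al. (2017) GBM RNA-seq cohort.

These tables drive the rule-application tests (vote thresholding, panel
thresholding, per-type summaries); they are inputs to the decision rules,
not outputs of this package's training code.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .consensus import VoteTable

#: Class labels of the three glioma-intrinsic transcriptional subtypes.
SUBTYPE_CLASSES = ["classical", "mesenchymal", "proneural"]


def _data_path(name: str):
    return resources.files("gbmpanel").joinpath("data", name)


def load_mcmaster_votes() -> pd.DataFrame:
    """Published vote counts for the McMaster cohort, one row per sample."""
    with resources.as_file(_data_path("mcmaster_votes.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"treated": int})
    df["reported_call"] = df["reported_call"].fillna("")
    return df.set_index("sample_id")


def mcmaster_vote_table() -> VoteTable:
    """The same data as a :class:`~gbmpanel.consensus.VoteTable`."""
    df = load_mcmaster_votes()
    return VoteTable(
        votes=df[SUBTYPE_CLASSES].astype(int),
        sample_types=df["sample_type"],
        n_members=100,
    )


def load_reference_frequencies() -> pd.Series:
    """Published top-20 gene appearance counts (out of 100 CV runs)."""
    with resources.as_file(_data_path("reference_frequencies.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return pd.Series(
        df["frequency"].astype(int).values,
        index=df["gene_id"].values,
        name="frequency",
    )


def reference_frequency_table() -> "FrequencyTable":
    """The published frequencies as a (truncated) FrequencyTable.

    Only the printed top-20 rows are known, so the table's counts do not
    sum to ``n_runs × top_k``; it is nevertheless sufficient for panel
    thresholding at any threshold above the last printed count.
    """
    from .selection import FrequencyTable

    counts = load_reference_frequencies()
    counts.index.name = "gene_id"
    counts = counts.sort_index().sort_values(ascending=False, kind="stable")
    return FrequencyTable(counts=counts, n_runs=100, top_k=20)
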