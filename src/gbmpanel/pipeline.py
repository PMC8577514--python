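"""End-to-end pipeline driver: filter → CPM → repeated CV → panel →
consensus ensemble → votes → assignment → summaries.

The driver owns two cross-stage guarantees that no single stage can see:

* **Normalization before alignment.**  CPM totals must be computed on the
  full gene set; restricting to the panel first would change every total.
  The driver normalizes both cohorts on all genes and only then aligns to
  the panel.
* **Determinism.**  One master seed derives all stage seeds; re-running an
  identical config reproduces every output file bit for bit, and the run
  manifest records the config hash, derived seeds, and output checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import consensus as cons
from . import preprocess as prep
from . import selection as sel
from . import simulate as sim
from .dataset import (
    LabeledDataset,
    dataset_from_files,
    derive_seed,
    write_labels,
    write_matrix,
    write_panel,
    write_truth_markers,
)
from .errors import GbmPanelError, PipelineStageError, ValidationError


@dataclass
class PipelineConfig:
    """One config object reproduces a full run end to end."""

    output_dir: str = "gbmpanel_run"
    seed: int | None = 0
    simulation: sim.SimulationSpec | None = field(
        default_factory=sim.SimulationSpec
    )
    train_matrix: str | None = None
    train_labels: str | None = None
    query_matrix: str | None = None
    query_sample_types: str | None = None
    normalization: prep.NormalizationConfig = field(
        default_factory=prep.NormalizationConfig
    )
    selection: sel.SelectionConfig = field(default_factory=sel.SelectionConfig)
    consensus: cons.ConsensusConfig = field(default_factory=cons.ConsensusConfig)

    def resolved(self) -> "PipelineConfig":
        """Derive stage seeds from the master seed (when one is set)."""
        if self.seed is None:
            return self
        out = replace(self)
        if out.simulation is not None:
            out.simulation = replace(out.simulation, seed=derive_seed(self.seed, 0))
        out.selection = replace(
            out.selection,
            seed=derive_seed(self.seed, 1),
            base=replace(out.selection.base, seed=derive_seed(self.seed, 1)),
        )
        out.consensus = replace(
            out.consensus,
            seed=derive_seed(self.seed, 2),
            base=replace(out.consensus.base, seed=derive_seed(self.seed, 2)),
        )
        return out


# ---------------------------------------------------------------------------
# Output-file dialects (all round-trippable)
# ---------------------------------------------------------------------------

def write_runs(runs: list[sel.CVRunResult], path: str | Path) -> None:
    rows = [
        {
            "run_index": r.run_index,
            "mean_validation_accuracy": repr(r.mean_validation_accuracy),
            "per_fold_accuracy": ",".join(repr(a) for a in r.per_fold_accuracy),
            "top_genes": ",".join(r.top_genes),
        }
        for r in runs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_runs(path: str | Path) -> list[sel.CVRunResult]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        sel.CVRunResult(
            run_index=int(row.run_index),
            mean_validation_accuracy=float(row.mean_validation_accuracy),
            top_genes=row.top_genes.split(","),
            per_fold_accuracy=[float(a) for a in row.per_fold_accuracy.split(",")],
        )
        for row in df.itertuples()
    ]


def write_frequency_table(table: sel.FrequencyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_runs={table.n_runs}\n# top_k={table.top_k}\n")
        table.counts.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_frequency_table(path: str | Path) -> sel.FrequencyTable:
    meta = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        k, v = line[1:].strip().split("=")
        meta[k.strip()] = int(v)
        body_start += 1
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[body_start:])), sep="\t")
    counts = pd.Series(
        df["frequency"].astype(int).values, index=df["gene_id"].values,
        name="frequency",
    )
    counts.index.name = "gene_id"
    return sel.FrequencyTable(counts=counts, n_runs=meta["n_runs"], top_k=meta["top_k"])


def write_votes(
    votes: cons.VoteTable, assignment: cons.Assignment, path: str | Path
) -> None:
    df = votes.votes.copy()
    df.insert(0, "sample_type", votes.sample_types)
    df["call"] = assignment.calls
    df.rename_axis("sample_id").to_csv(path, sep="\t")


def read_votes(path: str | Path, n_members: int | None = None):
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    classes = [c for c in df.columns if c not in ("sample_type", "call")]
    counts = df[classes].astype(int)
    if n_members is None:
        n_members = int(counts.sum(axis=1).iloc[0]) if len(counts) else 0
    votes = cons.VoteTable(
        votes=counts, sample_types=df["sample_type"], n_members=n_members
    )
    assignment = cons.Assignment(calls=df["call"])
    return votes, assignment


def write_summary(summary: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"statistic": list(summary), "value": [repr(v) for v in summary.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_summary(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row.statistic: float(row.value) for row in df.itertuples()}


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    return json.loads(json.dumps(asdict(config)))


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, GbmPanelError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, progress: bool = False) -> dict:
    """Execute the full pipeline and return the run manifest (also written
    to ``output_dir/manifest.json``)."""
    resolved = config.resolved()
    out = Path(resolved.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- inputs -------------------------------------------------------------
    with _stage("load_inputs"):
        if resolved.simulation is not None:
            train = sim.generate_cohort(resolved.simulation)
            query = sim.generate_query_cohort(resolved.simulation, train.truth)
            write_matrix(train.matrix, out / "train_matrix.tsv")
            write_labels(train.labels, out / "train_labels.tsv")
            write_truth_markers(train.truth.markers, out / "train_truth_markers.tsv")
            write_matrix(query.matrix, out / "query_matrix.tsv")
            write_labels(query.truth.labels, out / "query_truth_labels.tsv")
        elif resolved.train_matrix and resolved.train_labels:
            train = dataset_from_files(resolved.train_matrix, resolved.train_labels)
            query = None
            if resolved.query_matrix:
                query = dataset_from_files(resolved.query_matrix)
                if resolved.query_sample_types:
                    st = pd.read_csv(
                        resolved.query_sample_types, sep="\t", index_col="sample_id"
                    )["sample_type"]
                    query.sample_types = st.reindex(query.matrix.columns).fillna("unknown")
        else:
            raise ValidationError(
                "config must provide either a simulation spec or "
                "train_matrix + train_labels paths"
            )

    # -- preprocessing ------------------------------------------------------
    with _stage("filter"):
        train, filter_report = prep.filter_dataset(train)
    with _stage("normalize"):
        # CPM totals must see the full gene set: normalize before any
        # panel alignment (ordering guard for the whole driver).
        norm_train = prep.cpm_normalize_dataset(train, resolved.normalization)
        norm_query = (
            prep.cpm_normalize_dataset(query, resolved.normalization)
            if query is not None
            else None
        )

    # -- stability selection ------------------------------------------------
    with _stage("repeated_cv"):
        runs = sel.run_repeated_cv(norm_train, resolved.selection, progress=progress)
        write_runs(runs, out / "runs.tsv")
    with _stage("frequency_table"):
        table = sel.build_frequency_table(runs)
        write_frequency_table(table, out / "frequency_table.tsv")
    with _stage("select_panel"):
        panel = sel.select_panel(table, resolved.selection)
        write_panel(panel.genes, out / "panel.txt")
    with _stage("accuracy_summary"):
        acc = sel.summarize_accuracy(runs)
        write_summary(acc, out / "accuracy_summary.tsv")

    # -- consensus ----------------------------------------------------------
    with _stage("build_ensemble"):
        panel_train = prep.align_to_panel(norm_train, panel)
        ensemble = cons.build_ensemble(panel_train, resolved.consensus)
        pd.DataFrame(
            {
                "member": range(ensemble.n_members),
                "cv_accuracy": [repr(a) for a in ensemble.member_accuracies],
            }
        ).to_csv(out / "member_accuracy.tsv", sep="\t", index=False)

    votes = assignment = None
    if norm_query is not None:
        with _stage("vote"):
            panel_query = prep.align_to_panel(norm_query, panel)
            votes = cons.vote(ensemble, panel_query)
        with _stage("assign"):
            assignment = cons.assign(votes, resolved.consensus)
            write_votes(votes, assignment, out / "votes.tsv")
        with _stage("summarize_by_sample_type"):
            by_type = cons.summarize_by_sample_type(assignment, votes)
            by_type.to_csv(out / "summary_by_type.tsv", sep="\t")

    # -- manifest -----------------------------------------------------------
    cfg_dict = _config_dict(resolved)
    # the hash identifies the analytic configuration, not its destination
    hashed = {k: v for k, v in cfg_dict.items() if k != "output_dir"}
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()
        ).hexdigest(),
        "master_seed": config.seed,
        "filter_report": asdict(filter_report),
        "panel": panel.genes,
        "accuracy_summary": acc,
        "n_runs": len(runs),
        "n_query_samples": 0 if votes is None else int(len(votes.votes)),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_report(output_dir: str | Path, top_rows: int = 20) -> str:
    """Markdown summary of a finished run (accuracy, panel, per-type calls)."""
    out = Path(output_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"missing output file: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    for name in ("frequency_table.tsv", "accuracy_summary.tsv", "panel.txt"):
        if not (out / name).exists():
            raise ValidationError(f"missing output file: {out / name}")
    table = read_frequency_table(out / "frequency_table.tsv")
    acc = read_summary(out / "accuracy_summary.tsv")

    lines = ["# gbmpanel run report", ""]
    lines += [
        "## Cross-validation accuracy",
        "",
        f"- runs: {manifest['n_runs']}",
        f"- mean: {acc['mean']:.4f}",
        f"- sd: {acc['sd']:.4f}",
        f"- min: {acc['min']:.4f}",
        f"- max: {acc['max']:.4f}",
        "",
        f"## Gene frequency table (top {top_rows})",
        "",
        "| rank | gene | frequency |",
        "|---|---|---|",
    ]
    for rank, (gene, count) in enumerate(table.counts.head(top_rows).items(), 1):
        lines.append(f"| {rank} | {gene} | {count} |")
    lines += ["", "## Selected panel", ""]
    for gene in manifest["panel"]:
        lines.append(f"- {gene} ({int(table.counts.get(gene, 0))}/{table.n_runs})")

    votes_path = out / "votes.tsv"
    lines += ["", "## Query classification", ""]
    if votes_path.exists() and manifest["n_query_samples"] > 0:
        votes, assignment = read_votes(votes_path)
        by_type = cons.summarize_by_sample_type(assignment, votes)
        lines += [
            "| sample type | classified | total | fraction |",
            "|---|---|---|---|",
        ]
        for stype, row in by_type.iterrows():
            lines.append(
                f"| {stype} | {int(row.n_classified)} | {int(row.n_total)} "
                f"| {row.fraction_classified:.2f} |"
            )
    else:
        lines.append("zero query samples")
    return "\n".join(lines) + "\n"
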