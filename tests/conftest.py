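"""Shared fixtures: fast booster configs, small cohorts, and the two
desk-scale protocol runs (strong-effect and null) that several suites share.

The desk-scale runs use the generator's default study conditions
(2,000 genes, three classes of 50, 10 planted markers per class at log2
fold change 2) with a 20-run scaled protocol; they are session-scoped
because each one fits 200 boosted models.
"""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import gbmpanel as gp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


#: Booster protocol scaled for unit tests: fewer trees, same structure.
FAST_BOOSTER = gp.BoosterConfig(n_trees=60, early_stopping_patience=20)


@pytest.fixture
def fast_booster() -> gp.BoosterConfig:
    return dataclasses.replace(FAST_BOOSTER)


@pytest.fixture(scope="session")
def small_spec() -> gp.SimulationSpec:
    return gp.SimulationSpec(
        n_genes=300,
        samples_per_class=(15, 15, 15),
        n_informative_per_class=5,
        log2_fold_change=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec) -> gp.LabeledDataset:
    return gp.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_normalized(small_cohort) -> gp.LabeledDataset:
    filtered, _ = gp.filter_dataset(small_cohort)
    return gp.cpm_normalize_dataset(filtered)


# ---------------------------------------------------------------------------
# Desk-scale protocol runs (shared across selection + acceptance suites)
# ---------------------------------------------------------------------------

DESK_SPEC = gp.SimulationSpec(seed=101)
DESK_SELECTION = gp.SelectionConfig(n_runs=20, frequency_threshold=16, seed=202)


@pytest.fixture(scope="session")
def desk_cohort() -> gp.LabeledDataset:
    return gp.generate_cohort(DESK_SPEC)


@pytest.fixture(scope="session")
def desk_runs(desk_cohort):
    """Strong-effect protocol: 20 runs of 10-fold CV at default conditions."""
    filtered, _ = gp.filter_dataset(desk_cohort)
    norm = gp.cpm_normalize_dataset(filtered)
    return gp.run_repeated_cv(norm, DESK_SELECTION)


DESK_CONSENSUS = gp.ConsensusConfig(n_members=20, vote_threshold=16, seed=303)

SMOKE_SPEC = gp.SimulationSpec(
    n_genes=300,
    samples_per_class=(15, 15, 15),
    n_informative_per_class=5,
    mix_fraction=0.2,
    seed=0,  # overwritten by the master seed
)


def smoke_config(out_dir: str) -> gp.PipelineConfig:
    """A minutes-scale full-pipeline config used by the determinism checks."""
    return gp.PipelineConfig(
        output_dir=out_dir,
        seed=17,
        simulation=SMOKE_SPEC,
        selection=gp.SelectionConfig(
            n_runs=4, n_folds=3, top_k=15, frequency_threshold=3,
            base=FAST_BOOSTER,
        ),
        consensus=gp.ConsensusConfig(
            n_members=6, vote_threshold=5, n_folds_accuracy=3,
            base=FAST_BOOSTER,
        ),
    )


@pytest.fixture(scope="session")
def smoke_manifests(tmp_path_factory):
    """The same smoke config run twice into different directories."""
    d1 = tmp_path_factory.mktemp("run1")
    d2 = tmp_path_factory.mktemp("run2")
    m1 = gp.run_pipeline(smoke_config(str(d1)))
    m2 = gp.run_pipeline(smoke_config(str(d2)))
    return d1, m1, d2, m2


@pytest.fixture(scope="session")
def desk_panel(desk_runs):
    table = gp.build_frequency_table(desk_runs)
    return gp.select_panel(table, DESK_SELECTION)


@pytest.fixture(scope="session")
def desk_ensemble(desk_cohort, desk_panel):
    filtered, _ = gp.filter_dataset(desk_cohort)
    norm = gp.cpm_normalize_dataset(filtered)
    panel_train = gp.align_to_panel(norm, desk_panel)
    return gp.build_ensemble(panel_train, DESK_CONSENSUS)


@pytest.fixture(scope="session")
def desk_query_votes(desk_ensemble, desk_panel):
    """Votes + assignment on a mixed query cohort (30% ambiguous samples)."""
    spec = gp.query_spec(
        DESK_SPEC, samples_per_class=(25, 25, 25), mix_fraction=0.3
    )
    query = gp.generate_query_cohort(spec)
    norm = gp.cpm_normalize_dataset(query)
    aligned = gp.align_to_panel(norm, desk_panel)
    votes = gp.vote(desk_ensemble, aligned)
    assignment = gp.assign(votes, DESK_CONSENSUS)
    return votes, assignment, query.truth


@pytest.fixture(scope="session")
def null_runs():
    """Same protocol with the planted effect removed (log2 fold change 0)."""
    spec = dataclasses.replace(DESK_SPEC, log2_fold_change=0.0)
    cohort = gp.generate_cohort(spec)
    filtered, _ = gp.filter_dataset(cohort)
    norm = gp.cpm_normalize_dataset(filtered)
    return gp.run_repeated_cv(norm, DESK_SELECTION)
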