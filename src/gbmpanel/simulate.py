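"""Synthetic bulk RNA-seq cohorts with planted subtype-discriminative genes.

The generator emulates the statistical shape of a multi-class tumor-subtype
cohort: a negative-binomial count matrix with gene-level baseline expression,
library-size variation across samples, and a small set of marker genes that
are multiplicatively up-regulated in exactly one class.  Query cohorts share
the class profiles of their training cohort and can additionally carry a
batch scale shift and a fraction of ambiguous samples drawn from 50/50
two-class mixture profiles, which exercises the consensus classifier's
abstention path.

Class profiles are derived from a dedicated random stream keyed only by
``spec.seed``, so a training cohort and a query cohort generated from the
same spec share baselines and marker assignments while drawing disjoint
sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import MISSING_LABEL, CohortTruth, LabeledDataset
from .errors import ValidationError

#: Class names used when simulating the canonical three-subtype problem.
GBM_SUBTYPES = ("classical", "mesenchymal", "proneural")

# Sub-stream keys: profiles shared across cohorts, then per-cohort noise.
_STREAM_PROFILE = 0
_STREAM_TRAIN = 1
_STREAM_QUERY = 2


@dataclass
class SimulationSpec:
    """Parameters of one simulated cohort family.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 2,000 genes, three balanced classes of 50 samples, 10 markers
    per class up-regulated four-fold (log2 fold change 2).
    """

    n_classes: int = 3
    samples_per_class: tuple[int, ...] = (50, 50, 50)
    n_genes: int = 2000
    n_informative_per_class: int = 10
    log2_fold_change: float = 2.0
    baseline_log_mean_range: tuple[float, float] = (0.0, 4.0)
    dispersion: float = 0.3
    library_size_mean: float = 1e6
    library_size_cv: float = 0.3
    batch_scale_shift: float = 1.0
    mix_fraction: float = 0.0
    seed: int = 0
    class_names: tuple[str, ...] | None = field(default=None)

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if len(self.samples_per_class) != self.n_classes:
            raise ValidationError(
                "samples_per_class must have length n_classes "
                f"({len(self.samples_per_class)} != {self.n_classes})"
            )
        if any(n < 0 for n in self.samples_per_class):
            raise ValidationError("samples_per_class entries must be >= 0")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_informative_per_class < 0:
            raise ValidationError("n_informative_per_class must be >= 0")
        if self.n_informative_per_class * self.n_classes > self.n_genes:
            raise ValidationError(
                "n_informative_per_class × n_classes exceeds n_genes"
            )
        lo, hi = self.baseline_log_mean_range
        if hi < lo:
            raise ValidationError("baseline_log_mean_range must be (low, high)")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.library_size_mean <= 0:
            raise ValidationError("library_size_mean must be > 0")
        if self.library_size_cv < 0:
            raise ValidationError("library_size_cv must be >= 0")
        if self.batch_scale_shift <= 0:
            raise ValidationError("batch_scale_shift must be > 0")
        if not 0.0 <= self.mix_fraction <= 1.0:
            raise ValidationError("mix_fraction must be in [0, 1]")

    def classes(self) -> list[str]:
        if self.class_names is not None:
            if len(self.class_names) != self.n_classes:
                raise ValidationError("class_names must have length n_classes")
            return list(self.class_names)
        if self.n_classes == len(GBM_SUBTYPES):
            return list(GBM_SUBTYPES)
        return [f"class{k:02d}" for k in range(self.n_classes)]


@dataclass
class _ClassProfiles:
    """Shared generative parameters: baseline means and marker boosts."""

    gene_ids: list[str]
    classes: list[str]
    relative_expression: np.ndarray  # (n_genes,) baseline NB means, unnormalized
    baseline_total: float
    markers: dict[str, list[str]]
    marker_index: dict[str, np.ndarray]  # class -> planted gene row indices


def _build_profiles(spec: SimulationSpec) -> _ClassProfiles:
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, _STREAM_PROFILE])
    )
    gene_ids = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    classes = spec.classes()
    lo, hi = spec.baseline_log_mean_range
    rel = np.exp(rng.uniform(lo, hi, size=spec.n_genes))
    n_inf = spec.n_informative_per_class
    chosen = rng.choice(spec.n_genes, size=n_inf * spec.n_classes, replace=False)
    markers: dict[str, list[str]] = {}
    marker_index: dict[str, np.ndarray] = {}
    for k, cls in enumerate(classes):
        idx = np.sort(chosen[k * n_inf : (k + 1) * n_inf])
        marker_index[cls] = idx
        markers[cls] = [gene_ids[i] for i in idx]
    return _ClassProfiles(
        gene_ids=gene_ids,
        classes=classes,
        relative_expression=rel,
        baseline_total=float(rel.sum()),
        markers=markers,
        marker_index=marker_index,
    )


def _class_mean_profile(profiles: _ClassProfiles, cls: str, lfc: float) -> np.ndarray:
    """Per-gene expected count fractions for one class (unit library size).

    Marker genes of the class have their baseline mean multiplied by
    2**lfc; all other genes keep the class-independent baseline, so
    non-marker marginal means are exactly equal across classes.
    """
    mu = profiles.relative_expression.copy()
    mu[profiles.marker_index[cls]] *= 2.0 ** lfc
    return mu / profiles.baseline_total


def _draw_library_sizes(
    rng: np.random.Generator, n: int, mean: float, cv: float
) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean * cv**2, size=n)


def _sample_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with Var = m + dispersion·m² (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(means)
    r = 1.0 / dispersion
    p = r / (r + means)
    return rng.negative_binomial(r, p)


def generate_cohort(spec: SimulationSpec) -> LabeledDataset:
    """Generate a labeled training cohort of raw counts.

    Returns a :class:`LabeledDataset` whose ``truth`` records the planted
    marker genes per class; ``labels`` carry the (visible) training labels.
    Identical specs produce bit-identical matrices.
    """
    spec.validate()
    profiles = _build_profiles(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _STREAM_TRAIN]))

    sample_ids: list[str] = []
    labels: list[str] = []
    columns: list[np.ndarray] = []
    for cls, n_s in zip(profiles.classes, spec.samples_per_class):
        frac = _class_mean_profile(profiles, cls, spec.log2_fold_change)
        lib = _draw_library_sizes(rng, n_s, spec.library_size_mean, spec.library_size_cv)
        for j in range(n_s):
            counts = _sample_counts(rng, frac * lib[j], spec.dispersion)
            columns.append(counts)
            sample_ids.append(f"{cls}_{j:03d}")
            labels.append(cls)

    matrix = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((spec.n_genes, 0), int),
        index=profiles.gene_ids,
        columns=sample_ids,
        dtype=np.int64,
    )
    label_s = pd.Series(labels, index=sample_ids, name="label")
    truth = CohortTruth(
        markers=profiles.markers,
        labels=label_s.copy(),
        ambiguous=pd.Series(False, index=sample_ids),
    )
    return LabeledDataset(matrix, label_s, truth)


def generate_query_cohort(
    spec: SimulationSpec, truth: CohortTruth | None = None
) -> LabeledDataset:
    """Generate an unlabeled query cohort sharing the spec's class profiles.

    The visible labels are all the missing sentinel; the true generating
    classes live in ``truth``.  A ``spec.mix_fraction`` share of samples is
    drawn from an equal mixture of two distinct class profiles and flagged
    ambiguous.  All expected counts are scaled by ``spec.batch_scale_shift``
    before sampling, emulating a systematic depth difference between cohorts.

    Parameters
    ----------
    truth
        Optional truth record of a previously generated training cohort;
        when given, its marker map is checked against this spec's profiles
        so mismatched specs fail loudly instead of silently diverging.
    """
    spec.validate()
    profiles = _build_profiles(spec)
    if truth is not None and truth.markers != profiles.markers:
        raise ValidationError(
            "query spec does not reproduce the training cohort's class "
            "profiles (marker genes differ); generate both cohorts from "
            "the same spec"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _STREAM_QUERY]))

    class_fracs = {
        cls: _class_mean_profile(profiles, cls, spec.log2_fold_change)
        for cls in profiles.classes
    }
    true_labels: list[str] = []
    n_total = int(sum(spec.samples_per_class))
    for cls, n_s in zip(profiles.classes, spec.samples_per_class):
        true_labels.extend([cls] * n_s)

    n_mix = int(round(spec.mix_fraction * n_total))
    mix_positions = rng.choice(n_total, size=n_mix, replace=False) if n_mix else np.array([], int)
    is_mix = np.zeros(n_total, dtype=bool)
    is_mix[mix_positions] = True

    sample_ids = [f"query_{j:03d}" for j in range(n_total)]
    columns = []
    truth_labels = []
    lib = _draw_library_sizes(rng, n_total, spec.library_size_mean, spec.library_size_cv)
    for j in range(n_total):
        if is_mix[j]:
            a = true_labels[j]
            others = [c for c in profiles.classes if c != a]
            b = others[rng.integers(len(others))]
            frac = 0.5 * (class_fracs[a] + class_fracs[b])
            pair = sorted((a, b))
            truth_labels.append(f"{pair[0]}+{pair[1]}")
        else:
            frac = class_fracs[true_labels[j]]
            truth_labels.append(true_labels[j])
        means = frac * lib[j] * spec.batch_scale_shift
        columns.append(_sample_counts(rng, means, spec.dispersion))

    matrix = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((spec.n_genes, 0), int),
        index=profiles.gene_ids,
        columns=sample_ids,
        dtype=np.int64,
    )
    visible = pd.Series(MISSING_LABEL, index=sample_ids, name="label")
    truth_out = CohortTruth(
        markers=profiles.markers,
        labels=pd.Series(truth_labels, index=sample_ids, name="label"),
        ambiguous=pd.Series(is_mix, index=sample_ids),
    )
    return LabeledDataset(matrix, visible, truth_out)


def query_spec(train_spec: SimulationSpec, **overrides) -> SimulationSpec:
    """Derive a query-cohort spec from a training spec.

    Convenience for the common pattern of reusing the training profiles
    while changing only cohort-level knobs (sample counts, batch shift,
    mixture fraction).  Structural fields (genes, classes, effect size,
    seed) must stay identical for the profiles to be shared.
    """
    structural = {
        "n_classes", "n_genes", "n_informative_per_class", "log2_fold_change",
        "baseline_log_mean_range", "seed", "class_names",
    }
    bad = structural & set(overrides)
    if bad:
        raise ValidationError(
            f"cannot override structural fields in a query spec: {sorted(bad)}"
        )
    return replace(train_spec, **overrides)
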