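"""Synthetic RNA-seq cohort generator.

Emulates the statistical structure of a bulk breast-cancer RNA-seq cohort:
five intrinsic subtypes (Basal, Her2, LumA, LumB, Normal) with strong class
imbalance, ~20k gene features of which a minority are subtype-informative,
negative-binomial (gamma-Poisson) counts with sample-specific library sizes,
molecularly correlated LumA/LumB centroids, and clinical receptor status
(ER/PR/Her2) tied to marker-gene expression (ESR1, PGR, ERBB2) with label
noise.  Every downstream stage of the pipeline is testable against cohorts
drawn from this generator, with full ground truth available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructuralError

#: Canonical subtype order used for class-proportion vectors.
SUBTYPES = ("Basal", "Her2", "LumA", "LumB", "Normal")

#: Row/column order used in confusion-matrix reports.
REPORT_ORDER = ("Her2", "Basal", "LumA", "LumB", "Normal")

#: Receptor -> marker gene whose expression carries the receptor signal.
MARKER_GENES = {"ER": "ESR1", "PR": "PGR", "Her2": "ERBB2"}

#: Default class proportions: 132/65/393/190/105 of 885 samples.
DEFAULT_CLASS_COUNTS = (132, 65, 393, 190, 105)
DEFAULT_PROPORTIONS = tuple(c / 885 for c in DEFAULT_CLASS_COUNTS)

# Dedicated sub-stream indices hung off the cohort seed, so that e.g. the
# receptor-label noise can be re-drawn identically outside simulate_cohort.
_STREAM_COHORT = 0
_STREAM_RECEPTOR = 1


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Scale parameters are on the log2 scale where noted.  The defaults mirror
    the reference cohort the analysis is designed around: 885 samples in
    proportions 132/65/393/190/105 over (Basal, Her2, LumA, LumB, Normal)
    and 20477 gene features with library sizes around five million counted
    reads.
    """

    n_samples: int = 885
    class_proportions: Sequence[float] = DEFAULT_PROPORTIONS
    n_genes: int = 20477
    n_informative: int = 600
    effect_size: float = 0.7            # log2 shift of informative genes
    lumAB_correlation: float = 0.8      # fraction of LumB shifts shared with LumA
    dispersion: float = 0.35            # NB dispersion: var = mu + disp * mu^2
    library_size_mean: float = 5e6
    library_size_cv: float = 0.3
    receptor_noise_rate: float = 0.05   # clinical-label flip probability
    marker_shift: float = 3.0           # log2 marker-gene shift in positive samples
    pr_pos_given_er_pos: float = 0.85
    pr_pos_given_er_neg: float = 0.05
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    informative_activation: float = 0.5  # per-class P(an informative gene shifts)
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"invalid CohortConfig.{name}: {why}")

        if not (isinstance(self.n_samples, (int, np.integer)) and self.n_samples > 0):
            raise bad("n_samples", "must be a positive integer")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (len(SUBTYPES),) or (props < 0).any():
            raise bad("class_proportions",
                      f"must be {len(SUBTYPES)} non-negative reals")
        if abs(props.sum() - 1.0) > 1e-9:
            raise bad("class_proportions", f"must sum to 1, got {props.sum()!r}")
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes >= len(MARKER_GENES)):
            raise bad("n_genes", "must be a positive integer >= number of marker genes")
        if not (0 <= self.n_informative <= self.n_genes - len(MARKER_GENES)):
            raise bad("n_informative",
                      "must satisfy 0 <= n_informative <= n_genes - n_markers")
        if self.effect_size < 0:
            raise bad("effect_size", "must be non-negative")
        if not (0.0 <= self.lumAB_correlation <= 1.0):
            raise bad("lumAB_correlation", "must lie in [0, 1]")
        for name in ("dispersion", "library_size_mean", "library_size_cv",
                     "baseline_log2_sd"):
            if getattr(self, name) <= 0:
                raise bad(name, "must be positive")
        if not (0.0 <= self.receptor_noise_rate <= 0.5):
            raise bad("receptor_noise_rate", "must lie in [0, 0.5]")
        if self.marker_shift < 0:
            raise bad("marker_shift", "must be non-negative")
        for name in ("pr_pos_given_er_pos", "pr_pos_given_er_neg",
                     "informative_activation"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise bad(name, "must lie in [0, 1]")

    def replace(self, **updates) -> "CohortConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(updates)
        return CohortConfig(**current)


@dataclass
class Cohort:
    """A simulated cohort: counts, annotation, and latent ground truth.

    ``counts`` is a genes x samples integer DataFrame; ``annotation`` is
    indexed by sample id with columns ``subtype``, clinical ``ER``/``PR``/
    ``Her2`` labels ("pos"/"neg"), and the hidden truths ``ER_true``/
    ``PR_true``/``Her2_true``.  ``true_centroids`` holds the latent per-class
    log2 mean of every gene (genes x classes) including the expected
    marker-gene contribution, and serves as the reference centroid set for
    unsupervised label transfer.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame
    true_centroids: pd.DataFrame
    informative_genes: list[str]
    config: CohortConfig

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def validate(self) -> None:
        if self.counts.shape[1] != len(self.annotation):
            raise StructuralError("counts/annotation sample dimensions differ")
        for marker in MARKER_GENES.values():
            if marker not in self.counts.index:
                raise StructuralError(f"marker gene {marker!r} missing from cohort")


def allocate_class_counts(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` items over ``proportions``.

    Deterministic: quotas are floored and the leftover units go to the
    largest fractional remainders, ties broken by position.  Always sums
    exactly to ``n``.
    """
    props = np.asarray(proportions, dtype=float)
    quotas = n * props / props.sum()
    base = np.floor(quotas).astype(int)
    shortfall = n - int(base.sum())
    if shortfall > 0:
        remainders = quotas - base
        # stable argsort descending by remainder, ties by index
        order = np.lexsort((np.arange(len(props)), -remainders))
        base[order[:shortfall]] += 1
    return base


def _gene_ids(n_genes: int) -> list[str]:
    ids = list(MARKER_GENES.values())
    ids += [f"G{i:06d}" for i in range(1, n_genes - len(ids) + 1)]
    return ids


def _class_shift_matrix(config: CohortConfig, informative: np.ndarray,
                        n_genes: int, rng: np.random.Generator) -> np.ndarray:
    """Latent log2 shift of every gene in every class (genes x classes).

    Each class activates each informative gene independently with
    probability ``informative_activation`` and a random sign; LumB copies a
    ``lumAB_correlation`` fraction of LumA's per-gene shifts instead of
    drawing its own, which is what makes the two luminal classes hard to
    separate.
    """
    shifts = np.zeros((n_genes, len(SUBTYPES)))
    active = rng.random((len(informative), len(SUBTYPES))) < config.informative_activation
    signs = rng.choice([-1.0, 1.0], size=(len(informative), len(SUBTYPES)))
    per_class = active * signs * config.effect_size
    lum_a = SUBTYPES.index("LumA")
    lum_b = SUBTYPES.index("LumB")
    shared = rng.random(len(informative)) < config.lumAB_correlation
    per_class[shared, lum_b] = per_class[shared, lum_a]
    shifts[informative, :] = per_class
    return shifts


def _draw_true_receptor_status(subtype: np.ndarray, config: CohortConfig,
                               rng: np.random.Generator) -> pd.DataFrame:
    er = np.isin(subtype, ("LumA", "LumB"))
    her2 = subtype == "Her2"
    p_pr = np.where(er, config.pr_pos_given_er_pos, config.pr_pos_given_er_neg)
    pr = rng.random(len(subtype)) < p_pr
    return pd.DataFrame({"ER_true": er, "PR_true": pr, "Her2_true": her2})


def _noisy_labels(truth: pd.DataFrame, noise_rate: float,
                  rng: np.random.Generator) -> pd.DataFrame:
    out = {}
    for receptor in MARKER_GENES:
        true = truth[f"{receptor}_true"].to_numpy()
        flips = rng.random(len(true)) < noise_rate
        observed = np.where(flips, ~true, true)
        out[receptor] = np.where(observed, "pos", "neg")
    return pd.DataFrame(out, index=truth.index)


def simulate_cohort(config: CohortConfig | None = None, **overrides) -> Cohort:
    """Draw a complete synthetic cohort.

    The generative model: subtype labels by deterministic largest-remainder
    apportionment of the class proportions, shuffled by seed; per-gene
    baseline log2 means drawn once from a normal distribution; informative
    genes shifted per class by ``effect_size``; marker genes additionally
    shifted by ``marker_shift`` in receptor-positive samples; counts drawn
    negative-binomial with per-sample mean ``library_size * 2**latent /
    sum(2**latent)`` and a single global dispersion.  Identical configs
    (including seed) give bit-identical cohorts.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = config.replace(**overrides)

    root = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, _STREAM_COHORT])
    rng = np.random.default_rng(root)

    gene_ids = _gene_ids(config.n_genes)
    sample_ids = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    n_markers = len(MARKER_GENES)

    # subtype labels: exact apportionment, then a seeded shuffle
    counts_per_class = allocate_class_counts(config.n_samples, config.class_proportions)
    subtype = np.repeat(np.asarray(SUBTYPES, dtype=object), counts_per_class)
    rng.shuffle(subtype)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          config.n_genes)
    informative = n_markers + rng.choice(config.n_genes - n_markers,
                                         size=config.n_informative, replace=False)
    shifts = _class_shift_matrix(config, informative, config.n_genes, rng)

    truth = _draw_true_receptor_status(subtype, config, rng)
    truth.index = pd.Index(sample_ids, name="sample_id")

    class_idx = np.array([SUBTYPES.index(s) for s in subtype])
    latent = baseline[:, None] + shifts[:, class_idx]   # genes x samples
    for receptor, marker in MARKER_GENES.items():
        row = gene_ids.index(marker)
        latent[row, truth[f"{receptor}_true"].to_numpy()] += config.marker_shift

    library = rng.lognormal(
        mean=np.log(config.library_size_mean)
        - 0.5 * np.log1p(config.library_size_cv ** 2),
        sigma=np.sqrt(np.log1p(config.library_size_cv ** 2)),
        size=config.n_samples,
    )
    rel = np.exp2(latent)
    mu = rel / rel.sum(axis=0, keepdims=True) * library[None, :]
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(np.int64)

    # expected per-class centroid on the latent log2 scale, marker genes
    # included with their expected receptor contribution
    centroids = baseline[:, None] + shifts
    for receptor, marker in MARKER_GENES.items():
        row = gene_ids.index(marker)
        true_col = truth[f"{receptor}_true"].to_numpy()
        for k, cls in enumerate(SUBTYPES):
            mask = subtype == cls
            p_pos = float(true_col[mask].mean()) if mask.any() else 0.0
            centroids[row, k] += config.marker_shift * p_pos

    annotation = pd.DataFrame({"subtype": subtype}, index=truth.index)
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, _STREAM_RECEPTOR]))
    annotation = annotation.join(
        _noisy_labels(truth, config.receptor_noise_rate, noise_rng)).join(truth)

    cohort = Cohort(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                            columns=sample_ids),
        annotation=annotation,
        true_centroids=pd.DataFrame(centroids,
                                    index=pd.Index(gene_ids, name="gene_id"),
                                    columns=list(SUBTYPES)),
        informative_genes=[gene_ids[i] for i in sorted(informative)],
        config=config,
    )
    cohort.validate()
    return cohort


def simulate_receptor_status(cohort: Cohort,
                             config: CohortConfig | None = None) -> pd.DataFrame:
    """Clinical receptor labels for a cohort: truth plus independent flips.

    ER truth is positive exactly for LumA/LumB samples and Her2 truth for
    the Her2 class; PR is positive with a configured probability conditional
    on ER.  Each clinical label is then flipped independently with
    ``receptor_noise_rate``.  The marker-gene expression shifts implied by
    the truth are already present in ``cohort.counts`` (they act on the
    latent means before counts are drawn), so this function only (re)derives
    the label table — deterministically from ``config.seed``, matching what
    ``simulate_cohort`` stored in ``cohort.annotation``.
    """
    if config is None:
        config = cohort.config
    for marker in MARKER_GENES.values():
        if marker not in cohort.counts.index:
            raise StructuralError(f"marker gene {marker!r} absent from cohort")
    truth = cohort.annotation[["ER_true", "PR_true", "Her2_true"]]
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, _STREAM_RECEPTOR]))
    labels = _noisy_labels(truth, config.receptor_noise_rate, rng)
    return labels.join(truth).join(cohort.annotation["subtype"])


def informative_panel(cohort: Cohort, n: int = 50) -> list[str]:
    """A fixed-size panel of subtype-informative genes.

    The synthetic analogue of a curated intrinsic-subtype gene panel
    (PAM50-like): the first ``n`` informative genes in gene order.
    Deterministic for a given cohort.
    """
    if n > len(cohort.informative_genes):
        raise ConfigurationError(
            f"invalid panel size: {n} > {len(cohort.informative_genes)} informative genes")
    return cohort.informative_genes[:n]
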