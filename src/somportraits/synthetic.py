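"""Synthetic transcriptome cohorts with planted modular structure.

The generator emulates the statistical structure the portrayal framework
assumes in a disease cohort with latent molecular subtypes:

* four subtypes with unequal prevalence,
* two antagonistic *main* expression modules (each over-expressed in one main
  subtype and under-expressed in the opposite one),
* two *intermediate* modules, each active in one of the transitional
  subtypes,
* a contamination signature affecting a handful of samples regardless of
  subtype (mimicking, e.g., healthy-tissue admixture in a tumor biopsy),
* i.i.d. Gaussian noise on the log10 scale, and
* subtype-dependent exponential survival with independent censoring.

Raw intensities are emitted as ``10**(baseline + effects + noise)`` so the
data exercise the genuine preprocessing path (quantile normalization, log10,
gene-centering).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, GeneSetCollection, RAW, SurvivalTable

DEFAULT_CLASSES = ("S1", "S2", "S3", "S4")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    ``effects`` maps subtype name → additive shift in log10 units applied to
    the module's genes in samples of that subtype; subtypes not listed get no
    shift. Opposite-signed effects in two subtypes make a module antagonistic.
    """

    name: str
    n_genes: int
    effects: Mapping[str, float]

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError(f"module {self.name!r}: n_genes must be positive")
        for cls, eff in self.effects.items():
            if not math.isfinite(eff):
                raise ValueError(f"module {self.name!r}: non-finite effect for {cls!r}")


@dataclass(frozen=True)
class ContaminationSpec:
    """A signature of ``n_genes`` genes shifted by ``effect`` (log10 units)
    in the samples at ``sample_indices``, independent of subtype."""

    n_genes: int = 60
    sample_indices: tuple[int, ...] = (10, 50, 100)
    effect: float = 1.5


def default_modules(n_genes: int = 2000) -> tuple[ModuleSpec, ...]:
    """Two antagonistic main modules (5% of genes each) and two intermediate
    modules (4% each), the reference layout scaled to the gene count."""
    main = max(int(round(0.05 * n_genes)), 1)
    inter = max(int(round(0.04 * n_genes)), 1)
    return (
        ModuleSpec("main-1", main, {"S1": 1.0, "S4": -1.0}),
        ModuleSpec("main-2", main, {"S1": -1.0, "S4": 1.0}),
        ModuleSpec("intermediate-A", inter, {"S2": 1.0}),
        ModuleSpec("intermediate-B", inter, {"S3": 1.0}),
    )


def default_contamination(n_genes: int = 2000,
                          n_samples: int = 120) -> ContaminationSpec:
    """3% of genes shifted in three samples spread across the cohort."""
    return ContaminationSpec(
        n_genes=max(int(round(0.03 * n_genes)), 1),
        sample_indices=tuple(sorted({n_samples // 12, (5 * n_samples) // 12,
                                     (10 * n_samples) // 12})),
        effect=1.5,
    )


_AUTO = "auto"


@dataclass
class SyntheticConfig:
    """Cohort blueprint; the defaults define the package's reference cohort
    of 2,000 genes × 120 samples with subtype prevalences 28/19/20/33%.

    ``modules`` and ``contamination`` left at ``"auto"`` resolve to the
    reference layout scaled to the configured cohort size; ``contamination``
    may be ``None`` to disable the contamination signature.
    """

    n_genes: int = 2000
    n_samples: int = 120
    class_names: tuple[str, ...] = DEFAULT_CLASSES
    subtype_proportions: tuple[float, ...] = (0.28, 0.19, 0.20, 0.33)
    modules: tuple[ModuleSpec, ...] | str = _AUTO
    contamination: ContaminationSpec | None | str = _AUTO
    noise_sd: float = 0.3
    survival_medians: Mapping[str, float] = field(
        default_factory=lambda: {"S1": 8.0, "S2": 2.5, "S3": 2.5, "S4": 6.0}
    )
    censor_rate: float = 0.3
    baseline_log_range: tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.modules == _AUTO:
            self.modules = default_modules(self.n_genes)
        if self.contamination == _AUTO:
            self.contamination = default_contamination(self.n_genes, self.n_samples)

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        if len(self.subtype_proportions) != len(self.class_names):
            raise ValueError("one proportion per class is required")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if any(p < 0 for p in self.subtype_proportions):
            raise ValueError("subtype proportions must be non-negative")
        if not math.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and non-negative")
        if sum(m.n_genes for m in self.modules) > self.n_genes:
            raise ValueError("module genes exceed n_genes")
        if self.contamination is not None:
            bad = [i for i in self.contamination.sample_indices if not 0 <= i < self.n_samples]
            if bad:
                raise ValueError(f"contamination sample indices out of range: {bad}")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    sample_labels: pd.Series          # sample id -> class name
    gene_modules: pd.Series           # gene id -> module name or "" (background)
    contaminated_samples: list[str]
    class_names: tuple[str, ...]

    def module_gene_ids(self, module: str) -> list[str]:
        return list(self.gene_modules.index[self.gene_modules == module])

    @property
    def module_names(self) -> list[str]:
        names = [m for m in self.gene_modules.unique() if m]
        return sorted(names)


def allocate_class_counts(proportions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder rounding of class proportions to integer counts.

    Ties in the remainders are broken by class order, so the allocation is
    fully deterministic. E.g. proportions (0.28, 0.19, 0.20, 0.33) over 221
    samples give counts (62, 42, 44, 73).
    """
    raw = [p * n for p in proportions]
    counts = [int(math.floor(x)) for x in raw]
    shortfall = n - sum(counts)
    remainders = sorted(
        range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def generate_cohort(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a raw-scale cohort matrix plus its ground truth; seeded."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, config.n_samples

    counts = allocate_class_counts(config.subtype_proportions, m)
    labels = np.repeat(list(config.class_names), counts)
    sample_ids = [f"s{i + 1:03d}" for i in range(m)]
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]

    module_of_gene = np.full(n, "", dtype=object)
    cursor = 0
    for mod in config.modules:
        module_of_gene[cursor:cursor + mod.n_genes] = mod.name
        cursor += mod.n_genes
    contaminated: list[str] = []
    contam_slice = slice(0, 0)
    if config.contamination is not None and config.contamination.n_genes > 0:
        if cursor + config.contamination.n_genes > n:
            raise ValueError("contamination genes exceed n_genes after modules")
        contam_slice = slice(cursor, cursor + config.contamination.n_genes)
        module_of_gene[contam_slice] = "contamination"
        contaminated = [sample_ids[i] for i in config.contamination.sample_indices]

    lo, hi = config.baseline_log_range
    baseline = rng.uniform(lo, hi, size=n)

    exponent = np.tile(baseline[:, None], (1, m))
    cursor = 0
    for mod in config.modules:
        rows = slice(cursor, cursor + mod.n_genes)
        for cls, eff in mod.effects.items():
            exponent[rows, labels == cls] += eff
        cursor += mod.n_genes
    if contaminated:
        for c in config.contamination.sample_indices:
            exponent[contam_slice, c] += config.contamination.effect
    if config.noise_sd > 0:
        exponent += rng.normal(0.0, config.noise_sd, size=(n, m))

    data = pd.DataFrame(10.0 ** exponent, index=gene_ids, columns=sample_ids)
    truth = SyntheticTruth(
        sample_labels=pd.Series(labels, index=sample_ids, name="class"),
        gene_modules=pd.Series(module_of_gene, index=gene_ids, name="module"),
        contaminated_samples=contaminated,
        class_names=tuple(config.class_names),
    )
    return ExpressionMatrix(data, scale=RAW), truth


def generate_gene_sets(
    truth: SyntheticTruth,
    n_random: int,
    seed: int,
    random_set_size: int = 50,
) -> GeneSetCollection:
    """One exact-membership set per planted module plus uniform random sets.

    Set names carry their origin as a prefix (``module:`` / ``random:``); the
    category tag distinguishes planted from random sets, and the
    contamination signature gets its own ``contamination`` category so that
    outlier screening can flag it.
    """
    if n_random < 0:
        raise ValueError("n_random must be non-negative")
    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    all_genes = np.asarray(truth.gene_modules.index)
    for module in truth.module_names:
        category = "contamination" if module == "contamination" else "planted-module"
        collection.add(GeneSet(
            name=f"module:{module}",
            category=category,
            genes=tuple(truth.module_gene_ids(module)),
        ))
    for i in range(n_random):
        members = rng.choice(all_genes, size=random_set_size, replace=False)
        collection.add(GeneSet(
            name=f"random:{i + 1:04d}",
            category="random",
            genes=tuple(members.tolist()),
        ))
    return collection


def generate_survival(truth: SyntheticTruth, config: SyntheticConfig) -> SurvivalTable:
    """Exponential event times with per-class medians and independent censoring.

    Each record is censored with probability ``censor_rate``; a censored
    record reports a uniform time before its (unobserved) event, so censoring
    is non-informative with respect to the event process.
    """
    config.validate()
    medians = config.survival_medians
    missing = [c for c in truth.class_names if c not in medians]
    if missing:
        raise ValueError(f"survival_medians missing classes: {missing}")
    if any(v <= 0 for v in medians.values()):
        raise ValueError("survival medians must be positive")
    rng = np.random.default_rng(config.seed + 1)
    labels = truth.sample_labels
    scales = labels.map(lambda c: medians[c] / math.log(2)).to_numpy(dtype=float)
    event_times = rng.exponential(scales)
    censored = rng.uniform(size=len(labels)) < config.censor_rate
    times = np.where(censored, rng.uniform(0.0, event_times), event_times)
    df = pd.DataFrame({
        "sample_id": labels.index,
        "time": times,
        "event": (~censored).astype(int),
        "group": labels.to_numpy(),
    })
    return SurvivalTable(df)
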