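"""Synthetic cohorts with the statistical structure of TCGA-style inputs.

The generators emulate the features of real somatic-alteration data the
downstream analysis must cope with, without modelling any biology:

* extremely sparse binary mutation matrices with a heavy-tailed
  distribution of per-gene mutation rates and, optionally, groups of
  genes forced to share identical mutation profiles (the perfect
  collinearity seen when two genes are mutated in the same one or two
  patients);
* continuous copy-number matrices with segment structure, where genes
  in the same segment carry exactly (or nearly) the same values;
* gene-set collections with controlled sizes and strict superset/subset
  nesting;
* survival outcomes drawn from a proportional-hazards model with an
  exponential baseline and independent exponential censoring calibrated
  to a target censoring rate.

Every generator is a pure function of its config, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AlterationMatrix, FeatureMatrix, GeneSetCollection, SurvivalData

__all__ = [
    "SpmSimConfig",
    "CnvSimConfig",
    "GeneSetSimConfig",
    "SurvivalSimConfig",
    "generate_spm",
    "generate_cnv",
    "generate_gene_sets",
    "generate_survival",
]


class ConfigError(ValueError):
    """A simulation config violates its invariants."""


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


@dataclass
class SpmSimConfig:
    """Sparse binary somatic point mutation matrix.

    ``sparsity_target`` is the expected fraction of zero entries
    (real cohorts sit near 0.999); per-gene mutation rates are drawn
    from a Beta distribution with mean ``1 - sparsity_target`` and
    concentration ``rate_dispersion``, giving a few recurrently mutated
    genes and a long tail of near-silent ones.  ``n_duplicate_groups``
    groups of ``group_size`` genes are forced to identical rows.
    """

    n_genes: int = 2000
    n_samples: int = 500
    sparsity_target: float = 0.999
    rate_dispersion: float = 0.5
    n_duplicate_groups: int = 0
    group_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sparsity_target < 1):
            raise ConfigError("sparsity_target must be in [0, 1)")
        if self.rate_dispersion <= 0:
            raise ConfigError("rate_dispersion must be positive")
        if self.n_duplicate_groups * self.group_size > self.n_genes:
            raise ConfigError("duplicate groups exceed the number of genes")
        if min(self.n_genes, self.n_samples) < 1:
            raise ConfigError("need at least one gene and one sample")


def generate_spm(config: SpmSimConfig) -> AlterationMatrix:
    """Draw a binary gene-by-sample mutation matrix."""
    rng = np.random.default_rng(config.seed)
    mean_rate = 1.0 - config.sparsity_target
    kappa = config.rate_dispersion
    a, b = mean_rate * kappa, (1.0 - mean_rate) * kappa
    rates = rng.beta(a, b, size=config.n_genes)
    values = (
        rng.uniform(size=(config.n_genes, config.n_samples)) < rates[:, None]
    ).astype(np.int8)
    # duplicate groups occupy the leading genes: rows copied from the leader
    for g in range(config.n_duplicate_groups):
        start = g * config.group_size
        values[start : start + config.group_size] = values[start]
    df = pd.DataFrame(
        values, index=_gene_names(config.n_genes), columns=_sample_names(config.n_samples)
    )
    return AlterationMatrix(df, "binary")


@dataclass
class CnvSimConfig:
    """Segment-structured continuous copy-number matrix.

    Genes are partitioned into ``n_segments`` contiguous blocks; each
    (segment, sample) pair gets one Gaussian segment value shared by all
    genes of the block, plus per-gene noise with standard deviation
    ``noise_sd`` (exact sharing when ``within_segment_identical`` and
    ``noise_sd == 0``), mimicking genes called together in one region.
    """

    n_genes: int = 1000
    n_samples: int = 500
    n_segments: int = 100
    within_segment_identical: bool = True
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments > self.n_genes:
            raise ConfigError("n_segments cannot exceed n_genes")
        if self.n_segments < 1:
            raise ConfigError("need at least one segment")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def segment_assignments(n_genes: int, n_segments: int) -> np.ndarray:
    """Contiguous, near-equal partition of genes into segments."""
    return (np.arange(n_genes) * n_segments) // n_genes


def generate_cnv(config: CnvSimConfig) -> AlterationMatrix:
    """Draw a continuous gene-by-sample copy-number matrix."""
    rng = np.random.default_rng(config.seed)
    seg = segment_assignments(config.n_genes, config.n_segments)
    seg_values = rng.normal(0.0, 1.0, size=(config.n_segments, config.n_samples))
    values = seg_values[seg]
    if not config.within_segment_identical or config.noise_sd > 0:
        sd = config.noise_sd if config.noise_sd > 0 else 0.0
        values = values + rng.normal(0.0, sd, size=values.shape)
    df = pd.DataFrame(
        values, index=_gene_names(config.n_genes), columns=_sample_names(config.n_samples)
    )
    return AlterationMatrix(df, "continuous")


@dataclass
class GeneSetSimConfig:
    """Random gene sets over a fixed universe with optional strict nesting."""

    n_sets: int = 20
    set_size_range: tuple[int, int] = (15, 200)
    n_nested_pairs: int = 0
    gene_universe: list[str] = field(default_factory=lambda: _gene_names(2000))
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if lo < 2 or hi < lo:
            raise ConfigError("set_size_range must satisfy 2 <= min <= max")
        if hi > len(self.gene_universe):
            raise ConfigError("max set size exceeds the gene universe")
        if 2 * self.n_nested_pairs > self.n_sets:
            raise ConfigError("nested pairs need two sets each")


def generate_gene_sets(config: GeneSetSimConfig) -> GeneSetCollection:
    """Draw ``n_sets`` sets; the first ``2*n_nested_pairs`` of them form
    (superset, subset) pairs with the subset a strict subset."""
    rng = np.random.default_rng(config.seed)
    universe = np.asarray(config.gene_universe)
    lo, hi = config.set_size_range
    members: dict[str, frozenset[str]] = {}
    idx = 0
    for _ in range(config.n_nested_pairs):
        size_sup = int(rng.integers(max(lo, 2), hi + 1))
        sup = rng.choice(universe, size=size_sup, replace=False)
        size_sub = int(rng.integers(max(lo - 1, 1), size_sup))  # strictly smaller
        sub = rng.choice(sup, size=size_sub, replace=False)
        members[f"SET{idx + 1:03d}_SUPER"] = frozenset(sup)
        members[f"SET{idx + 2:03d}_SUB"] = frozenset(sub)
        idx += 2
    while idx < config.n_sets:
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=size, replace=False)
        members[f"SET{idx + 1:03d}"] = frozenset(genes)
        idx += 1
    desc = {name: "synthetic gene set" for name in members}
    return GeneSetCollection(members, desc)


@dataclass
class SurvivalSimConfig:
    """Proportional-hazards survival generator.

    Event times are exponential with hazard ``exp(x'beta) / baseline_scale``;
    censoring times are independent exponential with a scale found by
    bisection so the realized event fraction is close to
    ``1 - censoring_rate_target``.
    """

    betas: dict[str, float] = field(default_factory=dict)
    baseline_scale: float = 5.0
    censoring_rate_target: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_scale <= 0:
            raise ConfigError("baseline_scale must be positive")
        if not (0 <= self.censoring_rate_target < 1):
            raise ConfigError("censoring_rate_target must be in [0, 1)")


def generate_survival(features: FeatureMatrix, config: SurvivalSimConfig) -> SurvivalData:
    """Draw right-censored survival outcomes for the samples of ``features``."""
    if features.n_samples == 0:
        raise ConfigError("empty feature matrix")
    unknown = set(config.betas) - set(features.predictor_ids)
    if unknown:
        raise ConfigError(f"beta keys not in feature matrix: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(config.seed)
    n = features.n_samples
    eta = np.zeros(n)
    for name, beta in config.betas.items():
        eta += beta * features.values[name].to_numpy(dtype=float)
    hazard = np.exp(eta) / config.baseline_scale
    event_times = rng.exponential(1.0 / hazard)

    if config.censoring_rate_target == 0:
        time, event = event_times, np.ones(n, dtype=int)
    else:
        cens_uniform = rng.uniform(size=n)

        def realized_censoring(scale: float) -> float:
            cens = -scale * np.log(cens_uniform)
            return float((event_times > cens).mean())

        # bisection on the censoring-time scale against the target rate
        lo, hi = 1e-6, float(np.quantile(event_times, 0.99)) * 100 + 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if realized_censoring(mid) > config.censoring_rate_target:
                lo = mid
            else:
                hi = mid
        scale = 0.5 * (lo + hi)
        cens_times = -scale * np.log(cens_uniform)
        time = np.minimum(event_times, cens_times)
        event = (event_times <= cens_times).astype(int)

    time = np.maximum(time, 1e-9)  # strictly positive
    df = pd.DataFrame({"time": time, "event": event}, index=features.sample_ids)
    return SurvivalData(df)
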