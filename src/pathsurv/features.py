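"""Gene-level and pathway-level predictor construction.

Turns gene-by-sample alteration matrices into the sample-by-predictor
matrices the Cox models consume.  Three single-sample enrichment scores
are provided:

* ``binary_pathway_score`` -- 1 if any member gene of the pathway is
  mutated in the sample, else 0 (binary SPM method);
* ``log_odds_pathway_score`` -- the log odds ratio of the 2x2 table
  cross-classifying all matrix genes by pathway membership and mutation
  status in that sample (log-OR SPM method);
* ``gsva_score`` -- a kernel-CDF + KS-like-random-walk enrichment score
  for continuous (copy-number) data.

Plus gene filters (pathway/census restriction, minimum mutation count,
univariable-Cox screening) and SPM+CNV column concatenation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from .containers import AlterationMatrix, FeatureMatrix, GeneSetCollection, SurvivalData

logger = logging.getLogger(__name__)

__all__ = [
    "GsvaParams",
    "gene_level_features",
    "binary_pathway_score",
    "log_odds_pathway_score",
    "gsva_score",
    "combine_features",
    "filter_genes",
    "filter_by_min_mutations",
    "filter_by_univariable_cox",
]


def gene_level_features(matrix: AlterationMatrix) -> FeatureMatrix:
    """Transpose a gene-by-sample matrix into gene-level predictors."""
    source = "spm" if matrix.flavor == "binary" else "cnv"
    return FeatureMatrix(matrix.values.T.astype(float), level="gene", source=source)


def _membership(sets: GeneSetCollection, genes: list[str]) -> tuple[GeneSetCollection, np.ndarray]:
    """Restrict sets to matrix genes and build a sets-by-genes 0/1 matrix."""
    usable = sets.intersect_universe(genes)
    if len(usable) == 0:
        raise ValueError("no gene set has members in the matrix")
    gene_pos = {g: i for i, g in enumerate(genes)}
    M = np.zeros((len(usable), len(genes)), dtype=np.int64)
    for si, name in enumerate(usable.set_names):
        for g in usable.members[name]:
            M[si, gene_pos[g]] = 1
    return usable, M


def binary_pathway_score(
    spm: AlterationMatrix, sets: GeneSetCollection
) -> FeatureMatrix:
    """Per (pathway, sample): 1 if at least one member gene is mutated."""
    if spm.flavor != "binary":
        raise ValueError("binary pathway score requires a binary matrix")
    usable, M = _membership(sets, spm.gene_ids)
    hits = M @ spm.values.to_numpy(dtype=np.int64)  # sets x samples
    values = (hits > 0).astype(float)
    df = pd.DataFrame(values.T, index=spm.sample_ids, columns=usable.set_names)
    return FeatureMatrix(df, level="pathway", source="spm")


def log_odds_pathway_score(
    spm: AlterationMatrix, sets: GeneSetCollection, correction: float = 0.5
) -> FeatureMatrix:
    """Log odds ratio of pathway membership vs mutation per (pathway, sample).

    For pathway p and sample s the 2x2 table over all matrix genes is

    ====================  ==========  ============
    counts                mutated     not mutated
    ====================  ==========  ============
    in pathway            a           b
    not in pathway        c           d
    ====================  ==========  ============

    and the score is ``log(a*d / (b*c))``.  Whenever any cell is zero
    (the common case in sparse mutation data) the Haldane–Anscombe
    correction adds ``correction`` to all four cells of that table; with
    ``correction=0`` a zero cell raises instead of producing ±inf.
    """
    if spm.flavor != "binary":
        raise ValueError("log-odds pathway score requires a binary matrix")
    if correction < 0:
        raise ValueError("correction must be non-negative")
    usable, M = _membership(sets, spm.gene_ids)
    X = spm.values.to_numpy(dtype=np.int64)  # genes x samples
    n_genes = X.shape[0]
    set_sizes = M.sum(axis=1)  # restricted to matrix genes
    total_mut = X.sum(axis=0)  # per sample

    a = M @ X  # sets x samples: member genes mutated
    b = set_sizes[:, None] - a
    c = total_mut[None, :] - a
    d = (n_genes - set_sizes)[:, None] - c

    cells = np.stack([a, b, c, d]).astype(float)
    has_zero = (cells == 0).any(axis=0)
    if has_zero.any() and correction == 0:
        si, sj = np.argwhere(has_zero)[0]
        raise ValueError(
            f"zero cell in 2x2 table for set {usable.set_names[si]!r}, sample "
            f"{spm.sample_ids[sj]!r}; use a positive correction"
        )
    corrected = cells + np.where(has_zero[None, :, :], correction, 0.0)
    values = np.log(corrected[0] * corrected[3]) - np.log(corrected[1] * corrected[2])
    df = pd.DataFrame(values.T, index=spm.sample_ids, columns=usable.set_names)
    return FeatureMatrix(df, level="pathway", source="spm")


@dataclass
class GsvaParams:
    """Tunables of the GSVA-style enrichment score.

    ``kernel_bandwidth_rule='sd4'`` sets each gene's Gaussian-kernel
    bandwidth to its across-sample standard deviation divided by 4 (the
    reference rule for continuous data).  ``tau`` is the exponent on the
    symmetric rank statistic weighting in-set steps of the random walk.
    ``es_mode``: ``max_deviation_diff`` returns the sum of the largest
    positive and largest negative walk deviations; ``two_sided_max``
    returns the signed deviation of largest magnitude.
    """

    kernel_bandwidth_rule: str = "sd4"
    tau: float = 1.0
    es_mode: str = "max_deviation_diff"

    def __post_init__(self) -> None:
        if self.kernel_bandwidth_rule != "sd4":
            raise ValueError(f"unknown bandwidth rule {self.kernel_bandwidth_rule!r}")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.es_mode not in ("max_deviation_diff", "two_sided_max"):
            raise ValueError(f"unknown es_mode {self.es_mode!r}")


def _kernel_cdf_statistics(X: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF estimate of each entry within its gene row.

    z[i, j] = sum_k Phi((x[i, j] - x[i, k]) / h_i) with h_i = sd_i / 4.
    Constant genes get equal statistics for every sample.
    """
    p, n = X.shape
    sd = X.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1.0)
    z = np.empty_like(X, dtype=float)
    for i in range(p):  # per-gene pairwise differences; O(p * n^2)
        diffs = (X[i][:, None] - X[i][None, :]) / h[i]
        z[i] = ndtr(diffs).sum(axis=1)
    return z


def gsva_score(
    cnv: AlterationMatrix,
    sets: GeneSetCollection,
    params: GsvaParams | None = None,
) -> FeatureMatrix:
    """GSVA-style single-sample enrichment for a continuous matrix.

    Per gene, a Gaussian-kernel CDF estimate across samples gives an
    expression-level statistic; per sample, genes are ranked by it; a
    KS-like random walk down the ranked list (in-set steps weighted by
    the symmetric rank statistic ``|p/2 - rank|`` raised to ``tau``,
    out-of-set steps uniform) yields one enrichment score per
    (set, sample).  Scores are invariant to per-gene shifts because only
    within-gene differences and between-gene ranks enter.
    """
    if cnv.flavor != "continuous":
        raise ValueError("GSVA-style score requires a continuous matrix")
    if cnv.n_samples < 3:
        raise ValueError("GSVA-style score needs at least 3 samples")
    params = params or GsvaParams()
    usable, M = _membership(sets, cnv.gene_ids)
    p = cnv.n_genes
    full = [usable.set_names[i] for i in range(len(usable)) if M[i].sum() >= p]
    if full:
        for name in full:
            logger.warning("gene set %r covers every matrix gene; dropped", name)
        keep = [i for i, n_ in enumerate(usable.set_names) if n_ not in full]
        if not keep:
            raise ValueError("every gene set covers the whole matrix")
        M = M[keep]
        usable = GeneSetCollection(
            {n_: usable.members[n_] for n_ in usable.set_names if n_ not in full},
            usable.descriptions,
        )

    z = _kernel_cdf_statistics(cnv.values.to_numpy(dtype=float))
    n_sets, n_samples = M.shape[0], cnv.n_samples
    scores = np.empty((n_sets, n_samples))
    for j in range(n_samples):
        ranks = rankdata(z[:, j], method="ordinal")  # largest z -> rank p
        r_stat = np.abs(p / 2.0 - ranks) ** params.tau
        order = np.argsort(-ranks, kind="stable")  # walk from top-ranked gene
        r_ord = r_stat[order]
        for s in range(n_sets):
            in_set = M[s, order].astype(bool)
            denom_in = r_ord[in_set].sum()
            m = int(in_set.sum())
            step = np.where(
                in_set,
                r_ord / denom_in if denom_in > 0 else 0.0,
                -1.0 / (p - m),
            )
            walk = np.cumsum(step)
            if params.es_mode == "max_deviation_diff":
                scores[s, j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            else:
                scores[s, j] = walk[np.argmax(np.abs(walk))]
    df = pd.DataFrame(scores.T, index=cnv.sample_ids, columns=usable.set_names)
    return FeatureMatrix(df, level="pathway", source="cnv")


def combine_features(f1: FeatureMatrix, f2: FeatureMatrix) -> FeatureMatrix:
    """Column-concatenate SPM-derived and CNV-derived predictors.

    Predictor ids are prefixed by their origin ("SPM:"/"CNV:") so the
    same gene or pathway can appear once per data type.
    """
    prefix = {"spm": "SPM:", "cnv": "CNV:", "combined": ""}
    shared = [s for s in f1.sample_ids if s in set(f2.sample_ids)]
    if not shared and f2.n_predictors > 0 and f2.n_samples > 0:
        raise ValueError("feature matrices share no samples")
    if f2.n_predictors == 0:
        left = f1.values.rename(columns=lambda c: prefix[f1.source] + c)
        return FeatureMatrix(left, level=f1.level, source="combined")
    left = f1.values.loc[shared].rename(columns=lambda c: prefix[f1.source] + c)
    right = f2.values.loc[shared].rename(columns=lambda c: prefix[f2.source] + c)
    level = f1.level if f1.level == f2.level else "gene"
    return FeatureMatrix(pd.concat([left, right], axis=1), level=level, source="combined")


def filter_genes(matrix: AlterationMatrix, keep) -> AlterationMatrix:
    """Restrict a matrix to ``keep`` ∩ its genes (row order preserved)."""
    return matrix.restrict_genes(keep)


def filter_by_min_mutations(spm: AlterationMatrix, min_count: int) -> AlterationMatrix:
    """Keep genes mutated in strictly more than ``min_count`` samples.

    With ``min_count=2`` this is the recurrence filter that removes the
    near-private mutations responsible for most perfect collinearity.
    """
    if spm.flavor != "binary":
        raise ValueError("minimum-mutation filter requires a binary matrix")
    counts = spm.values.sum(axis=1)
    mask = counts > min_count
    return AlterationMatrix(spm.values.loc[mask], "binary")


def filter_by_univariable_cox(
    matrix: AlterationMatrix,
    survival_train: SurvivalData,
    alpha: float = 0.05,
) -> frozenset[str]:
    """Genes whose univariable Cox Wald p-value is <= ``alpha`` on training data.

    Must only ever see training samples; applying it before a train/test
    split leaks outcome information.  Genes whose fit fails (constant
    rows, separation) are excluded.
    """
    from .models import CoxPH  # local import to avoid a cycle

    shared = [s for s in matrix.sample_ids if s in set(survival_train.sample_ids)]
    if survival_train.subset(shared).n_events == 0:
        raise ValueError("no events in the training data")
    X = matrix.values[shared].T.astype(float)
    y = survival_train.subset(shared)
    kept = []
    for gene in X.columns:
        res = CoxPH(X[[gene]], y).fit()
        pval = res.p_values.get(gene)
        if pval is not None and np.isfinite(pval) and pval <= alpha:
            kept.append(gene)
    return frozenset(kept)
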