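import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from pathsurv.containers import AlterationMatrix, FeatureMatrix, GeneSetCollection
from pathsurv.features import (
    GsvaParams,
    binary_pathway_score,
    combine_features,
    filter_by_min_mutations,
    filter_by_univariable_cox,
    filter_genes,
    gene_level_features,
    gsva_score,
    log_odds_pathway_score,
)
from pathsurv.simulate import SpmSimConfig, SurvivalSimConfig, generate_spm, generate_survival


def naive_log_odds(matrix: AlterationMatrix, sets: GeneSetCollection, correction=0.5):
    """Double-loop counting oracle for the 2x2 log odds ratio."""
    genes = matrix.gene_ids
    out = {}
    for name in sets.set_names:
        members = sets[name] & set(genes)
        if not members:
            continue
        for sample in matrix.sample_ids:
            a = b = c = d = 0
            for g in genes:
                mut = matrix.values.loc[g, sample] == 1
                if g in members:
                    a, b = a + mut, b + (not mut)
                else:
                    c, d = c + mut, d + (not mut)
            cells = [a, b, c, d]
            if 0 in cells:
                cells = [x + correction for x in cells]
            out[(name, sample)] = math.log(cells[0] * cells[3] / (cells[1] * cells[2]))
    return out


def random_instance(seed):
    rng = np.random.default_rng(seed)
    n_genes, n_samples = 20, 10
    df = pd.DataFrame(
        (rng.uniform(size=(n_genes, n_samples)) < 0.2).astype(int),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    matrix = AlterationMatrix(df, "binary")
    members = {}
    for k in range(3):
        size = int(rng.integers(2, 8))
        members[f"P{k}"] = frozenset(rng.choice(matrix.gene_ids, size, replace=False))
    return matrix, GeneSetCollection(members)


class TestLogOddsScore:
    @pytest.mark.parametrize("seed", range(100))
    def test_matches_counting_oracle_exactly(self, seed):
        matrix, sets = random_instance(seed)
        feats = log_odds_pathway_score(matrix, sets)
        oracle = naive_log_odds(matrix, sets)
        for (name, sample), expected in oracle.items():
            assert feats.values.loc[sample, name] == pytest.approx(expected, abs=1e-12)

    def test_balanced_table_is_zero(self):
        # a=b=c=d=1: OR = 1, log-OR = 0
        df = pd.DataFrame(
            [[1, 0], [0, 1], [1, 0], [0, 1]],
            index=["g1", "g2", "g3", "g4"],
            columns=["s1", "s2"],
        )
        m = AlterationMatrix(df, "binary")
        sets = GeneSetCollection({"P": frozenset({"g1", "g2"})})
        f = log_odds_pathway_score(m, sets)
        assert f.values.loc["s1", "P"] == pytest.approx(0.0)

    def test_no_zero_cell_means_no_correction(self):
        # a=2, b=8, c=5, d=85 -> log(2*85/(8*5)) = log(4.25)
        genes = [f"g{i}" for i in range(100)]
        col = np.zeros(100, dtype=int)
        col[:2] = 1       # two member genes mutated
        col[10:15] = 1    # five non-member genes mutated
        df = pd.DataFrame({"s1": col}, index=genes)
        m = AlterationMatrix(df, "binary")
        sets = GeneSetCollection({"P": frozenset(genes[:10])})
        f = log_odds_pathway_score(m, sets)
        assert f.values.loc["s1", "P"] == pytest.approx(math.log(4.25))

    def test_unmutated_sample_uses_corrected_formula(self):
        genes = [f"g{i}" for i in range(10)]
        df = pd.DataFrame({"s1": np.zeros(10, dtype=int)}, index=genes)
        m = AlterationMatrix(df, "binary")
        sets = GeneSetCollection({"P": frozenset(genes[:3])})
        f = log_odds_pathway_score(m, sets)
        # a=0, b=3, c=0, d=7 -> log((.5*7.5)/(3.5*.5))
        assert f.values.loc["s1", "P"] == pytest.approx(math.log((0.5 * 7.5) / (3.5 * 0.5)))

    def test_zero_correction_with_zero_cell_raises(self):
        genes = [f"g{i}" for i in range(10)]
        df = pd.DataFrame({"s1": np.zeros(10, dtype=int)}, index=genes)
        m = AlterationMatrix(df, "binary")
        sets = GeneSetCollection({"P": frozenset(genes[:3])})
        with pytest.raises(ValueError, match="correction"):
            log_odds_pathway_score(m, sets, correction=0.0)


class TestBinaryScore:
    @pytest.mark.parametrize("seed", range(100))
    def test_matches_any_member_mutated_oracle(self, seed):
        matrix, sets = random_instance(seed)
        feats = binary_pathway_score(matrix, sets)
        for name in feats.predictor_ids:
            members = sets[name] & set(matrix.gene_ids)
            for sample in matrix.sample_ids:
                expected = float(
                    any(matrix.values.loc[g, sample] == 1 for g in members)
                )
                assert feats.values.loc[sample, name] == expected

    def test_mutation_free_sample_scores_zero_everywhere(self, toy_sets):
        df = pd.DataFrame(
            [[1, 0], [0, 0], [1, 0]], index=["g1", "g2", "g3"], columns=["s1", "s2"]
        )
        m = AlterationMatrix(df, "binary")
        f = binary_pathway_score(m, toy_sets)
        assert (f.values.loc["s2"] == 0).all()

    def test_universe_pathway_is_one_for_any_mutated_sample(self, toy_spm):
        sets = GeneSetCollection({"ALL": frozenset(toy_spm.gene_ids)})
        f = binary_pathway_score(toy_spm, sets)
        assert (f.values["ALL"] == 1).all()  # every toy sample has >=1 mutation


def naive_gsva(X, set_mask, tau, es_mode):
    """Step-by-step trace of the kernel-CDF + random-walk score."""
    p, n = X.shape
    z = np.zeros((p, n))
    for i in range(p):
        h = np.std(X[i], ddof=1) / 4.0
        for j in range(n):
            z[i, j] = sum(norm.cdf((X[i, j] - X[i, k]) / h) for k in range(n))
    scores = np.zeros(n)
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-z[i, j], i))
        ranks = {gene: p - pos for pos, gene in enumerate(order)}  # largest z -> rank p
        r = {i: abs(p / 2.0 - ranks[i]) ** tau for i in range(p)}
        denom = sum(r[i] for i in range(p) if set_mask[i])
        m = int(np.sum(set_mask))
        walk, level = [], 0.0
        for i in order:
            level += r[i] / denom if set_mask[i] else -1.0 / (p - m)
            walk.append(level)
        walk = np.array(walk)
        if es_mode == "max_deviation_diff":
            scores[j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
        else:
            scores[j] = walk[np.argmax(np.abs(walk))]
    return scores


class TestGsvaScore:
    @staticmethod
    def _matrix(seed=0, p=4, n=3):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.standard_normal((p, n)),
            index=[f"g{i}" for i in range(p)],
            columns=[f"s{j}" for j in range(n)],
        )
        return AlterationMatrix(df, "continuous")

    @pytest.mark.parametrize("es_mode", ["max_deviation_diff", "two_sided_max"])
    def test_matches_hand_executed_trace(self, es_mode):
        m = self._matrix(seed=42, p=4, n=3)
        sets = GeneSetCollection({"P": frozenset({"g0", "g2"})})
        feats = gsva_score(m, sets, GsvaParams(tau=1.0, es_mode=es_mode))
        mask = np.array([True, False, True, False])
        expected = naive_gsva(m.values.to_numpy(), mask, 1.0, es_mode)
        assert np.allclose(feats.values["P"].to_numpy(), expected, atol=1e-10)

    def test_trace_agrees_on_larger_random_instances(self):
        m = self._matrix(seed=7, p=10, n=6)
        sets = GeneSetCollection({"P": frozenset({"g1", "g4", "g7"})})
        feats = gsva_score(m, sets, GsvaParams(tau=1.0))
        mask = np.isin(np.arange(10), [1, 4, 7])
        expected = naive_gsva(m.values.to_numpy(), mask, 1.0, "max_deviation_diff")
        assert np.allclose(feats.values["P"].to_numpy(), expected, atol=1e-10)

    def test_identical_samples_get_identical_scores(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(5)
        df = pd.DataFrame(
            {"s1": col, "s2": col, "s3": rng.standard_normal(5)},
            index=[f"g{i}" for i in range(5)],
        )
        m = AlterationMatrix(df, "continuous")
        sets = GeneSetCollection({"P": frozenset({"g0", "g3"})})
        f = gsva_score(m, sets)
        assert f.values.loc["s1", "P"] == pytest.approx(f.values.loc["s2", "P"])

    def test_per_gene_shift_invariance(self):
        m = self._matrix(seed=3, p=6, n=5)
        sets = GeneSetCollection({"P": frozenset({"g0", "g2", "g4"})})
        base = gsva_score(m, sets)
        shifted = m.values.copy()
        shifted.loc["g2"] += 100.0
        f2 = gsva_score(AlterationMatrix(shifted, "continuous"), sets)
        assert np.allclose(base.values.to_numpy(), f2.values.to_numpy())

    def test_gene_order_permutation_leaves_scores_unchanged(self):
        m = self._matrix(seed=9, p=8, n=5)
        sets = GeneSetCollection({"P": frozenset({"g1", "g5"})})
        base = gsva_score(m, sets)
        perm = m.values.iloc[::-1]
        f2 = gsva_score(AlterationMatrix(perm, "continuous"), sets)
        assert np.allclose(base.values.to_numpy(), f2.values.to_numpy())

    def test_sample_permutation_permutes_scores(self):
        m = self._matrix(seed=11, p=6, n=5)
        sets = GeneSetCollection({"P": frozenset({"g0", "g3"})})
        base = gsva_score(m, sets)
        cols = list(m.values.columns)[::-1]
        f2 = gsva_score(AlterationMatrix(m.values[cols], "continuous"), sets)
        assert np.allclose(
            base.values.loc[cols].to_numpy(), f2.values.to_numpy()
        )

    def test_rejects_binary_input_and_too_few_samples(self, toy_spm):
        sets = GeneSetCollection({"P": frozenset({"g1"})})
        with pytest.raises(ValueError, match="continuous"):
            gsva_score(toy_spm, sets)
        m = self._matrix(seed=2, p=4, n=2)
        with pytest.raises(ValueError, match="3 samples"):
            gsva_score(m, sets)

    def test_whole_matrix_set_dropped(self):
        m = self._matrix(seed=5, p=4, n=4)
        sets = GeneSetCollection(
            {"ALL": frozenset(m.gene_ids), "OK": frozenset({"g0", "g1"})}
        )
        f = gsva_score(m, sets)
        assert f.predictor_ids == ["OK"]


class TestCombineAndFilters:
    def test_combine_concatenates_with_prefixes(self):
        idx = [f"s{i}" for i in range(10)]
        f1 = FeatureMatrix(
            pd.DataFrame(np.ones((10, 5)), index=idx,
                         columns=[f"a{i}" for i in range(5)]), "gene", "spm")
        f2 = FeatureMatrix(
            pd.DataFrame(np.zeros((10, 7)), index=idx,
                         columns=[f"b{i}" for i in range(7)]), "gene", "cnv")
        combined = combine_features(f1, f2)
        assert combined.values.shape == (10, 12)
        assert combined.predictor_ids[0] == "SPM:a0"
        assert combined.predictor_ids[-1] == "CNV:b6"
        assert combined.source == "combined"

    def test_same_name_kept_under_both_prefixes(self):
        idx = ["s1", "s2"]
        f1 = FeatureMatrix(pd.DataFrame({"g": [1.0, 0.0]}, index=idx), "gene", "spm")
        f2 = FeatureMatrix(pd.DataFrame({"g": [0.2, 0.3]}, index=idx), "gene", "cnv")
        combined = combine_features(f1, f2)
        assert set(combined.predictor_ids) == {"SPM:g", "CNV:g"}

    def test_disjoint_samples_error(self):
        f1 = FeatureMatrix(pd.DataFrame({"a": [1.0]}, index=["s1"]), "gene", "spm")
        f2 = FeatureMatrix(pd.DataFrame({"b": [1.0]}, index=["s2"]), "gene", "cnv")
        with pytest.raises(ValueError, match="share no samples"):
            combine_features(f1, f2)

    def test_filter_genes_identity_and_empty(self, toy_spm):
        assert filter_genes(toy_spm, set(toy_spm.gene_ids)) == toy_spm
        with pytest.raises(Exception):
            filter_genes(toy_spm, {"nothing"})

    def test_min_mutation_filter_is_strict(self):
        df = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 1, 0], [0, 0, 0, 0]],
            index=["twice", "thrice", "never"],
            columns=[f"s{j}" for j in range(4)],
        )
        m = AlterationMatrix(df, "binary")
        kept = filter_by_min_mutations(m, 2)
        assert kept.gene_ids == ["thrice"]  # "more than 2" excludes exactly 2
        kept0 = filter_by_min_mutations(m, 0)
        assert kept0.gene_ids == ["twice", "thrice"]
        assert filter_by_min_mutations(m, 10).n_genes == 0

    def test_univariable_cox_filter_finds_signal_and_drops_constants(self):
        spm = generate_spm(SpmSimConfig(n_genes=6, n_samples=400,
                                        sparsity_target=0.6, seed=20))
        feats = gene_level_features(spm)
        y = generate_survival(
            feats,
            SurvivalSimConfig(betas={spm.gene_ids[0]: 2.0},
                              censoring_rate_target=0.2, seed=21),
        )
        frozen = spm.values.copy()
        frozen.iloc[1] = 0  # constant gene: unfittable, must be excluded
        m = AlterationMatrix(frozen, "binary")
        kept = filter_by_univariable_cox(m, y, alpha=0.05)
        assert spm.gene_ids[0] in kept
        assert spm.gene_ids[1] not in kept
        everything = filter_by_univariable_cox(m, y, alpha=1.0)
        assert spm.gene_ids[1] not in everything  # still unfittable
        assert len(everything) >= len(kept)
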