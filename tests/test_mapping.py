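import numpy as np
import pandas as pd
import pytest

import spatialmap as sm
from spatialmap.datasets_io import SCDataset, SpatialDataset
from spatialmap.glsm import GLSMFit
from spatialmap.mapping import (EmptyReferenceError, MappingError,
                                ReferenceGene, assign_pixels,
                                build_reference_set, cell_type_centers,
                                predict_gene, select_reference_gene)


def _sc(counts, types, genes=None):
    counts = np.asarray(counts)
    return SCDataset(counts=counts,
                     cell_ids=[f"c{i}" for i in range(counts.shape[0])],
                     gene_names=genes or [f"g{j}" for j in
                                          range(counts.shape[1])],
                     cell_types=types)


class TestCenters:
    def test_single_cell_type_center_is_its_profile(self):
        sc = _sc([[1, 2, 3], [4, 5, 6]], ["a", "b"])
        centers = cell_type_centers(sc, normalization="raw")
        assert centers.matrix[0].tolist() == [1, 2, 3]
        assert centers.matrix[1].tolist() == [4, 5, 6]
        assert centers.types == ["a", "b"]

    def test_raw_center_is_arithmetic_mean(self):
        sc = _sc([[2, 0], [4, 0]], ["t", "t"])
        centers = cell_type_centers(sc, normalization="raw")
        assert centers.matrix[0, 0] == 3.0

    def test_matches_groupby_mean_oracle(self, rng):
        counts = rng.poisson(4.0, size=(50, 12)) + 1
        labels = list(rng.choice([f"t{i}" for i in range(5)], size=50))
        sc = _sc(counts, labels)
        centers = cell_type_centers(sc, normalization="lognorm")
        expr = sm.lognormalize(counts)
        oracle = pd.DataFrame(expr).groupby(np.array(labels)).mean()
        assert np.allclose(centers.matrix,
                           oracle.loc[centers.types].to_numpy())

    def test_requested_missing_type_errors(self):
        sc = _sc([[1]], ["a"], genes=["g"])
        with pytest.raises(MappingError, match="ghost"):
            cell_type_centers(sc, types=["a", "ghost"])


def _spatial(counts, genes):
    counts = np.asarray(counts)
    n = counts.shape[0]
    return SpatialDataset(counts=counts,
                          coords=np.c_[np.arange(n), np.zeros(n)],
                          pixel_ids=[f"p{i}" for i in range(n)],
                          gene_names=genes)


class TestAssignPixels:
    def test_scaled_profile_gets_correlation_one(self):
        sc = _sc([[1, 2, 3, 4], [4, 3, 2, 1]], ["up", "down"])
        centers = cell_type_centers(sc, normalization="raw")
        spatial = _spatial([[2, 4, 6, 8], [8, 6, 4, 2]], sc.gene_names)
        asg = assign_pixels(spatial, centers, sc.gene_names)
        assert asg.types == ["up", "down"]
        assert np.allclose(asg.correlations, 1.0)

    def test_single_anticorrelated_center_still_assigned(self):
        sc = _sc([[1, 2, 3]], ["only"])
        centers = cell_type_centers(sc, normalization="raw")
        spatial = _spatial([[3, 2, 1], [3, 2, 1]], sc.gene_names)
        asg = assign_pixels(spatial, centers, sc.gene_names)
        assert asg.types == ["only", "only"]
        assert np.allclose(asg.correlations, -1.0)

    def test_matches_brute_force_loop(self, rng):
        from scipy.stats import pearsonr
        counts = rng.poisson(5.0, size=(20, 8)) + 1
        labels = ["a"] * 4 + ["b"] * 3 + ["c"] * 5
        sc = _sc(rng.poisson(5.0, size=(12, 8)) + 1, labels)
        centers = cell_type_centers(sc, normalization="raw")
        spatial = _spatial(counts, sc.gene_names)
        asg = assign_pixels(spatial, centers, sc.gene_names)
        for i in range(20):
            rs = [pearsonr(counts[i], centers.matrix[t]).statistic
                  for t in range(3)]
            assert asg.types[i] == centers.types[int(np.argmax(rs))]
            assert asg.correlations[i] == pytest.approx(max(rs))

    def test_invariant_to_pixel_rescaling(self, rng):
        counts = rng.poisson(5.0, size=(10, 6)) + 1
        sc = _sc(rng.poisson(5.0, size=(8, 6)) + 1, ["a"] * 4 + ["b"] * 4)
        centers = cell_type_centers(sc)  # lognorm: depth-normalised
        a1 = assign_pixels(_spatial(counts, sc.gene_names), centers,
                           sc.gene_names)
        a2 = assign_pixels(_spatial(counts * 7, sc.gene_names), centers,
                           sc.gene_names)
        assert a1.types == a2.types
        assert np.allclose(a1.correlations, a2.correlations)

    def test_constant_pixel_gets_most_common_type(self):
        sc = _sc([[1, 2, 3], [3, 2, 1]], ["a", "b"])
        centers = cell_type_centers(sc, normalization="raw")
        spatial = _spatial([[1, 2, 3], [2, 4, 6], [5, 5, 5]], sc.gene_names)
        with pytest.warns(UserWarning, match="constant"):
            asg = assign_pixels(spatial, centers, sc.gene_names)
        assert asg.types[:2] == ["a", "a"]
        assert asg.types[2] == "a"  # the most common assigned type


@pytest.fixture(scope="module")
def strong_pipeline():
    """Paired data with clear signal, plus fitted pieces reused by tests."""
    cfg = sm.EffectConfig(beta=2.0, null_fraction=0.3, plant_duplicate=True)
    paired, truths = sm.simulate_paired_datasets(
        n_pixels=300, n_genes=20, n_cells=300, n_types=4,
        effect_config=cfg, seed=3)
    centers = cell_type_centers(paired.sc)
    assignment = assign_pixels(paired.spatial, centers, paired.shared_genes)
    kernel = sm.kernel_from_spec(paired.spatial.coords, ("car", 0.5))
    refset = build_reference_set(paired, assignment, kernel, p_cut=1.0)
    return paired, truths, centers, assignment, kernel, refset


class TestReferenceSet:
    def test_vacuous_cut_keeps_every_fitted_gene(self, strong_pipeline):
        paired, _, _, _, _, refset = strong_pipeline
        assert set(refset.genes) | set(refset.failed) == set(
            paired.shared_genes)

    def test_strong_gene_passes_the_default_cut(self, strong_pipeline):
        paired, truths, centers, assignment, kernel, _ = strong_pipeline
        strict = build_reference_set(paired, assignment, kernel, p_cut=0.05)
        signal_genes = {g for g, t in truths.items() if t.role == "signal"}
        assert signal_genes & set(strict.genes)
        # every retained p-value honours the cut
        assert all(r.p_value < 0.05 for r in strict.entries)

    def test_impossible_cut_raises_empty_reference(self, strong_pipeline):
        paired, truths, centers, assignment, kernel, _ = strong_pipeline
        null_only = [g for g, t in truths.items() if t.role == "null"]
        sub = sm.PairedData(spatial=paired.spatial, sc=paired.sc,
                            shared_genes=sorted(null_only))
        with pytest.raises(EmptyReferenceError, match="looser"):
            build_reference_set(sub, assignment, kernel, p_cut=1e-9)


class TestSelectReference:
    def test_planted_duplicate_has_correlation_one(self, strong_pipeline):
        paired, _, _, _, _, refset = strong_pipeline
        genes = paired.sc.gene_names
        dup_a, dup_b = genes[-2], genes[-1]  # identical scRNA-seq columns
        if dup_a not in refset.genes:
            pytest.skip("duplicate gene did not fit")
        ref, corr = select_reference_gene(dup_b, refset, paired.sc)
        assert ref == dup_a
        assert corr == pytest.approx(1.0)

    def test_planted_correlate_wins_over_noise(self, rng):
        m = 200
        base = rng.poisson(10.0, size=m)
        noise = rng.poisson(10.0, size=(m, 4))
        planted = base + rng.poisson(1.0, size=m)  # r ~ 0.9 with base
        counts = np.column_stack([base, planted, noise])
        sc = _sc(counts, ["t"] * m,
                 genes=["target", "planted", "n1", "n2", "n3", "n4"])
        fake_fit = GLSMFit(0, 0, 0, 0, np.zeros(2), np.zeros(2), 1, 0.01, 1,
                           True)
        refset = sm.ReferenceSet(
            entries=[ReferenceGene(g, fake_fit, 0.01)
                     for g in ["planted", "n1", "n2", "n3", "n4"]],
            p_cut=0.05)
        ref, corr = select_reference_gene("target", refset, sc)
        assert ref == "planted"
        assert corr > 0.5

    def test_tie_breaks_lexicographically(self, rng):
        m = 50
        col = rng.poisson(5.0, size=m) + 1
        counts = np.column_stack([col, col, col])
        sc = _sc(counts, ["t"] * m, genes=["target", "zz", "aa"])
        fake_fit = GLSMFit(0, 0, 0, 0, np.zeros(2), np.zeros(2), 1, 0.01, 1,
                           True)
        refset = sm.ReferenceSet(
            entries=[ReferenceGene(g, fake_fit, 0.01) for g in ["zz", "aa"]],
            p_cut=0.05)
        ref, corr = select_reference_gene("target", refset, sc,
                                          normalization="raw")
        assert ref == "aa"
        assert corr == pytest.approx(1.0)
        # reordering the non-selected candidates never changes the answer
        refset2 = sm.ReferenceSet(
            entries=[ReferenceGene(g, fake_fit, 0.01) for g in ["aa", "zz"]],
            p_cut=0.05)
        assert select_reference_gene("target", refset2, sc,
                                     normalization="raw")[0] == "aa"

    def test_constant_target_rejected(self):
        sc = _sc(np.column_stack([np.full(10, 3), np.arange(10)]),
                 ["t"] * 10, genes=["flat", "ref"])
        fake_fit = GLSMFit(0, 0, 0, 0, np.zeros(2), np.zeros(2), 1, 0.01, 1,
                           True)
        refset = sm.ReferenceSet(entries=[ReferenceGene("ref", fake_fit, 0.01)],
                                 p_cut=0.05)
        with pytest.raises(MappingError, match="constant"):
            select_reference_gene("flat", refset, sc, normalization="raw")


class TestPredict:
    def test_intercept_only_collapse(self, strong_pipeline):
        paired, _, centers, assignment, _, refset = strong_pipeline
        n = paired.spatial.n_pixels
        flat = ReferenceGene("flat", GLSMFit(
            alpha_hat=-2.0, beta_hat=0.0, sigma2_hat=0.0, h2_hat=0.0,
            g_blup=np.zeros(n), e_blup=np.zeros(n), beta_se=1.0, p_value=1.0,
            n_iterations=1, converged=True), 1.0)
        pred = predict_gene(paired.shared_genes[0], flat, centers, assignment,
                            paired.spatial.size_factors)
        assert np.allclose(pred.lambda_hat, np.exp(-2.0))

    def test_self_prediction_recovers_observed_pattern(self):
        ds, truth = sm.simulate_glsm_counts(
            n=300, params=sm.GLSMParams(alpha=-4, beta=1.0, sigma2=1.0,
                                        h2=0.8),
            kernel=("gaussian", 2.0), seed=8)
        K = sm.kernel_from_spec(ds.coords, ("gaussian", 2.0))
        fit = sm.fit_glsm(sm.GLSMSpec(y=ds.counts[:, 0],
                                      offset=ds.size_factors, x=truth.x, K=K))
        lam = np.exp(fit.alpha_hat + truth.x * fit.beta_hat
                     + fit.g_blup + fit.e_blup)
        r = np.corrcoef(ds.counts[:, 0], ds.size_factors * lam)[0, 1]
        assert r > 0.9

    def test_sampling_is_deterministic_under_seed(self, strong_pipeline):
        paired, _, centers, assignment, _, refset = strong_pipeline
        gene = refset.genes[0]
        kw = dict(centers=centers, assignment=assignment,
                  size_factors=paired.spatial.size_factors, mode="sample")
        p1 = predict_gene(gene, refset.entries[0], seed=7, **kw)
        p2 = predict_gene(gene, refset.entries[0], seed=7, **kw)
        p3 = predict_gene(gene, refset.entries[0], seed=8, **kw)
        assert np.array_equal(p1.sampled_counts, p2.sampled_counts)
        assert not np.array_equal(p1.sampled_counts, p3.sampled_counts)

    def test_missing_target_errors(self, strong_pipeline):
        paired, _, centers, assignment, _, refset = strong_pipeline
        with pytest.raises(MappingError):
            predict_gene("no_such_gene", refset.entries[0], centers,
                         assignment, paired.spatial.size_factors)


def test_null_admission_rate_is_near_nominal():
    """With beta = 0 everywhere, ~5% of genes should pass p < 0.05."""
    cfg = sm.EffectConfig(null_fraction=1.0, h2_null=0.0)
    paired, truths = sm.simulate_paired_datasets(
        n_pixels=150, n_genes=200, n_cells=300, n_types=4,
        effect_config=cfg, seed=21)
    centers = cell_type_centers(paired.sc)
    assignment = assign_pixels(paired.spatial, centers, paired.shared_genes)
    kernel = sm.kernel_from_spec(paired.spatial.coords, ("car", 0.5))
    refset = build_reference_set(paired, assignment, kernel, p_cut=0.05)
    rate = len(refset.genes) / (200 - len(refset.failed))
    assert 0.01 <= rate <= 0.10
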