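"""Validation machinery: leave-n-genes-out CV, downsampling, kernel sweeps.

Cross-validation treats the genes shared by the two modalities as ground
truth: a seeded subset of shared genes is held out, the reference set is
fitted on the remainder only (held-out spatial counts never enter the
fitting -- the training subset even recomputes its size factors from
training genes alone), each held-out gene is predicted from its most
correlated reference, and the prediction is scored by the Pearson
correlation between observed and predicted counts (a log1p-scale option is
available).  Genes that cannot be scored (constant observed counts, no
usable reference) are recorded and excluded from the summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .datasets_io import PairedData
from .glsm import GLSMControl, GLSMError, GLSMSpec, fit_glsm
from .kernels import kernel_from_spec
from .mapping import (EmptyReferenceError, MappingError, ReferenceGene,
                      ReferenceSet, assign_pixels, build_reference_set,
                      cell_type_centers, loo_covariate, predict_gene,
                      select_reference_gene)


class EvaluationError(ValueError):
    """Invalid evaluation setup."""


def pearson(a, b) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise EvaluationError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise EvaluationError("correlation undefined for a constant input")
    return float(scipy.stats.pearsonr(a, b).statistic)


@dataclass
class CVResult:
    """Per-held-out-gene scores plus summary statistics."""

    table: pd.DataFrame  # gene, pearson, reference_gene, reference_corr, status
    summary: dict
    test_genes: list[str] = field(default_factory=list)
    train_genes: list[str] = field(default_factory=list)
    reference_set: ReferenceSet = None  # kept for reuse/diagnostics

    @staticmethod
    def summarize(table: pd.DataFrame) -> dict:
        scored = table.loc[table["status"] == "ok", "pearson"]
        n = int(scored.size)
        return {
            "mean": float(scored.mean()) if n else float("nan"),
            "min": float(scored.min()) if n else float("nan"),
            "max": float(scored.max()) if n else float("nan"),
            "se": float(scored.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
            "n_scored": n,
            "n_excluded": int((table["status"] != "ok").sum()),
        }


def _score_predictions(paired, test_genes, refset, centers, assignment,
                       size_factors, normalization, scale) -> pd.DataFrame:
    rows = []
    for gene in test_genes:
        try:
            ref_gene, ref_corr = select_reference_gene(
                gene, refset, paired.sc, normalization)
            pred = predict_gene(gene, refset.get(ref_gene), centers,
                                assignment, size_factors,
                                reference_corr=ref_corr)
            observed = paired.spatial.gene_counts(gene).astype(float)
            predicted = pred.predicted_counts
            if scale == "log1p":
                observed, predicted = np.log1p(observed), np.log1p(predicted)
            r = pearson(observed, predicted)
            rows.append((gene, r, ref_gene, ref_corr, "ok"))
        except (MappingError, EmptyReferenceError, EvaluationError, KeyError) as exc:
            rows.append((gene, np.nan, "", np.nan, f"excluded: {exc}"))
    return pd.DataFrame(
        rows, columns=["gene", "pearson", "reference_gene",
                       "reference_corr", "status"])


def run_cv(paired: PairedData, test_genes, train_genes,
           kernel, p_cut: float = 0.05, normalization: str = "lognorm",
           scale: str = "counts", control: GLSMControl | None = None,
           knn: int = 4) -> CVResult:
    """Score held-out genes given an explicit train/test gene split.

    The reference set (and the pixel-to-type assignment feeding its
    covariates, and the training size factors) is computed from the training
    genes only.
    """
    test_genes = sorted(test_genes)
    train_genes = sorted(train_genes)
    if set(test_genes) & set(train_genes):
        raise EvaluationError("train and test gene sets overlap")
    centers = cell_type_centers(paired.sc, normalization)
    if not test_genes:
        table = _score_predictions(paired, [], None, centers, None, None,
                                   normalization, scale)
        return CVResult(table=table, summary=CVResult.summarize(table),
                        test_genes=[], train_genes=train_genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-pixel drops on tiny subsets
        train_spatial = paired.spatial.subset_genes(train_genes)
    train_paired = PairedData(spatial=train_spatial, sc=paired.sc,
                              shared_genes=train_genes)
    K = kernel_from_spec(train_spatial.coords, kernel, knn=knn)
    assignment = assign_pixels(train_spatial, centers, train_genes)
    refset = build_reference_set(train_paired, assignment, K,
                                 p_cut=p_cut, control=control)
    table = _score_predictions(paired, test_genes, refset, centers,
                               assignment, train_spatial.size_factors,
                               normalization, scale)
    return CVResult(table=table, summary=CVResult.summarize(table),
                    test_genes=test_genes, train_genes=train_genes,
                    reference_set=refset)


def leave_n_genes_out(paired: PairedData, n_test: int, kernel,
                      seed: int, **kwargs) -> CVResult:
    """Hold out ``n_test`` seeded random shared genes and score them."""
    shared = sorted(paired.shared_genes)
    if n_test >= len(shared):
        raise EvaluationError("n_test must be below the number of shared genes")
    rng = np.random.default_rng(seed)
    test = sorted(rng.choice(shared, size=n_test, replace=False).tolist())
    train = [g for g in shared if g not in set(test)]
    return run_cv(paired, test, train, kernel, **kwargs)


def permuted_reference_cv(paired: PairedData, cv: CVResult, seed: int,
                          normalization: str = "lognorm",
                          scale: str = "counts") -> CVResult:
    """Null pipeline: rescore the same test genes with permuted references.

    The selected reference genes are shuffled among the targets (reusing the
    already fitted reference set), destroying the target-reference match
    while keeping everything else identical.
    """
    if cv.reference_set is None:
        raise EvaluationError("cv result carries no reference set")
    rng = np.random.default_rng(seed)
    scored = cv.table[cv.table["status"] == "ok"]
    genes = scored["gene"].tolist()
    refs = scored["reference_gene"].tolist()
    permuted = [refs[i] for i in rng.permutation(len(refs))]
    centers = cell_type_centers(paired.sc, normalization)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train_spatial = paired.spatial.subset_genes(cv.train_genes)
    assignment = assign_pixels(train_spatial, centers, cv.train_genes)
    rows = []
    for gene, ref_gene in zip(genes, permuted):
        try:
            pred = predict_gene(gene, cv.reference_set.get(ref_gene), centers,
                                assignment, train_spatial.size_factors)
            observed = paired.spatial.gene_counts(gene).astype(float)
            predicted = pred.predicted_counts
            if scale == "log1p":
                observed, predicted = np.log1p(observed), np.log1p(predicted)
            rows.append((gene, pearson(observed, predicted), ref_gene,
                         np.nan, "ok"))
        except (MappingError, EvaluationError, KeyError) as exc:
            rows.append((gene, np.nan, ref_gene, np.nan, f"excluded: {exc}"))
    table = pd.DataFrame(rows, columns=["gene", "pearson", "reference_gene",
                                        "reference_corr", "status"])
    return CVResult(table=table, summary=CVResult.summarize(table),
                    test_genes=genes, train_genes=cv.train_genes,
                    reference_set=cv.reference_set)


def downsampling_experiment(paired: PairedData, n_test: int, train_sizes,
                            kernel, seed: int, p_cut: float = 0.05,
                            normalization: str = "lognorm",
                            scale: str = "counts",
                            control: GLSMControl | None = None,
                            knn: int = 4) -> pd.DataFrame:
    """Refit on nested seeded subsamples of the training genes.

    One test split is fixed; training subsets are nested prefixes of a single
    seeded permutation of the training pool, so the candidate reference set
    only grows with ``train_size`` (each gene's fit depends only on that
    gene, so per-gene fits are computed once and cached).  The pixel
    assignment is computed once from the full pool.  Returns a table of
    (train_size, mean_pearson, mean_reference_corr, n_excluded).
    """
    shared = sorted(paired.shared_genes)
    rng = np.random.default_rng(seed)
    test = sorted(rng.choice(shared, size=n_test, replace=False).tolist())
    pool = [g for g in shared if g not in set(test)]
    train_sizes = list(train_sizes)
    if max(train_sizes) > len(pool):
        raise EvaluationError(
            f"train_size {max(train_sizes)} exceeds the pool of {len(pool)}")
    order = [pool[i] for i in rng.permutation(len(pool))]

    centers = cell_type_centers(paired.sc, normalization)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pool_spatial = paired.spatial.subset_genes(pool)
    K = kernel_from_spec(pool_spatial.coords, kernel, knn=knn)
    assignment = assign_pixels(pool_spatial, centers, pool)

    fit_cache: dict[str, ReferenceGene] = {}

    def fitted(gene):
        if gene not in fit_cache:
            y = pool_spatial.gene_counts(gene)
            try:
                x = loo_covariate(pool_spatial, centers, pool, gene)
                fit = fit_glsm(GLSMSpec(y=y, offset=pool_spatial.size_factors,
                                        x=x, K=K), control)
                fit_cache[gene] = ReferenceGene(gene, fit, fit.p_value)
            except (GLSMError, MappingError) as exc:
                fit_cache[gene] = exc
        return fit_cache[gene]

    out = []
    for size in sorted(train_sizes):
        subset = sorted(order[:size])
        entries = []
        for g in subset:
            r = fitted(g)
            if isinstance(r, ReferenceGene) and r.p_value < p_cut:
                entries.append(r)
        if not entries:
            out.append((size, np.nan, np.nan, n_test))
            continue
        refset = ReferenceSet(entries=entries, p_cut=p_cut)
        table = _score_predictions(paired, test, refset, centers, assignment,
                                   pool_spatial.size_factors, normalization,
                                   scale)
        ok = table[table["status"] == "ok"]
        out.append((size, float(ok["pearson"].mean()),
                    float(ok["reference_corr"].mean()),
                    int((table["status"] != "ok").sum())))
    return pd.DataFrame(out, columns=["train_size", "mean_pearson",
                                      "mean_reference_corr", "n_excluded"])


def kernel_sensitivity(paired: PairedData, n_test: int, kernel_grid,
                       seed: int, **kwargs) -> pd.DataFrame:
    """Rerun the same CV split under each kernel configuration.

    ``kernel_grid`` is a sequence of ``("car", alpha_s)`` /
    ``("gaussian", bandwidth)`` pairs (e.g. CAR alpha_s over 0.1..0.9 and
    the default Gaussian bandwidth sweep).  A configuration that fails is
    recorded as failed and the sweep continues.
    """
    kernel_grid = list(kernel_grid)
    if not kernel_grid:
        raise EvaluationError("kernel grid is empty")
    rows = []
    for kind, param in kernel_grid:
        try:
            cv = leave_n_genes_out(paired, n_test, (kind, param), seed,
                                   **kwargs)
            rows.append((kind, float(param), cv.summary["mean"], "ok"))
        except Exception as exc:  # any single config may fail; keep sweeping
            rows.append((kind, float(param), np.nan, f"failed: {exc}"))
    return pd.DataFrame(rows, columns=["kernel", "parameter",
                                       "mean_pearson", "status"])
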