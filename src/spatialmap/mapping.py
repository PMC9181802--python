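"""Integration layer: cell-type centers, pixel assignment, reference genes,
and prediction of unmeasured genes.

The scRNA-seq side supplies, for every cell type, a "center": the average
expression profile over the cells of that type.  Each spatial pixel is
assigned the center most Pearson-correlated with its expression profile over
the shared genes; the assigned center's expression of a gene then serves as
the per-pixel covariate x_i of the spatial model.

Shared genes whose fitted covariate effect is significant (p < 0.05 by
default) form the *reference set*.  An unmeasured target gene borrows the
fitted parameters of the reference gene most correlated with it across cells
in scRNA-seq space, and its spatial rate is predicted as

    lambda_hat_i = exp(alpha_hat + x_i^(un) beta_hat + g_hat_i + e_hat_i)

with x^(un) the assigned-center expression of the target gene.  The fitted
g_hat and e_hat of the reference are reused as printed in that formula; no
fresh nugget is drawn in the deterministic "mean" mode, and "sample" mode
additionally draws Poisson counts under an explicit seed.

By default centers (and all correlation computations) use depth-normalised
counts-per-10k, log1p-transformed: the covariate enters a log-scale linear
predictor, so a log-scale summary of scRNA-seq expression is the natural
choice.  ``normalization="raw"`` retains plain mean counts.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .datasets_io import PairedData, SCDataset, SpatialDataset
from .glsm import GLSMControl, GLSMFit, GLSMSpec, GLSMError, fit_glsm
from .kernels import KernelMatrix


class MappingError(ValueError):
    """Invalid integration inputs."""


class EmptyReferenceError(MappingError):
    """No gene passed the significance cut."""


def lognormalize(counts, size_factors=None, scale: float = 1e4) -> np.ndarray:
    """log1p of counts per ``scale`` total (rows are observations)."""
    counts = np.asarray(counts, dtype=float)
    sf = counts.sum(axis=1) if size_factors is None else np.asarray(size_factors, float)
    sf = np.where(sf <= 0, 1.0, sf)
    return np.log1p(counts / sf[:, None] * scale)


@dataclass
class CellTypeCenters:
    """T cell types x p genes matrix of average (transformed) expression."""

    matrix: np.ndarray
    types: list[str]
    gene_names: list[str]
    normalization: str = "lognorm"

    def type_index(self, label: str) -> int:
        try:
            return self.types.index(label)
        except ValueError:
            raise MappingError(f"unknown cell type {label!r}") from None

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise MappingError(f"gene {gene!r} not in centers") from None


@dataclass
class PixelAssignment:
    """Per-pixel assigned cell type and the correlation it achieved."""

    types: list[str]
    correlations: np.ndarray
    centers: CellTypeCenters
    type_indices: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.type_indices is None:
            self.type_indices = np.array(
                [self.centers.type_index(t) for t in self.types])

    def covariate(self, gene: str) -> np.ndarray:
        """x_i for ``gene``: the assigned center's expression of that gene."""
        j = self.centers.gene_index(gene)
        return self.centers.matrix[self.type_indices, j]

    def x_table(self, genes=None) -> pd.DataFrame:
        genes = list(genes) if genes is not None else self.centers.gene_names
        return pd.DataFrame(
            {g: self.covariate(g) for g in genes})


@dataclass
class ReferenceGene:
    gene: str
    fit: GLSMFit
    p_value: float


@dataclass
class ReferenceSet:
    """Shared genes with significant fits, retained with their full fits."""

    entries: list[ReferenceGene]
    p_cut: float
    failed: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return [r.gene for r in self.entries]

    def get(self, gene: str) -> ReferenceGene:
        for r in self.entries:
            if r.gene == gene:
                return r
        raise KeyError(gene)


@dataclass
class PredictionResult:
    """Per-pixel predicted rate and counts for one target gene."""

    gene: str
    lambda_hat: np.ndarray
    predicted_counts: np.ndarray
    reference_gene: str
    reference_corr: float
    sampled_counts: np.ndarray = None


def cell_type_centers(sc: SCDataset, normalization: str = "lognorm",
                      types=None) -> CellTypeCenters:
    """Average expression per cell type ("center"), one row per type.

    ``normalization="lognorm"`` averages log1p counts-per-10k;
    ``"raw"`` averages raw counts.  Types default to the sorted labels found
    in the data; explicitly requested types with no cells raise an error.
    """
    if normalization == "lognorm":
        expr = lognormalize(sc.counts)
    elif normalization == "raw":
        expr = sc.counts.astype(float)
    else:
        raise MappingError(f"unknown normalization {normalization!r}")
    labels = np.asarray(sc.cell_types)
    types = sorted(set(sc.cell_types)) if types is None else list(types)
    rows = []
    for t in types:
        mask = labels == t
        if not mask.any():
            raise MappingError(f"cell type {t!r} has no cells")
        rows.append(expr[mask].mean(axis=0))
    return CellTypeCenters(matrix=np.vstack(rows), types=types,
                           gene_names=list(sc.gene_names),
                           normalization=normalization)


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between each row of A and each row of B."""
    Az = A - A.mean(axis=1, keepdims=True)
    Bz = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Az ** 2).sum(axis=1))
    sb = np.sqrt((Bz ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Az @ Bz.T) / np.outer(sa, sb)
    return corr


def assign_pixels(spatial: SpatialDataset, centers: CellTypeCenters,
                  shared_genes) -> PixelAssignment:
    """Assign each pixel the center with the highest Pearson correlation.

    Correlations are computed over the shared genes, with the pixel profile
    transformed the same way as the centers.  Ties break to the
    lexicographically first type label; a constant pixel profile (undefined
    correlation) is assigned the globally most common type with a warning.
    """
    shared = list(shared_genes)
    if len(shared) < 3:
        raise MappingError("need at least 3 shared genes for correlations")
    sp_idx = [spatial.gene_index(g) for g in shared]
    ct_idx = [centers.gene_index(g) for g in shared]
    if centers.normalization == "lognorm":
        profiles = lognormalize(spatial.counts, spatial.size_factors)[:, sp_idx]
    else:
        profiles = spatial.counts[:, sp_idx].astype(float)
    C = centers.matrix[:, ct_idx]
    order = np.argsort(centers.types)  # lexicographic tie-break via ordering
    corr = _rowwise_pearson(profiles, C[order])
    corr = np.where(np.isnan(corr), -np.inf, corr)
    best = np.argmax(corr, axis=1)  # first max -> lexicographically first
    assigned = np.array(order)[best]
    achieved = corr[np.arange(corr.shape[0]), best]
    constant = ~np.isfinite(achieved)
    if constant.any():
        ok_types = [centers.types[i] for i, c in zip(assigned, constant) if not c]
        common = (Counter(ok_types).most_common(1)[0][0]
                  if ok_types else sorted(centers.types)[0])
        warnings.warn(
            f"{int(constant.sum())} pixel(s) with constant profiles assigned "
            f"the most common type {common!r}", stacklevel=2)
        assigned = assigned.copy()
        assigned[constant] = centers.type_index(common)
        achieved = np.where(constant, np.nan, achieved)
    return PixelAssignment(
        types=[centers.types[i] for i in assigned],
        correlations=achieved, centers=centers,
        type_indices=np.asarray(assigned))


def loo_covariate(spatial: SpatialDataset, centers: CellTypeCenters,
                  shared_genes, gene: str) -> np.ndarray:
    """Covariate for ``gene`` from an assignment that never saw its counts.

    The pixel-to-type assignment is recomputed over the shared genes minus
    ``gene`` itself, so a gene's own spatial counts cannot tilt the
    assignment that builds its covariate (which would otherwise inflate the
    beta test under the null).
    """
    others = [g for g in shared_genes if g != gene]
    asg = assign_pixels(spatial, centers, others)
    return asg.covariate(gene)


def build_reference_set(paired: PairedData, assignment: PixelAssignment,
                        kernel: KernelMatrix, p_cut: float = 0.05,
                        control: GLSMControl | None = None,
                        adjust: str | None = None,
                        loo_covariates: bool = True) -> ReferenceSet:
    """Fit the GLSM for every shared gene and keep those with p < ``p_cut``.

    ``adjust="bh"`` applies Benjamini-Hochberg to the p-values before the
    cut (the default uses raw p-values).  By default each gene's covariate
    comes from a leave-that-gene-out pixel assignment (see
    :func:`loo_covariate`), which keeps the test of beta calibrated; the
    given ``assignment`` supplies the centers (and the covariates directly
    when ``loo_covariates=False`` or too few genes remain).  Genes whose fit
    fails (e.g. all zero counts, constant covariate) are recorded in
    ``failed`` and skipped.
    """
    if not 0.0 < p_cut <= 1.0:
        raise MappingError("p_cut must be in (0, 1]")
    spatial = paired.spatial
    use_loo = loo_covariates and len(paired.shared_genes) >= 4
    fits: list[tuple[str, GLSMFit]] = []
    failed: dict[str, str] = {}
    for gene in paired.shared_genes:
        y = spatial.gene_counts(gene)
        try:
            if use_loo:
                x = loo_covariate(spatial, assignment.centers,
                                  paired.shared_genes, gene)
            else:
                x = assignment.covariate(gene)
            fit = fit_glsm(GLSMSpec(y=y, offset=spatial.size_factors, x=x,
                                    K=kernel), control)
        except (GLSMError, MappingError) as exc:
            failed[gene] = str(exc)
            continue
        fits.append((gene, fit))
    if not fits:
        raise EmptyReferenceError("no shared gene could be fitted")
    pvals = np.array([f.p_value for _, f in fits])
    if adjust == "bh":
        pvals = false_discovery_control(pvals, method="bh")
    entries = [ReferenceGene(gene=g, fit=f, p_value=float(p))
               for (g, f), p in zip(fits, pvals) if p < p_cut]
    if not entries:
        raise EmptyReferenceError(
            f"no gene passed p < {p_cut}; consider a looser cut")
    return ReferenceSet(entries=entries, p_cut=p_cut, failed=failed)


def _sc_profile(sc: SCDataset, normalization: str) -> np.ndarray:
    if normalization == "lognorm":
        return lognormalize(sc.counts)
    if normalization == "raw":
        return sc.counts.astype(float)
    raise MappingError(f"unknown normalization {normalization!r}")


def select_reference_gene(target_gene: str, reference_set: ReferenceSet,
                          sc: SCDataset,
                          normalization: str = "lognorm") -> tuple[str, float]:
    """Pick the reference gene most correlated with the target across cells.

    Correlations are Pearson, computed in scRNA-seq space on the same
    transform as the centers (flaggable); ties break lexicographically.
    """
    if not reference_set.entries:
        raise EmptyReferenceError("reference set is empty")
    expr = _sc_profile(sc, normalization)
    t = expr[:, sc.gene_index(target_gene)]
    if np.ptp(t) == 0:
        raise MappingError(
            f"target {target_gene!r} is constant across cells; "
            "correlation undefined")
    candidates = sorted(g for g in reference_set.genes if g != target_gene)
    if not candidates:
        raise EmptyReferenceError(
            f"no reference candidate other than {target_gene!r}")
    cols = expr[:, [sc.gene_index(g) for g in candidates]]
    corr = _rowwise_pearson(t[None, :], cols.T)[0]
    corr = np.where(np.isnan(corr), -np.inf, corr)
    best = int(np.argmax(corr))  # first max: lexicographically first on ties
    return candidates[best], float(corr[best])


def predict_gene(target_gene: str, reference: ReferenceGene,
                 centers: CellTypeCenters, assignment: PixelAssignment,
                 size_factors, mode: str = "mean", seed: int | None = None,
                 reference_corr: float = np.nan) -> PredictionResult:
    """Predict the spatial pattern of ``target_gene`` from a reference fit.

    lambda_hat_i = exp(alpha_hat + x_i^(un) beta_hat + g_hat_i + e_hat_i)
    with the reference gene's fitted parameters and BLUPs, and predicted
    counts N_i lambda_hat_i.  ``mode="sample"`` additionally draws
    Poisson(N_i lambda_hat_i) with the given seed.
    """
    fit = reference.fit
    x_un = assignment.covariate(target_gene)
    eta = (fit.alpha_hat + x_un * fit.beta_hat + fit.g_blup + fit.e_blup)
    lam = np.exp(np.clip(eta, -30.0, 30.0))
    N = np.asarray(size_factors, dtype=float)
    predicted = N * lam
    sampled = None
    if mode == "sample":
        rng = np.random.default_rng(seed)
        sampled = rng.poisson(predicted)
    elif mode != "mean":
        raise MappingError(f"unknown prediction mode {mode!r}")
    return PredictionResult(
        gene=target_gene, lambda_hat=lam, predicted_counts=predicted,
        reference_gene=reference.gene, reference_corr=float(reference_corr),
        sampled_counts=sampled)
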