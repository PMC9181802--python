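"""Synthetic paired datasets drawn from the model's own generative chain.

``simulate_glsm_counts`` draws one gene exactly as the model assumes:
g ~ MVN(0, sigma^2 h^2 K), e ~ MVN(0, sigma^2 (1-h^2) I),
log lambda = alpha + x beta + g + e, y_i ~ Poisson(N_i lambda_i).

``simulate_paired_datasets`` emulates the paired-input structure: cell-type
center profiles on the log scale, scRNA-seq counts per cell drawn Poisson
around its type's center, pixels assigned contiguous true cell types
(Voronoi regions of seeded anchors), and spatial counts per gene generated
by the single-gene chain with x = the (pixel-centred) true-center expression.

Signal genes come in *groups* (default size 4) that share one standardised
spatial field realisation -- a co-expression module -- while each gene keeps
its own independent nugget e (the model treats e as per-gene sequencing
error).  A configurable fraction of genes is null (beta = 0, spatially
flat), exercising both the calibration and the power path of the pipeline.

Default scale: 400 pixels on a 20x20 grid with offsets
N_i ~ LogNormal(log 500, 0.3), 100 genes, 500 cells, 5 types -- the order of
magnitude of image-based spatial assays (hundreds to a few thousand pixels,
~1,000 genes) while staying fast on a single CPU.  Every routine takes an
explicit seed and regenerates bit-identically from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets_io import PairedData, SCDataset, SpatialDataset
from .kernels import KernelMatrix, kernel_from_spec


class SimulationError(ValueError):
    pass


@dataclass
class GLSMParams:
    """Generative parameters of one gene (symbols of the spatial model)."""

    alpha: float = -4.0
    beta: float = 0.0
    sigma2: float = 1.0
    h2: float = 0.5


@dataclass
class SimulationTruth:
    """Everything needed to check an estimate against its generative truth."""

    alpha: float
    beta: float
    sigma2: float
    h2: float
    kernel_kind: str
    kernel_param: float
    x: np.ndarray
    g: np.ndarray
    e: np.ndarray
    lam: np.ndarray
    size_factors: np.ndarray
    seed: int
    cell_types: np.ndarray = None  # per-pixel true type (paired simulations)
    role: str = ""                 # "signal" / "null" in paired simulations
    group: int = -1                # co-expression module index


@dataclass
class EffectConfig:
    """Study conditions of the paired-data generator.

    ``beta`` / ``h2_signal`` describe signal genes (spatially structured,
    covariate effect present), ``h2_null`` the spatially flat null genes
    (beta = 0).  ``group_size`` genes share one spatial field realisation.
    ``center_sd`` is the between-type spread of log-expression centers
    (2 sd separation makes types well separated); ``center_jitter_sd`` the
    per-gene deviation within a co-expression group.
    """

    beta: float = 1.0
    sigma2: float = 1.0
    h2_signal: float = 0.8
    h2_null: float = 0.0
    null_fraction: float = 0.5
    group_size: int = 4
    alpha: float = -4.0
    base_log_mean: float = 1.0
    center_sd: float = 1.0
    center_jitter_sd: float = 0.2
    cell_depth_sd: float = 0.3
    kernel: tuple = ("car", 0.5)
    knn: int = 4
    plant_duplicate: bool = False


def make_coords(n: int, layout: str = "grid",
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Pixel coordinates: a near-square grid or uniform random positions."""
    if layout == "grid":
        side = math.ceil(math.sqrt(n))
        xs, ys = np.meshgrid(np.arange(side), np.arange(side))
        return np.column_stack([xs.ravel(), ys.ravel()])[:n].astype(float)
    if layout == "uniform-random":
        if rng is None:
            rng = np.random.default_rng(0)
        return rng.uniform(0, math.sqrt(n), size=(n, 2))
    raise SimulationError(f"unknown coords layout {layout!r}")


def _chol_psd(K: np.ndarray) -> np.ndarray:
    return np.linalg.cholesky(K + 1e-10 * np.eye(K.shape[0]))


def simulate_glsm_counts(n: int = 400, coords_layout: str = "grid",
                         params: GLSMParams | None = None,
                         kernel=("car", 0.5), seed: int = 1,
                         x=None, size_factors=None, coords=None,
                         gene_name: str = "gene_000"):
    """Draw one gene from the generative chain; returns (dataset, truth).

    ``x`` defaults to standard normal, ``size_factors`` to
    LogNormal(log 500, 0.3).  The returned single-gene ``SpatialDataset``
    carries the generative size factors explicitly (they play the role of the
    full-transcriptome totals, which a one-gene slice cannot recompute).
    """
    params = params or GLSMParams()
    rng = np.random.default_rng(seed)
    if coords is None:
        coords = make_coords(n, coords_layout, rng)
    else:
        coords = np.asarray(coords, dtype=float)
    K = kernel_from_spec(coords, kernel)
    N = (rng.lognormal(np.log(500.0), 0.3, size=n) if size_factors is None
         else np.asarray(size_factors, dtype=float))
    x = rng.standard_normal(n) if x is None else np.asarray(x, dtype=float)
    s2g = params.sigma2 * params.h2
    s2e = params.sigma2 * (1.0 - params.h2)
    g = (math.sqrt(s2g) * (_chol_psd(K.K) @ rng.standard_normal(n))
         if s2g > 0 else np.zeros(n))
    e = (math.sqrt(s2e) * rng.standard_normal(n)
         if s2e > 0 else np.zeros(n))
    lam = np.exp(np.clip(params.alpha + x * params.beta + g + e, -30, 30))
    y = rng.poisson(N * lam)
    kind = K.kind
    kparam = K.params.get("alpha_s", K.params.get("bandwidth", float("nan")))
    ds = SpatialDataset(
        counts=y[:, None], coords=coords,
        pixel_ids=[f"px_{i:05d}" for i in range(n)],
        gene_names=[gene_name], size_factors=N)
    truth = SimulationTruth(
        alpha=params.alpha, beta=params.beta, sigma2=params.sigma2,
        h2=params.h2, kernel_kind=kind, kernel_param=float(kparam),
        x=x, g=g, e=e, lam=lam, size_factors=N, seed=seed)
    return ds, truth


def simulate_paired_datasets(n_pixels: int = 400, n_genes: int = 100,
                             n_cells: int = 500, n_types: int = 5,
                             effect_config: EffectConfig | None = None,
                             seed: int = 1, coords_layout: str = "grid"):
    """Paired spatial + scRNA-seq data with known per-gene truth.

    Returns ``(PairedData, truths)`` where ``truths`` maps each gene name to
    its :class:`SimulationTruth` (including the per-pixel true cell types and
    the gene's role and co-expression group).
    """
    cfg = effect_config or EffectConfig()
    if n_types < 2:
        raise SimulationError("need at least 2 cell types")
    if n_genes < 10:
        raise SimulationError("need at least 10 genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    types = [f"type_{t}" for t in range(n_types)]

    # -- roles and co-expression groups ------------------------------------
    n_null = int(round(cfg.null_fraction * n_genes))
    roles = np.array(["null"] * n_null + ["signal"] * (n_genes - n_null))
    rng.shuffle(roles)
    signal_idx = np.flatnonzero(roles == "signal")
    groups = np.full(n_genes, -1)
    for gi, start in enumerate(range(0, len(signal_idx), cfg.group_size)):
        groups[signal_idx[start:start + cfg.group_size]] = gi
    n_groups = int(groups.max()) + 1 if signal_idx.size else 0

    # -- cell-type center profiles on the log scale ------------------------
    # each type-effect vector is standardised to spread exactly center_sd:
    # planted co-expression groups must be reliably correlated in scRNA-seq
    # space (they exist to serve as each other's reference genes), which a
    # raw Gaussian draw does not guarantee for small n_types
    def type_effect() -> np.ndarray:
        b = rng.standard_normal(n_types)
        b = (b - b.mean()) / max(b.std(), 1e-12)
        return cfg.center_sd * b

    mu_g = cfg.base_log_mean + 0.25 * rng.standard_normal(n_genes)
    group_effects = np.vstack([type_effect() for _ in range(max(n_groups, 1))])
    centers_log = np.empty((n_types, n_genes))
    for j in range(n_genes):
        b = group_effects[groups[j]] if groups[j] >= 0 else type_effect()
        jitter = cfg.center_jitter_sd * rng.standard_normal(n_types)
        centers_log[:, j] = mu_g[j] + b + jitter

    # -- scRNA-seq counts ---------------------------------------------------
    cell_types = np.array([types[i % n_types] for i in range(n_cells)])
    rng.shuffle(cell_types)
    type_index = np.array([types.index(t) for t in cell_types])
    depth_factor = rng.lognormal(0.0, cfg.cell_depth_sd, size=n_cells)
    sc_rate = depth_factor[:, None] * np.exp(centers_log[type_index])
    sc_counts = rng.poisson(sc_rate)

    # -- spatial side -------------------------------------------------------
    coords = make_coords(n_pixels, coords_layout, rng)
    anchor_idx = rng.choice(n_pixels, size=n_types, replace=False)
    d2 = ((coords[:, None, :] - coords[anchor_idx][None, :, :]) ** 2).sum(-1)
    pixel_type_idx = np.argmin(d2, axis=1)  # contiguous Voronoi regions
    pixel_types = np.array([types[i] for i in pixel_type_idx])

    K = kernel_from_spec(coords, cfg.kernel, knn=cfg.knn)
    L = _chol_psd(K.K)
    group_fields = (L @ rng.standard_normal((n_pixels, max(n_groups, 1)))).T

    N_target = rng.lognormal(np.log(500.0), 0.3, size=n_pixels)
    counts = np.empty((n_pixels, n_genes), dtype=np.int64)
    truths: dict[str, SimulationTruth] = {}
    for j, gene in enumerate(genes):
        signal = roles[j] == "signal"
        beta = cfg.beta if signal else 0.0
        h2 = cfg.h2_signal if signal else cfg.h2_null
        x = centers_log[pixel_type_idx, j]
        x = x - x.mean()
        s2g = cfg.sigma2 * h2
        s2e = cfg.sigma2 * (1.0 - h2)
        if s2g > 0:
            u = group_fields[groups[j]] if groups[j] >= 0 else L @ rng.standard_normal(n_pixels)
            g_vec = math.sqrt(s2g) * u
        else:
            g_vec = np.zeros(n_pixels)
        e_vec = math.sqrt(s2e) * rng.standard_normal(n_pixels) if s2e > 0 else np.zeros(n_pixels)
        lam = np.exp(np.clip(cfg.alpha + beta * x + g_vec + e_vec, -30, 30))
        counts[:, j] = rng.poisson(N_target * lam)
        truths[gene] = SimulationTruth(
            alpha=cfg.alpha, beta=beta, sigma2=cfg.sigma2, h2=h2,
            kernel_kind=K.kind,
            kernel_param=float(K.params.get("alpha_s",
                                            K.params.get("bandwidth", np.nan))),
            x=x, g=g_vec, e=e_vec, lam=lam, size_factors=N_target, seed=seed,
            cell_types=pixel_types, role=str(roles[j]), group=int(groups[j]))

    if cfg.plant_duplicate:
        # make the last gene an exact scRNA-seq duplicate of the second-last
        sc_counts[:, -1] = sc_counts[:, -2]
        centers_log[:, -1] = centers_log[:, -2]

    spatial = SpatialDataset.from_arrays(
        counts, coords, [f"px_{i:05d}" for i in range(n_pixels)], genes)
    sc = SCDataset(counts=sc_counts,
                   cell_ids=[f"cell_{i:05d}" for i in range(n_cells)],
                   gene_names=genes, cell_types=list(cell_types))
    shared = sorted(set(spatial.gene_names) & set(genes))
    return PairedData(spatial=spatial, sc=sc, shared_genes=shared), truths
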