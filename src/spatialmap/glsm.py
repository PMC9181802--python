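"""Poisson generalized linear spatial model fitted by PQL with AI-REML.

Model, for one gene across n pixels:

    y_i ~ Poisson(N_i * lambda_i)
    log lambda_i = alpha + x_i * beta + g_i + e_i
    g ~ MVN(0, sigma^2 h^2 K)          (spatially structured effect)
    e ~ MVN(0, sigma^2 (1 - h^2) I)    (independent nugget)

where N_i is the per-pixel size factor (total counts, the offset), x_i is the
cell-type-level expression mapped to pixel i, K a spatial kernel and
h^2 in [0, 1] the fraction of the random variance on the log-rate scale that
is spatial.

Inference is penalized quasi-likelihood (PQL): a second-order Taylor expansion
of the Poisson log-likelihood around the current linear predictor eta turns the
counts into a working Gaussian response (pseudodata)

    ytilde_i = eta_i + (y_i - mu_i) / mu_i,    mu_i = N_i exp(eta_i),

with working weights w_i = mu_i (the conditional mean and variance of a
log-link Poisson).  The pseudodata follow an LMM with covariance

    V = sigma^2 h^2 K + sigma^2 (1 - h^2) I + diag(1 / w),

whose variance components are updated by average-information (AI) REML, the
fixed effects by generalized least squares and the random effects by BLUP.
Alternating the linearisation and the LMM inference to convergence yields the
parameter estimates, the BLUPs and a Wald test of H0: beta = 0.

Internally the variance components are carried as
theta = (sigma^2 h^2, sigma^2 (1 - h^2)), the standard AI-REML
parameterisation, with nonnegativity clipping and step-halving so that the
working REML log-likelihood never decreases across accepted steps; reported
h^2 is snapped to the boundary below 1e-4 / above 1 - 1e-4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.stats import norm

from .kernels import KernelMatrix

ETA_CLIP = 30.0
_THETA_FLOOR = 1e-8
H2_SNAP = 1e-4


class GLSMError(RuntimeError):
    """Model fitting failure."""


class IdentifiabilityError(GLSMError):
    """A degenerate design (constant covariate, flat likelihood)."""


class KernelIdentifiabilityWarning(UserWarning):
    """K = I makes the REML likelihood flat in h^2."""


@dataclass
class GLSMControl:
    """Convergence control for the PQL outer loop and the AI inner loop."""

    max_outer: int = 100
    outer_tol: float = 1e-5
    max_inner: int = 20
    inner_tol: float = 1e-4
    max_halvings: int = 12


@dataclass
class GLSMSpec:
    """Inputs of one single-gene fit: counts, offset, covariate, kernel."""

    y: np.ndarray
    offset: np.ndarray
    x: np.ndarray
    K: KernelMatrix

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        n = self.y.shape[0]
        if self.offset.shape != (n,) or self.x.shape != (n,):
            raise GLSMError("y, offset and x must have equal length")
        if self.K.n != n:
            raise GLSMError(f"kernel is {self.K.n}x{self.K.n} but n = {n}")
        if np.any(self.y < 0):
            raise GLSMError("counts must be nonnegative")
        if np.any(self.offset <= 0):
            raise GLSMError("offsets (size factors) must be positive")
        if np.ptp(self.x) == 0:
            raise IdentifiabilityError(
                "covariate x is constant (collinear with the intercept)")


@dataclass
class PQLState:
    """Working quantities of one PQL linearisation."""

    eta: np.ndarray
    mu: np.ndarray
    pseudodata: np.ndarray
    weights: np.ndarray


@dataclass
class GLSMFit:
    """Estimates, BLUPs, the Wald test of beta and convergence diagnostics."""

    alpha_hat: float
    beta_hat: float
    sigma2_hat: float
    h2_hat: float
    g_blup: np.ndarray
    e_blup: np.ndarray
    beta_se: float
    p_value: float
    n_iterations: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)


def compute_pseudodata(y, offset, eta) -> PQLState:
    """Linearise the Poisson likelihood around ``eta``.

    mu_i = N_i exp(eta_i); pseudodata ytilde_i = eta_i + (y_i - mu_i)/mu_i;
    working weights w_i = mu_i.  ``eta`` is clipped at +/-30 (with a warning)
    to keep mu finite.
    """
    y = np.asarray(y, dtype=float)
    offset = np.asarray(offset, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(offset <= 0):
        raise GLSMError("offsets must be positive")
    if not np.all(np.isfinite(eta)):
        raise GLSMError("eta must be finite")
    if np.any(np.abs(eta) > ETA_CLIP):
        warnings.warn(f"linear predictor clipped at +/-{ETA_CLIP}", stacklevel=2)
        eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    mu = offset * np.exp(eta)
    pseudodata = eta + (y - mu) / mu
    return PQLState(eta=eta, mu=mu, pseudodata=pseudodata, weights=mu.copy())


class _WorkingLMM:
    """The Gaussian working model ytilde ~ N(X b, th1 K + th2 I + diag(1/w))."""

    def __init__(self, pseudodata, weights, X, K):
        self.y = np.ascontiguousarray(pseudodata, dtype=float)
        self.R = 1.0 / np.asarray(weights, dtype=float)
        self.X = np.ascontiguousarray(X, dtype=float)
        self.K = np.ascontiguousarray(K, dtype=float)
        self.n = self.y.shape[0]
        self.I = np.eye(self.n)

    def eval(self, theta):
        """Factor V and return everything the REML score/AI update needs."""
        th1, th2 = theta
        V = th1 * self.K + th2 * self.I + np.diag(self.R)
        try:
            c = cho_factor(V, lower=True, check_finite=False)
        except LinAlgError:
            V = V + 1e-6 * self.I  # jitter once, then give up
            c = cho_factor(V, lower=True, check_finite=False)
        Vi_y = cho_solve(c, self.y, check_finite=False)
        Vi_X = cho_solve(c, self.X, check_finite=False)
        XtViX = self.X.T @ Vi_X
        try:
            cx = cho_factor(XtViX, lower=True, check_finite=False)
        except LinAlgError as exc:
            raise IdentifiabilityError("X'V^{-1}X is singular") from exc
        b = cho_solve(cx, self.X.T @ Vi_y, check_finite=False)
        Py = Vi_y - Vi_X @ b
        logdet_V = 2.0 * np.sum(np.log(np.diag(c[0])))
        logdet_X = 2.0 * np.sum(np.log(np.diag(cx[0])))
        ll = -0.5 * (logdet_V + logdet_X + self.y @ Py)
        return {"theta": (th1, th2), "c": c, "cx": cx, "b": b, "Py": Py,
                "Vi_X": Vi_X, "XtViX": XtViX, "ll": ll}

    def apply_P(self, piece, v):
        """P v with P = V^{-1} - V^{-1} X (X'V^{-1}X)^{-1} X' V^{-1}."""
        Viv = cho_solve(piece["c"], v, check_finite=False)
        return Viv - piece["Vi_X"] @ cho_solve(
            piece["cx"], self.X.T @ Viv, check_finite=False)

    def score_and_ai(self, piece):
        """REML score vector and average-information matrix at ``piece``."""
        Py = piece["Py"]
        KPy = self.K @ Py
        PKPy = self.apply_P(piece, KPy)
        PPy = self.apply_P(piece, Py)
        ViK = cho_solve(piece["c"], self.K, check_finite=False)
        Vi_X = piece["Vi_X"]
        tr_PK = np.trace(ViK) - np.trace(
            cho_solve(piece["cx"], Vi_X.T @ (self.K @ Vi_X), check_finite=False))
        Vi = cho_solve(piece["c"], self.I, check_finite=False)
        tr_PI = np.trace(Vi) - np.trace(
            cho_solve(piece["cx"], Vi_X.T @ Vi_X, check_finite=False))
        score = np.array([
            -0.5 * (tr_PK - Py @ KPy),
            -0.5 * (tr_PI - Py @ Py),
        ])
        ai = 0.5 * np.array([
            [KPy @ PKPy, KPy @ PPy],
            [KPy @ PPy, Py @ PPy],
        ])
        return score, ai


def _ai_step(lmm: _WorkingLMM, piece, control: GLSMControl):
    """One accepted AI-REML step (with step-halving for monotonicity)."""
    score, ai = lmm.score_and_ai(piece)
    try:
        delta = np.linalg.solve(ai + 1e-12 * np.eye(2), score)
    except np.linalg.LinAlgError:
        delta = score / max(np.abs(np.diag(ai)).max(), 1.0)
    theta = np.asarray(piece["theta"])
    step = 1.0
    for _ in range(control.max_halvings):
        trial = np.maximum(theta + step * delta, _THETA_FLOOR)
        candidate = lmm.eval(trial)
        if candidate["ll"] >= piece["ll"] - 1e-10:
            return candidate, ai
        step *= 0.5
    return piece, ai  # no improving step found; stay put


def reml_ai_step(pseudodata, weights, x, K, sigma2, h2,
                 control: GLSMControl | None = None):
    """One AI-REML update of (sigma2, h2) for the working LMM.

    Returns ``(sigma2_new, h2_new, ai_matrix)``.  If K is (numerically) the
    identity, sigma^2 h^2 K + sigma^2 (1-h^2) I = sigma^2 I for every h^2 and
    the REML likelihood is flat in h^2; a
    :class:`KernelIdentifiabilityWarning` is emitted.
    """
    control = control or GLSMControl()
    Kmat = K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    _warn_if_identity(Kmat)
    X = _design(np.asarray(x, dtype=float))
    lmm = _WorkingLMM(pseudodata, weights, X, Kmat)
    theta = (max(sigma2 * h2, _THETA_FLOOR),
             max(sigma2 * (1.0 - h2), _THETA_FLOOR))
    piece = lmm.eval(theta)
    piece, ai = _ai_step(lmm, piece, control)
    return _theta_to_sigma_h2(piece["theta"]) + (ai,)


def _warn_if_identity(Kmat: np.ndarray) -> None:
    n = Kmat.shape[0]
    if np.allclose(Kmat, np.eye(n), atol=1e-12, rtol=0):
        warnings.warn(
            "K is the identity: the variance split h^2 between the spatial "
            "and nugget components is not identifiable (REML likelihood is "
            "flat in h^2)", KernelIdentifiabilityWarning, stacklevel=3)


def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x])


def _theta_to_sigma_h2(theta) -> tuple[float, float]:
    th1, th2 = float(theta[0]), float(theta[1])
    sigma2 = th1 + th2
    if sigma2 <= 2 * _THETA_FLOOR:
        return sigma2, 0.0
    h2 = th1 / sigma2
    if h2 < H2_SNAP:
        h2 = 0.0
    elif h2 > 1.0 - H2_SNAP:
        h2 = 1.0
    return sigma2, h2


def blup_random_effects(pseudodata, weights, x, K, alpha, beta, sigma2, h2):
    """BLUPs of the spatial effect g and the nugget e from the working LMM.

    g_hat = sigma2 h2 K V^{-1} r and e_hat = sigma2 (1 - h2) V^{-1} r with
    r = ytilde - alpha - x beta; h2 = 0 gives g = 0 exactly, h2 = 1 gives
    e = 0 exactly.
    """
    Kmat = K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    X = _design(np.asarray(x, dtype=float))
    lmm = _WorkingLMM(pseudodata, weights, X, Kmat)
    th1 = sigma2 * h2
    th2 = sigma2 * (1.0 - h2)
    piece = lmm.eval((max(th1, _THETA_FLOOR if th1 > 0 else 0.0),
                      max(th2, _THETA_FLOOR if th2 > 0 else 0.0)))
    r = lmm.y - X @ np.array([alpha, beta])
    Vir = cho_solve(piece["c"], r, check_finite=False)
    g = th1 * (Kmat @ Vir)
    e = th2 * Vir
    return g, e


def fit_glsm(spec: GLSMSpec, control: GLSMControl | None = None) -> GLSMFit:
    """Fit the Poisson GLSM by alternating PQL linearisation and AI-REML.

    Each outer iteration recomputes the pseudodata at the current linear
    predictor, runs the AI-REML inner loop on the variance components,
    updates (alpha, beta) by GLS and (g, e) by BLUP.  Convergence is declared
    when the relative change of (alpha, beta, sigma2, h2) drops below
    ``control.outer_tol``; otherwise the last iterate is returned with
    ``converged=False``.  The Wald statistic beta_hat / se(beta_hat) is
    referred to a standard normal for the two-sided test of H0: beta = 0.
    """
    control = control or GLSMControl()
    y, N, x = spec.y, spec.offset, spec.x
    Kmat = spec.K.K
    _warn_if_identity(Kmat)
    X = _design(x)

    rate = np.mean(y / N)
    if rate <= 0:
        raise GLSMError("all counts are zero; the intercept is -infinity")
    alpha, beta = float(np.log(rate)), 0.0
    theta = np.array([0.5, 0.5])  # sigma2 = 1, h2 = 0.5
    g = np.zeros_like(y)
    e = np.zeros_like(y)
    params = np.array([alpha, beta, 1.0, 0.5])
    converged = False
    ll_trace: list[list[float]] = []
    n_iter = 0

    for n_iter in range(1, control.max_outer + 1):
        eta = np.clip(alpha + x * beta + g + e, -ETA_CLIP, ETA_CLIP)
        state = compute_pseudodata(y, N, eta)
        lmm = _WorkingLMM(state.pseudodata, state.weights, X, Kmat)
        piece = lmm.eval(tuple(np.maximum(theta, _THETA_FLOOR)))
        inner_lls = [piece["ll"]]
        for _ in range(control.max_inner):
            new_piece, _ai = _ai_step(lmm, piece, control)
            inner_lls.append(new_piece["ll"])
            moved = np.max(np.abs(np.asarray(new_piece["theta"]) -
                                  np.asarray(piece["theta"])) /
                           (np.abs(np.asarray(piece["theta"])) + 1e-8))
            piece = new_piece
            if moved < control.inner_tol:
                break
        ll_trace.append(inner_lls)
        theta = np.asarray(piece["theta"])
        alpha, beta = float(piece["b"][0]), float(piece["b"][1])
        sigma2, h2 = _theta_to_sigma_h2(theta)
        # BLUP from the same working model (P y = V^{-1}(ytilde - X b))
        Py = piece["Py"]
        g = sigma2 * h2 * (Kmat @ Py)
        e = sigma2 * (1.0 - h2) * Py
        new_params = np.array([alpha, beta, sigma2, h2])
        rel = np.max(np.abs(new_params - params) / (np.abs(params) + 1e-3))
        params = new_params
        if rel < control.outer_tol:
            converged = True
            break

    sigma2, h2 = _theta_to_sigma_h2(theta)
    cov_b = np.linalg.inv(piece["XtViX"])
    beta_se = float(np.sqrt(cov_b[1, 1]))
    z = beta / beta_se if beta_se > 0 else 0.0
    p_value = float(2.0 * norm.sf(abs(z)))
    if not converged:
        warnings.warn(
            f"PQL did not converge in {control.max_outer} outer iterations",
            stacklevel=2)
    return GLSMFit(
        alpha_hat=alpha, beta_hat=beta, sigma2_hat=sigma2, h2_hat=h2,
        g_blup=g, e_blup=e, beta_se=beta_se, p_value=p_value,
        n_iterations=n_iter, converged=converged,
        diagnostics={"reml_ll_trace": ll_trace, "wald_z": z,
                     "theta": tuple(theta)},
    )
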