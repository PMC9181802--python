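"""Independent oracles used to cross-check the implementation.

Everything here deliberately avoids the package's numerical internals: the
Laplace marginal likelihood is maximised by direct numerical optimisation,
the REML log-likelihood is evaluated from scratch with slogdet, Moran's I is
the textbook statistic, and the Poisson GLM oracle is statsmodels' IRLS.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def laplace_mle(y, N, x, K, start):
    """Maximum likelihood for the Poisson GLSM via a Laplace approximation.

    Integrates the combined random effect u = g + e ~ MVN(0, Sigma) out of
    the likelihood with a Laplace approximation at the joint mode (inner
    Newton), and maximises over (alpha, beta, log sigma2, logit h2) with
    Nelder-Mead.  Returns the optimiser result; ``x[1]`` is beta_hat.
    """
    y = np.asarray(y, float)
    N = np.asarray(N, float)
    x = np.asarray(x, float)
    n = len(y)
    I = np.eye(n)

    def nll(p):
        alpha, beta, log_s2, logit_h2 = p
        s2, h2 = np.exp(log_s2), expit(logit_h2)
        Sigma = s2 * h2 * K + s2 * (1 - h2) * I + 1e-8 * I
        Sinv = np.linalg.inv(Sigma)
        _, logdetS = np.linalg.slogdet(Sigma)
        u = np.zeros(n)
        for _ in range(100):
            eta = np.clip(alpha + beta * x + u, -30, 30)
            mu = N * np.exp(eta)
            step = np.linalg.solve(np.diag(mu) + Sinv, (y - mu) - Sinv @ u)
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = np.clip(alpha + beta * x + u, -30, 30)
        mu = N * np.exp(eta)
        joint = y @ eta - mu.sum() - 0.5 * (u @ Sinv @ u) - 0.5 * logdetS
        _, logdetH = np.linalg.slogdet(np.diag(mu) + Sinv)
        return -(joint - 0.5 * logdetH)

    return minimize(nll, np.asarray(start, float), method="Nelder-Mead",
                    options=dict(maxiter=4000, xatol=1e-6, fatol=1e-8))


def reml_loglik(ydata, weights, X, K, th1, th2):
    """REML log-likelihood of the working LMM, computed from scratch."""
    n = len(ydata)
    V = th1 * K + th2 * np.eye(n) + np.diag(1.0 / np.asarray(weights, float))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    b = np.linalg.solve(XtViX, X.T @ Vi @ ydata)
    r = ydata - X @ b
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return -0.5 * (ldV + ldX + r @ Vi @ r)


def morans_i(values, W):
    """Textbook Moran's I under the binary weight matrix W."""
    z = np.asarray(values, float)
    z = z - z.mean()
    return len(z) / W.sum() * (z @ W @ z) / (z @ z)


def poisson_glm_irls(y, N, x):
    """Plain Poisson GLM with log link and offset, via statsmodels IRLS."""
    import statsmodels.api as smapi
    X = np.column_stack([np.ones_like(np.asarray(x, float)), x])
    res = smapi.GLM(y, X, family=smapi.families.Poisson(),
                    offset=np.log(np.asarray(N, float))).fit()
    return float(res.params[0]), float(res.params[1])
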