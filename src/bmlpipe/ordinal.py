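"""Proportional-odds (cumulative logit) modelling and its score test.

The model for an ordinal outcome with categories ``0 .. J-1`` is
``P(Y <= j | x) = sigmoid(theta_j - x'beta)`` with a single slope vector
shared across thresholds.  The score test of the proportional-odds
assumption evaluates the score of the threshold-specific-slopes
(unconstrained) model at the constrained maximum likelihood estimate:
``S = U' I^{-1} U ~ chi^2 with p*(J-2) df`` under proportionality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.miscmodels.ordinal_model import OrderedModel


def fit_proportional_odds(y: np.ndarray, X: pd.DataFrame):
    """Fit the cumulative logit model; returns the statsmodels result."""
    y = np.asarray(y)
    model = OrderedModel(y, X, distr="logit")
    return model, model.fit(method="bfgs", disp=False)


def _unconstrained_loglik_grad(params, y, X, J):
    """Log-likelihood and analytic score of the threshold-specific-slopes
    cumulative model, parameters ``(theta_1..theta_{J-1}, beta_1.., beta_{J-1})``."""
    n, p = X.shape
    theta = params[:J - 1]
    betas = params[J - 1:].reshape(J - 1, p)
    eta = theta[None, :] - X @ betas.T          # (n, J-1)
    gam = special.expit(eta)
    dgam = gam * (1 - gam)
    # category probabilities
    pad = np.hstack([np.zeros((n, 1)), gam, np.ones((n, 1))])
    probs = np.diff(pad, axis=1)                # (n, J)
    probs = np.clip(probs, 1e-300, None)
    ll = float(np.log(probs[np.arange(n), y]).sum())

    # d ll / d eta_j = (1[y==j] / pi_j - 1[y==j+1] / pi_{j+1}) * gam'(eta_j)
    g_eta = np.zeros((n, J - 1))
    for j in range(J - 1):
        g_eta[:, j] = ((y == j) / probs[:, j]
                       - (y == j + 1) / probs[:, j + 1]) * dgam[:, j]
    grad_theta = g_eta.sum(axis=0)
    grad_beta = np.concatenate(
        [-(g_eta[:, j][:, None] * X).sum(axis=0) for j in range(J - 1)])
    return ll, np.concatenate([grad_theta, grad_beta])


def score_test_proportional_odds(y: np.ndarray, X: pd.DataFrame
                                 ) -> tuple[float, int, float]:
    """Score test of equal slopes across thresholds.

    Returns ``(statistic, df, p_value)``.  ``df = p * (J - 2)``; with only
    three outcome levels this equals the number of predictors.
    """
    y = np.asarray(y).astype(int)
    Xv = np.asarray(X, dtype=float)
    J = int(y.max()) + 1
    p = Xv.shape[1]
    if J < 3:
        raise ValueError("score test needs at least 3 outcome levels")

    model, res = fit_proportional_odds(y, X)
    theta = model.transform_threshold_params(res.params)[1:-1]
    beta = res.params[:p]
    full = np.concatenate([theta, np.tile(beta, J - 1)])

    _, U = _unconstrained_loglik_grad(full, y, Xv, J)
    # observed information via central differences of the analytic score
    dim = full.size
    H = np.zeros((dim, dim))
    h = 1e-5 * np.maximum(1.0, np.abs(full))
    for k in range(dim):
        up, dn = full.copy(), full.copy()
        up[k] += h[k]
        dn[k] -= h[k]
        _, gu = _unconstrained_loglik_grad(up, y, Xv, J)
        _, gd = _unconstrained_loglik_grad(dn, y, Xv, J)
        H[:, k] = (gu - gd) / (2 * h[k])
    info = -(H + H.T) / 2.0
    stat = float(U @ np.linalg.solve(info, U))
    df = p * (J - 2)
    return stat, df, float(stats.chi2.sf(stat, df))
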