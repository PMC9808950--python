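"""Vectorised likelihood engine for paired-choice episodic logit models.

Everything here works on compact arrays extracted from a long-format dataset:
per task, the incremental-dummy encodings of the two alternatives (XA, XB),
their lifespans (TA, TB), the task-level scale design Z3, and the observed
choice y (1 if alternative A was chosen).

The deterministic utility of an alternative is V = (1 - beta'X) * T**alpha and
the probability that A is chosen under scale mu = exp(gamma'z3) is
sigmoid(mu * (V_A - V_B)). The same weighted log-likelihood/gradient routine
serves the pooled conditional and heteroskedastic logits (one taste class, one
scale class, unit weights) and the generalized M-step of the SALC EM (M taste
classes x S scale classes, posterior weights).

Structural parameters are packed as
``[beta_1..beta_M (20 each), log(alpha_1..alpha_M), gamma_1..gamma_S (K each)]``;
alpha is optimised on the log scale to keep it positive.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit

N_BETA = 20


def pack_structural(beta: np.ndarray, log_alpha: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    return np.concatenate([np.ravel(beta), np.ravel(log_alpha), np.ravel(gamma)])


def unpack_structural(theta: np.ndarray, M: int, S: int, K: int):
    beta = theta[: M * N_BETA].reshape(M, N_BETA)
    log_alpha = theta[M * N_BETA : M * N_BETA + M]
    gamma = theta[M * N_BETA + M :].reshape(S, K)
    return beta, log_alpha, gamma


def n_structural(M: int, S: int, K: int) -> int:
    return M * (N_BETA + 1) + S * K


def _powT(T: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """T**alpha broadcast to (n, M); T = 0 maps to 0 for any alpha > 0."""
    return T[:, None] ** alpha[None, :]


def value_diff(XA, XB, TA, TB, beta, alpha):
    """V_A - V_B per task and taste class, shape (n, M)."""
    TAa, TBa = _powT(TA, alpha), _powT(TB, alpha)
    EA = 1.0 - XA @ beta.T
    EB = 1.0 - XB @ beta.T
    return EA * TAa - EB * TBa


def neg_weighted_loglik(theta, arrays, M, S, weights=None, with_grad=True):
    """Negative (posterior-weighted) log-likelihood and its gradient.

    arrays : tuple (XA, XB, TA, TB, Z3, y)
    weights : optional (n, M, S) non-negative weights; unit weights if None.

    Returns (f, grad) if with_grad else f.
    """
    XA, XB, TA, TB, Z3, y = arrays
    K = Z3.shape[1]
    beta, log_alpha, gamma = unpack_structural(theta, M, S, K)
    alpha = np.exp(log_alpha)

    TAa, TBa = _powT(TA, alpha), _powT(TB, alpha)
    EA = 1.0 - XA @ beta.T                      # (n, M)
    EB = 1.0 - XB @ beta.T
    dV = EA * TAa - EB * TBa                    # (n, M)
    mu = np.exp(Z3 @ gamma.T)                   # (n, S)

    eta = dV[:, :, None] * mu[:, None, :]       # (n, M, S)
    sign = 2.0 * y - 1.0                        # +1 if A chosen
    ll_terms = log_expit(sign[:, None, None] * eta)
    if weights is None:
        f = -ll_terms.sum()
    else:
        f = -float(np.sum(weights * ll_terms))
    if not with_grad:
        return f

    resid = y[:, None, None] - expit(eta)       # d loglik / d eta
    G = resid if weights is None else weights * resid

    # gamma: d eta/d gamma_sk = dV * mu * z3_k
    A = np.einsum("tms,tm->ts", G, dV) * mu     # (n, S)
    grad_gamma = A.T @ Z3                       # (S, K)

    # beta: d dV/d beta_mj = -(XA_j TA^a_m - XB_j TB^a_m)
    Gm = np.einsum("tms,ts->tm", G, mu)         # (n, M)
    grad_beta = -((Gm * TAa).T @ XA) + ((Gm * TBa).T @ XB)

    # alpha (chain through a = log alpha)
    lnTA = np.where(TA > 0, np.log(np.where(TA > 0, TA, 1.0)), 0.0)
    lnTB = np.where(TB > 0, np.log(np.where(TB > 0, TB, 1.0)), 0.0)
    dV_dalpha = EA * TAa * lnTA[:, None] - EB * TBa * lnTB[:, None]
    grad_a = alpha * np.einsum("tm,tm->m", Gm, dV_dalpha)

    grad = pack_structural(grad_beta, grad_a, grad_gamma)
    return f, -grad


def task_log_probs(theta, arrays, M, S):
    """Log-probability of each observed choice per (task, m, s), shape (n, M, S)."""
    XA, XB, TA, TB, Z3, y = arrays
    K = Z3.shape[1]
    beta, log_alpha, gamma = unpack_structural(theta, M, S, K)
    alpha = np.exp(log_alpha)
    dV = value_diff(XA, XB, TA, TB, beta, alpha)
    mu = np.exp(Z3 @ gamma.T)
    eta = dV[:, :, None] * mu[:, None, :]
    sign = 2.0 * y - 1.0
    return log_expit(sign[:, None, None] * eta)


def numerical_hessian(grad_fn, theta, rel_step=1e-5):
    """Central-difference Hessian of a scalar function from its gradient."""
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    H = np.empty((p, p))
    for i in range(p):
        h = rel_step * (1.0 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        H[i] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def covariance_from_hessian(H: np.ndarray) -> np.ndarray:
    """Inverse observed information; pseudo-inverse if H is singular."""
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov
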