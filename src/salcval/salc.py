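"""Scale-adjusted latent class (SALC) model estimated by EM.

The population is a mixture of M *taste* classes (each with its own QALY
decrements beta_m and lifespan power alpha_m) crossed with S *scale* classes
(each with its own task-level scale function gamma_s). Separating the two
matters because apparent differences in attribute importance can be an
artefact of some respondents simply answering more noisily: taste classes
differ in *relative* attribute effects, scale classes in the *absolute*
magnitude of all effects (equivalently, in error variance).

Class membership is covariate-driven via multinomial logits: respondent
covariates z1 (demographics, own health, caregiving, cTTO exposure) enter the
taste membership p(m | delta), and a distinct set z2 (stated difficulty,
survey length, demographics) enters the scale membership p(s | theta) — using
separate covariate sets is what makes the taste/scale split empirically
credible. The likelihood of respondent i's task sequence is

    P(y_i) = sum_m p(m|delta) sum_s p(s|theta) prod_t P(y_it | m, s)

with heteroskedastic-logit task probabilities within each (m, s) cell.

Estimation is by a generalized EM: the E-step computes posterior weights over
the M x S grid; the M-step updates the membership logits by weighted
multinomial-logit maximisation, and the structural parameters
{beta_m, alpha_m, gamma_s} by one capped quasi-Newton run on the posterior-
weighted likelihood (they must be updated jointly, since every gamma_s
multiplies every taste class's value difference). Multiple random starts
around the pooled fit guard against local optima; models are compared by BIC
with N = number of respondents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from . import _engine
from .choice_models import (
    ChoiceData,
    LogitFit,
    ScaleClassParams,
    _fit_pooled,
)
from .health_value import TasteClassParams, dummy_names

__all__ = [
    "MembershipParams",
    "SALCModel",
    "FitResult",
    "EMError",
    "build_membership_design",
    "membership_prob",
    "respondent_likelihood",
    "mixture_loglik",
    "em_fit",
    "posterior_membership",
    "model_search",
    "order_classes",
]


class EMError(RuntimeError):
    """Raised when the EM ascent property is violated (a numerical defect)."""


def build_membership_design(
    covariates: pd.DataFrame | None, columns: list[str] | None, n_respondents: int | None = None
) -> tuple[np.ndarray, list[str]]:
    """Membership design matrix with a leading intercept column.

    ``columns`` selects dummy columns from the covariate table; ``None`` or an
    empty list yields an intercept-only design.
    """
    if not columns:
        if n_respondents is None:
            n_respondents = 0 if covariates is None else len(covariates)
        return np.ones((n_respondents, 1)), ["intercept"]
    missing = [c for c in columns if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    Z = np.column_stack(
        [np.ones(len(covariates))] + [covariates[c].to_numpy(dtype=float) for c in columns]
    )
    return Z, ["intercept"] + list(columns)


@dataclass
class MembershipParams:
    """Multinomial-logit membership coefficients; class 1 is the reference.

    ``delta`` has shape (M-1, K1) over the taste design z1, ``theta`` shape
    (S-1, K2) over the scale design z2. Exponentiated coefficients are odds
    ratios of belonging to class m (or s) versus class 1.
    """

    delta: np.ndarray
    theta: np.ndarray
    z1_names: list[str] = field(default_factory=lambda: ["intercept"])
    z2_names: list[str] = field(default_factory=lambda: ["intercept"])
    delta_se: np.ndarray | None = None
    theta_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta = np.atleast_2d(np.asarray(self.delta, dtype=float))
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if self.delta.size == 0:
            self.delta = self.delta.reshape(0, len(self.z1_names))
        if self.theta.size == 0:
            self.theta = self.theta.reshape(0, len(self.z2_names))


@dataclass
class SALCModel:
    """M taste classes x S scale classes plus membership parameters."""

    taste_classes: list[TasteClassParams]
    scale_classes: list[ScaleClassParams]
    membership: MembershipParams

    @property
    def M(self) -> int:
        return len(self.taste_classes)

    @property
    def S(self) -> int:
        return len(self.scale_classes)

    def structural_vector(self) -> np.ndarray:
        return _engine.pack_structural(
            np.stack([t.beta for t in self.taste_classes]),
            np.log([t.alpha for t in self.taste_classes]),
            np.stack([s.gamma for s in self.scale_classes]),
        )


@dataclass
class FitResult:
    """A fitted SALC model with diagnostics."""

    model: SALCModel
    loglik: float
    n_params: int
    bic: float
    converged: bool
    em_iterations: int
    start_index: int
    posterior: np.ndarray          # (R, M, S)
    resp_ids: np.ndarray
    start_logliks: list[float] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list)
    degenerate_classes: bool = False
    message: str = ""

    def taste_shares(self, kind: str = "posterior") -> np.ndarray:
        """Taste-class shares in percent; ``kind`` is 'posterior' or 'prior'."""
        if kind == "posterior":
            return 100.0 * self.posterior.sum(axis=2).mean(axis=0)
        Z1 = getattr(self, "_Z1", None)
        if Z1 is None:
            raise ValueError("prior shares need the stored z1 design")
        return 100.0 * membership_prob(self.model.membership.delta, Z1, self.model.M).mean(axis=0)

    def scale_shares(self) -> np.ndarray:
        return 100.0 * self.posterior.sum(axis=1).mean(axis=0)


def membership_prob(coeffs: np.ndarray, Z: np.ndarray, n_classes: int) -> np.ndarray:
    """Class membership probabilities, shape (n, n_classes).

    ``coeffs`` holds the (n_classes - 1, K) non-reference coefficient rows;
    the reference class has a zero linear index.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    if coeffs.size == 0:
        coeffs = coeffs.reshape(0, Z.shape[1])
    if coeffs.shape != (n_classes - 1, Z.shape[1]):
        raise ValueError(
            f"coefficients shape {coeffs.shape} incompatible with "
            f"{n_classes} classes and {Z.shape[1]} covariates"
        )
    eta = np.concatenate([np.zeros((len(Z), 1)), Z @ coeffs.T], axis=1)
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=1, keepdims=True)


def _log_membership(coeffs, Z, n_classes):
    eta = np.concatenate([np.zeros((len(Z), 1)), Z @ np.atleast_2d(coeffs).T], axis=1) \
        if np.size(coeffs) else np.zeros((len(Z), n_classes))
    return eta - logsumexp(eta, axis=1, keepdims=True)


def _respondent_logp(data: ChoiceData, theta: np.ndarray, M: int, S: int, z3: np.ndarray):
    """Sum task log-probabilities per respondent, shape (R, M, S)."""
    logp = _engine.task_log_probs(theta, data.arrays(z3), M, S)
    L = np.zeros((data.n_respondents, M, S))
    np.add.at(L, data.resp_idx, logp)
    return L


def _e_step(L, log_pm, log_ps):
    """Posterior weights and per-respondent log-likelihoods."""
    logpost = log_pm[:, :, None] + log_ps[:, None, :] + L
    ll_i = logsumexp(logpost, axis=(1, 2))
    w = np.exp(logpost - ll_i[:, None, None])
    return w, ll_i


def mixture_loglik(
    data: ChoiceData, model: SALCModel, Z1: np.ndarray | None = None,
    Z2: np.ndarray | None = None, z3: np.ndarray | None = None,
    merge_matched: bool = True,
):
    """Observed-data log-likelihood and posteriors under a SALC model.

    Returns ``(total_ll, per_respondent_ll, posterior)``.
    """
    M, S = model.M, model.S
    R = data.n_respondents
    if Z1 is None:
        Z1 = np.ones((R, 1))
    if Z2 is None:
        Z2 = np.ones((R, 1))
    if z3 is None:
        K = model.scale_classes[0].gamma.size
        z3, _ = data.scale_design(intercept_only=(K == 1), merge_matched=merge_matched)
    theta = model.structural_vector()
    L = _respondent_logp(data, theta, M, S, z3)
    log_pm = _log_membership(model.membership.delta, Z1, M)
    log_ps = _log_membership(model.membership.theta, Z2, S)
    w, ll_i = _e_step(L, log_pm, log_ps)
    return float(ll_i.sum()), ll_i, w


def respondent_likelihood(
    data: ChoiceData, model: SALCModel, respondent, Z1=None, Z2=None,
) -> float:
    """Mixture likelihood (not log) of one respondent's task sequence."""
    if data.n_tasks == 0:
        raise ValueError("respondent has no tasks")
    _, ll_i, _ = mixture_loglik(data, model, Z1, Z2)
    idx = np.flatnonzero(data.resp_ids == respondent)
    if idx.size == 0:
        raise ValueError(f"unknown respondent {respondent!r}")
    return float(np.exp(ll_i[idx[0]]))


def posterior_membership(
    data: ChoiceData, model: SALCModel, Z1=None, Z2=None,
) -> np.ndarray:
    """Posterior grade-of-membership matrices, shape (R, M, S).

    Rows follow ``data.resp_ids``; each matrix sums to 1. Marginalise over
    axis 2 for taste membership, axis 1 for scale membership.
    """
    _, _, w = mixture_loglik(data, model, Z1, Z2)
    return w


def _fit_weighted_multinomial(Z, wbar, start):
    """Weighted multinomial logit for the membership M-step.

    Maximises sum_i sum_c wbar[i, c] * log softmax(Z @ coef')[i, c] over the
    non-reference coefficient rows.
    """
    n, C = wbar.shape
    K = Z.shape[1]
    if C == 1:
        return np.zeros((0, K)), 0.0

    def negll(flat):
        coeffs = flat.reshape(C - 1, K)
        logp = _log_membership(coeffs, Z, C)
        p = np.exp(logp)
        f = -float(np.sum(wbar * logp))
        grad = -(wbar[:, 1:] - p[:, 1:]).T @ Z  # wbar rows sum to 1
        return f, grad.ravel()

    res = optimize.minimize(
        negll, np.ravel(start), jac=True, method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    f0 = negll(np.ravel(start))[0]
    if res.fun > f0:  # ascent guard
        return np.atleast_2d(start).reshape(C - 1, K), -f0
    return res.x.reshape(C - 1, K), -res.fun


def _n_params(M, S, K3, K1, K2):
    return M * (_engine.N_BETA + 1) + S * K3 + (M - 1) * K1 + (S - 1) * K2


def _make_starts(pooled_theta, M, S, K, n_starts, K1, K2, rng):
    """Random starts: perturb the pooled fit, spread the powers and scale
    intercepts across classes, and draw small random membership intercepts."""
    beta0, a0, gamma0 = _engine.unpack_structural(pooled_theta, 1, 1, K)
    starts = []
    a_spread = np.linspace(-0.7, 0.7, M) if M > 1 else np.zeros(1)
    g_spread = np.linspace(-0.5, 0.5, S) if S > 1 else np.zeros(1)
    for k in range(n_starts):
        noise = 0.0 if (k == 0 and M == 1 and S == 1) else 1.0
        beta = beta0 + noise * rng.normal(0.0, 0.03, size=(M, _engine.N_BETA))
        beta *= 1.0 + noise * rng.normal(0.0, 0.2, size=(M, 1))
        a = a0[0] + a_spread + noise * rng.normal(0.0, 0.15, size=M)
        gamma = np.tile(gamma0, (S, 1)) + noise * rng.normal(0.0, 0.1, size=(S, K))
        gamma[:, 0] += g_spread
        theta = _engine.pack_structural(beta, a, gamma)
        delta = rng.normal(0.0, 0.2, size=(M - 1, K1)) * noise
        th = rng.normal(0.0, 0.2, size=(S - 1, K2)) * noise
        starts.append((theta, delta, th))
    return starts


def _run_em(data, arrays_z3, Z1, Z2, M, S, start, tol, max_iter, gem_maxiter,
            monotone_tol=1e-6):
    """EM iterations from one start; returns state dict."""
    XAetc = arrays_z3
    z3 = XAetc[4]
    theta, delta, thet = start
    ll_old = None
    w = None
    converged = False
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        L = _respondent_logp(data, theta, M, S, z3)
        log_pm = _log_membership(delta, Z1, M)
        log_ps = _log_membership(thet, Z2, S)
        w, ll_i = _e_step(L, log_pm, log_ps)
        ll = float(ll_i.sum())
        trace.append(ll)
        if ll_old is not None:
            if ll < ll_old - monotone_tol * (1.0 + abs(ll_old)):
                raise EMError(
                    f"EM log-likelihood decreased from {ll_old:.8f} to {ll:.8f}"
                )
            if abs(ll - ll_old) < tol * (1.0 + abs(ll_old)):
                converged = True
                break
        ll_old = ll
        # M-step (a): membership logits against posterior marginals
        delta, _ = _fit_weighted_multinomial(Z1, w.sum(axis=2), delta)
        thet, _ = _fit_weighted_multinomial(Z2, w.sum(axis=1), thet)
        # M-step (b): joint structural update (generalized: capped ascent)
        Wt = w[data.resp_idx]
        f0 = _engine.neg_weighted_loglik(theta, XAetc, M, S, Wt, with_grad=False)
        res = optimize.minimize(
            _engine.neg_weighted_loglik, theta, args=(XAetc, M, S, Wt),
            jac=True, method="L-BFGS-B",
            options={"maxiter": gem_maxiter, "ftol": 1e-12},
        )
        if res.fun <= f0:
            theta = res.x
    return {
        "theta": theta, "delta": delta, "thet": thet, "loglik": ll_old,
        "posterior": w, "iterations": it, "converged": converged, "trace": trace,
    }


def em_fit(
    data: ChoiceData,
    M: int,
    S: int,
    Z1: np.ndarray | None = None,
    Z2: np.ndarray | None = None,
    z1_names: list[str] | None = None,
    z2_names: list[str] | None = None,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    intercept_only_scale: bool = False,
    merge_matched: bool = True,
    gem_maxiter: int = 40,
    burn_in: int = 12,
    n_polish: int = 3,
    compute_se: bool = False,
    pooled_fit: LogitFit | None = None,
) -> FitResult:
    """Fit an M-taste x S-scale SALC model by multi-start generalized EM.

    All ``n_starts`` starts (random perturbations around the pooled fit) run
    ``burn_in`` EM iterations; the best ``n_polish`` are iterated to
    convergence (relative log-likelihood change below ``tol``) and the overall
    best is returned with every start's log-likelihood recorded. The EM ascent
    property is asserted on every iteration; a decrease raises :class:`EMError`.
    """
    if M < 1 or S < 1:
        raise ValueError("M and S must be >= 1")
    R = data.n_respondents
    if Z1 is None:
        Z1, z1_names = np.ones((R, 1)), ["intercept"]
    if Z2 is None:
        Z2, z2_names = np.ones((R, 1)), ["intercept"]
    z1_names = z1_names or [f"z1_{j}" for j in range(Z1.shape[1])]
    z2_names = z2_names or [f"z2_{j}" for j in range(Z2.shape[1])]

    z3, z3_names = data.scale_design(intercept_only_scale, merge_matched)
    K = z3.shape[1]
    arrays = data.arrays(z3)
    rng = np.random.default_rng(seed)

    if pooled_fit is None:
        pooled_fit = _fit_pooled(data, intercept_only_scale, merge_matched,
                                 None, False, "pooled-start")
    pooled_theta = _engine.pack_structural(
        pooled_fit.taste.beta, np.log([pooled_fit.taste.alpha]), pooled_fit.scale.gamma
    )

    starts = _make_starts(pooled_theta, M, S, K, n_starts, Z1.shape[1], Z2.shape[1], rng)
    # burn-in phase
    states = []
    for st in starts:
        states.append(_run_em(data, arrays, Z1, Z2, M, S, st,
                              tol, min(burn_in, max_iter), gem_maxiter))
    order = np.argsort([-(s["loglik"] if s["loglik"] is not None else -np.inf)
                        for s in states])
    polish = list(order[: max(1, min(n_polish, n_starts))])
    for idx in polish:
        s = states[idx]
        if not s["converged"]:
            states[idx] = _run_em(
                data, arrays, Z1, Z2, M, S,
                (s["theta"], s["delta"], s["thet"]), tol, max_iter, gem_maxiter,
            )
            states[idx]["iterations"] += s["iterations"]
            states[idx]["trace"] = s["trace"] + states[idx]["trace"]

    start_logliks = [float(s["loglik"]) for s in states]
    best_idx = int(np.argmax([s["loglik"] for s in states]))
    best = states[best_idx]
    if not any(states[i]["converged"] for i in polish):
        warnings.warn("no EM start converged within max_iter; result is flagged")

    beta, log_alpha, gamma = _engine.unpack_structural(best["theta"], M, S, K)
    taste = [TasteClassParams(beta[m], float(np.exp(log_alpha[m]))) for m in range(M)]
    scale = [ScaleClassParams(gamma[s], names=list(z3_names)) for s in range(S)]
    member = MembershipParams(best["delta"], best["thet"],
                              z1_names=list(z1_names), z2_names=list(z2_names))
    model = SALCModel(taste, scale, member)

    prior_m = membership_prob(member.delta, Z1, M).mean(axis=0)
    prior_s = membership_prob(member.theta, Z2, S).mean(axis=0)
    degenerate = bool(min(prior_m.min(), prior_s.min()) < 0.005)
    if degenerate:
        warnings.warn(
            f"near-empty latent class: prior shares taste={prior_m}, scale={prior_s}"
        )

    n_params = _n_params(M, S, K, Z1.shape[1], Z2.shape[1])
    ll = float(best["loglik"])
    result = FitResult(
        model=model, loglik=ll, n_params=n_params,
        bic=float(-2.0 * ll + n_params * np.log(R)),
        converged=bool(best["converged"]), em_iterations=int(best["iterations"]),
        start_index=best_idx, posterior=best["posterior"], resp_ids=data.resp_ids,
        start_logliks=start_logliks, loglik_trace=list(best["trace"]),
        degenerate_classes=degenerate,
    )
    result._Z1, result._Z2, result._z3 = Z1, Z2, z3
    if compute_se:
        _attach_standard_errors(result, data, arrays, Z1, Z2)
    return result


def _obs_score(data, arrays, Z1, Z2, M, S, K, K1, K2, full):
    """Score of the observed-data log-likelihood (Fisher's identity)."""
    n_str = _engine.n_structural(M, S, K)
    theta = full[:n_str]
    delta = full[n_str : n_str + (M - 1) * K1].reshape(M - 1, K1)
    thet = full[n_str + (M - 1) * K1 :].reshape(S - 1, K2)
    z3 = arrays[4]
    L = _respondent_logp(data, theta, M, S, z3)
    log_pm = _log_membership(delta, Z1, M)
    log_ps = _log_membership(thet, Z2, S)
    w, _ = _e_step(L, log_pm, log_ps)
    _, neg_g = _engine.neg_weighted_loglik(theta, arrays, M, S, w[data.resp_idx])
    g_struct = -neg_g
    pm = np.exp(log_pm)
    ps = np.exp(log_ps)
    g_delta = (w.sum(axis=2)[:, 1:] - pm[:, 1:]).T @ Z1 if M > 1 else np.zeros((0, K1))
    g_theta = (w.sum(axis=1)[:, 1:] - ps[:, 1:]).T @ Z2 if S > 1 else np.zeros((0, K2))
    return np.concatenate([g_struct, g_delta.ravel(), g_theta.ravel()])


def _attach_standard_errors(result: FitResult, data, arrays, Z1, Z2) -> None:
    """Observed-information SEs at the EM optimum (delta method for alpha)."""
    model = result.model
    M, S = model.M, model.S
    K = model.scale_classes[0].gamma.size
    K1, K2 = Z1.shape[1], Z2.shape[1]
    full = np.concatenate([
        model.structural_vector(),
        model.membership.delta.ravel(),
        model.membership.theta.ravel(),
    ])
    H = _engine.numerical_hessian(
        lambda th: -_obs_score(data, arrays, Z1, Z2, M, S, K, K1, K2, th), full
    )
    cov = _engine.covariance_from_hessian(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    n_str = _engine.n_structural(M, S, K)
    nb = _engine.N_BETA
    for m, t in enumerate(model.taste_classes):
        t.beta_se = se[m * nb : (m + 1) * nb]
        t.alpha_se = t.alpha * se[M * nb + m]
    for s_i, sc in enumerate(model.scale_classes):
        sc.gamma_se = se[M * (nb + 1) + s_i * K : M * (nb + 1) + (s_i + 1) * K]
    d_se = se[n_str : n_str + (M - 1) * K1]
    t_se = se[n_str + (M - 1) * K1 :]
    model.membership.delta_se = d_se.reshape(M - 1, K1)
    model.membership.theta_se = t_se.reshape(S - 1, K2)


def model_search(
    data: ChoiceData,
    M_grid=(1, 2, 3),
    S_grid=(1, 2),
    **em_kwargs,
) -> list[FitResult]:
    """Fit every (M, S) combination and rank converged fits by BIC ascending.

    Fits that raise are recorded as non-converged placeholder results and sort
    last. Shares one pooled starting fit across the grid.
    """
    if "pooled_fit" not in em_kwargs:
        em_kwargs["pooled_fit"] = _fit_pooled(
            data, em_kwargs.get("intercept_only_scale", False),
            em_kwargs.get("merge_matched", True), None, False, "pooled-start",
        )
    results = []
    for M in M_grid:
        for S in S_grid:
            try:
                results.append(em_fit(data, M, S, **em_kwargs))
            except Exception as exc:  # per-fit failure must not kill the search
                warnings.warn(f"SALC({M},{S}) failed: {exc}")
                results.append(FitResult(
                    model=SALCModel([], [], MembershipParams(np.zeros((0, 1)), np.zeros((0, 1)))),
                    loglik=-np.inf, n_params=0, bic=np.inf, converged=False,
                    em_iterations=0, start_index=-1,
                    posterior=np.zeros((0, M, S)), resp_ids=np.array([]),
                    message=str(exc),
                ))
    return sorted(results, key=lambda r: (not r.converged, r.bic))


def order_classes(obj):
    """Canonical class labelling: taste classes sorted by power alpha
    ascending (quality-of-life oriented first), scale classes by scale
    intercept ascending; alpha ties broken by total decrement descending.
    Membership coefficients are re-referenced to the new first classes, which
    leaves every membership probability — and hence the likelihood — unchanged.
    Accepts a :class:`SALCModel` or a :class:`FitResult`.
    """
    if isinstance(obj, FitResult):
        model = order_classes(obj.model)
        perm_m = _taste_perm(obj.model)
        perm_s = _scale_perm(obj.model)
        post = obj.posterior[:, perm_m][:, :, perm_s] if obj.posterior.size else obj.posterior
        out = FitResult(
            model=model, loglik=obj.loglik, n_params=obj.n_params, bic=obj.bic,
            converged=obj.converged, em_iterations=obj.em_iterations,
            start_index=obj.start_index, posterior=post, resp_ids=obj.resp_ids,
            start_logliks=list(obj.start_logliks),
            loglik_trace=list(obj.loglik_trace),
            degenerate_classes=obj.degenerate_classes, message=obj.message,
        )
        for attr in ("_Z1", "_Z2", "_z3"):
            if hasattr(obj, attr):
                setattr(out, attr, getattr(obj, attr))
        return out

    model: SALCModel = obj
    perm_m, perm_s = _taste_perm(model), _scale_perm(model)
    taste = [model.taste_classes[i] for i in perm_m]
    scale = [model.scale_classes[i] for i in perm_s]
    delta_full = np.vstack([np.zeros((1, model.membership.delta.shape[1])),
                            model.membership.delta])[perm_m]
    theta_full = np.vstack([np.zeros((1, model.membership.theta.shape[1])),
                            model.membership.theta])[perm_s]
    member = MembershipParams(
        delta_full[1:] - delta_full[0],   # re-reference to the new class 1
        theta_full[1:] - theta_full[0],
        z1_names=list(model.membership.z1_names),
        z2_names=list(model.membership.z2_names),
    )
    return SALCModel(taste, scale, member)


def _taste_perm(model: SALCModel) -> list[int]:
    keys = [(t.alpha, -float(t.beta.sum())) for t in model.taste_classes]
    return sorted(range(model.M), key=lambda i: keys[i])


def _scale_perm(model: SALCModel) -> list[int]:
    return sorted(range(model.S), key=lambda i: model.scale_classes[i].gamma[0])


def class_parameter_table(result: FitResult) -> pd.DataFrame:
    """Per-taste-class coefficient table (20 decrements + power per class)."""
    rows = []
    for m, t in enumerate(result.model.taste_classes, start=1):
        names = dummy_names() + ["power"]
        est = np.append(t.beta, t.alpha)
        se = np.append(
            t.beta_se if t.beta_se is not None else np.full(20, np.nan),
            t.alpha_se if t.alpha_se is not None else np.nan,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 2.0 * stats.norm.sf(np.abs(est / se))
        rows.append(pd.DataFrame({
            "taste_class": m, "name": names, "estimate": est,
            "std_error": se, "p_value": p,
        }))
    return pd.concat(rows, ignore_index=True)


def membership_odds_table(result: FitResult) -> pd.DataFrame:
    """Taste-membership odds ratios exp(delta) with delta-method SEs."""
    mem = result.model.membership
    rows = []
    for m in range(mem.delta.shape[0]):
        orr = np.exp(mem.delta[m])
        se = (orr * mem.delta_se[m]) if mem.delta_se is not None else np.full_like(orr, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 2.0 * stats.norm.sf(np.abs(mem.delta[m] / mem.delta_se[m])) \
                if mem.delta_se is not None else np.full_like(orr, np.nan)
        rows.append(pd.DataFrame({
            "taste_class": m + 2, "name": mem.z1_names,
            "odds_ratio": orr, "std_error": se, "p_value": p,
        }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["taste_class", "name", "odds_ratio", "std_error", "p_value"]
    )


def model_to_dict(model: SALCModel) -> dict:
    """JSON-serialisable representation of a SALC model."""
    return {
        "taste_classes": [
            {"beta": t.beta.tolist(), "alpha": t.alpha, "label": t.label}
            for t in model.taste_classes
        ],
        "scale_classes": [
            {"gamma": s.gamma.tolist(), "names": list(s.names)}
            for s in model.scale_classes
        ],
        "membership": {
            "delta": model.membership.delta.tolist(),
            "theta": model.membership.theta.tolist(),
            "z1_names": list(model.membership.z1_names),
            "z2_names": list(model.membership.z2_names),
        },
    }


def model_from_dict(d: dict) -> SALCModel:
    member = MembershipParams(
        delta=np.asarray(d["membership"]["delta"], dtype=float),
        theta=np.asarray(d["membership"]["theta"], dtype=float),
        z1_names=list(d["membership"]["z1_names"]),
        z2_names=list(d["membership"]["z2_names"]),
    )
    return SALCModel(
        [TasteClassParams(np.asarray(t["beta"]), t["alpha"], t.get("label", ""))
         for t in d["taste_classes"]],
        [ScaleClassParams(np.asarray(s["gamma"]), names=list(s["names"]))
         for s in d["scale_classes"]],
        member,
    )


def model_comparison_table(results: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "M": [r.model.M for r in results],
        "S": [r.model.S for r in results],
        "loglik": [r.loglik for r in results],
        "n_params": [r.n_params for r in results],
        "bic": [r.bic for r in results],
        "converged": [r.converged for r in results],
    })
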