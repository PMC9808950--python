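"""Conditional and heteroskedastic logit models for paired episode choices.

Respondents see two health episodes per task and pick the preferred one.
Under a random utility model with extreme-value type 1 errors, the choice
probability for alternative A is

    P(A) = sigmoid( mu * (V_A - V_B) ),    V = (1 - beta'X) * T**alpha

Because V is measured in QALYs while the logit index lives on the log-odds
scale, the scale parameter mu is *estimated* rather than fixed at 1: it is the
conversion factor from QALYs to log odds. The conditional logit (CL) uses a
single constant scale; the heteroskedastic logit (HCL) lets the scale vary
systematically with task format and response time through

    mu_it = exp( gamma' z3_it )

where z3 holds an intercept, a matched-pair indicator, and task-type-specific
response-duration bins (scale and error variance are inversely related, so a
smaller mu means noisier responses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _engine
from .health_value import TasteClassParams, encode_states, dummy_names

__all__ = [
    "TASK_TYPES",
    "DURATION_BINS",
    "ValidationError",
    "ScaleClassParams",
    "ChoiceData",
    "LogitFit",
    "duration_bin",
    "build_scale_design",
    "scale_factor",
    "choice_prob",
    "loglik",
    "fit_cl",
    "fit_hcl",
    "read_choice_csv",
    "write_choice_csv",
]

TASK_TYPES = ("latent_pair", "matched_AB", "matched_BC")

#: Half-open response-time bins in seconds: [1, 15), [15, 30), [30, 60), [60, inf).
DURATION_BINS = ("1-14", "15-29", "30-59", "60+")
_BIN_EDGES = np.array([0.0, 15.0, 30.0, 60.0, np.inf])

REQUIRED_COLUMNS = [
    "respondent_id", "task_id", "task_type", "alt_id",
    "state", "lifespan_years", "duration_sec", "chosen",
]


class ValidationError(ValueError):
    """Raised when a choice dataset violates the long-format contract."""


def duration_bin(seconds) -> np.ndarray:
    """Bin response durations; returns bin labels from :data:`DURATION_BINS`."""
    seconds = np.atleast_1d(np.asarray(seconds, dtype=float))
    if np.any(seconds <= 0):
        raise ValidationError("duration_sec must be positive")
    idx = np.searchsorted(_BIN_EDGES, seconds, side="right") - 1
    return np.asarray(DURATION_BINS)[idx]


def build_scale_design(
    task_type: np.ndarray,
    duration_sec: np.ndarray,
    intercept_only: bool = False,
    merge_matched: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Task-level scale design matrix z3.

    Columns (full design): intercept; matched-pair indicator; latent-pair
    duration bins (reference 15-29 s); matched-pair duration bins (reference
    30-59 s). With ``merge_matched=False`` the A-vs-B and B-vs-C matched pairs
    get separate indicators instead of one.
    """
    task_type = np.asarray(task_type)
    n = len(task_type)
    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(n))]
    if not intercept_only:
        is_latent = task_type == "latent_pair"
        is_matched = ~is_latent
        if merge_matched:
            cols.append(("matched", is_matched.astype(float)))
        else:
            cols.append(("matched_AB", (task_type == "matched_AB").astype(float)))
            cols.append(("matched_BC", (task_type == "matched_BC").astype(float)))
        bins = duration_bin(duration_sec)
        for b in DURATION_BINS:
            if b != "15-29":  # latent-pair reference bin
                cols.append((f"latent:dur{b}", (is_latent & (bins == b)).astype(float)))
        for b in DURATION_BINS:
            if b != "30-59":  # matched-pair reference bin
                cols.append((f"matched:dur{b}", (is_matched & (bins == b)).astype(float)))
    names = [c[0] for c in cols]
    return np.column_stack([c[1] for c in cols]), names


@dataclass
class ScaleClassParams:
    """Coefficients gamma of the log-linear scale function, intercept first.

    ``exp(gamma[0])`` for the reference task is the QALY-to-log-odds
    conversion factor of this scale class.
    """

    gamma: np.ndarray
    names: list[str] = field(default_factory=lambda: ["intercept"])
    gamma_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if len(self.names) != self.gamma.size:
            raise ValueError(
                f"gamma has {self.gamma.size} coefficients but {len(self.names)} names"
            )


def scale_factor(scale: ScaleClassParams, z3: np.ndarray) -> np.ndarray | float:
    """Scale mu = exp(gamma'z3) for one design row or a matrix of rows."""
    z3 = np.asarray(z3, dtype=float)
    if z3.shape[-1] != scale.gamma.size:
        raise ValueError(
            f"z3 has {z3.shape[-1]} columns but gamma has {scale.gamma.size}"
        )
    mu = np.exp(z3 @ scale.gamma)
    return float(mu) if np.ndim(mu) == 0 else mu


@dataclass
class ChoiceData:
    """Compact per-task arrays extracted from a long-format choice dataset."""

    XA: np.ndarray           # (n_tasks, 20) dummies of alternative A
    XB: np.ndarray
    TA: np.ndarray           # lifespans in years
    TB: np.ndarray
    y: np.ndarray            # 1 if A chosen
    task_type: np.ndarray
    duration_sec: np.ndarray
    resp_idx: np.ndarray     # respondent index per task
    resp_ids: np.ndarray     # unique respondent ids, in resp_idx order
    task_ids: np.ndarray

    @property
    def n_tasks(self) -> int:
        return len(self.y)

    @property
    def n_respondents(self) -> int:
        return len(self.resp_ids)

    def scale_design(self, intercept_only=False, merge_matched=True):
        return build_scale_design(
            self.task_type, self.duration_sec, intercept_only, merge_matched
        )

    def arrays(self, z3: np.ndarray):
        return (self.XA, self.XB, self.TA, self.TB, z3, self.y)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChoiceData":
        """Build from a long-format frame (two rows per task, alt A and B)."""
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        df = df.sort_values(["respondent_id", "task_id", "alt_id"], kind="stable")

        bad_type = ~df["task_type"].isin(TASK_TYPES)
        if bad_type.any():
            rows = df.index[bad_type][:5].tolist()
            raise ValidationError(f"unknown task_type in rows {rows}")

        counts = df.groupby(["respondent_id", "task_id"], sort=False).size()
        if (counts != 2).any():
            bad = counts[counts != 2].index[:5].tolist()
            raise ValidationError(
                f"each task needs exactly two alternative rows; offending tasks: {bad}"
            )
        a = df[df["alt_id"] == "A"].reset_index(drop=True)
        b = df[df["alt_id"] == "B"].reset_index(drop=True)
        if len(a) != len(b):
            raise ValidationError("alt_id must be exactly {'A','B'} within each task")

        chosen_sum = a["chosen"].to_numpy() + b["chosen"].to_numpy()
        if np.any(chosen_sum != 1):
            bad = a.loc[chosen_sum != 1, ["respondent_id", "task_id"]].head().values.tolist()
            raise ValidationError(f"exactly one alternative must be chosen; offending tasks: {bad}")

        TA = a["lifespan_years"].to_numpy(dtype=float)
        TB = b["lifespan_years"].to_numpy(dtype=float)
        if np.any(TA < 0) or np.any(TB < 0):
            raise ValidationError("lifespan_years must be non-negative")
        latent = a["task_type"].to_numpy() == "latent_pair"
        if np.any(latent & (TA != TB)):
            bad = a.loc[latent & (TA != TB), ["respondent_id", "task_id"]].head().values.tolist()
            raise ValidationError(
                f"latent_pair tasks must carry a common lifespan; offending tasks: {bad}"
            )

        resp_ids, resp_idx = np.unique(a["respondent_id"].to_numpy(), return_inverse=True)
        return cls(
            XA=encode_states(a["state"]),
            XB=encode_states(b["state"]),
            TA=TA,
            TB=TB,
            y=a["chosen"].to_numpy(dtype=float),
            task_type=a["task_type"].to_numpy(),
            duration_sec=a["duration_sec"].to_numpy(dtype=float),
            resp_idx=resp_idx,
            resp_ids=resp_ids,
            task_ids=a["task_id"].to_numpy(),
        )


def read_choice_csv(path) -> ChoiceData:
    """Read and validate a long-format choice CSV."""
    return ChoiceData.from_frame(pd.read_csv(path, dtype={"state": str}))


def write_choice_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def choice_prob(
    task_or_data,
    taste: TasteClassParams,
    scale: ScaleClassParams,
    z3: np.ndarray | None = None,
):
    """Probability that alternative A is chosen.

    Accepts either a :class:`ChoiceData` (vectorised; ``z3`` optional,
    defaults to the design implied by ``scale.names``) or a tuple
    ``((state_A, T_A), (state_B, T_B))`` with an explicit ``z3`` row.
    """
    from scipy.special import expit

    if isinstance(task_or_data, ChoiceData):
        data = task_or_data
        if z3 is None:
            z3, _ = data.scale_design(intercept_only=(len(scale.names) == 1))
        mu = scale_factor(scale, z3)
        dV = _engine.value_diff(
            data.XA, data.XB, data.TA, data.TB,
            taste.beta[None, :], np.array([taste.alpha]),
        )[:, 0]
        return expit(mu * dV)

    (state_a, t_a), (state_b, t_b) = task_or_data
    if t_a < 0 or t_b < 0:
        raise ValueError("lifespans must be non-negative")
    from .health_value import episode_value

    dv = episode_value((state_a, t_a), taste) - episode_value((state_b, t_b), taste)
    mu = scale_factor(scale, np.ones(1) if z3 is None else z3)
    return float(expit(mu * dv))


def loglik(data: ChoiceData, taste: TasteClassParams, scale: ScaleClassParams,
           merge_matched: bool = True) -> float:
    """Log-likelihood of the observed choices under one taste/scale class."""
    z3, names = data.scale_design(
        intercept_only=(len(scale.names) == 1), merge_matched=merge_matched
    )
    if len(names) != scale.gamma.size:
        raise ValueError(f"scale has {scale.gamma.size} coefficients; design needs {len(names)}")
    theta = _engine.pack_structural(
        taste.beta, np.log([taste.alpha]), scale.gamma
    )
    f = _engine.neg_weighted_loglik(theta, data.arrays(z3), 1, 1, with_grad=False)
    ll = -f
    if not np.isfinite(ll):
        warnings.warn("log-likelihood is -inf under degenerate parameters")
    return ll


@dataclass
class LogitFit:
    """Result of a pooled CL or HCL fit."""

    taste: TasteClassParams
    scale: ScaleClassParams
    loglik: float
    n_params: int
    bic: float
    converged: bool
    n_respondents: int
    message: str = ""
    model: str = "cl"

    def to_table(self) -> pd.DataFrame:
        """Coefficient table: name, estimate, std_error, p_value (Wald)."""
        names = dummy_names() + ["power"] + [f"scale:{n}" for n in self.scale.names]
        est = np.concatenate([self.taste.beta, [self.taste.alpha], self.scale.gamma])
        se = np.concatenate([
            self.taste.beta_se if self.taste.beta_se is not None else np.full(20, np.nan),
            [self.taste.alpha_se if self.taste.alpha_se is not None else np.nan],
            self.scale.gamma_se if self.scale.gamma_se is not None else
            np.full(self.scale.gamma.size, np.nan),
        ])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"name": names, "estimate": est, "std_error": se, "p_value": p}
        )


def _fit_pooled(data: ChoiceData, intercept_only: bool, merge_matched: bool,
                start: np.ndarray | None, compute_se: bool, model: str) -> LogitFit:
    z3, names = data.scale_design(intercept_only, merge_matched)
    K = z3.shape[1]
    arrays = data.arrays(z3)
    if start is None:
        start = _engine.pack_structural(
            np.zeros(20), np.log([0.5]), np.concatenate([[np.log(2.0)], np.zeros(K - 1)])
        )
    res = optimize.minimize(
        _engine.neg_weighted_loglik, start, args=(arrays, 1, 1),
        jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta, log_alpha, gamma = _engine.unpack_structural(res.x, 1, 1, K)
    alpha = float(np.exp(log_alpha[0]))

    beta_se = alpha_se = gamma_se = None
    if compute_se:
        H = _engine.numerical_hessian(
            lambda th: _engine.neg_weighted_loglik(th, arrays, 1, 1)[1], res.x
        )
        cov = _engine.covariance_from_hessian(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        beta_se = se[:20]
        alpha_se = alpha * se[20]  # delta method through a = log(alpha)
        gamma_se = se[21:]

    ll = -res.fun
    n_params = res.x.size
    bic = -2.0 * ll + n_params * np.log(data.n_respondents)
    if not res.success:
        warnings.warn(f"{model} fit did not converge: {res.message}")
    return LogitFit(
        taste=TasteClassParams(beta[0], alpha, label=model,
                               beta_se=beta_se, alpha_se=alpha_se),
        scale=ScaleClassParams(gamma[0], names=names, gamma_se=gamma_se),
        loglik=float(ll), n_params=n_params, bic=float(bic),
        converged=bool(res.success), n_respondents=data.n_respondents,
        message=str(res.message), model=model,
    )


def fit_cl(data: ChoiceData, start: np.ndarray | None = None,
           compute_se: bool = True) -> LogitFit:
    """Conditional logit: one taste class, one constant (but estimated) scale."""
    return _fit_pooled(data, True, True, start, compute_se, "cl")


def fit_hcl(data: ChoiceData, start: np.ndarray | None = None,
            compute_se: bool = True, merge_matched: bool = True) -> LogitFit:
    """Heteroskedastic logit: scale varies with task type and duration bin."""
    return _fit_pooled(data, False, merge_matched, start, compute_se, "hcl")
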