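"""Synthetic EQ-VT-style choice data with known latent-class structure.

Emulates the ordinal arm of an EQ-5D-5L valuation survey: each respondent
completes 10 latent scale pairs (health states only, no lifespan attribute)
followed by 12 matched-pair blocks, each a linked A-vs-B then B-vs-C
comparison over health state plus lifespan. Half the respondents get a shared
lifespan in the first pair of each block, and a configurable fraction
completed cTTO tasks beforehand (which enters only as a covariate). Choices
are simulated forward from a known SALC model: each respondent draws a taste
and a scale class from the covariate-driven membership logits, response
durations come from scale-class-specific log-normals (so duration bins carry
genuine scale signal), and each binary choice is sampled from the logistic
choice probability — equivalent to adding Gumbel noise to the utilities.

The generated tables use the same long CSV dialect the estimation modules
read, so every stage of the pipeline is testable end to end without the
(request-only) study data. The lifespan menu, state pool and duration
distributions are plausible stand-ins, not the study's actual design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choice_models import ChoiceData, build_scale_design
from .health_value import encode_states
from .salc import MembershipParams, SALCModel, build_membership_design, membership_prob
from .choice_models import ScaleClassParams
from .health_value import TasteClassParams
from . import _engine
from . import published

__all__ = [
    "DesignConfig",
    "GroundTruth",
    "generate_design",
    "generate_respondents",
    "simulate_choices",
    "simulate_dataset",
    "default_ground_truth",
    "two_taste_truth",
]


@dataclass
class DesignConfig:
    """Survey-design knobs; defaults mirror the study conditions."""

    n_respondents: int = 1000
    n_latent_pairs: int = 10
    n_matched_blocks: int = 12          # each block = one AB + one BC pair
    lifespans: tuple = (1.0, 2.0, 4.0, 7.0, 10.0, 15.0)
    shared_lifespan_fraction: float = 0.5
    ctto_fraction: float = 0.3
    #: log-normal (mean, sd) of response seconds, one pair per scale class
    duration_lognormal: tuple = ((3.2, 0.7), (2.9, 0.6))
    dominance_filter: bool = True
    #: overrides for respondent covariate distributions (see
    #: :func:`generate_respondents` for recognised keys)
    covariate_probs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.lifespans) == 0 or min(self.lifespans) <= 0:
            raise ValueError("lifespan menu must be non-empty and positive")
        for f in (self.shared_lifespan_fraction, self.ctto_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def tasks_per_respondent(self) -> int:
        return self.n_latent_pairs + 2 * self.n_matched_blocks


@dataclass
class GroundTruth:
    """A full SALC model plus the covariate columns its membership logits use."""

    model: SALCModel
    z1_columns: list = field(default_factory=list)
    z2_columns: list = field(default_factory=list)


# level distributions by severity stratum (mild / moderate / severe blocks)
_STRATA = np.array([
    [0.45, 0.25, 0.15, 0.10, 0.05],
    [0.15, 0.20, 0.30, 0.20, 0.15],
    [0.05, 0.10, 0.15, 0.30, 0.40],
])


def _draw_levels(rng, n, strata_idx):
    """Severity levels (n, 5) with per-row stratum-specific distributions."""
    u = rng.random((n, 5))
    cum = _STRATA.cumsum(axis=1)[strata_idx]          # (n, 5)
    return 1 + (u[:, :, None] > cum[:, None, :]).sum(axis=2)


def _dominated(lev_a, lev_b, t_a=None, t_b=None):
    """True where the pair is weakly ordered on every attribute (ties count)."""
    a_le = np.all(lev_a <= lev_b, axis=1)
    b_le = np.all(lev_b <= lev_a, axis=1)
    if t_a is not None:
        a_le &= t_a >= t_b
        b_le &= t_b >= t_a
    return a_le | b_le


def _nondominated_pair(rng, n, strata_idx, t_a=None, t_b=None, enabled=True):
    """Draw both sides jointly, redrawing whole violating pairs: redrawing
    one side alone can never fix a pair whose other side is 11111 or 55555."""
    lev_a = _draw_levels(rng, n, strata_idx)
    lev_b = _draw_levels(rng, n, strata_idx)
    if enabled:
        for _ in range(500):
            bad = _dominated(lev_a, lev_b, t_a, t_b)
            if not bad.any():
                break
            k = int(bad.sum())
            lev_a[bad] = _draw_levels(rng, k, strata_idx[bad])
            lev_b[bad] = _draw_levels(rng, k, strata_idx[bad])
    return lev_a, lev_b


def _codes(levels):
    return np.array(["".join(map(str, row)) for row in levels])


def generate_design(config: DesignConfig, seed: int = 0) -> pd.DataFrame:
    """Task table: two rows (alternatives A and B) per task per respondent.

    Latent pairs carry a common lifespan of 1 year on both sides so the
    lifespan factor cancels; matched pairs draw lifespans from the menu, with
    the first pair of each block sharing its lifespan inside the shared arm.
    The B alternative of each block is common to its AB and BC pairs, and no
    emitted pair is weakly ordered on all attributes.
    """
    rng = np.random.default_rng(seed)
    R = config.n_respondents
    shared = rng.random(R) < config.shared_lifespan_fraction
    rows = []

    # latent scale pairs: stratify severity across the 10 pairs
    for k in range(config.n_latent_pairs):
        strata = np.full(R, k % 3)
        lev_a, lev_b = _nondominated_pair(rng, R, strata, enabled=config.dominance_filter)
        rows.append((f"L{k + 1:02d}", "latent_pair", _codes(lev_a), _codes(lev_b),
                     np.ones(R), np.ones(R)))

    menu = np.asarray(config.lifespans, dtype=float)
    for b in range(config.n_matched_blocks):
        strata = np.full(R, b % 3)

        def draw_block(k, idx):
            t_a = menu[rng.integers(0, len(menu), k)]
            t_b = np.where(shared[idx], t_a, menu[rng.integers(0, len(menu), k)])
            t_c = menu[rng.integers(0, len(menu), k)]
            return (_draw_levels(rng, k, strata[idx]), _draw_levels(rng, k, strata[idx]),
                    _draw_levels(rng, k, strata[idx]), t_a, t_b, t_c)

        all_idx = np.arange(R)
        lev_a, lev_b, lev_c, t_a, t_b, t_c = draw_block(R, all_idx)
        if config.dominance_filter:
            # redraw whole blocks so the shared B side and lifespans can move
            for _ in range(500):
                bad = _dominated(lev_a, lev_b, t_a, t_b) \
                    | _dominated(lev_b, lev_c, t_b, t_c)
                if not bad.any():
                    break
                idx = np.flatnonzero(bad)
                (lev_a[idx], lev_b[idx], lev_c[idx],
                 t_a[idx], t_b[idx], t_c[idx]) = draw_block(len(idx), idx)
        rows.append((f"M{b + 1:02d}AB", "matched_AB", _codes(lev_a), _codes(lev_b), t_a, t_b))
        rows.append((f"M{b + 1:02d}BC", "matched_BC", _codes(lev_b), _codes(lev_c), t_b, t_c))

    resp = np.arange(1, R + 1)
    frames = []
    for task_id, task_type, code_a, code_b, t_a, t_b in rows:
        for alt, code, t in (("A", code_a, t_a), ("B", code_b, t_b)):
            frames.append(pd.DataFrame({
                "respondent_id": resp, "task_id": task_id, "task_type": task_type,
                "alt_id": alt, "state": code, "lifespan_years": t,
            }))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["respondent_id", "task_id", "alt_id"], kind="stable",
                          ignore_index=True)


def generate_respondents(config: DesignConfig, seed: int = 0) -> pd.DataFrame:
    """Respondent covariate table (all dummies) for the membership designs.

    Binary columns default to plausible population rates; any rate (or the
    ``age``/``vas`` category probability vectors) can be overridden through
    ``config.covariate_probs``.
    """
    rng = np.random.default_rng(seed)
    R = config.n_respondents
    p = {
        "age": [0.30, 0.30, 0.25, 0.15],   # 15-29 / 30-44 / 45-59 / 60-80
        "vas": [0.15, 0.15, 0.30, 0.40],   # <70 / 70-79 / 80-89 / >=90
        "female": 0.5, "own_mo": 0.4, "own_sc": 0.2, "own_ua": 0.3,
        "own_pd": 0.5, "own_ad": 0.4, "care_family": 0.3, "care_self": 0.2,
        "diff_understand": 0.2, "diff_attributes": 0.2, "diff_choose": 0.25,
        "long_survey": 0.3,
    }
    p.update(config.covariate_probs)
    age = rng.choice(4, size=R, p=p["age"])
    vas = rng.choice(4, size=R, p=p["vas"])
    df = pd.DataFrame({
        "respondent_id": np.arange(1, R + 1),
        "age_15_29": (age == 0).astype(int),
        "age_45_59": (age == 2).astype(int),
        "age_60_80": (age == 3).astype(int),
        "female": rng.binomial(1, p["female"], R),
        "vas_lt70": (vas == 0).astype(int),
        "vas_70_79": (vas == 1).astype(int),
        "vas_80_89": (vas == 2).astype(int),
        "own_mo": rng.binomial(1, p["own_mo"], R),
        "own_sc": rng.binomial(1, p["own_sc"], R),
        "own_ua": rng.binomial(1, p["own_ua"], R),
        "own_pd": rng.binomial(1, p["own_pd"], R),
        "own_ad": rng.binomial(1, p["own_ad"], R),
        "care_family": rng.binomial(1, p["care_family"], R),
        "care_self": rng.binomial(1, p["care_self"], R),
        "ctto_completed": rng.binomial(1, config.ctto_fraction, R),
        "diff_understand": rng.binomial(1, p["diff_understand"], R),
        "diff_attributes": rng.binomial(1, p["diff_attributes"], R),
        "diff_choose": rng.binomial(1, p["diff_choose"], R),
        "long_survey": rng.binomial(1, p["long_survey"], R),
    })
    return df


def simulate_choices(
    design: pd.DataFrame,
    respondents: pd.DataFrame,
    truth: GroundTruth,
    seed: int = 0,
    config: DesignConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate durations and choices under a known SALC model.

    Returns ``(dataset, assignments)``: the long-format choice dataset
    (directly consumable by the estimation readers) and the sampled latent
    taste/scale class of each respondent (1-based labels).
    """
    config = config or DesignConfig(n_respondents=respondents.shape[0])
    rng = np.random.default_rng(seed)
    model = truth.model
    M, S = model.M, model.S

    Z1, _ = build_membership_design(respondents, truth.z1_columns, len(respondents))
    Z2, _ = build_membership_design(respondents, truth.z2_columns, len(respondents))
    pm = membership_prob(model.membership.delta, Z1, M)
    ps = membership_prob(model.membership.theta, Z2, S)
    m_i = (rng.random(len(pm))[:, None] > pm.cumsum(axis=1)).sum(axis=1)
    s_i = (rng.random(len(ps))[:, None] > ps.cumsum(axis=1)).sum(axis=1)

    a = design[design["alt_id"] == "A"].reset_index(drop=True)
    b = design[design["alt_id"] == "B"].reset_index(drop=True)
    resp_ids, resp_idx = np.unique(a["respondent_id"].to_numpy(), return_inverse=True)

    # durations from the respondent's scale-class log-normal
    dur_params = np.asarray(config.duration_lognormal, dtype=float)
    if len(dur_params) < S:
        dur_params = np.tile(dur_params, (S, 1))[:S]
    mlog, sdlog = dur_params[s_i[resp_idx], 0], dur_params[s_i[resp_idx], 1]
    duration = np.exp(rng.normal(mlog, sdlog))
    duration = np.clip(duration, 1.0, None)

    K = model.scale_classes[0].gamma.size
    z3, _ = build_scale_design(a["task_type"].to_numpy(), duration,
                               intercept_only=(K == 1))
    beta = np.stack([t.beta for t in model.taste_classes])
    alpha = np.array([t.alpha for t in model.taste_classes])
    dV = _engine.value_diff(
        encode_states(a["state"]), encode_states(b["state"]),
        a["lifespan_years"].to_numpy(float), b["lifespan_years"].to_numpy(float),
        beta, alpha,
    )                                                   # (n, M)
    gamma = np.stack([s.gamma for s in model.scale_classes])
    mu = np.exp(z3 @ gamma.T)                           # (n, S)
    from scipy.special import expit

    eta = mu[np.arange(len(a)), s_i[resp_idx]] * dV[np.arange(len(a)), m_i[resp_idx]]
    y = (rng.random(len(a)) < expit(eta)).astype(int)

    out_a = a.copy()
    out_b = b.copy()
    out_a["duration_sec"] = duration
    out_b["duration_sec"] = duration
    out_a["chosen"] = y
    out_b["chosen"] = 1 - y
    data = pd.concat([out_a, out_b], ignore_index=True).sort_values(
        ["respondent_id", "task_id", "alt_id"], kind="stable", ignore_index=True
    )
    assignments = pd.DataFrame({
        "respondent_id": respondents["respondent_id"].to_numpy(),
        "taste_class": m_i + 1,
        "scale_class": s_i + 1,
    })
    return data, assignments


def simulate_dataset(
    config: DesignConfig, truth: GroundTruth, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Design + respondents + choices with seeds derived from one master seed.

    Returns ``(dataset, respondents, assignments)``.
    """
    children = np.random.SeedSequence(seed).generate_state(3) % (2**31 - 1)
    design = generate_design(config, int(children[0]))
    respondents = generate_respondents(config, int(children[1]))
    data, assignments = simulate_choices(design, respondents, truth,
                                         int(children[2]), config)
    return data, respondents, assignments


def default_ground_truth() -> GroundTruth:
    """Three taste classes with published-magnitude parameters, two scale
    classes, and cTTO/difficulty-driven membership — the forward model used
    for end-to-end exercises."""
    taste = [published.taste_class_params(k) for k in (1, 2, 3)]
    names = ["intercept", "matched",
             "latent:dur1-14", "latent:dur30-59", "latent:dur60+",
             "matched:dur1-14", "matched:dur15-29", "matched:dur60+"]
    shape = np.array([0.0, -0.25, -0.25, -0.10, -0.30, 0.20, 0.10, -0.20])
    scale = [
        ScaleClassParams(shape + np.array([np.log(2.5)] + [0.0] * 7), names=list(names)),
        ScaleClassParams(shape + np.array([np.log(5.0)] + [0.0] * 7), names=list(names)),
    ]
    member = MembershipParams(
        delta=np.array([[0.40, np.log(0.532)], [0.00, np.log(0.371)]]),
        theta=np.array([[0.70, -0.40]]),
        z1_names=["intercept", "ctto_completed"],
        z2_names=["intercept", "diff_understand"],
    )
    return GroundTruth(SALCModel(taste, scale, member),
                       z1_columns=["ctto_completed"], z2_columns=["diff_understand"])


def two_taste_truth(alphas=(0.1, 0.5), mu: float = 4.0) -> GroundTruth:
    """Well-separated two-taste/one-scale truth for recovery exercises:
    a quality-oriented class (large decrements, strong lifespan discounting)
    versus a quantity-oriented class (small decrements, mild discounting),
    equal prior shares, constant scale ``mu``."""
    taste = [
        TasteClassParams(published.taste_class_params(1).beta, alphas[0],
                         label="quality-oriented"),
        TasteClassParams(published.taste_class_params(3).beta, alphas[1],
                         label="quantity-oriented"),
    ]
    scale = [ScaleClassParams(np.array([np.log(mu)]))]
    member = MembershipParams(delta=np.zeros((1, 1)), theta=np.zeros((0, 1)))
    return GroundTruth(SALCModel(taste, scale, member))
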