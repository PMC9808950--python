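"""Episodic QALY value function over EQ-5D-5L health states.

The EQ-5D-5L descriptive system codes a health state by five dimensions
(mobility, self-care, usual activities, pain/discomfort, anxiety/depression),
each at a severity level 1 (no problems) to 5 (extreme problems/unable), so a
state is a 5-digit string such as ``"21345"`` and the system spans
5**5 = 3125 states.

The value of a whole health episode (state Q lived for T years) is modelled
multiplicatively on the QALY scale::

    V = (1 - beta' X) * T**alpha

where ``X`` is a vector of 20 *incremental* severity dummies (four per
dimension, one per level transition 1-2, 2-3, 3-4, 4-5), ``beta`` holds the
QALY decrement of each transition, and the power ``alpha`` relaxes constant
proportionality in lifespan (alpha < 1 means the marginal value of additional
life-years declines, i.e. discounting). Full health for one year anchors the
scale at 1 and immediate death (T = 0) at 0; states may be valued below 0
(worse than dead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "HealthState",
    "EpisodeProfile",
    "TasteClassParams",
    "all_states",
    "encode_state",
    "encode_states",
    "episode_value",
    "value_set",
    "value_range",
    "dummy_names",
]

#: Dimension short codes in canonical order.
DIMENSIONS = ("MO", "SC", "UA", "PD", "AD")

_TRANSITIONS = ("1-2", "2-3", "3-4", "4-5")


def dummy_names() -> list[str]:
    """Names of the 20 incremental dummies in canonical order.

    ``MO:1-2`` is the transition from no problems to slight problems on
    mobility, and so on; the order is dimension-major.
    """
    return [f"{d}:{t}" for d in DIMENSIONS for t in _TRANSITIONS]


@dataclass(frozen=True)
class HealthState:
    """One EQ-5D-5L profile; each level is an integer in 1..5."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for pos, level in enumerate(self.levels):
            if not isinstance(level, (int, np.integer)) or not 1 <= level <= 5:
                raise ValueError(
                    f"invalid severity level {level!r} at position {pos + 1} "
                    f"({DIMENSIONS[pos]}); levels must be integers in 1..5"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return (
            self.mobility,
            self.self_care,
            self.usual_activities,
            self.pain_discomfort,
            self.anxiety_depression,
        )

    @classmethod
    def from_string(cls, code: str) -> "HealthState":
        """Parse a 5-character state code such as ``"21345"``."""
        code = str(code)
        if len(code) != 5:
            raise ValueError(
                f"state code {code!r} has length {len(code)}; expected 5 digits"
            )
        levels = []
        for pos, ch in enumerate(code):
            if ch not in "12345":
                raise ValueError(
                    f"invalid digit {ch!r} at position {pos + 1} of state code "
                    f"{code!r}; each digit must be 1-5"
                )
            levels.append(int(ch))
        return cls(*levels)

    def __str__(self) -> str:
        return "".join(str(v) for v in self.levels)


@dataclass(frozen=True)
class EpisodeProfile:
    """A health episode: an EQ-5D-5L state lived for ``lifespan_years``.

    ``lifespan_years == 0`` denotes immediate death.
    """

    state: HealthState
    lifespan_years: float

    def __post_init__(self) -> None:
        if self.lifespan_years < 0:
            raise ValueError(
                f"lifespan_years must be non-negative, got {self.lifespan_years}"
            )


@dataclass
class TasteClassParams:
    """Value-function parameters of one taste class.

    beta : 20 QALY decrements aligned with :func:`dummy_names`. Hypothesised
        positive (problems reduce value) but not constrained.
    alpha : positive lifespan power; alpha < 1 implies discounting.
    """

    beta: np.ndarray
    alpha: float
    label: str = ""
    beta_se: np.ndarray | None = field(default=None, repr=False)
    alpha_se: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (20,):
            raise ValueError(f"beta must have shape (20,), got {self.beta.shape}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


def _as_state(state: HealthState | str) -> HealthState:
    return state if isinstance(state, HealthState) else HealthState.from_string(state)


def encode_state(state: HealthState | str) -> np.ndarray:
    """Incremental-dummy encoding of a state.

    A dimension at level L activates the first L-1 of its four transition
    dummies, so ``beta @ encode_state(s)`` is the cumulative QALY decrement of
    ``s`` relative to full health.
    """
    st = _as_state(state)
    x = np.zeros(20)
    for d, level in enumerate(st.levels):
        x[4 * d : 4 * d + level - 1] = 1.0
    return x


def encode_states(codes) -> np.ndarray:
    """Vectorised :func:`encode_state` over an iterable of state codes.

    Returns an (n, 20) array.
    """
    codes = [str(c) for c in codes]
    levels = np.array([[int(ch) for ch in HealthState.from_string(c).levels] for c in codes])
    # prefix-of-ones pattern: dummy k (0-based within dimension) active iff level > k+1
    k = np.arange(1, 5)
    return (levels[:, :, None] > k[None, None, :]).reshape(len(codes), 20).astype(float)


def episode_value(
    episode: EpisodeProfile | tuple,
    params: TasteClassParams,
) -> float:
    """Value ``(1 - beta'X) * T**alpha`` of a health episode on the QALY scale."""
    if not isinstance(episode, EpisodeProfile):
        state, t = episode
        episode = EpisodeProfile(_as_state(state), float(t))
    decrement = float(params.beta @ encode_state(episode.state))
    return (1.0 - decrement) * episode.lifespan_years ** params.alpha


def all_states() -> list[str]:
    """All 3125 EQ-5D-5L state codes in lexicographic order."""
    grids = np.meshgrid(*[np.arange(1, 6)] * 5, indexing="ij")
    codes = np.stack([g.ravel() for g in grids], axis=1)
    return ["".join(map(str, row)) for row in codes]


def value_set(params: TasteClassParams) -> pd.DataFrame:
    """Tabulate values of all 3125 states at T = 1 year.

    Returns a DataFrame with columns ``state`` (5-char code, lexicographic
    order) and ``value``.
    """
    codes = all_states()
    x = encode_states(codes)
    values = 1.0 - x @ params.beta  # T = 1 so the lifespan factor is 1
    return pd.DataFrame({"state": codes, "value": values})


def value_range(params: TasteClassParams) -> tuple[float, float]:
    """(min, max) of the value set over the 3124 states other than full health.

    Full health ``11111`` is the anchor (value exactly 1) and is excluded, so
    the maximum reflects the mildest actual health loss — or gain, when a
    level-1-to-2 coefficient is estimated negative.
    """
    vs = value_set(params)
    vals = vs.loc[vs["state"] != "11111", "value"]
    return float(vals.min()), float(vals.max())
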