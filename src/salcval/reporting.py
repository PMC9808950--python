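"""Post-estimation comparisons and file output.

Includes Lin's concordance correlation coefficient (agreement of two
coefficient vectors around the 45-degree line — used to compare conditional
and heteroskedastic value sets), per-dimension QALY burden profiles, and the
CSV writers for value sets and coefficient tables. All CSV output uses fixed
6-decimal formatting so golden files diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .health_value import DIMENSIONS, TasteClassParams, value_set

__all__ = [
    "lin_ccc",
    "burden_profile",
    "write_value_set_csv",
    "write_table_csv",
    "write_manifest",
]


def lin_ccc(x, y, ci: bool = False, level: float = 0.95):
    """Lin's concordance correlation coefficient.

    Uses population (n-denominator) moments:
    ``ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))**2)``.
    With ``ci=True`` also returns a two-sided confidence interval from the
    Fisher z-transform with Lin's asymptotic variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    if vx + vy == 0.0:
        raise ValueError("both vectors are constant")
    sxy = ((x - mx) * (y - my)).mean()
    ccc = 2.0 * sxy / (vx + vy + (mx - my) ** 2)
    if not ci:
        return float(ccc)

    from scipy import stats

    r = sxy / np.sqrt(vx * vy) if vx > 0 and vy > 0 else np.nan
    u = (mx - my) / (vx * vy) ** 0.25
    z = np.arctanh(ccc)
    var_z = (
        (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - ccc**2) ** 2)
        - ccc**4 * u**4 / (2 * r**2 * (1 - ccc**2) ** 2)
    ) / (n - 2)
    half = stats.norm.ppf(0.5 + level / 2.0) * np.sqrt(var_z)
    return float(ccc), float(np.tanh(z - half)), float(np.tanh(z + half))


def burden_profile(params: TasteClassParams) -> pd.DataFrame:
    """Value at T = 1 of each single-dimension worst case (one dimension at
    level 5, the rest at level 1): 1 minus the sum of that dimension's four
    incremental decrements."""
    sums = params.beta.reshape(5, 4).sum(axis=1)
    return pd.DataFrame({
        "dimension": list(DIMENSIONS),
        "state": ["".join("5" if i == d else "1" for i in range(5)) for d in range(5)],
        "value": 1.0 - sums,
    })


def write_value_set_csv(params: TasteClassParams, path) -> None:
    """Export the 3125-state value set at T = 1 (state, value; 6 decimals)."""
    vs = value_set(params)
    vs.to_csv(path, index=False, float_format="%.6f")


def write_table_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def write_manifest(path, config: dict, seed: int, extra: dict | None = None) -> None:
    """Reproducibility manifest: config, its hash, seed, package version."""
    from . import __version__

    payload = {
        "package": "salcval",
        "version": __version__,
        "seed": int(seed),
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
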