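"""Half-life estimation from actinomycin-D chase time courses.

Each replicate's relative abundances are renormalized to its own t=0
measurement and fitted by ordinary least squares of log abundance on time
with a free intercept; the decay constant is the negated slope and the
half-life is ln2/k.  A non-positive decay constant yields a "no decay
detected" status with a non-finite half-life.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

LN2 = float(np.log(2.0))


@dataclass
class DecayFit:
    condition: str
    k: float                 # decay constant, 1/min
    half_life: float         # min; inf when no decay detected
    fit_r2: float
    status: str              # "ok" | "no decay detected"
    n_replicates: int = 1
    replicate_half_lives: list[float] = field(default_factory=list)


def _fit_loglinear(times: np.ndarray, abundances: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln(abundance) on time; returns (k, half_life, r2)."""
    if np.unique(times).size < 3:
        raise ValueError("need >= 3 distinct time points")
    if (abundances <= 0).any():
        raise ValueError("abundances must be > 0")
    res = sps.linregress(times, np.log(abundances))
    k = -float(res.slope)
    r2 = float(res.rvalue ** 2)
    half_life = LN2 / k if k > 0 else float("inf")
    return k, half_life, r2


def fit_decay(
    series: pd.DataFrame,
    condition: str | None = None,
    pooling: str = "per-replicate",
) -> DecayFit:
    """Fit one condition's decay series.

    ``series`` needs columns replicate / time_min / rel_abundance (a
    ``condition`` column is filtered when ``condition`` is given).
    ``pooling='per-replicate'`` fits each replicate separately after t=0
    renormalization and averages the estimates; ``'pooled'`` fits all
    renormalized points jointly.
    """
    if pooling not in ("per-replicate", "pooled"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    df = series
    if condition is not None:
        df = df[df["condition"] == condition]
    if df.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    label = condition if condition is not None else str(df.get("condition", pd.Series(["?"])).iloc[0])
    if (df["rel_abundance"] <= 0).any():
        raise ValueError("abundances must be > 0")

    normed = []
    for rep, sub in df.groupby("replicate"):
        sub = sub.sort_values("time_min")
        t0 = sub[sub["time_min"] == 0]
        if t0.empty:
            raise ValueError(f"replicate {rep}: no t=0 measurement")
        scale = float(t0["rel_abundance"].iloc[0])
        normed.append(
            (rep, sub["time_min"].to_numpy(float), sub["rel_abundance"].to_numpy(float) / scale)
        )

    if pooling == "pooled":
        times = np.concatenate([t for _, t, _ in normed])
        abund = np.concatenate([a for _, _, a in normed])
        k, half_life, r2 = _fit_loglinear(times, abund)
        status = "ok" if k > 0 else "no decay detected"
        return DecayFit(label, k, half_life, r2, status, n_replicates=len(normed))

    ks, hs, r2s = [], [], []
    for _rep, times, abund in normed:
        k, h, r2 = _fit_loglinear(times, abund)
        ks.append(k)
        hs.append(h)
        r2s.append(r2)
    k_mean = float(np.mean(ks))
    finite = [h for h in hs if np.isfinite(h)]
    if k_mean > 0 and len(finite) == len(hs):
        half_life = float(np.mean(hs))
        status = "ok"
    else:
        half_life = float("inf")
        status = "no decay detected"
    return DecayFit(
        label, k_mean, half_life, float(np.mean(r2s)), status,
        n_replicates=len(normed), replicate_half_lives=hs,
    )


def fit_all_conditions(series: pd.DataFrame, pooling: str = "per-replicate") -> pd.DataFrame:
    """One fitted row per condition in the decay table."""
    rows = []
    for condition in sorted(series["condition"].unique()):
        fit = fit_decay(series, condition, pooling=pooling)
        rows.append(
            {
                "condition": fit.condition,
                "n_reps": fit.n_replicates,
                "k": fit.k,
                "half_life_min": fit.half_life,
                "fit_r2": fit.fit_r2,
                "status": fit.status,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HalfLifeComparison:
    condition_a: str
    condition_b: str
    half_life_a: float
    half_life_b: float
    delta: float                  # b - a, min
    ratio: float
    ci_low: float                 # bootstrap interval on delta
    ci_high: float
    status: str                   # "ok" | "indeterminate"


def compare_half_lives(
    series: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> HalfLifeComparison:
    """Difference report between two conditions with a bootstrap interval on
    the half-life difference (resampling replicates with replacement)."""
    fit_a = fit_decay(series, condition_a)
    fit_b = fit_decay(series, condition_b)
    if not (np.isfinite(fit_a.half_life) and np.isfinite(fit_b.half_life)):
        return HalfLifeComparison(
            condition_a, condition_b, fit_a.half_life, fit_b.half_life,
            float("nan"), float("nan"), float("nan"), float("nan"),
            status="indeterminate",
        )
    delta = fit_b.half_life - fit_a.half_life
    ratio = fit_b.half_life / fit_a.half_life

    rng = np.random.default_rng(seed)
    hs_a = np.asarray(fit_a.replicate_half_lives or [fit_a.half_life])
    hs_b = np.asarray(fit_b.replicate_half_lives or [fit_b.half_life])
    boot = (
        hs_b[rng.integers(0, len(hs_b), size=(n_boot, len(hs_b)))].mean(axis=1)
        - hs_a[rng.integers(0, len(hs_a), size=(n_boot, len(hs_a)))].mean(axis=1)
    )
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return HalfLifeComparison(
        condition_a, condition_b, fit_a.half_life, fit_b.half_life,
        float(delta), float(ratio), float(lo), float(hi), status="ok",
    )
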