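"""Monte-Carlo estimation of power, false-positive rate and effect-size inflation.

Power is estimated as the fraction of replications in which the two-sided
Pearson correlation test rejects at the chosen alpha.  Alongside power, the
engine records the mean of the *significant* correlation estimates — the
effect size a literature affected by a file-drawer problem would report —
which quantifies inflation under selection on significance and under
variance-enriched (extreme-group) sampling.

All replications are vectorized: a grid cell at 10,000 replications runs in
well under a second on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .population import LatentSpec, Population, generate_latent_population, generate_population
from .sampling import SamplingPlan, draw_samples

__all__ = [
    "PowerResult",
    "pearson_test",
    "estimate_power",
    "run_grid",
    "prescreen_factor_sweep",
]

DEFAULT_REPS = 10_000


@dataclass(frozen=True)
class PowerResult:
    """One Monte-Carlo summary: power and mean significant effect size.

    ``mean_sig_r`` is the signed mean of the correlation estimates among the
    significant replications; it is NaN when no replication is significant.
    """

    r_o: float
    n: int
    plan: SamplingPlan
    n_reps: int
    alpha: float
    power: float
    mean_sig_r: float
    n_sig: int


def _pearson_batch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and two-sided t-test p for (reps, n) arrays."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    denom = sx * sy
    if np.any(denom == 0):
        raise ValueError("constant input vector: correlation undefined")
    r = (xc * yc).sum(axis=1) / denom
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return r, p


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value (t, n-2 df).

    Raises on constant inputs or fewer than 4 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    r, p = _pearson_batch(x[None, :], y[None, :])
    return float(r[0]), float(p[0])


def _resolve_population(
    pop_or_spec: Population | LatentSpec | float,
    seed: np.random.SeedSequence,
    pop_size: int,
) -> Population:
    if isinstance(pop_or_spec, Population):
        return pop_or_spec
    if isinstance(pop_or_spec, LatentSpec):
        return generate_latent_population(pop_or_spec, size=pop_size, seed=seed)
    return generate_population(float(pop_or_spec), size=pop_size, seed=seed)


def estimate_power(
    pop_or_spec: Population | LatentSpec | float,
    plan: SamplingPlan,
    n_reps: int = DEFAULT_REPS,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence | None = None,
    pop_size: int = 1_000_000,
    abs_effect: bool = False,
) -> PowerResult:
    """Monte-Carlo power of the Pearson test under a sampling plan.

    Parameters
    ----------
    pop_or_spec
        A ready :class:`Population`, a :class:`LatentSpec`, or a float
        observable correlation (a direct-mode population is generated).
    plan
        Sampling scheme, final n, prescreening factor, dropout settings.
    n_reps
        Number of independent replications (>= 100).
    abs_effect
        If True, ``mean_sig_r`` averages |r| instead of signed r.

    Deterministic given ``seed`` and parameters.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pop_ss, draw_ss = ss.spawn(2)
    pop = _resolve_population(pop_or_spec, pop_ss, pop_size)
    rng = np.random.default_rng(draw_ss)
    x, y = draw_samples(pop, plan, n_reps, rng)
    r, p = _pearson_batch(x, y)
    sig = p < alpha
    n_sig = int(sig.sum())
    power = n_sig / n_reps
    if n_sig > 0:
        vals = np.abs(r[sig]) if abs_effect else r[sig]
        mean_sig_r = float(vals.mean())
    else:
        import warnings

        warnings.warn("no significant replication; mean_sig_r is NaN", stacklevel=2)
        mean_sig_r = math.nan
    return PowerResult(
        r_o=pop.r_target,
        n=plan.n,
        plan=plan,
        n_reps=n_reps,
        alpha=alpha,
        power=power,
        mean_sig_r=mean_sig_r,
        n_sig=n_sig,
    )


def _result_row(res: PowerResult) -> dict:
    return {
        "r_o": res.r_o,
        "n": res.n,
        "scheme": res.plan.scheme,
        "factor": res.plan.prescreen_factor,
        "n_reps": res.n_reps,
        "power": res.power,
        "mean_sig_r": res.mean_sig_r,
        "n_sig": res.n_sig,
    }


def run_grid(
    r_o_values: list[float] | None = None,
    n_values: list[int] | None = None,
    plans: list[dict] | None = None,
    n_reps: int = DEFAULT_REPS,
    alpha: float = 0.05,
    seed: int | None = None,
    pop_size: int = 1_000_000,
) -> pd.DataFrame:
    """Power over a grid of (r_o, n, plan), one population per r_o level.

    ``plans`` is a list of dicts with keys accepted by :class:`SamplingPlan`
    except ``n`` (filled from the n grid); default is the no-prescreening
    random scheme.  Default grids are r_o in {0, 0.1, ..., 0.9} and n in
    {20, 30, ..., 120}.  Each cell runs on its own substream derived from
    the master seed, so results are reproducible and order-independent.

    Returns a long-format DataFrame, one row per cell.
    """
    if r_o_values is None:
        r_o_values = [round(0.1 * k, 1) for k in range(10)]
    if n_values is None:
        n_values = list(range(20, 121, 10))
    if plans is None:
        plans = [{"scheme": "random", "prescreen_factor": 1}]
    if not r_o_values or not n_values or not plans:
        raise ValueError("grids must be nonempty")
    master = np.random.SeedSequence(seed)
    rows = []
    for i, r_o in enumerate(r_o_values):
        pop = generate_population(
            r_o, size=pop_size, seed=np.random.SeedSequence(entropy=master.entropy or 0, spawn_key=(1, i))
        )
        for j, n in enumerate(n_values):
            for k, plan_kw in enumerate(plans):
                plan = SamplingPlan(n=n, **plan_kw)
                cell_ss = np.random.SeedSequence(
                    entropy=master.entropy or 0, spawn_key=(2, i, j, k)
                )
                res = estimate_power(
                    pop, plan, n_reps=n_reps, alpha=alpha, seed=cell_ss
                )
                rows.append(_result_row(res))
    return pd.DataFrame(rows)


def prescreen_factor_sweep(
    r_o: float,
    n_values: list[int],
    factors: list[int],
    n_reps: int = DEFAULT_REPS,
    alpha: float = 0.05,
    seed: int | None = None,
    pop_size: int = 1_000_000,
    scheme: str = "extreme",
) -> pd.DataFrame:
    """Power per (n, prescreening factor) at a fixed observable correlation.

    Factor 1 is simple random sampling (nothing to select away).  Shows how
    much scanned sample size can be traded against behavioral prescreening.
    """
    if any(f < 1 for f in factors):
        raise ValueError("factors must be >= 1")
    master = np.random.SeedSequence(seed)
    pop = generate_population(
        r_o, size=pop_size, seed=np.random.SeedSequence(entropy=master.entropy or 0, spawn_key=(1,))
    )
    rows = []
    for j, n in enumerate(n_values):
        for k, factor in enumerate(factors):
            if factor == 1:
                plan = SamplingPlan(scheme="random", n=n)
            else:
                plan = SamplingPlan(scheme=scheme, n=n, prescreen_factor=factor)
            cell_ss = np.random.SeedSequence(
                entropy=master.entropy or 0, spawn_key=(2, j, k)
            )
            res = estimate_power(pop, plan, n_reps=n_reps, alpha=alpha, seed=cell_ss)
            rows.append(_result_row(res))
    return pd.DataFrame(rows)
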