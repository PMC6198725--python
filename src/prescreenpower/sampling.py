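"""Sampling schemes: simple random, extreme-group, and even-coverage.

A study sample of final size n is drawn from a synthetic population.  Under
prescreening, a larger behavioral pool of ``n * prescreen_factor`` is drawn
first and the scanned subsample is selected on the behavioral values x only:

* ``extreme`` — retain the n/2 lowest and n/2 highest x in the pool.  This
  enriches the in-sample behavioral variance, which is what boosts the power
  of the Pearson correlation test.
* ``even`` — retain n observations whose x values cover the pool's range as
  evenly as possible (greedy nearest-neighbour assignment to equally spaced
  targets).  Suited to discriminating functional forms rather than detecting
  a monotone association.

Brain values y are "revealed" only for the retained participants, modelling
that only selected participants are scanned.  Optional dropout models
invitees declining the scanning session: more than n/2 per tail are invited
and a uniformly random subset is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import Population

__all__ = [
    "SamplingPlan",
    "draw_sample",
    "draw_samples",
    "even_coverage_select",
    "apply_dropout",
]

SCHEMES = ("random", "extreme", "even")


@dataclass(frozen=True)
class SamplingPlan:
    """How a scanned sample of size n is drawn from a population.

    Parameters
    ----------
    scheme
        "random", "extreme" (tail selection) or "even" (range coverage).
    n
        Final scanned sample size.  Must be even for scheme="extreme".
    prescreen_factor
        Behavioral pool size as a multiple of n (1 for scheme="random").
    dropout_rate
        Anticipated proportion of invitees lost before scanning (extreme
        scheme only).  When > 0 and ``invited_per_tail`` is not given,
        ``round(n/2 * (1 + dropout_rate))`` participants are invited per
        tail and n/2 of them retained uniformly at random.
    invited_per_tail
        Explicit invited count per tail, overriding the rate-derived value.
    seed
        Optional default seed for :func:`draw_sample`.
    """

    scheme: str
    n: int
    prescreen_factor: int = 1
    dropout_rate: float = 0.0
    invited_per_tail: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if self.n < 4:
            raise ValueError(f"n must be >= 4, got {self.n}")
        if self.prescreen_factor < 1:
            raise ValueError("prescreen_factor must be >= 1")
        if self.scheme == "random" and self.prescreen_factor != 1:
            raise ValueError("scheme='random' requires prescreen_factor = 1")
        if self.scheme == "extreme" and self.n % 2 != 0:
            raise ValueError("scheme='extreme' splits n/2 per tail; n must be even")
        if not 0.0 <= self.dropout_rate < 0.5:
            raise ValueError("dropout_rate must be in [0, 0.5)")
        if (self.dropout_rate > 0 or self.invited_per_tail is not None) and self.scheme != "extreme":
            raise ValueError("dropout is modelled for scheme='extreme' only")
        if self.invited_per_tail is not None:
            if self.invited_per_tail < self.n // 2:
                raise ValueError("invited_per_tail must be >= n/2")
            if 2 * self.invited_per_tail > self.pool_size:
                raise ValueError("invited_per_tail exceeds half the prescreening pool")

    @property
    def pool_size(self) -> int:
        return self.n * self.prescreen_factor

    @property
    def effective_invited_per_tail(self) -> int:
        """Invited count per tail after resolving dropout settings."""
        if self.scheme != "extreme":
            return 0
        if self.invited_per_tail is not None:
            return self.invited_per_tail
        if self.dropout_rate > 0:
            return min(
                self.pool_size // 2, round(self.n / 2 * (1 + self.dropout_rate))
            )
        return self.n // 2


def even_coverage_select(x_values: np.ndarray, n: int) -> np.ndarray:
    """Select n indices whose x values cover the range as evenly as possible.

    n target points are equally spaced from min(x) to max(x); each target,
    in order, is greedily assigned the nearest observation not yet selected
    (ties broken toward the lower value).  The pool minimum and maximum are
    always selected.

    Returns
    -------
    ndarray of int
        n distinct indices into ``x_values``.
    """
    x_values = np.asarray(x_values, dtype=float)
    m = len(x_values)
    if n > m:
        raise ValueError(f"cannot select {n} from a pool of {m}")
    if n == m:
        return np.arange(m)
    order = np.argsort(x_values, kind="stable")
    vals = x_values[order]
    targets = np.linspace(vals[0], vals[-1], n)
    avail = np.ones(m, dtype=bool)
    chosen = np.empty(n, dtype=np.int64)
    for k, t in enumerate(targets):
        pos = int(np.searchsorted(vals, t))
        left = pos - 1
        while left >= 0 and not avail[left]:
            left -= 1
        right = pos
        while right < m and not avail[right]:
            right += 1
        if left < 0:
            pick = right
        elif right >= m:
            pick = left
        else:
            # tie -> lower value
            pick = left if (t - vals[left]) <= (vals[right] - t) else right
        avail[pick] = False
        chosen[k] = order[pick]
    return chosen


def apply_dropout(
    invited_per_tail: int,
    retained_per_tail: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Positions (0-based, within one invited tail) retained after dropout.

    The invited tail holds the ``invited_per_tail`` most extreme
    participants; a uniformly random subset of ``retained_per_tail`` of them
    accepts the scanning invitation.  Acceptance is assumed independent of
    the trait value.
    """
    if retained_per_tail > invited_per_tail:
        raise ValueError("retained_per_tail must be <= invited_per_tail")
    if retained_per_tail == invited_per_tail:
        return np.arange(invited_per_tail)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.sort(rng.choice(invited_per_tail, size=retained_per_tail, replace=False))


def _select_extreme_rows(
    x_pool: np.ndarray, n: int, invited_per_tail: int, rng: np.random.Generator
) -> np.ndarray:
    """Column indices of retained observations, per row of a pooled draw.

    ``x_pool`` has shape (n_reps, pool_size).  Returns (n_reps, n) column
    indices: the n/2 lowest and n/2 highest x per row, routed through the
    invitation/dropout step when ``invited_per_tail > n/2``.
    """
    half = n // 2
    reps, m = x_pool.shape
    order = np.argsort(x_pool, axis=1, kind="stable")
    low_inv = order[:, :invited_per_tail]
    high_inv = order[:, m - invited_per_tail:]
    if invited_per_tail == half:
        return np.concatenate([low_inv, high_inv], axis=1)
    # uniform random subset of invitees per tail: rank random keys
    keys_low = rng.random((reps, invited_per_tail))
    keys_high = rng.random((reps, invited_per_tail))
    keep_low = np.argpartition(keys_low, half - 1, axis=1)[:, :half]
    keep_high = np.argpartition(keys_high, half - 1, axis=1)[:, :half]
    low = np.take_along_axis(low_inv, keep_low, axis=1)
    high = np.take_along_axis(high_inv, keep_high, axis=1)
    return np.concatenate([low, high], axis=1)


def draw_samples(
    pop: Population,
    plan: SamplingPlan,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_reps`` independent samples under ``plan``, vectorized.

    Each replication draws ``n * prescreen_factor`` population indices with
    replacement and applies the scheme's selection on x only.  Returns
    (x, y) arrays of shape (n_reps, n).
    """
    m = plan.pool_size
    if pop.size <= m:
        raise ValueError(
            f"population of size {pop.size} too small for pool of {m}"
        )
    idx = rng.integers(0, pop.size, size=(n_reps, m))
    x_pool = pop.x[idx]
    if plan.scheme == "random":
        cols = None
    elif plan.scheme == "extreme":
        cols = _select_extreme_rows(
            x_pool, plan.n, plan.effective_invited_per_tail, rng
        )
    else:  # even
        cols = np.empty((n_reps, plan.n), dtype=np.int64)
        for i in range(n_reps):
            cols[i] = even_coverage_select(x_pool[i], plan.n)
    if cols is None:
        sel_idx = idx
        x_sel = x_pool
    else:
        sel_idx = np.take_along_axis(idx, cols, axis=1)
        x_sel = np.take_along_axis(x_pool, cols, axis=1)
    # y revealed only for the retained participants
    y_sel = pop.y[sel_idx]
    return x_sel, y_sel


def draw_sample(
    pop: Population,
    plan: SamplingPlan,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a single study sample (x, y) of length ``plan.n``."""
    if seed is None:
        seed = plan.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, y = draw_samples(pop, plan, 1, rng)
    return x[0], y[0]
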