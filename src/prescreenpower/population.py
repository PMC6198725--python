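"""Synthetic bivariate populations with a controlled observable correlation.

Three generation modes:

* ``direct`` — behavioral values x ~ N(0,1), brain values
  ``y = r_o * x + sqrt(1 - r_o^2) * e`` with independent e ~ N(0,1), so both
  marginals are standard normal and corr(x, y) = r_o by construction.  The
  realized correlation is checked against a tolerance (default 0.01) and the
  draw is rejected and repeated if outside it.
* ``latent`` — a true-trait correlation r_h plus per-measure reliabilities;
  observed scores mix the trait with independent measurement error so that
  corr(x, y) equals the attenuated value r_h * sqrt(rel_brain * rel_behav).
* ``heteroscedastic`` — latent mode where the behavioral error standard
  deviation scales with the latent trait (through its normal CDF rank),
  renormalized so the population-average error variance is unchanged.  This
  isolates heteroscedasticity from any change in overall reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .attenuation import attenuate

__all__ = [
    "Population",
    "LatentSpec",
    "generate_population",
    "generate_latent_population",
]

DEFAULT_SIZE = 1_000_000
MAX_ATTEMPTS = 100


@dataclass
class Population:
    """A large synthetic bivariate population (behavioral x, brain y)."""

    x: np.ndarray
    y: np.ndarray
    r_target: float
    r_empirical: float
    size: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y) or len(self.x) != self.size:
            raise ValueError("x and y must both have length == size")


@dataclass(frozen=True)
class LatentSpec:
    """True-trait correlation plus reliabilities (and heteroscedasticity).

    ``hetero_gamma = 0`` gives homoscedastic measurement error.  The implied
    observable correlation is ``attenuate(r_h, rel_brain, rel_behav)``.
    """

    r_h: float
    rel_brain: float
    rel_behav: float
    hetero_gamma: float = 0.0

    @property
    def r_o(self) -> float:
        return attenuate(self.r_h, self.rel_brain, self.rel_behav)


def generate_population(
    r_o: float,
    size: int = DEFAULT_SIZE,
    tolerance: float = 0.01,
    seed: int | np.random.SeedSequence | None = None,
    max_attempts: int = MAX_ATTEMPTS,
) -> Population:
    """Generate a population with observable correlation ``r_o``.

    The draw is accepted only if the realized Pearson correlation lies
    within ``tolerance`` of the target; otherwise it is regenerated, up to
    ``max_attempts`` times.

    Parameters
    ----------
    r_o
        Target observable correlation, |r_o| < 1.
    size
        Population count (>= 100).
    tolerance
        Maximum accepted |corr(x, y) - r_o|.
    seed
        Master seed; identical seed and parameters give identical output.
    """
    if not abs(r_o) < 1:
        raise ValueError(f"|r_o| must be < 1, got {r_o}")
    if size < 100:
        raise ValueError(f"size must be >= 100, got {size}")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    x_ss, e_ss = ss.spawn(2)
    rng_x = np.random.default_rng(x_ss)
    rng_e = np.random.default_rng(e_ss)
    for attempt in range(1, max_attempts + 1):
        x = rng_x.standard_normal(size)
        e = rng_e.standard_normal(size)
        y = r_o * x + np.sqrt(1.0 - r_o**2) * e
        r_emp = float(np.corrcoef(x, y)[0, 1])
        if abs(r_emp - r_o) <= tolerance:
            return Population(
                x=x,
                y=y,
                r_target=r_o,
                r_empirical=r_emp,
                size=size,
                meta={"mode": "direct", "tolerance": tolerance, "attempts": attempt},
            )
    raise RuntimeError(
        f"no draw within tolerance {tolerance} of r_o={r_o} "
        f"after {max_attempts} attempts"
    )


def generate_latent_population(
    spec: LatentSpec,
    size: int = DEFAULT_SIZE,
    seed: int | np.random.SeedSequence | None = None,
    tolerance: float = 0.01,
    max_attempts: int = MAX_ATTEMPTS,
) -> Population:
    """Generate a population from latent traits plus measurement error.

    Latent traits (t_x, t_y) are bivariate standard normal with correlation
    ``spec.r_h``.  Observed scores are

        x = sqrt(rel_behav) * t_x + sqrt(1 - rel_behav) * eps_x
        y = sqrt(rel_brain) * t_y + sqrt(1 - rel_brain) * eps_y

    with independent standard-normal errors, so corr(x, y) is the attenuated
    correlation.  With ``hetero_gamma > 0`` the behavioral error sd is scaled
    by ``1 + hetero_gamma * Phi(t_x)``, renormalized so the mean error
    variance over the population is unchanged (total reliability preserved).
    """
    r_target = spec.r_o  # validates reliabilities and r_h
    if size < 100:
        raise ValueError(f"size must be >= 100, got {size}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(4)]
    rel_x, rel_y = spec.rel_behav, spec.rel_brain
    for attempt in range(1, max_attempts + 1):
        t_x = streams[0].standard_normal(size)
        e_t = streams[1].standard_normal(size)
        t_y = spec.r_h * t_x + np.sqrt(1.0 - spec.r_h**2) * e_t
        eps_x = streams[2].standard_normal(size)
        eps_y = streams[3].standard_normal(size)
        if spec.hetero_gamma > 0:
            scale = 1.0 + spec.hetero_gamma * stats.norm.cdf(t_x)
            # E[(1 + g*U)^2] with U ~ Uniform(0,1): renormalize so the
            # population-average error variance stays 1 - rel_behav
            norm = np.sqrt(1.0 + spec.hetero_gamma + spec.hetero_gamma**2 / 3.0)
            err_x = np.sqrt(1.0 - rel_x) * (scale / norm) * eps_x
        else:
            err_x = np.sqrt(1.0 - rel_x) * eps_x
        x = np.sqrt(rel_x) * t_x + err_x
        y = np.sqrt(rel_y) * t_y + np.sqrt(1.0 - rel_y) * eps_y
        r_emp = float(np.corrcoef(x, y)[0, 1])
        if abs(r_emp - r_target) <= tolerance:
            mode = "heteroscedastic" if spec.hetero_gamma > 0 else "latent"
            return Population(
                x=x,
                y=y,
                r_target=r_target,
                r_empirical=r_emp,
                size=size,
                meta={
                    "mode": mode,
                    "r_h": spec.r_h,
                    "rel_brain": spec.rel_brain,
                    "rel_behav": spec.rel_behav,
                    "hetero_gamma": spec.hetero_gamma,
                    "tolerance": tolerance,
                    "attempts": attempt,
                },
            )
    raise RuntimeError(
        f"no latent draw within tolerance {tolerance} of implied r_o={r_target} "
        f"after {max_attempts} attempts"
    )


def save_population(pop: Population, csv_path: str) -> None:
    """Persist a population as two-column CSV with a JSON meta sidecar."""
    import json
    import pathlib

    import pandas as pd

    pd.DataFrame({"x": pop.x, "y": pop.y}).to_csv(csv_path, index=False)
    sidecar = pathlib.Path(csv_path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "r_target": pop.r_target,
                "r_empirical": pop.r_empirical,
                "size": pop.size,
                "meta": pop.meta,
            },
            indent=2,
        )
    )


def load_population(csv_path: str) -> Population:
    """Load a population saved by :func:`save_population`."""
    import json
    import pathlib

    import pandas as pd

    df = pd.read_csv(csv_path)
    sidecar = pathlib.Path(csv_path).with_suffix(".json")
    info = json.loads(sidecar.read_text())
    return Population(
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        r_target=info["r_target"],
        r_empirical=info["r_empirical"],
        size=info["size"],
        meta=info["meta"],
    )
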