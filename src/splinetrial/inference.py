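"""Posterior inference for binomial event rates under arbitrary [0, 1] priors.

All posteriors here are one-dimensional, so no MCMC is needed: the posterior
density of a rate is evaluated on a fixed grid over [0, 1] (in log space, so
large trials do not underflow), normalised by the trapezoid rule, and sampled
by inverse-CDF interpolation.  The absolute risk reduction (ARR)
``pi_T - pi_C`` is handled by independent posterior draws from the two arms;
an exact grid-convolution routine is provided as a cross-check.

Highest-density intervals (HDI) are computed either from draws (shortest
interval containing the requested mass) or from a grid density (water-level
scan, which also detects non-contiguous highest-density regions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .elicitation import BetaPrior, SplinePrior

__all__ = [
    "GridPosterior",
    "HdiInterval",
    "grid_posterior",
    "sample_posterior",
    "arr_posterior",
    "arr_grid_convolution",
    "tail_prob",
    "hdi",
    "export_draws_csv",
]

DEFAULT_GRID_SIZE = 2001
DEFAULT_ARR_DRAWS = 20_000


@dataclass(frozen=True)
class GridPosterior:
    """Normalised posterior density of a rate on an equally spaced grid."""

    grid: np.ndarray
    density: np.ndarray
    log_norm: float  # log of the unnormalised integral, kept for diagnostics

    def __post_init__(self) -> None:
        if self.grid.shape != self.density.shape:
            raise ValueError("grid/density shape mismatch")
        if np.any(self.density < 0):
            raise ValueError("posterior density must be nonnegative")

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def cdf(self) -> np.ndarray:
        """Trapezoid CDF on the grid, clipped to end exactly at 1."""
        c = cumulative_trapezoid(self.density, self.grid, initial=0.0)
        return np.clip(c / c[-1], 0.0, 1.0)

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def prob_below(self, threshold: float) -> float:
        """Exact-on-the-grid posterior probability P(rate < threshold)."""
        c = self.cdf()
        return float(np.interp(threshold, self.grid, c))


@dataclass(frozen=True)
class HdiInterval:
    """Highest-density interval: the shortest region holding ``coverage`` mass.

    ``contiguous`` is False when the highest-density region found on a grid
    splits into more than one interval; ``low``/``high`` then bound the full
    region (the decision rules consume a single pair of bounds).
    """

    low: float
    high: float
    coverage: float
    contiguous: bool = True

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("HDI bounds out of order")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must lie in (0, 1]")

    def contains(self, x: float) -> bool:
        """Strict interiority, the convention used by the futility rules."""
        return self.low < x < self.high


def grid_posterior(
    prior: SplinePrior | BetaPrior,
    successes: int,
    n: int,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> GridPosterior:
    """Posterior of a binomial rate on a grid: density ∝ prior(x)·xˢ(1−x)ⁿ⁻ˢ.

    Computed in log space and trapezoid-normalised.  With ``n = 0`` the
    prior itself is returned on the grid.  Grid points where the prior has
    an integrable singularity (Beta shapes below 1 at the boundary) are
    assigned zero mass; the trapezoid rule cannot represent them anyway.
    """
    if successes < 0 or n < 0:
        raise ValueError("counts must be nonnegative")
    if successes > n:
        raise ValueError("successes cannot exceed n")
    if grid_size < 3:
        raise ValueError("grid_size must be at least 3")
    x = np.linspace(0.0, 1.0, grid_size)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_d = prior.logpdf(x)
        if n > 0:
            # xlogy-style guards: 0·log 0 = 0 at the boundary
            log_lik = np.where(
                x > 0, successes * np.log(np.where(x > 0, x, 1.0)),
                0.0 if successes == 0 else -np.inf)
            log_lik = log_lik + np.where(
                x < 1, (n - successes) * np.log(np.where(x < 1, 1.0 - x, 1.0)),
                0.0 if successes == n else -np.inf)
            log_d = log_d + log_lik
    log_d = np.where(np.isfinite(log_d), log_d, -np.inf)
    if not np.any(np.isfinite(log_d)):
        raise ValueError("posterior density is zero everywhere on the grid")
    peak = np.max(log_d)
    density = np.exp(log_d - peak)
    norm = np.trapezoid(density, x)
    density = density / norm
    log_norm = peak + np.log(norm)
    return GridPosterior(grid=x, density=density, log_norm=float(log_norm))


def sample_posterior(
    post: GridPosterior,
    n_draws: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Inverse-CDF draws from a grid posterior (linear interpolation)."""
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, n_draws)
    return np.interp(u, post.cdf(), post.grid)


def arr_posterior(
    post_t: GridPosterior,
    post_c: GridPosterior,
    n_draws: int = DEFAULT_ARR_DRAWS,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Draws of the absolute risk reduction pi_T − pi_C.

    The two arms are modelled as independent; each receives its own
    deterministically derived substream of the seed, so draws for one arm
    do not perturb the other.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    ss_t, ss_c = ss.spawn(2)
    draws_t = sample_posterior(post_t, n_draws, ss_t)
    draws_c = sample_posterior(post_c, n_draws, ss_c)
    return draws_t - draws_c


def arr_grid_convolution(
    post_t: GridPosterior, post_c: GridPosterior, threshold: float = 0.0
) -> float:
    """Exact P(pi_T − pi_C < threshold) by discrete convolution of the grids.

    Serves as the deterministic cross-check for the sampling estimator:
    the two grid densities are reduced to cell masses and the difference
    distribution is accumulated exactly.
    """
    if post_t.grid.shape != post_c.grid.shape:
        raise ValueError("posteriors must share a grid size")
    # cell masses via trapezoid weights
    w_t = np.diff(post_t.cdf())
    w_c = np.diff(post_c.cdf())
    mid = (post_t.grid[:-1] + post_t.grid[1:]) / 2.0
    # difference of cell midpoints: mid_i - mid_j < threshold
    # correlate: for each i, count mass of c-cells with mid_c > mid_i - threshold
    order = np.argsort(mid)
    cum_c = np.concatenate([[0.0], np.cumsum(w_c[order])])
    # P(C > t) = 1 - F_C(t); use searchsorted on sorted midpoints
    sorted_mid = mid[order]
    idx = np.searchsorted(sorted_mid, mid - threshold, side="right")
    p_c_greater = 1.0 - cum_c[idx]
    return float(np.sum(w_t * p_c_greater))


def tail_prob(samples: np.ndarray, threshold: float) -> float:
    """Fraction of draws strictly below the threshold."""
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ValueError("tail_prob requires a nonempty sample")
    return float(np.mean(samples < threshold))


def hdi(samples_or_grid, coverage: float) -> HdiInterval:
    """Highest-density interval at the given coverage.

    * array of draws — the shortest window containing ``ceil(coverage·N)``
      sorted draws (deterministic given the draws);
    * :class:`GridPosterior` — water-level scan: grid cells are admitted in
      order of decreasing density until the requested mass is reached; when
      the admitted region is not a single run of cells, the bounding
      interval of the whole region is returned with ``contiguous=False``.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    if isinstance(samples_or_grid, GridPosterior):
        return _hdi_grid(samples_or_grid, coverage)
    samples = np.sort(np.asarray(samples_or_grid, dtype=float))
    n = samples.size
    if n == 0:
        raise ValueError("hdi requires a nonempty sample")
    k = int(np.ceil(coverage * n))
    if k >= n:
        return HdiInterval(float(samples[0]), float(samples[-1]), coverage)
    widths = samples[k - 1:] - samples[: n - k + 1]
    i = int(np.argmin(widths))
    return HdiInterval(float(samples[i]), float(samples[i + k - 1]), coverage)


def export_draws_csv(samples: np.ndarray, path) -> None:
    """Dump a posterior trace as CSV (draw_index, value) for debugging."""
    import pandas as pd

    pd.DataFrame({
        "draw_index": np.arange(len(samples)),
        "value": np.asarray(samples),
    }).to_csv(path, index=False)


def _hdi_grid(post: GridPosterior, coverage: float) -> HdiInterval:
    mass = np.diff(post.cdf())  # mass per cell
    cell_density = (post.density[:-1] + post.density[1:]) / 2.0
    order = np.argsort(cell_density)[::-1]
    cum = np.cumsum(mass[order])
    n_keep = int(np.searchsorted(cum, coverage, side="left")) + 1
    keep = np.sort(order[:n_keep])
    contiguous = bool(np.all(np.diff(keep) == 1))
    low = float(post.grid[keep[0]])
    high = float(post.grid[keep[-1] + 1])
    return HdiInterval(low, high, coverage, contiguous=contiguous)
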