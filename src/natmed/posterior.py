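"""Exact conjugate posteriors for stratum mortality probabilities.

Deaths in a stratum are binomial with an unknown rate (the potential outcome,
PO) and the birth count as the number of trials.  Under a beta(a, b) prior the
posterior is beta(a + deaths, b + births - deaths) in closed form, so instead
of MCMC we draw independent Monte-Carlo samples directly from the exact
posterior.  Derived quantities (differences, ratios, percentages) are computed
drawwise and summarized by the median and the 2.5/97.5 percentile credibility
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import stats

from .categorize import Race, StrataCounts

__all__ = [
    "PriorSpec",
    "BETA_1_10",
    "UNIFORM",
    "JEFFREYS",
    "PosteriorDraws",
    "PosteriorSummary",
    "posterior_draws",
    "exact_quantile",
    "race_marginal_po",
    "summarize",
]

DEFAULT_N_DRAWS = 10_000

SeedLike = Union[int, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PriorSpec:
    """Beta prior shapes for a mortality probability."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"beta shapes must be positive, got ({self.a}, {self.b})")

    def label(self) -> str:
        return f"beta({self.a:g},{self.b:g})"


#: Default weakly informative prior favouring rates near zero.
BETA_1_10 = PriorSpec(1.0, 10.0)
#: uniform(0,1), represented as beta(1,1).
UNIFORM = PriorSpec(1.0, 1.0)
#: Jeffreys prior, used for stratum-membership (incidence) proportions.
JEFFREYS = PriorSpec(0.5, 0.5)


@dataclass
class PosteriorDraws:
    """A Monte-Carlo sample of a PO or any drawwise-derived quantity."""

    values: np.ndarray
    seed: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size

    def derived(self, values: np.ndarray, label: str) -> "PosteriorDraws":
        return PosteriorDraws(values, seed=self.seed, label=label)


@dataclass(frozen=True)
class PosteriorSummary:
    """Median and central 95% credibility interval."""

    median: float
    lo2_5: float
    hi97_5: float

    def __post_init__(self) -> None:
        if not (self.lo2_5 <= self.median <= self.hi97_5):
            raise ValueError(f"unordered summary {self}")

    def as_tuple(self) -> tuple[float, float, float]:
        return self.median, self.lo2_5, self.hi97_5


def _check_counts(r: int, n: int) -> None:
    if n < 0 or r < 0:
        raise ValueError("negative counts")
    if r > n:
        raise ValueError(f"deaths exceed births ({r} > {n})")


def posterior_draws(
    r: int,
    n: int,
    prior: PriorSpec = BETA_1_10,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: SeedLike = 0,
) -> PosteriorDraws:
    """Independent draws from the exact beta(a + r, b + n - r) posterior.

    With r = n = 0 this is the prior itself.  ``seed`` may be an integer or a
    shared :class:`numpy.random.Generator` (the latter keeps several derived
    quantities on one drawwise-aligned stream).
    """
    _check_counts(r, n)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = _rng(seed)
    vals = rng.beta(prior.a + r, prior.b + n - r, size=n_draws)
    return PosteriorDraws(vals, seed=seed if isinstance(seed, int) else None,
                          label=f"PO(r={r},n={n})|{prior.label()}")


def exact_quantile(r: int, n: int, prior: PriorSpec, q: float) -> float:
    """Closed-form q-quantile of the conjugate posterior (analytic oracle)."""
    _check_counts(r, n)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    return float(stats.beta.ppf(q, prior.a + r, prior.b + n - r))


def race_marginal_po(
    counts: StrataCounts,
    race: Race,
    prior: PriorSpec = BETA_1_10,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: SeedLike = 0,
) -> PosteriorDraws:
    """Posterior of the race-marginal mortality rate, pooling all strata."""
    r = int(counts.race_deaths[race.axis])
    n = int(counts.race_births[race.axis])
    d = posterior_draws(r, n, prior, n_draws, seed)
    d.label = f"marginal PO[{race.name}]|{prior.label()}"
    return d


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Empirical 2.5/50/97.5 percentiles (linear interpolation)."""
    if len(draws) == 0:
        raise ValueError("cannot summarize empty draws")
    lo, med, hi = np.percentile(draws.values, [2.5, 50.0, 97.5])
    return PosteriorSummary(float(med), float(lo), float(hi))
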