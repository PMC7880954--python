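"""Two-group normal population models and dataset simulation.

The sample-size search repeatedly draws datasets of a candidate size
from a null population and from an alternative population.  Because the
Bayes factor depends on the data only through the per-group sufficient
statistics, datasets can be simulated either as raw observation vectors
or directly as sufficient statistics: the sample mean of ``n`` normal
draws is ``N(mu, sigma^2/n)`` and the unbiased sample variance is an
independent ``sigma^2 * chi2(n-1)/(n-1)``.  The two routes are
distributionally identical; the sufficient-statistic route costs O(1)
per dataset instead of O(n) and is the default in the search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes_factor import SummaryStats, VarianceModel

__all__ = ["PopulationSpec", "SimBatch", "cohens_d", "gen_raw", "gen_suffstats", "stream_rng"]

# fixed stream labels so that (seed, N, population) always maps to the
# same datasets, for every fraction and for repeated runs
_POP_STREAM = {"null": 0, "alt": 1}


@dataclass(frozen=True)
class PopulationSpec:
    """Normal two-group population: means, variances and variance model."""

    mu1: float
    mu2: float
    sigma2_1: float = 1.0
    sigma2_2: float = 1.0
    model: VarianceModel = VarianceModel.EQUAL_VAR

    def __post_init__(self) -> None:
        if self.sigma2_1 <= 0 or self.sigma2_2 <= 0:
            raise ValueError("population variances must be positive")
        if self.model is VarianceModel.EQUAL_VAR and self.sigma2_1 != self.sigma2_2:
            raise ValueError("equal-variance model requires sigma2_1 == sigma2_2")

    def as_null(self) -> "PopulationSpec":
        """The matched null population: both means set to ``mu2``."""
        return PopulationSpec(self.mu2, self.mu2, self.sigma2_1, self.sigma2_2, self.model)


def cohens_d(pop: PopulationSpec) -> float:
    """Standardised mean difference ``(mu1 - mu2) / sqrt((s1^2 + s2^2)/2)``."""
    return (pop.mu1 - pop.mu2) / np.sqrt((pop.sigma2_1 + pop.sigma2_2) / 2.0)


def stream_rng(master_seed: int, n_per_group: int, population: str) -> np.random.Generator:
    """Deterministic child generator keyed by (seed, candidate N, population).

    Distinct keys give statistically independent streams; identical keys
    reproduce the same datasets, so all prior fractions are evaluated on
    the same simulated data.
    """
    seq = np.random.SeedSequence(master_seed, spawn_key=(int(n_per_group), _POP_STREAM[population]))
    return np.random.default_rng(seq)


def gen_raw(pop: PopulationSpec, n_per_group: int, rng: np.random.Generator):
    """Draw one raw dataset: two i.i.d. normal samples of size ``n_per_group``."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    y1 = rng.normal(pop.mu1, np.sqrt(pop.sigma2_1), size=n_per_group)
    y2 = rng.normal(pop.mu2, np.sqrt(pop.sigma2_2), size=n_per_group)
    return y1, y2


@dataclass(frozen=True)
class SimBatch:
    """``T`` simulated datasets of common per-group size, as sufficient statistics."""

    n_per_group: int
    mean1: np.ndarray
    mean2: np.ndarray
    var1: np.ndarray
    var2: np.ndarray
    model: VarianceModel

    def __len__(self) -> int:
        return self.mean1.size

    def as_stats(self) -> SummaryStats:
        """Array-valued SummaryStats covering the whole batch."""
        return SummaryStats(
            n1=self.n_per_group,
            n2=self.n_per_group,
            mean1=self.mean1,
            mean2=self.mean2,
            var1=self.var1,
            var2=self.var2,
            model=self.model,
        )

    def __iter__(self):
        for i in range(len(self)):
            yield SummaryStats(
                n1=self.n_per_group,
                n2=self.n_per_group,
                mean1=float(self.mean1[i]),
                mean2=float(self.mean2[i]),
                var1=float(self.var1[i]),
                var2=float(self.var2[i]),
                model=self.model,
            )


def gen_suffstats(pop: PopulationSpec, n_per_group: int, T: int, rng: np.random.Generator) -> SimBatch:
    """Draw ``T`` datasets directly on the sufficient-statistic scale.

    Exact sampling distributions for normal data: means are normal with
    variance ``sigma^2/n``; unbiased variances are scaled chi-square with
    ``n - 1`` degrees of freedom, independent of the means.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if T < 1:
        raise ValueError("T must be >= 1")
    n = n_per_group
    mean1 = rng.normal(pop.mu1, np.sqrt(pop.sigma2_1 / n), size=T)
    mean2 = rng.normal(pop.mu2, np.sqrt(pop.sigma2_2 / n), size=T)
    var1 = pop.sigma2_1 * rng.chisquare(n - 1, size=T) / (n - 1)
    var2 = pop.sigma2_2 * rng.chisquare(n - 1, size=T) / (n - 1)
    return SimBatch(n_per_group=n, mean1=mean1, mean2=mean2, var1=var1, var2=var2, model=pop.model)
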