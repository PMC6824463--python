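"""Plasmid-loss-rate statistic and catenane-distribution summaries.

The loss rate per generation follows the standard minichromosome-stability
formula 100 * (1 - RMP^(1/G)), where RMP is the ratio of plasmid maintenance
(colonies on selective medium / colonies on nonselective medium) and G the
number of generations of nonselective growth.  Catenane band intensities from
nicked 2D gels arrive as numeric weights over the integer catenane number
CatA_n; the headline summary is the weighted discrete median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import ValidationError

__all__ = [
    "PlasmidAssay",
    "CatenaneDistribution",
    "plasmid_loss_rate",
    "loss_rate_with_ci",
    "summarize_assays",
    "median_catenane",
    "compare_catenation",
]


@dataclass(frozen=True)
class PlasmidAssay:
    """Colony counts from one plasmid-loss culture."""

    n_selective: int
    n_nonselective: int
    G: float

    def __post_init__(self) -> None:
        if self.n_selective < 0 or self.n_nonselective < 0:
            raise ValidationError("colony counts must be non-negative")
        if self.n_selective > self.n_nonselective:
            raise ValidationError(
                f"n_selective ({self.n_selective}) > n_nonselective "
                f"({self.n_nonselective})"
            )
        if self.G <= 0:
            raise ValidationError(f"G must be > 0, got {self.G}")


def plasmid_loss_rate(assay: PlasmidAssay) -> float:
    """Plasmid loss in % per generation: 100 * (1 - RMP^(1/G))."""
    if assay.n_nonselective == 0:
        raise ValidationError("n_nonselective must be > 0")
    rmp = assay.n_selective / assay.n_nonselective
    if rmp == 0.0:
        return 100.0
    return 100.0 * (1.0 - rmp ** (1.0 / assay.G))


def loss_rate_with_ci(
    assay: PlasmidAssay,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, Optional[tuple[float, float]]]:
    """Point estimate and percentile-bootstrap CI of the loss rate.

    Resamples n_selective ~ Binomial(n_nonselective, RMP-hat).  With
    ``n_boot`` = 0 only the point estimate is returned.
    """
    rate = plasmid_loss_rate(assay)
    if n_boot <= 0:
        return rate, None
    rng = np.random.default_rng(seed)
    rmp_hat = assay.n_selective / assay.n_nonselective
    draws = rng.binomial(assay.n_nonselective, rmp_hat, size=n_boot)
    boot = np.array(
        [
            plasmid_loss_rate(PlasmidAssay(int(k), assay.n_nonselective, assay.G))
            for k in draws
        ]
    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return rate, (float(lo), float(hi))


def summarize_assays(assays: Sequence[PlasmidAssay]) -> dict:
    """Mean +/- SD of the loss rate over replicate cultures."""
    if not assays:
        raise ValidationError("no assays given")
    rates = np.array([plasmid_loss_rate(a) for a in assays])
    return {
        "n": len(rates),
        "mean_rate_pct": float(rates.mean()),
        "sd_rate_pct": float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
        "rates_pct": rates.tolist(),
    }


@dataclass
class CatenaneDistribution:
    """Normalized weights over discrete catenane number n >= 1."""

    weights: dict[int, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError("empty catenane distribution")
        if any(n < 1 for n in self.weights):
            raise ValidationError("catenane numbers must be >= 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("weights must be non-negative")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValidationError("weights sum to zero")
        # zero-weight entries are absent bands, not part of the distribution
        self.weights = {
            int(n): w / total for n, w in sorted(self.weights.items()) if w > 0
        }

    def ns(self) -> np.ndarray:
        return np.array(sorted(self.weights), dtype=int)

    def probs(self) -> np.ndarray:
        ns = self.ns()
        return np.array([self.weights[int(n)] for n in ns])

    def shift(self, k: int) -> "CatenaneDistribution":
        return CatenaneDistribution({n + k: w for n, w in self.weights.items()})


def median_catenane(dist: CatenaneDistribution) -> int:
    """Weighted discrete median: smallest n with cumulative weight >= 0.5."""
    cum = 0.0
    for n in sorted(dist.weights):
        cum += dist.weights[n]
        if cum >= 0.5 - 1e-12:
            return n
    return max(dist.weights)  # unreachable for normalized weights


def compare_catenation(
    dist_a: CatenaneDistribution,
    dist_b: CatenaneDistribution,
    n_boot: int = 1000,
    seed: int = 0,
    lanes_a: Optional[Sequence[CatenaneDistribution]] = None,
    lanes_b: Optional[Sequence[CatenaneDistribution]] = None,
    effective_count: int = 1000,
    level: float = 0.95,
) -> tuple[int, Optional[tuple[float, float]]]:
    """Difference of median catenane numbers, median(b) - median(a), with CI.

    With replicate lanes the CI resamples lanes; otherwise each distribution
    is resampled multinomially at ``effective_count`` draws (a stated stand-in
    for band-intensity counting noise).
    """
    delta = median_catenane(dist_b) - median_catenane(dist_a)
    if n_boot <= 0:
        return delta, None
    rng = np.random.default_rng(seed)

    def resample(dist: CatenaneDistribution, lanes) -> CatenaneDistribution:
        if lanes:
            picks = rng.integers(0, len(lanes), len(lanes))
            agg: dict[int, float] = {}
            for i in picks:
                for n, w in lanes[i].weights.items():
                    agg[n] = agg.get(n, 0.0) + w
            return CatenaneDistribution(agg)
        ns, ps = dist.ns(), dist.probs()
        counts = rng.multinomial(effective_count, ps)
        if counts.sum() == 0:  # pragma: no cover - multinomial total is fixed
            return dist
        keep = counts > 0
        return CatenaneDistribution(dict(zip(ns[keep].tolist(), counts[keep].tolist())))

    boot = np.array(
        [
            median_catenane(resample(dist_b, lanes_b)) - median_catenane(resample(dist_a, lanes_a))
            for _ in range(n_boot)
        ]
    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return delta, (float(lo), float(hi))
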