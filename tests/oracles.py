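"""Independent reference implementations used to cross-check the package.

These are deliberately written as direct, slow transcriptions of the
definitions (explicit loops, no vectorization) so that agreement with the
package's optimized implementations is meaningful.
"""

import numpy as np


def brute_force_peaks(y: np.ndarray, bin_size: int, persistence_bp: int) -> list[int]:
    """Apex bins under the '+ to - with > persistence_bp' peak definition.

    A bin b qualifies when every derivative step in the window of
    m = persistence_bp // bin_size + 1 steps before b is >= 0 with at least
    one > 0, and every step in the m steps starting at b is <= 0 with at
    least one < 0.  Consecutive qualifying bins describe one plateau peak at
    their midpoint (lower median).
    """
    m = persistence_bp // bin_size + 1
    n = len(y)
    qualifying = []
    for b in range(n):
        if b - m < 0 or b + m > n - 1:
            continue
        pre = [y[k + 1] - y[k] for k in range(b - m, b)]
        post = [y[k + 1] - y[k] for k in range(b, b + m)]
        if all(d >= 0 for d in pre) and any(d > 0 for d in pre) and \
           all(d <= 0 for d in post) and any(d < 0 for d in post):
            qualifying.append(b)
    apexes = []
    run: list[int] = []
    for b in qualifying + [None]:
        if run and (b is None or b != run[-1] + 1):
            k = len(run)
            apexes.append(run[k // 2] if k % 2 else run[k // 2 - 1])
            run = []
        if b is not None:
            run.append(b)
    return apexes


def piecewise_linear_profile(rng: np.random.Generator, n_bins: int) -> np.ndarray:
    """Random piecewise-linear copy-number-like profile on n_bins bins."""
    n_knots = int(rng.integers(4, 30))
    knots = np.sort(rng.choice(n_bins, size=n_knots, replace=False))
    knots[0], knots[-1] = 0, n_bins - 1
    values = rng.uniform(1.0, 2.0, size=n_knots)
    return np.interp(np.arange(n_bins), knots, values)


def weighted_median_oracle(weights: dict[int, float]) -> int:
    """Smallest n whose cumulative normalized weight reaches one half."""
    total = sum(weights.values())
    cum = 0.0
    for n in sorted(weights):
        cum += weights[n] / total
        if cum >= 0.5 - 1e-12:
            return n
    raise AssertionError("unreachable for positive-total weights")


def hypergeom_upper_tail_by_enumeration(
    universe: list[str], complex_members: set[str], hits: set[str]
) -> float:
    """P(overlap >= observed) by exhaustive enumeration of hit sets.

    Enumerates every subset of the universe of size |hits| and counts those
    whose overlap with the complex reaches the observed overlap.
    """
    from itertools import combinations

    observed = len(complex_members & hits)
    n_hits = len(hits)
    favorable = 0
    total = 0
    for combo in combinations(universe, n_hits):
        total += 1
        if len(complex_members & set(combo)) >= observed:
            favorable += 1
    return favorable / total
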