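"""Training/test splits for the coastline sampling designs.

Three strategies are compared. *Aggregated*: the training data is one
contiguous stretch of coast; four placements (cases 1-4) start the stretch
at the 0, 25, 50 and 75 % positions along the chain. *Interspaced*: k >= 5
contiguous stretches spread evenly along the coast, alternating with
unsampled stretches (at 50 % sampling the selected and unselected runs have
equal length). *Random*: a uniform random subset, the null design. In every
case the unselected points form the test set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

FRACTIONS = (0.10, 0.20, 0.30, 0.40, 0.50)
AGGREGATED_CASES = (1, 2, 3, 4)
_CASE_STARTS = {1: 0.0, 2: 0.25, 3: 0.50, 4: 0.75}
MIN_STRETCHES = 5


@dataclass(frozen=True)
class SamplingScenario:
    """One sampling design: strategy, size fraction, placement, seed."""

    strategy: str                  # aggregated | interspaced | random
    fraction: float
    case: int | None = None       # aggregated placement 1..4, or stretch count k
    seed: int | None = None       # random strategy only

    def __post_init__(self):
        if self.strategy not in ("aggregated", "interspaced", "random"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must be in (0, 1)")
        if self.strategy == "aggregated" and self.case not in AGGREGATED_CASES:
            raise ValueError(f"aggregated case must be one of {AGGREGATED_CASES}")
        if self.strategy == "interspaced" and (self.case or 0) < MIN_STRETCHES:
            raise ValueError(f"interspaced needs at least {MIN_STRETCHES} stretches")

    @property
    def label(self) -> str:
        if self.strategy == "aggregated":
            return f"aggregated_case{self.case}_{int(round(self.fraction * 100))}pct"
        if self.strategy == "interspaced":
            return f"interspaced_k{self.case}_{int(round(self.fraction * 100))}pct"
        return f"random_seed{self.seed}_{int(round(self.fraction * 100))}pct"


@dataclass(frozen=True)
class SampleSplit:
    """Disjoint train/test index sets covering 0..n-1."""

    train: frozenset
    test: frozenset

    @property
    def train_indices(self) -> np.ndarray:
        return np.fromiter(sorted(self.train), dtype=int)

    @property
    def test_indices(self) -> np.ndarray:
        return np.fromiter(sorted(self.test), dtype=int)


def _make_split(n: int, train_idx) -> SampleSplit:
    train = frozenset(int(i) for i in train_idx)
    test = frozenset(range(n)) - train
    return SampleSplit(train, test)


def sample_size(n: int, fraction: float) -> int:
    """Training-set size: fraction of n, rounded half away from zero."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    size = math.floor(fraction * n + 0.5)
    if size == 0:
        raise ValueError("empty training sample")
    return size


def aggregated_split(n: int, fraction: float, case: int) -> SampleSplit:
    """One contiguous training block at a case-dependent start position.

    Cases 1-4 start the block at 0 %, 25 %, 50 % and 75 % of the chain;
    the start is clipped so the block fits within the coast.
    """
    if case not in AGGREGATED_CASES:
        raise ValueError(f"case must be one of {AGGREGATED_CASES}")
    size = sample_size(n, fraction)
    if size >= n:
        raise ValueError("aggregated block would cover the whole coast")
    start = int(round(_CASE_STARTS[case] * n))
    start = min(start, n - size)
    return _make_split(n, range(start, start + size))


def interspaced_split(n: int, fraction: float, k: int = MIN_STRETCHES) -> SampleSplit:
    """k evenly spaced contiguous training stretches along the chain.

    Stretch j starts at round(j*n/k); lengths are as equal as possible
    (differing by at most one, longer stretches first) and total the
    sample size. At 50 % sampling with k dividing n/2 the selected and
    unselected runs alternate with identical lengths.
    """
    if k < MIN_STRETCHES:
        raise ValueError(f"at least {MIN_STRETCHES} stretches required")
    size = sample_size(n, fraction)
    if k > size:
        raise ValueError("more stretches than training points")
    base, extra = divmod(size, k)
    starts = [int(round(j * n / k)) for j in range(k)]
    lengths = [base + (1 if j < extra else 0) for j in range(k)]
    idx: list = []
    for j, (s, L) in enumerate(zip(starts, lengths)):
        end = s + L
        limit = starts[j + 1] if j + 1 < k else n
        if end > limit:
            raise ValueError(
                f"stretch {j} (start {s}, length {L}) overlaps the next; "
                f"use fewer stretches (k < {k}) at fraction {fraction}"
            )
        idx.extend(range(s, end))
    return _make_split(n, idx)


def random_split(n: int, fraction: float, seed: int) -> SampleSplit:
    """Uniform random training subset without replacement (the null design)."""
    size = sample_size(n, fraction)
    rng = np.random.default_rng(seed)
    train = rng.choice(n, size=size, replace=False)
    return _make_split(n, train)


def split_for(n: int, scenario: SamplingScenario) -> SampleSplit:
    """The train/test split a scenario induces on an n-point coast."""
    if scenario.strategy == "aggregated":
        return aggregated_split(n, scenario.fraction, scenario.case)
    if scenario.strategy == "interspaced":
        return interspaced_split(n, scenario.fraction, scenario.case or MIN_STRETCHES)
    return random_split(n, scenario.fraction, scenario.seed or 0)


def scenario_grid(
    n: int | None = None,
    interspaced_k: int = MIN_STRETCHES,
) -> list:
    """The 19 non-null design scenarios evaluated per habitat.

    Interspaced at 10-50 % (5), aggregated case 1 at 10-50 % (5), and
    aggregated cases 2-4 at 20-40 % (9). The exact placement mix is a
    reproducibility pin for designs the original survey chose by hand in
    GIS; swap in a custom list to re-pin it.
    """
    grid = [SamplingScenario("interspaced", f, interspaced_k) for f in FRACTIONS]
    grid += [SamplingScenario("aggregated", f, 1) for f in FRACTIONS]
    grid += [
        SamplingScenario("aggregated", f, c)
        for c in (2, 3, 4)
        for f in (0.20, 0.30, 0.40)
    ]
    return grid


def null_scenarios(n_reps: int = 10, base_seed: int = 0) -> list:
    """Random (null) scenarios: every fraction x n_reps seeded replicates."""
    return [
        SamplingScenario("random", f, seed=base_seed + r)
        for f in FRACTIONS
        for r in range(n_reps)
    ]
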