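"""Construction of systematic and random test splits.

A split partitions the trial range 1..n into two halves of equal length.
Systematic splits are parameterized by a *grain size* g: alternating
consecutive blocks of g trials are assigned to the two halves, the first
block to half A.  Grain 1 is the odd/even split; grain n/2 is the
first/second-half split.  A grain is valid when n / g is an even
integer, which yields grains {1, 2, 3, 4, 6, 8, 12, 24} for a 48-trial
test and {1, 2, 3, 4, 6, 12} for its first half.

Random splits draw half A uniformly among all subsets of size n/2.

Two structural eligibility rules exclude (measure, grain) cells where
the task structure forces a degenerate reliability:

* category credit comes in runs of six consecutive trials, which grains
  1 and 3 divide exactly in half for every patient, forcing r = 1 — so
  grains 1 and 3 are ineligible for the category measure and any
  composite containing it;
* set-loss errors cannot occur on consecutive trials (an SE trial draws
  negative feedback, which removes the next trial's SE opportunity), so
  the odd/even split structurally anticorrelates SE halves — grain 1 is
  ineligible for the set-loss measure and its composites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np


@dataclass(frozen=True)
class SplitScheme:
    """A partition of trials 1..n_trials into two equal halves."""

    half_a: frozenset[int]
    half_b: frozenset[int]
    provenance: str

    def __post_init__(self) -> None:
        if self.half_a & self.half_b:
            raise ValueError("halves overlap")
        if len(self.half_a) != len(self.half_b):
            raise ValueError("halves differ in size")

    @property
    def n_trials(self) -> int:
        return len(self.half_a) + len(self.half_b)

    def indicator(self) -> np.ndarray:
        """Boolean vector over trials 1..n, True where the trial is in half A."""
        ind = np.zeros(self.n_trials, dtype=bool)
        ind[[t - 1 for t in self.half_a]] = True
        return ind


def valid_grains(n_trials: int) -> list[int]:
    """Grain sizes g for which n_trials / g is an even integer."""
    return [g for g in range(1, n_trials // 2 + 1) if n_trials % g == 0 and (n_trials // g) % 2 == 0]


def systematic_split(n_trials: int, grain: int) -> SplitScheme:
    """Alternating-block split with the given grain size."""
    if grain not in valid_grains(n_trials):
        raise ValueError(
            f"grain {grain} invalid for {n_trials} trials "
            f"(valid: {valid_grains(n_trials)})"
        )
    trials = np.arange(1, n_trials + 1)
    block = (trials - 1) // grain
    in_a = block % 2 == 0
    return SplitScheme(
        half_a=frozenset(trials[in_a].tolist()),
        half_b=frozenset(trials[~in_a].tolist()),
        provenance=f"systematic(grain={grain})",
    )


def random_split(n_trials: int, rng: np.random.Generator) -> SplitScheme:
    """Uniformly random equal split of trials 1..n_trials."""
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even for an equal split")
    half = rng.choice(n_trials, size=n_trials // 2, replace=False) + 1
    a = frozenset(int(t) for t in half)
    b = frozenset(range(1, n_trials + 1)) - a
    return SplitScheme(half_a=a, half_b=frozenset(b), provenance="random")


def random_split_masks(
    n_trials: int, n_iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """Half-A membership masks for many random splits at once.

    Returns an (n_iterations, n_trials) boolean array; each row has
    exactly n_trials/2 True entries, drawn uniformly.  Row i equals the
    indicator of the i-th sequential :func:`random_split` draw only in
    distribution, not bitwise; both samplers are uniform.
    """
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even for an equal split")
    # argpartition of iid uniforms gives a uniformly random half-subset per row
    u = rng.random((n_iterations, n_trials))
    order = np.argsort(u, axis=1)
    masks = np.zeros((n_iterations, n_trials), dtype=bool)
    np.put_along_axis(masks, order[:, : n_trials // 2], True, axis=1)
    return masks


def eligible(members: Iterable[str], grain: int) -> bool:
    """Whether a (measure-set, grain) systematic cell is analyzable.

    Composites inherit ineligibility from any member.
    """
    members = set(members)
    if "n_cat" in members and grain in (1, 3):
        return False
    if "n_SE" in members and grain == 1:
        return False
    return True
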