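"""Testcross designs: sparse tester allocation and the incomplete factorial.

A sparse design with ``k`` testers partitions the ``n`` candidate lines into
``k`` equal random subsets, one per tester, so that full-sibs typically end up
on different testers while total testcross count stays fixed at ``n``. The
named designs use k in {1, 2, 3, 4, 5, 10, 20, 50, 100, 600, 1200} at the full
scale of 1,200 lines per pool. The incomplete-factorial comparator instead
pairs the two pools by a random bijection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breeding import LinePopulation
from .rng import child_rng

__all__ = [
    "DESIGN_TESTER_COUNTS",
    "INCOMPLETE_FACTORIAL",
    "TestcrossAssignment",
    "allocate_sparse",
    "select_testers",
    "incomplete_factorial_pairs",
]

DESIGN_TESTER_COUNTS = (1, 2, 3, 4, 5, 10, 20, 50, 100, 600, 1200)
INCOMPLETE_FACTORIAL = "incomplete_factorial"


@dataclass(frozen=True)
class TestcrossAssignment:
    """Line-to-tester mapping realizing one design for one pool and cycle."""

    design_name: str
    k: int
    tester_ids: np.ndarray  # k line indices in the opposite pool
    line_to_tester: np.ndarray  # per line, an index into tester_ids

    @property
    def n_lines(self) -> int:
        return len(self.line_to_tester)

    @property
    def tester_of_line(self) -> np.ndarray:
        """Opposite-pool line index of the tester assigned to each line."""
        return self.tester_ids[self.line_to_tester]

    def loads(self) -> np.ndarray:
        return np.bincount(self.line_to_tester, minlength=self.k)


def allocate_sparse(
    n_lines: int,
    tester_ids: np.ndarray,
    seed: int,
    family: np.ndarray | None = None,
    design_name: str | None = None,
) -> TestcrossAssignment:
    """Partition lines into equal random subsets, one per tester.

    With ``family`` given, allocation is stratified: within each family, lines
    are spread over testers round-robin in random order (a sensitivity
    variant); by default the partition is an unconstrained uniform one, which
    already spreads full-sib families across testers in expectation.
    """
    tester_ids = np.asarray(tester_ids)
    k = len(tester_ids)
    if k < 1 or n_lines % k:
        raise ValueError(f"tester count {k} must divide the line count {n_lines}")
    rng = child_rng(seed, "allocate")
    assignment = np.empty(n_lines, dtype=np.int64)
    if family is None:
        perm = rng.permutation(n_lines)
        assignment[perm] = np.arange(n_lines) % k
    else:
        offset = 0
        for fam in np.unique(family):
            members = np.flatnonzero(family == fam)
            assignment[rng.permutation(members)] = (offset + np.arange(len(members))) % k
            offset += len(members)
        # rebalance: stratified round-robin can leave unequal loads only when
        # family sizes are uneven; repair by moving lines from over- to
        # under-loaded testers at random
        target = n_lines // k
        loads = np.bincount(assignment, minlength=k)
        while loads.max() > target:
            over = int(np.argmax(loads))
            under = int(np.argmin(loads))
            movable = np.flatnonzero(assignment == over)
            assignment[rng.choice(movable)] = under
            loads = np.bincount(assignment, minlength=k)
    return TestcrossAssignment(
        design_name=design_name or f"sparse_{k}t",
        k=k,
        tester_ids=tester_ids,
        line_to_tester=assignment,
    )


def select_testers(pool: LinePopulation | int, k: int, seed: int) -> np.ndarray:
    """Draw ``k`` distinct tester lines uniformly from the opposite pool."""
    n = pool if isinstance(pool, (int, np.integer)) else pool.n_lines
    if k > n:
        raise ValueError(f"cannot select {k} testers from a pool of {n} lines")
    rng = child_rng(seed, "testers")
    return np.sort(rng.choice(n, size=k, replace=False))


def incomplete_factorial_pairs(
    n_pool_f: int, n_pool_m: int, seed: int
) -> TestcrossAssignment:
    """Random perfect matching between equally sized pools.

    Each line of each pool appears in exactly one hybrid; the assignment maps
    female-pool line i to its male-pool partner.
    """
    if n_pool_f != n_pool_m:
        raise ValueError("incomplete factorial requires equally sized pools")
    rng = child_rng(seed, "factorial")
    partner = rng.permutation(n_pool_m)
    return TestcrossAssignment(
        design_name=INCOMPLETE_FACTORIAL,
        k=n_pool_m,
        tester_ids=np.arange(n_pool_m),
        line_to_tester=partner,
    )
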