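"""Greedy maximal-coverage reserve selection.

Both approaches select a fixed number of cells (the target size) by greedy
complementarity:

* raw-data approach — over the surveyed cells only, each step adds the cell
  contributing the most not-yet-covered recorded species (the first pick is
  simply the cell with the largest observed richness); once every recorded
  species is covered, the selection is topped up to the target size with
  uniformly random cells from the unsurveyed range.
* ENM approach — over all cells, each step adds the cell with the largest
  marginal gain in the expected number of species covered,
  ``sum_s [1 - prod_{i in A} (1 - p_si)]``, which is submodular, so the
  greedy solution is within a factor (1 - 1/e) of the optimum.

Ties are broken toward the lowest cell index in both greedies, making the
selections deterministic given the inputs.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass

import numpy as np

from .community_gen import Community
from .survey import Observation

__all__ = [
    "ReserveSelection",
    "greedy_raw",
    "greedy_expected",
    "expected_richness",
    "species_covered",
]


@dataclass
class ReserveSelection:
    approach: str  # "raw" | "enm"
    target_size: int
    selected: list[int]  # greedy cells first, random-fill cells after
    n_random_fill: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected cells must be unique")
        if len(self.selected) != self.target_size:
            raise ValueError("selection size must equal the target size")

    def to_json(self) -> str:
        return json.dumps(
            {
                "approach": self.approach,
                "target_size": self.target_size,
                "selected": list(map(int, self.selected)),
                "n_random_fill": self.n_random_fill,
                "seed": self.seed,
            }
        )


def _greedy_raw_order(observed: np.ndarray) -> list[int]:
    """Greedy column order over the survey submatrix until all recorded
    species are covered; returned indices are submatrix columns."""
    covered = np.zeros(observed.shape[0], dtype=bool)
    available = np.ones(observed.shape[1], dtype=bool)
    order: list[int] = []
    while True:
        gains = observed[~covered][:, available].sum(axis=0)
        if gains.size == 0 or gains.max() == 0:
            break
        j_avail = int(np.argmax(gains))  # argmax → first (lowest) index on ties
        j = int(np.flatnonzero(available)[j_avail])
        order.append(j)
        covered |= observed[:, j]
        available[j] = False
        if covered.all():
            break
    return order


def greedy_raw(
    observation: Observation,
    target_size: int,
    n_sites: int,
    rng: np.random.Generator,
    seed: int | None = None,
) -> ReserveSelection:
    """Raw-data approach: greedy complementarity on the observed records.

    The greedy phase runs until either the target size is reached or every
    species recorded in the survey is covered.  Remaining slots are filled
    with uniformly random cells from the unsurveyed range; if that range is
    exhausted, remaining surveyed cells are used (random order).
    """
    if target_size > n_sites:
        raise ValueError("target size exceeds the number of cells")
    surveyed = observation.design.surveyed
    order = _greedy_raw_order(observation.observed)
    selected = [int(surveyed[j]) for j in order[:target_size]]
    n_fill = target_size - len(selected)
    if n_fill > 0:
        chosen = set(selected)
        unsurveyed = np.setdiff1d(np.arange(n_sites), surveyed, assume_unique=False)
        pool = unsurveyed[~np.isin(unsurveyed, list(chosen))]
        take = min(n_fill, len(pool))
        if take:
            selected.extend(
                int(c) for c in rng.choice(pool, size=take, replace=False)
            )
        still = target_size - len(selected)
        if still > 0:
            leftover = np.setdiff1d(surveyed, np.asarray(selected, dtype=np.int64))
            selected.extend(
                int(c) for c in rng.choice(leftover, size=still, replace=False)
            )
    return ReserveSelection(
        approach="raw",
        target_size=target_size,
        selected=selected,
        n_random_fill=n_fill,
        seed=seed,
    )


def expected_richness(prob: np.ndarray, cells) -> float:
    """Expected number of species with at least one presence among ``cells``.

    ``sum_s [1 - prod_{i in cells} (1 - p_si)]``; rows that are entirely NaN
    (excluded species) contribute nothing.
    """
    cells = np.asarray(list(cells), dtype=np.int64)
    if cells.size == 0:
        return 0.0
    if cells.min() < 0 or cells.max() >= prob.shape[1]:
        raise IndexError("cell index out of range")
    sub = prob[:, cells]
    valid = ~np.isnan(sub).any(axis=1)
    miss = np.prod(1.0 - sub[valid], axis=1)
    return float(np.sum(1.0 - miss))


def greedy_expected(
    prob: np.ndarray, target_size: int, lazy: bool = True
) -> ReserveSelection:
    """ENM approach: greedily maximize expected species coverage.

    Maintains per-species residual non-coverage probabilities
    ``r_s = prod_{i in A} (1 - p_si)``; the marginal gain of cell j is
    ``sum_s r_s * p_sj``.  The lazy variant keeps stale gains in a priority
    queue and re-evaluates only the head — submodularity guarantees gains
    only shrink, so the pick is identical to the naive full recomputation.
    """
    n_sites = prob.shape[1]
    if target_size > n_sites:
        raise ValueError("target size exceeds the number of cells")
    P = prob[~np.isnan(prob).any(axis=1)]
    if P.shape[0] == 0:
        raise ValueError("no non-excluded species to prioritize")
    r = np.ones(P.shape[0])
    selected: list[int] = []
    if lazy:
        gains = P.sum(axis=0)
        heap = [(-gains[j], j) for j in range(n_sites)]
        heapq.heapify(heap)
        stale = np.zeros(n_sites, dtype=bool)
        chosen = np.zeros(n_sites, dtype=bool)
        for _ in range(target_size):
            while True:
                negg, j = heapq.heappop(heap)
                if chosen[j]:
                    continue
                if stale[j]:
                    g = float(r @ P[:, j])
                    stale[j] = False
                    heapq.heappush(heap, (-g, j))
                    continue
                break
            selected.append(int(j))
            chosen[j] = True
            r = r * (1.0 - P[:, j])
            stale[:] = ~chosen
    else:
        available = np.ones(n_sites, dtype=bool)
        for _ in range(target_size):
            gains = r @ P
            gains[~available] = -np.inf
            j = int(np.argmax(gains))
            selected.append(j)
            available[j] = False
            r = r * (1.0 - P[:, j])
    return ReserveSelection(
        approach="enm",
        target_size=target_size,
        selected=selected,
        n_random_fill=0,
    )


def species_covered(community: Community, cells) -> int:
    """Number of species with at least one TRUE presence among ``cells``.

    Judged against the ground-truth distribution, so species the survey
    never recorded still count when the selected cells happen to contain
    them.
    """
    cells = np.asarray(list(cells), dtype=np.int64)
    if cells.size == 0:
        return 0
    return int(community.presence[:, cells].any(axis=1).sum())
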