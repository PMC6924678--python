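"""Virtual community generation on a one-dimensional environmental gradient.

A community is a binary species x site presence/absence matrix that
simultaneously satisfies three constraints:

1. a rank-abundance curve (number of presence sites per species),
2. a richness pattern (number of species per site), and
3. unimodal environmental preferences for every species.

Generation proceeds in two phases.  First, a random matrix with exactly the
preset row and column sums (margins) is constructed, without regard to the
environment.  Second, pairs of species are repeatedly swapped between pairs
of sites whenever the swap strictly increases the total log-suitability of
the occupied cells; such 2x2 checkerboard swaps leave both margins
untouched, so the rank-abundance curve and richness pattern are preserved
exactly while the spatial arrangement converges toward the environmental
preferences.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "CommunitySpec",
    "DistributionSpec",
    "NicheRule",
    "MarginVectors",
    "Community",
    "InfeasibleMarginsError",
    "build_rank_abundance",
    "build_richness",
    "reconcile_margins",
    "gale_ryser_feasible",
    "assign_niches",
    "suitability",
    "log_suitability_matrix",
    "initial_assignment",
    "refine_by_swapping",
    "swap_objective",
    "generate_community",
    "default_community_spec",
]


class InfeasibleMarginsError(ValueError):
    """Raised when preset margins cannot be realized by any binary matrix."""


# ---------------------------------------------------------------------------
# specification dataclasses


@dataclass(frozen=True)
class DistributionSpec:
    """A marginal-distribution family plus its parameters.

    Families
    --------
    ``log_linear``
        For abundance: value at rank r is ``max_value * exp(-decay * r)``
        (log value linear in rank).  For richness: i.i.d. draws with
        ``P(k) ∝ exp(-rate * k)`` on ``0..max_value`` (log frequency linear
        in the value).
    ``log_normal``
        i.i.d. draws with ``log(value) ~ Normal(mu, sigma)`` (abundance
        only).
    ``empirical_table``
        i.i.d. draws from a user-supplied (value, frequency) table, sampled
        with replacement.  ``params`` holds either ``path`` to a two-column
        delimited text file or explicit ``values``/``frequencies`` lists.
    """

    family: str
    params: dict = field(default_factory=dict)

    _FAMILIES = ("log_linear", "log_normal", "empirical_table")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {self._FAMILIES}"
            )

    def table(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, frequencies) for an empirical_table spec."""
        if self.family != "empirical_table":
            raise ValueError("table() only applies to empirical_table specs")
        if "path" in self.params:
            raw = np.loadtxt(self.params["path"], delimiter=None, ndmin=2)
            if raw.shape[1] < 2:
                raw = np.loadtxt(self.params["path"], delimiter=",", ndmin=2)
            values, freqs = raw[:, 0], raw[:, 1]
        else:
            values = np.asarray(self.params["values"], dtype=float)
            freqs = np.asarray(self.params["frequencies"], dtype=float)
        if np.any(freqs < 0) or freqs.sum() <= 0:
            raise ValueError("empirical table frequencies must be non-negative, sum > 0")
        return values, freqs


@dataclass(frozen=True)
class NicheRule:
    """Unimodal suitability parameters shared by all species.

    Suitability of environment ``e`` for a species with optimum ``c`` and
    width ``w`` is ``expit(height - ((e - c) / w)**2)``: a symmetric
    unimodal curve peaking at ``expit(height)``.  Niche width grows linearly
    with relative abundance (``width = width_intercept +
    width_slope * abundance / n_sites``): a species occupying many cells of
    a single gradient cannot do so with a narrow niche.
    """

    height: float = 2.0
    width_intercept: float = 0.05
    width_slope: float = 0.5


@dataclass(frozen=True)
class CommunitySpec:
    n_sites: int
    n_species: int
    rank_abundance: DistributionSpec
    richness_pattern: DistributionSpec
    niche: NicheRule = field(default_factory=NicheRule)
    seed: int = 0
    #: abort if more than this fraction of species had to be clamped at n_sites
    max_clamp_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CommunitySpec":
        d = dict(d)
        d["rank_abundance"] = DistributionSpec(**d["rank_abundance"])
        d["richness_pattern"] = DistributionSpec(**d["richness_pattern"])
        d["niche"] = NicheRule(**d.get("niche", {}))
        return cls(**d)


@dataclass
class MarginVectors:
    """Preset row sums (abundance) and column sums (richness)."""

    abundance: np.ndarray
    richness: np.ndarray

    def validate(self, n_sites: int, n_species: int) -> None:
        ab, ri = self.abundance, self.richness
        if ab.min() < 1 or ab.max() > n_sites:
            raise ValueError("abundance out of [1, n_sites]")
        if ri.min() < 0 or ri.max() > n_species:
            raise ValueError("richness out of [0, n_species]")
        if ab.sum() != ri.sum():
            raise ValueError("margin totals differ")


@dataclass
class Community:
    """Ground-truth community: presence matrix plus niche parameters."""

    presence: np.ndarray  # bool, (n_species, n_sites)
    environment: np.ndarray  # float, (n_sites,), strictly increasing
    optima: np.ndarray  # float, (n_species,)
    widths: np.ndarray  # float, (n_species,)
    spec: CommunitySpec
    margins: MarginVectors

    @property
    def n_species(self) -> int:
        return self.presence.shape[0]

    @property
    def n_sites(self) -> int:
        return self.presence.shape[1]

    @property
    def abundance(self) -> np.ndarray:
        return self.margins.abundance


# ---------------------------------------------------------------------------
# margin construction


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def build_rank_abundance(
    spec: DistributionSpec,
    n_species: int,
    n_sites: int,
    rng: np.random.Generator,
    max_clamp_fraction: float = 0.1,
) -> np.ndarray:
    """Number of presence sites per species, species 0 being the most abundant.

    Values are rounded half-up and clamped to [1, n_sites]; if more than
    ``max_clamp_fraction`` of species exceed n_sites before clamping the
    requested curve cannot fit on the grid and the spec is rejected.
    """
    if spec.family == "log_linear":
        decay = float(spec.params.get("decay", spec.params.get("slope", 1.0)))
        max_value = float(spec.params.get("max_abundance", n_sites / 2))
        if decay <= 0 or max_value <= 0:
            raise ValueError("log_linear rank-abundance needs decay > 0, max_abundance > 0")
        raw = max_value * np.exp(-decay * np.arange(n_species))
    elif spec.family == "log_normal":
        mu = float(spec.params.get("mu", math.log(n_sites) / 3))
        sigma = float(spec.params.get("sigma", 1.0))
        if sigma <= 0:
            raise ValueError("log_normal sigma must be > 0")
        raw = np.sort(np.exp(rng.normal(mu, sigma, size=n_species)))[::-1]
    else:  # empirical_table
        values, freqs = spec.table()
        raw = np.sort(rng.choice(values, size=n_species, p=freqs / freqs.sum()))[::-1]
    n_over = int(np.count_nonzero(raw > n_sites + 0.5))
    if n_over > max_clamp_fraction * n_species:
        raise ValueError(
            f"rank-abundance spec infeasible: {n_over}/{n_species} species "
            f"exceed the {n_sites}-site grid before clamping"
        )
    return np.clip(_round_half_up(raw), 1, n_sites)


def build_richness(
    spec: DistributionSpec,
    n_sites: int,
    n_species: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Number of species per site, placed in a spatially random manner.

    Sites are exchangeable by construction: richness values are drawn
    i.i.d., so the pattern carries no spatial or environmental structure.
    """
    if spec.family == "log_linear":
        rate = float(spec.params.get("rate", 0.05))
        max_value = int(spec.params.get("max_richness", n_species))
        if rate <= 0:
            raise ValueError("log_linear richness needs rate > 0")
        support = np.arange(0, min(max_value, n_species) + 1)
        weights = np.exp(-rate * support)
        return rng.choice(support, size=n_sites, p=weights / weights.sum())
    if spec.family == "empirical_table":
        values, freqs = spec.table()
        draw = rng.choice(values, size=n_sites, p=freqs / freqs.sum())
        return np.clip(_round_half_up(draw), 0, n_species)
    raise ValueError(f"unsupported richness family {spec.family!r}")


def gale_ryser_feasible(
    abundance: np.ndarray, richness: np.ndarray, n_sites: int
) -> tuple[bool, int]:
    """Check that a bipartite degree pair (row sums, column sums) is realizable.

    Returns (feasible, k) where k is the first violated prefix inequality
    (1-based over the descending-sorted abundance), or 0 when feasible:
    sum of the k largest abundances must not exceed sum_j min(richness_j, k).
    """
    ab = np.sort(np.asarray(abundance, dtype=np.int64))[::-1]
    ri = np.asarray(richness, dtype=np.int64)
    if ab.sum() != ri.sum():
        return False, -1
    if len(ab) and ab.max() > n_sites:
        return False, -2
    lhs = np.cumsum(ab)
    # rhs_k = sum_j min(r_j, k), computed for all k at once via the sorted richness
    ri_sorted = np.sort(ri)
    csum = np.concatenate([[0], np.cumsum(ri_sorted)])
    total = ri_sorted.sum()
    for k in range(1, len(ab) + 1):
        # number of sites with richness < k
        below = int(np.searchsorted(ri_sorted, k, side="left"))
        rhs = csum[below] + k * (len(ri_sorted) - below)
        if lhs[k - 1] > rhs:
            return False, k
        if rhs >= total:
            break  # inequalities for larger k are implied
    return True, 0


def reconcile_margins(
    abundance: np.ndarray,
    richness: np.ndarray,
    n_sites: int,
    n_species: int,
    rng: np.random.Generator,
) -> MarginVectors:
    """Equalize the two margin totals and certify realizability.

    The richness vector is the one adjusted (the rank-abundance curve is the
    primary constraint): unit increments or decrements are applied at
    uniformly chosen sites, respecting the [0, n_species] bounds, until the
    totals match.  The adjusted pair must pass the Gale-Ryser feasibility
    check.
    """
    ab = np.asarray(abundance, dtype=np.int64).copy()
    ri = np.asarray(richness, dtype=np.int64).copy()
    deficit = int(ab.sum() - ri.sum())
    step = 1 if deficit > 0 else -1
    guard = 0
    while deficit != 0:
        i = int(rng.integers(len(ri)))
        if step > 0 and ri[i] < n_species:
            ri[i] += 1
            deficit -= 1
        elif step < 0 and ri[i] > 0:
            ri[i] -= 1
            deficit += 1
        guard += 1
        if guard > 1000 * (abs(deficit) + len(ri)):
            raise InfeasibleMarginsError("cannot equalize margin totals within bounds")
    ok, k = gale_ryser_feasible(ab, ri, n_sites)
    if not ok:
        raise InfeasibleMarginsError(
            f"margins not realizable: Gale-Ryser prefix inequality k={k} violated"
        )
    margins = MarginVectors(abundance=ab, richness=ri)
    margins.validate(n_sites, n_species)
    return margins


# ---------------------------------------------------------------------------
# niches and suitability


def assign_niches(
    margins: MarginVectors, spec: CommunitySpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw each species' environmental optimum and niche width.

    Optima are uniform over the environmental range [0, 1]; widths follow
    the linear rule of ``NicheRule`` and are therefore non-decreasing in
    abundance.
    """
    optima = rng.uniform(0.0, 1.0, size=spec.n_species)
    rule = spec.niche
    widths = rule.width_intercept + rule.width_slope * (
        margins.abundance / spec.n_sites
    )
    if np.any(widths <= 0):
        raise ValueError("niche width rule produced a non-positive width")
    return optima, widths


def suitability(e, c, w, h):
    """Unimodal environmental suitability: expit(h - ((e - c) / w)**2)."""
    z = (np.asarray(e, dtype=float) - c) / w
    return expit(h - z * z)


def log_suitability_matrix(
    environment: np.ndarray,
    optima: np.ndarray,
    widths: np.ndarray,
    height: float,
) -> np.ndarray:
    """log suitability for every (species, site) pair, shape (n_species, n_sites)."""
    z = (environment[None, :] - optima[:, None]) / widths[:, None]
    return log_expit(height - z * z)


# ---------------------------------------------------------------------------
# matrix construction


def initial_assignment(
    margins: MarginVectors, rng: np.random.Generator, n_trades: int | None = None
) -> np.ndarray:
    """Random binary matrix with exactly the preset margins, environment-blind.

    A deterministic Gale-Ryser fill (each species, in descending abundance,
    claims the sites with the largest remaining capacity) produces one
    realization; curveball trades — random exchanges of non-shared sites
    between two species — then mix it toward the uniform distribution over
    all margin-preserving matrices.
    """
    ab, ri = margins.abundance, margins.richness
    n_species, n_sites = len(ab), len(ri)
    capacity = ri.astype(np.int64).copy()
    P = np.zeros((n_species, n_sites), dtype=bool)
    order = np.argsort(-ab, kind="stable")
    for s in order:
        k = int(ab[s])
        # random tie-break among equal capacities
        pick = np.lexsort((rng.random(n_sites), -capacity))[:k]
        if capacity[pick[-1]] < 1:
            raise InfeasibleMarginsError("margins not realizable during fill")
        P[s, pick] = True
        capacity[pick] -= 1
    if np.any(capacity != 0):
        raise InfeasibleMarginsError("fill left unmet richness capacity")
    _curveball(P, rng, n_trades or 5 * n_species)
    return P


def _curveball(P: np.ndarray, rng: np.random.Generator, n_trades: int) -> None:
    """In-place curveball mixing: margins are invariant under every trade."""
    n_species = P.shape[0]
    if n_species < 2:
        return
    rows = [set(np.flatnonzero(P[s])) for s in range(n_species)]
    for _ in range(n_trades):
        a, b = rng.choice(n_species, size=2, replace=False)
        only_a = list(rows[a] - rows[b])
        only_b = list(rows[b] - rows[a])
        pool = only_a + only_b
        if not only_a or not only_b:
            continue
        perm = rng.permutation(len(pool))
        new_a = {pool[i] for i in perm[: len(only_a)]}
        new_b = {pool[i] for i in perm[len(only_a):]}
        rows[a] = (rows[a] - set(only_a)) | new_a
        rows[b] = (rows[b] - set(only_b)) | new_b
    P[:] = False
    for s, sites in enumerate(rows):
        P[s, list(sites)] = True


def swap_objective(P: np.ndarray, log_suit: np.ndarray) -> float:
    """Consistency objective: total log suitability over occupied cells."""
    return float(log_suit[P].sum())


def refine_by_swapping(
    P: np.ndarray,
    log_suit: np.ndarray,
    rng: np.random.Generator,
    stall_limit: int | None = None,
    max_proposals: int = 10_000_000,
    tol: float = 1e-12,
) -> tuple[np.ndarray, dict]:
    """Improve environmental consistency by margin-preserving pair swaps.

    Proposal: two distinct sites i, j uniformly; one species present at i
    and absent at j, and one present at j and absent at i, uniformly.
    Exchanging the two presences is a checkerboard swap — both margins are
    untouched — and is accepted iff it strictly increases the total log
    suitability of occupied cells (equivalently, the product of
    suitabilities).

    After ``stall_limit`` consecutive rejected random proposals (default
    10 x n_sites) or ``max_proposals`` in total, the refinement finishes
    with systematic sweeps over every site pair, applying the best
    improving species exchange for each pair, until a full sweep makes no
    swap: the returned matrix admits no improving pair swap at all.
    """
    n_species, n_sites = P.shape
    if stall_limit is None:
        stall_limit = 10 * n_sites
    Q = P.copy()
    n_accepted = 0
    n_proposals = 0
    stall = 0
    delta_total = 0.0
    chunk = 4096
    while stall < stall_limit and n_proposals < max_proposals:
        sites = rng.integers(n_sites, size=(chunk, 2))
        picks = rng.random(size=(chunk, 2))
        for (i, j), (u1, u2) in zip(sites, picks):
            n_proposals += 1
            if i == j:
                stall += 1
                continue
            at_i = Q[:, i]
            at_j = Q[:, j]
            cand_ij = np.flatnonzero(at_i & ~at_j)  # movable i -> j
            cand_ji = np.flatnonzero(at_j & ~at_i)  # movable j -> i
            if cand_ij.size == 0 or cand_ji.size == 0:
                stall += 1
                continue
            s1 = int(cand_ij[int(u1 * cand_ij.size)])
            s2 = int(cand_ji[int(u2 * cand_ji.size)])
            delta = (
                log_suit[s1, j] - log_suit[s1, i] + log_suit[s2, i] - log_suit[s2, j]
            )
            if delta > tol:
                Q[s1, i] = False
                Q[s1, j] = True
                Q[s2, j] = False
                Q[s2, i] = True
                n_accepted += 1
                stall = 0
                delta_total += delta
            else:
                stall += 1
            if stall >= stall_limit or n_proposals >= max_proposals:
                break
    n_sweep, sweep_gain = _sweep_to_local_optimum(Q, log_suit, rng, tol)
    return Q, {
        "n_proposals": n_proposals,
        "n_accepted": n_accepted + n_sweep,
        "n_sweep_accepted": n_sweep,
        "objective_gain": delta_total + sweep_gain,
    }


def _sweep_to_local_optimum(
    Q: np.ndarray, log_suit: np.ndarray, rng: np.random.Generator, tol: float
) -> tuple[int, float]:
    """Apply best-improving species exchanges over all site pairs until none
    remains; certifies that no improving pair swap exists in the result."""
    n_sites = Q.shape[1]
    n_accepted = 0
    gain_total = 0.0
    improved = True
    while improved:
        improved = False
        order = rng.permutation(n_sites * (n_sites - 1) // 2)
        pairs = np.column_stack(np.triu_indices(n_sites, k=1))[order]
        for i, j in pairs:
            at_i = Q[:, i]
            at_j = Q[:, j]
            d = log_suit[:, j] - log_suit[:, i]
            cand_ij = np.flatnonzero(at_i & ~at_j)
            cand_ji = np.flatnonzero(at_j & ~at_i)
            if cand_ij.size == 0 or cand_ji.size == 0:
                continue
            s1 = int(cand_ij[np.argmax(d[cand_ij])])
            s2 = int(cand_ji[np.argmin(d[cand_ji])])
            delta = d[s1] - d[s2]
            if delta > tol:
                Q[s1, i] = False
                Q[s1, j] = True
                Q[s2, j] = False
                Q[s2, i] = True
                n_accepted += 1
                gain_total += float(delta)
                improved = True
    return n_accepted, gain_total


# ---------------------------------------------------------------------------
# pipeline


def generate_community(spec: CommunitySpec) -> Community:
    """Full generation pipeline; deterministic for a given spec (incl. seed).

    Environment values are ``e_i = i / (n_sites - 1)``: the gradient
    increases linearly along the spatial axis and spans the unit interval.
    """
    rng = np.random.default_rng(spec.seed)
    environment = np.arange(spec.n_sites) / (spec.n_sites - 1)
    abundance = build_rank_abundance(
        spec.rank_abundance, spec.n_species, spec.n_sites, rng, spec.max_clamp_fraction
    )
    richness = build_richness(spec.richness_pattern, spec.n_sites, spec.n_species, rng)
    margins = reconcile_margins(abundance, richness, spec.n_sites, spec.n_species, rng)
    optima, widths = assign_niches(margins, spec, rng)
    P0 = initial_assignment(margins, rng)
    log_suit = log_suitability_matrix(environment, optima, widths, spec.niche.height)
    P, _stats = refine_by_swapping(P0, log_suit, rng)
    return Community(
        presence=P,
        environment=environment,
        optima=optima,
        widths=widths,
        spec=spec,
        margins=margins,
    )


def default_community_spec(
    n_sites: int = 1000,
    n_species: int = 1000,
    kind: str = "log_linear",
    seed: int = 0,
    niche: NicheRule | None = None,
) -> CommunitySpec:
    """A ready-to-run spec with margins scaled to the grid.

    ``kind`` selects the rank-abundance family (``log_linear`` or
    ``log_normal``).  The most abundant species occupies half the grid and
    the curve decays to single-site occupancy at the last rank; the
    richness pattern is log-linear with its rate matched so that the
    expected total of the two margins agree (small residual differences are
    absorbed by margin reconciliation).
    """
    max_ab = n_sites / 2
    if kind == "log_linear":
        decay = math.log(max_ab) / max(n_species - 1, 1)
        ra = DistributionSpec("log_linear", {"max_abundance": max_ab, "decay": decay})
        expected_total = max_ab * (1 - math.exp(-decay * n_species)) / (
            1 - math.exp(-decay)
        )
    elif kind == "log_normal":
        sigma = 1.2
        mu = math.log(max_ab) / 2
        ra = DistributionSpec("log_normal", {"mu": mu, "sigma": sigma})
        expected_total = n_species * math.exp(mu + sigma**2 / 2)
    else:
        raise ValueError(f"unknown default community kind {kind!r}")
    mean_richness = max(expected_total / n_sites, 1.0)
    rate = 1.0 / mean_richness
    max_richness = min(n_species, int(10 * mean_richness))
    rp = DistributionSpec("log_linear", {"rate": rate, "max_richness": max_richness})
    return CommunitySpec(
        n_sites=n_sites,
        n_species=n_species,
        rank_abundance=ra,
        richness_pattern=rp,
        niche=niche or NicheRule(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization (triplet CSV layout, 0-based ids)


def write_community(community: Community, out_dir: str | Path) -> None:
    """Write presence triplets, site table, species table and the spec echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp, si = np.nonzero(community.presence)
    with open(out / "presence.csv", "w") as fh:
        fh.write("species_id,site_id,presence\n")
        for s, i in zip(sp, si):
            fh.write(f"{s},{i},1\n")
    with open(out / "sites.csv", "w") as fh:
        fh.write("site_id,environment\n")
        for i, e in enumerate(community.environment):
            fh.write(f"{i},{e:.10g}\n")
    with open(out / "species.csv", "w") as fh:
        fh.write("species_id,optimum,width,abundance\n")
        for s in range(community.n_species):
            fh.write(
                f"{s},{community.optima[s]:.10g},{community.widths[s]:.10g},"
                f"{community.margins.abundance[s]}\n"
            )
    with open(out / "spec.json", "w") as fh:
        json.dump(community.spec.to_dict(), fh, indent=2)


def read_community(in_dir: str | Path) -> Community:
    """Read a community written by :func:`write_community`."""
    src = Path(in_dir)
    with open(src / "spec.json") as fh:
        spec = CommunitySpec.from_dict(json.load(fh))
    sites = np.loadtxt(src / "sites.csv", delimiter=",", skiprows=1, ndmin=2)
    environment = sites[np.argsort(sites[:, 0]), 1]
    species = np.loadtxt(src / "species.csv", delimiter=",", skiprows=1, ndmin=2)
    order = np.argsort(species[:, 0])
    optima = species[order, 1]
    widths = species[order, 2]
    abundance = species[order, 3].astype(np.int64)
    n_species, n_sites = len(optima), len(environment)
    P = np.zeros((n_species, n_sites), dtype=bool)
    trip = np.loadtxt(src / "presence.csv", delimiter=",", skiprows=1, ndmin=2)
    if trip.size:
        P[trip[:, 0].astype(int), trip[:, 1].astype(int)] = True
    margins = MarginVectors(abundance=abundance, richness=P.sum(axis=0))
    return Community(
        presence=P,
        environment=environment,
        optima=optima,
        widths=widths,
        spec=spec,
        margins=margins,
    )
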