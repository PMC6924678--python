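"""Virtual surveys with controlled range and spatial bias.

The surveyed fraction R of the grid is laid out in N equal blocks: each
block receives a run of ``n_sites * R / N`` consecutive cells at a uniformly
random offset.  Fewer blocks means the surveyed cells are more spatially
clumped, i.e. a stronger survey bias ("strong" = 2 blocks, "weak" = 5
blocks, "none" = a simple random sample of cells).  Surveys are error-free:
the observation is the true presence/absence matrix restricted to the
surveyed cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .community_gen import Community

__all__ = ["BIAS_BLOCKS", "SurveyDesign", "Observation", "make_survey", "observe"]

#: block count per named bias level; None = simple random sampling
BIAS_BLOCKS = {"none": None, "weak": 5, "strong": 2}


@dataclass(frozen=True)
class SurveyDesign:
    R: float
    bias_level: str
    n_blocks: int | None
    surveyed: np.ndarray  # sorted cell indices
    seed: int | None = None

    @property
    def n_surveyed(self) -> int:
        return len(self.surveyed)

    def to_json(self) -> str:
        return json.dumps(
            {
                "R": self.R,
                "bias_level": self.bias_level,
                "n_blocks": self.n_blocks,
                "seed": self.seed,
                "surveyed": self.surveyed.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SurveyDesign":
        d = json.loads(text)
        return cls(
            R=d["R"],
            bias_level=d["bias_level"],
            n_blocks=d["n_blocks"],
            surveyed=np.asarray(d["surveyed"], dtype=np.int64),
            seed=d.get("seed"),
        )


@dataclass
class Observation:
    """Truth restricted to the surveyed cells (surveys are error-free)."""

    design: SurveyDesign
    observed: np.ndarray  # bool, (n_species, n_surveyed)
    observed_abundance: np.ndarray  # presences per species within the survey

    @property
    def recorded_species(self) -> np.ndarray:
        """Indices of species with at least one record in the survey."""
        return np.flatnonzero(self.observed_abundance > 0)


def _n_cells(R: float, n_sites: int) -> int:
    return int(np.floor(n_sites * R + 0.5))


def make_survey(
    R: float,
    bias_level: str,
    n_sites: int,
    rng: np.random.Generator,
    seed: int | None = None,
) -> SurveyDesign:
    """Choose the surveyed cell set for a given range R and bias level.

    Blocked designs place ``n_sites*R/N`` consecutive cells per block at a
    uniform offset; if ``n_sites*R`` is indivisible by N the remainder cells
    are assigned one each to randomly chosen blocks.  The "none" level is a
    simple random sample of cells without replacement.
    """
    if not (0.0 < R <= 1.0):
        raise ValueError(f"R must be in (0, 1], got {R}")
    if bias_level not in BIAS_BLOCKS:
        raise ValueError(f"bias_level must be one of {sorted(BIAS_BLOCKS)}")
    n_cells = _n_cells(R, n_sites)
    if n_cells < 1:
        raise ValueError("survey must cover at least one cell")
    n_blocks = BIAS_BLOCKS[bias_level]
    if n_blocks is None:
        cells = np.sort(rng.choice(n_sites, size=n_cells, replace=False))
        return SurveyDesign(R, bias_level, None, cells.astype(np.int64), seed)
    if n_sites % n_blocks != 0:
        raise ValueError(f"{n_blocks} blocks do not evenly divide {n_sites} cells")
    block_size = n_sites // n_blocks
    quota = np.full(n_blocks, n_cells // n_blocks, dtype=np.int64)
    remainder = n_cells - quota.sum()
    if remainder:
        quota[rng.choice(n_blocks, size=int(remainder), replace=False)] += 1
    if np.any(quota > block_size):
        raise ValueError("per-block quota exceeds block size")
    pieces = []
    for b in range(n_blocks):
        q = int(quota[b])
        if q == 0:
            continue
        start = int(rng.integers(0, block_size - q + 1))
        pieces.append(b * block_size + start + np.arange(q))
    cells = np.sort(np.concatenate(pieces))
    return SurveyDesign(R, bias_level, n_blocks, cells.astype(np.int64), seed)


def observe(community: Community, design: SurveyDesign) -> Observation:
    """Restrict the true presence matrix to the surveyed cells."""
    if design.surveyed.max(initial=-1) >= community.n_sites:
        raise IndexError("survey design indexes cells outside the community grid")
    sub = community.presence[:, design.surveyed]
    return Observation(
        design=design,
        observed=sub,
        observed_abundance=sub.sum(axis=1),
    )


def write_observation(obs: Observation, path: str | Path) -> None:
    """Triplet CSV of observed presences; site ids are the original cell ids."""
    with open(path, "w") as fh:
        fh.write("species_id,site_id,presence\n")
        sp, col = np.nonzero(obs.observed)
        for s, c in zip(sp, col):
            fh.write(f"{s},{obs.design.surveyed[c]},1\n")
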