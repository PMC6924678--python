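"""Effectiveness evaluation and the factorial simulation sweep.

The central quantity is the effectiveness index

    (species covered by the ENM-based reserve)
    / (species covered by the raw-data reserve)  -  1,

positive exactly when prioritizing on modelled probabilities covers more
species than prioritizing on the raw records.  ``run_one`` executes the full
pipeline for one factor combination (survey -> models -> both selections ->
metrics, with both approaches consuming the identical observation), and
``run_sweep`` crosses community types, replicates, survey ranges, bias
levels, target sizes and algorithms into a long-format results table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .community_gen import Community, CommunitySpec, default_community_spec, generate_community
from .niche_models import ModelConfig, fit_niche_models
from .prioritization import greedy_expected, greedy_raw, species_covered
from .survey import make_survey, observe

__all__ = [
    "RunRecord",
    "SweepConfig",
    "derive_seed",
    "effectiveness_index",
    "rare_species_metrics",
    "run_one",
    "plan_sweep",
    "run_sweep",
    "summarize_sweep",
]

logger = logging.getLogger("nichesim")

RARE_THRESHOLD_DEFAULT = 20  # presence records below which a species is "rare"


def derive_seed(master_seed: int, *tokens) -> int:
    """Stable per-cell sub-seed from the master seed and a factor tuple.

    Hash-based so any single factorial cell can be re-run in isolation and
    reproduce its record exactly.  Always < 2**31.
    """
    text = repr((int(master_seed),) + tuple(tokens))
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def effectiveness_index(covered_enm: int, covered_raw: int) -> float:
    """covered_enm / covered_raw - 1; NaN (with a warning) when raw covers none."""
    if covered_enm < 0 or covered_raw < 0:
        raise ValueError("coverage counts must be non-negative")
    if covered_raw == 0:
        logger.warning("raw-data reserve covers zero species; effectiveness undefined")
        return float("nan")
    return covered_enm / covered_raw - 1.0


def rare_species_metrics(
    community: Community, cells, threshold: int = RARE_THRESHOLD_DEFAULT
) -> tuple[int, float]:
    """(number of covered rare species, their ratio among all covered species).

    Rare means fewer than ``threshold`` true presence records.  The ratio is
    0.0 when the reserve covers no species at all.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    cells = np.asarray(list(cells), dtype=np.int64)
    if cells.size == 0:
        return 0, 0.0
    covered = community.presence[:, cells].any(axis=1)
    rare = community.abundance < threshold
    n_rare = int(np.count_nonzero(covered & rare))
    n_total = int(np.count_nonzero(covered))
    return n_rare, (n_rare / n_total if n_total else 0.0)


@dataclass
class RunRecord:
    """One factorial cell's factors and metrics."""

    community_type: str
    replicate: int
    R: float
    bias_level: str
    target_proportion: float
    algorithm: str
    target_size: int
    covered_raw: int
    covered_enm: int
    effectiveness: float
    covered_rare_raw: int
    covered_rare_enm: int
    rare_ratio_raw: float
    rare_ratio_enm: float
    effectiveness_rare: float
    mean_auc: float
    n_excluded_species: int
    n_recorded_species: int
    seed: int

    def to_row(self) -> dict:
        return dataclasses.asdict(self)


def _target_size(target_proportion: float, n_sites: int) -> int:
    return int(np.floor(target_proportion * n_sites + 0.5))


def run_one(
    community: Community,
    R: float,
    bias_level: str,
    target_proportion: float,
    algorithm: str,
    master_seed: int,
    model_config: ModelConfig | None = None,
    rare_threshold: int = RARE_THRESHOLD_DEFAULT,
    community_type: str = "custom",
    replicate: int = 0,
) -> RunRecord:
    """Execute one survey -> model -> prioritize -> evaluate pipeline.

    The same observation feeds both the raw-data and the ENM approach (a
    paired design); the survey, the model fits and the raw random fill each
    consume an independent sub-seed derived from ``master_seed``, so the
    record is reproducible from its factors alone.

    ``algorithm="oracle"`` substitutes the true presence/absence matrix
    (restricted to species recorded in the survey) for fitted
    probabilities — the perfect-knowledge reference in which the two
    approaches tie whenever the survey is complete.
    """
    model_config = model_config or ModelConfig()
    n_sites = community.n_sites
    factors = (community_type, replicate, R, bias_level, algorithm)
    survey_rng = np.random.default_rng(derive_seed(master_seed, "survey", *factors[:4]))
    design = make_survey(R, bias_level, n_sites, survey_rng)
    obs = observe(community, design)

    if algorithm == "oracle":
        prob = community.presence.astype(float)
        prob[obs.observed_abundance == 0, :] = np.nan
        n_excluded = int(np.count_nonzero(obs.observed_abundance == 0))
        mean_auc = float("nan")
        clip = None
    else:
        model_rng = np.random.default_rng(derive_seed(master_seed, "model", *factors))
        models = fit_niche_models(
            obs, community.environment, algorithm, model_config, model_rng
        )
        prob = models.prob
        n_excluded = models.n_excluded
        mean_auc = models.mean_auc(community)
        clip = model_config.clip

    return _evaluate_selections(
        community, obs, prob, clip, R, bias_level, target_proportion, algorithm,
        master_seed, rare_threshold, community_type, replicate,
        n_excluded, mean_auc,
    )


def _evaluate_selections(
    community, obs, prob, clip, R, bias_level, target_proportion, algorithm,
    master_seed, rare_threshold, community_type, replicate, n_excluded, mean_auc,
) -> RunRecord:
    n_sites = community.n_sites
    target_size = _target_size(target_proportion, n_sites)
    raw_seed = derive_seed(
        master_seed, "rawfill", community_type, replicate, R, bias_level,
        target_proportion, algorithm,
    )
    raw_sel = greedy_raw(
        obs, target_size, n_sites, np.random.default_rng(raw_seed), seed=raw_seed
    )
    if np.count_nonzero(obs.observed_abundance > 0) == 0:
        # an empty survey leaves the ENM approach with no species to model;
        # its reserve degrades to a random selection, like the raw fill
        fill_seed = derive_seed(
            master_seed, "enmfill", community_type, replicate, R, bias_level,
            target_proportion, algorithm,
        )
        cells = np.random.default_rng(fill_seed).choice(
            n_sites, size=target_size, replace=False
        )
        from .prioritization import ReserveSelection

        enm_sel = ReserveSelection(
            "enm", target_size, [int(c) for c in cells], target_size, seed=fill_seed
        )
    else:
        P = prob if clip is None else np.clip(prob, clip, 1.0 - clip)
        enm_sel = greedy_expected(P, target_size)

    covered_raw = species_covered(community, raw_sel.selected)
    covered_enm = species_covered(community, enm_sel.selected)
    rare_raw, ratio_raw = rare_species_metrics(community, raw_sel.selected, rare_threshold)
    rare_enm, ratio_enm = rare_species_metrics(community, enm_sel.selected, rare_threshold)
    eff_rare = (
        rare_enm / rare_raw - 1.0 if rare_raw > 0 else float("nan")
    )
    return RunRecord(
        community_type=community_type,
        replicate=replicate,
        R=R,
        bias_level=bias_level,
        target_proportion=target_proportion,
        algorithm=algorithm,
        target_size=target_size,
        covered_raw=covered_raw,
        covered_enm=covered_enm,
        effectiveness=effectiveness_index(covered_enm, covered_raw),
        covered_rare_raw=rare_raw,
        covered_rare_enm=rare_enm,
        rare_ratio_raw=ratio_raw,
        rare_ratio_enm=ratio_enm,
        effectiveness_rare=eff_rare,
        mean_auc=mean_auc,
        n_excluded_species=n_excluded,
        n_recorded_species=int(np.count_nonzero(obs.observed_abundance > 0)),
        seed=master_seed,
    )


# ---------------------------------------------------------------------------
# factorial sweep

#: the full-scale factorial: 19 survey ranges x 3 biases x 5 targets
R_VALUES_FULL = tuple(round(0.05 * k, 2) for k in range(1, 20))
BIAS_LEVELS_FULL = ("none", "weak", "strong")
TARGET_PROPORTIONS_FULL = (0.010, 0.025, 0.050, 0.091, 0.17)
ALGORITHMS_FULL = ("glm", "gam", "rf")


@dataclass
class SweepConfig:
    community_specs: dict[str, CommunitySpec]
    n_replicates: int = 10
    R_values: Sequence[float] = R_VALUES_FULL
    bias_levels: Sequence[str] = BIAS_LEVELS_FULL
    target_proportions: Sequence[float] = TARGET_PROPORTIONS_FULL
    algorithms: Sequence[str] = ALGORITHMS_FULL
    master_seed: int = 0
    model_config: ModelConfig = field(default_factory=ModelConfig)
    rare_threshold: int = RARE_THRESHOLD_DEFAULT

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        d = dict(d)
        specs = {}
        for name, s in d.pop("community_types").items():
            specs[name] = (
                s if isinstance(s, CommunitySpec) else CommunitySpec.from_dict(s)
            )
        mc = d.pop("model_config", None)
        kwargs = {
            "community_specs": specs,
            "n_replicates": d.pop("n_replicates", 10),
            "master_seed": d.pop("master_seed", 0),
        }
        for key in ("R_values", "bias_levels", "target_proportions", "algorithms",
                    "rare_threshold"):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ValueError(f"unknown sweep config keys: {sorted(d)}")
        if mc is not None:
            kwargs["model_config"] = (
                mc if isinstance(mc, ModelConfig) else ModelConfig(**mc)
            )
        return cls(**kwargs)


def plan_sweep(config: SweepConfig) -> list[tuple]:
    """Enumerate every factorial cell (type, replicate, R, bias, target, algorithm)."""
    return list(
        itertools.product(
            sorted(config.community_specs),
            range(config.n_replicates),
            config.R_values,
            config.bias_levels,
            config.target_proportions,
            config.algorithms,
        )
    )


_KEY_COLS = ["community_type", "replicate", "R", "bias_level",
             "target_proportion", "algorithm"]


def run_sweep(
    config: SweepConfig,
    out_path: str | Path | None = None,
    resume: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full factorial design and return the long-format results table.

    Replicate communities are generated once per (community type, replicate)
    and reused across all survey/bias/target/algorithm levels; model fits
    are likewise shared across target sizes, which only affect the
    prioritization step.  With ``resume=True`` and an existing ``out_path``,
    completed cells are skipped and new records appended.
    """
    done: set[tuple] = set()
    rows: list[dict] = []
    if out_path is not None:
        # config echo alongside the long-format CSV
        echo = {
            "community_types": {
                name: s.to_dict() for name, s in config.community_specs.items()
            },
            "n_replicates": config.n_replicates,
            "R_values": list(config.R_values),
            "bias_levels": list(config.bias_levels),
            "target_proportions": list(config.target_proportions),
            "algorithms": list(config.algorithms),
            "master_seed": config.master_seed,
            "model_config": dataclasses.asdict(config.model_config),
            "rare_threshold": config.rare_threshold,
        }
        echo_path = Path(out_path).with_suffix(".config.json")
        with open(echo_path, "w") as fh:
            json.dump(echo, fh, indent=2)
    if resume and out_path is not None and Path(out_path).exists():
        prior = pd.read_csv(out_path)
        rows = prior.to_dict("records")
        done = {tuple(r[k] for k in _KEY_COLS) for r in rows}
        logger.info("resuming sweep: %d records already present", len(done))

    plan = plan_sweep(config)
    grouped: dict[tuple, list[tuple]] = {}
    for cell in plan:
        ctype, rep, R, bias, target, algo = cell
        grouped.setdefault((ctype, rep, R, bias, algo), []).append(cell)

    n_done = 0
    community_cache: dict[tuple, Community] = {}
    for (ctype, rep, R, bias, algo), cells in grouped.items():
        pending = [c for c in cells if (ctype, rep, c[2], bias, c[4], algo) not in done]
        if not pending:
            continue
        ck = (ctype, rep)
        if ck not in community_cache:
            spec = dataclasses.replace(
                config.community_specs[ctype],
                seed=derive_seed(config.master_seed, "community", ctype, rep),
            )
            community_cache[ck] = generate_community(spec)
        community = community_cache[ck]

        survey_rng = np.random.default_rng(
            derive_seed(config.master_seed, "survey", ctype, rep, R, bias)
        )
        design = make_survey(R, bias, community.n_sites, survey_rng)
        obs = observe(community, design)
        if algo == "oracle":
            prob = community.presence.astype(float)
            prob[obs.observed_abundance == 0, :] = np.nan
            n_excluded = int(np.count_nonzero(obs.observed_abundance == 0))
            mean_auc = float("nan")
            clip = None
        else:
            model_rng = np.random.default_rng(
                derive_seed(config.master_seed, "model", ctype, rep, R, bias, algo)
            )
            models = fit_niche_models(
                obs, community.environment, algo, config.model_config, model_rng
            )
            prob = models.prob
            n_excluded = models.n_excluded
            mean_auc = models.mean_auc(community)
            clip = config.model_config.clip

        for cell in pending:
            target = cell[4]
            rec = _evaluate_selections(
                community, obs, prob, clip, R, bias, target, algo,
                config.master_seed, config.rare_threshold, ctype, rep,
                n_excluded, mean_auc,
            )
            rows.append(rec.to_row())
            n_done += 1
            if progress and n_done % 50 == 0:
                logger.info("sweep progress: %d new records", n_done)
        if out_path is not None:
            pd.DataFrame(rows).to_csv(out_path, index=False)
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df


def summarize_sweep(
    results: pd.DataFrame,
    groupby: Sequence[str],
    rare: bool = False,
) -> pd.DataFrame:
    """Percentage of beneficial cases and median effectiveness per group.

    Beneficial means effectiveness (or the rare-species effectiveness when
    ``rare=True``) strictly greater than zero; undefined (NaN) ratios are
    excluded from the denominator but counted in ``n_missing``.
    """
    if results.empty:
        raise ValueError("results table is empty")
    groupby = list(groupby)
    for g in groupby:
        if g not in results.columns:
            raise KeyError(f"unknown factor {g!r}")
    col = "effectiveness_rare" if rare else "effectiveness"

    def agg(g: pd.DataFrame) -> pd.Series:
        valid = g[col].dropna()
        n_pos = int((valid > 0).sum())
        return pd.Series(
            {
                "n": len(g),
                "n_valid": len(valid),
                "n_missing": len(g) - len(valid),
                "n_beneficial": n_pos,
                "pct_beneficial": 100.0 * n_pos / len(valid) if len(valid) else float("nan"),
                "median_effectiveness": float(valid.median()) if len(valid) else float("nan"),
            }
        )

    out = results.groupby(groupby, sort=True).apply(agg, include_groups=False)
    return out.reset_index()


def medians_by_R(
    results: pd.DataFrame, groupby: Sequence[str], rare: bool = False
) -> pd.DataFrame:
    """Median effectiveness at each survey range R within each group
    (the quantity a median-effectiveness line chart traces)."""
    col = "effectiveness_rare" if rare else "effectiveness"
    keys = list(groupby) + ["R"]
    med = results.groupby(keys, sort=True)[col].median()
    return med.rename("median_effectiveness").reset_index()


def default_sweep_config(
    n_sites: int = 1000,
    n_species: int = 1000,
    master_seed: int = 0,
    **overrides,
) -> SweepConfig:
    """The full-scale factorial shape over the package's default community types.

    Type 3 demonstrates the empirical-table mechanism with a synthetic
    heavy-tailed frequency table (many rare, few very common species) — a
    stand-in for rank-abundance tables extracted from real survey reports,
    which users supply as two-column text files.
    """
    from .community_gen import DistributionSpec

    base1 = default_community_spec(n_sites, n_species, "log_linear")
    base2 = default_community_spec(n_sites, n_species, "log_normal")
    # synthetic heavy-tailed table: P(abundance = k) ∝ k^-1.6 on a log grid
    values = np.unique(np.round(np.geomspace(1, n_sites / 2, 40))).astype(float)
    freqs = values ** -1.6
    ra3 = DistributionSpec(
        "empirical_table", {"values": values.tolist(), "frequencies": freqs.tolist()}
    )
    mean_ab3 = float((values * freqs).sum() / freqs.sum())
    rp3 = DistributionSpec(
        "log_linear",
        {
            "rate": n_sites / (mean_ab3 * n_species),
            "max_richness": min(n_species, int(10 * mean_ab3 * n_species / n_sites)),
        },
    )
    base3 = dataclasses.replace(base1, rank_abundance=ra3, richness_pattern=rp3)
    specs = {
        "type1_log_linear": base1,
        "type2_log_normal": base2,
        "type3_empirical": base3,
    }
    cfg = SweepConfig(community_specs=specs, master_seed=master_seed)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg
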