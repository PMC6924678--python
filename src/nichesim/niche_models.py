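"""Per-species presence/absence niche models and whole-grid prediction.

One model is fitted per species on the surveyed cells only, then used to
predict the probability of presence at every cell of the grid.  Three
algorithms are supported:

``glm``
    Binomial GLM with logit link and a linear + quadratic term of the single
    environmental variable — the same functional form that generates the
    community, so the model is correctly specified.
``gam``
    Binomial GAM with logit link and a penalized cubic B-spline of the
    environment.
``rf``
    Random-forest classifier on the single environmental predictor;
    predicted probabilities are the forests' vote fractions, and tree
    complexity (minimum leaf size) is tuned by out-of-bag error.

Species never observed in the survey cannot be modelled and are excluded;
species observed everywhere in the survey carry no contrast and receive a
constant-prevalence predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from statsmodels.gam.api import BSplines, GLMGam

from .community_gen import Community
from .survey import Observation

__all__ = [
    "ModelConfig",
    "SpeciesModel",
    "NicheModelSet",
    "fit_species_model",
    "fit_niche_models",
    "predict_probabilities",
    "compute_auc",
]

ALGORITHMS = ("glm", "gam", "rf")

STATUS_FITTED = "fitted"
STATUS_EXCLUDED = "excluded_never_observed"
STATUS_DEGENERATE = "degenerate_constant"


@dataclass(frozen=True)
class ModelConfig:
    """Tuning knobs for the three algorithms.

    glm_ridge
        L2 penalty applied only when the plain IRLS fit fails to converge
        (e.g. complete separation).
    gam_df_cap
        Upper bound on the B-spline basis dimension; the effective dimension
        is ``min(cap, n_distinct_env - 1)`` and falls back to the quadratic
        GLM when fewer than 5 distinct environment values are surveyed.
    gam_alpha
        Fixed smoothing penalty weight for the spline.
    rf_n_estimators / rf_leaf_grid
        Forest size and the minimum-leaf-size grid searched by out-of-bag
        error.
    clip
        Probabilities are clipped to [clip, 1 - clip] before entering the
        expected-coverage greedy, so that a numerically exact 1.0 cannot
        permanently zero a species' residual.
    """

    glm_ridge: float = 1e-4
    gam_df_cap: int = 10
    gam_degree: int = 3
    gam_alpha: float = 1e-3
    rf_n_estimators: int = 500
    rf_leaf_grid: tuple[int, ...] = (1, 5, 10, 25)
    clip: float = 1e-9


@dataclass
class SpeciesModel:
    status: str
    predict: Callable[[np.ndarray], np.ndarray]
    meta: dict = field(default_factory=dict)


@dataclass
class NicheModelSet:
    """Fitted predictors and the species x site probability matrix.

    ``prob`` rows are NaN for excluded (never-observed) species;
    ``included`` flags the species that have a probability row.
    """

    algorithm: str
    statuses: list[str]
    prob: np.ndarray  # (n_species, n_sites); NaN rows for excluded species
    included: np.ndarray  # bool mask over species
    fit_meta: list[dict]

    @property
    def n_excluded(self) -> int:
        return int(np.count_nonzero(~self.included))

    def mean_auc(self, community: Community) -> float:
        """Mean rank-based AUC over modelled species, judged against truth.

        Species whose true distribution is constant over the grid (never or
        always present) have undefined AUC and are skipped.
        """
        aucs = []
        for s in np.flatnonzero(self.included):
            a = compute_auc(self.prob[s], community.presence[s])
            if not np.isnan(a):
                aucs.append(a)
        return float(np.mean(aucs)) if aucs else float("nan")


def _constant_model(p: float, status: str, **meta) -> SpeciesModel:
    return SpeciesModel(
        status=status,
        predict=lambda env, _p=float(np.clip(p, 0.0, 1.0)): np.full(
            np.asarray(env).shape, _p
        ),
        meta={"constant": float(p), **meta},
    )


def _fit_glm(env: np.ndarray, y: np.ndarray, config: ModelConfig) -> SpeciesModel:
    X = np.column_stack([np.ones_like(env), env, env**2])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e6:
            raise RuntimeError("diverged")
        conf = np.asarray(res.conf_int())
        return SpeciesModel(
            status=STATUS_FITTED,
            predict=lambda e, b=params: expit(b[0] + b[1] * e + b[2] * e**2),
            meta={
                "coef": params.tolist(),
                "conf_int": conf.tolist(),
                "penalized": False,
            },
        )
    except Exception:
        pass
    # ridge rescue for separation / non-convergence
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lr = LogisticRegression(
                penalty="l2", C=1.0 / config.glm_ridge, solver="lbfgs", max_iter=1000
            )
            lr.fit(np.column_stack([env, env**2]), y)
        b = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        return SpeciesModel(
            status=STATUS_FITTED,
            predict=lambda e, b=b: expit(b[0] + b[1] * e + b[2] * e**2),
            meta={"coef": b.tolist(), "penalized": True},
        )
    except Exception:
        return _constant_model(float(y.mean()), STATUS_FITTED, fallback="constant")


def _fit_gam(env: np.ndarray, y: np.ndarray, config: ModelConfig) -> SpeciesModel:
    distinct = np.unique(env)
    df = min(config.gam_df_cap, len(distinct) - 1)
    if df < config.gam_degree + 1:
        # not enough support for a spline basis; quadratic GLM stands in
        m = _fit_glm(env, y, config)
        m.meta["gam_fallback"] = "glm"
        return m
    lo, hi = float(env.min()), float(env.max())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            smoother = BSplines(
                env[:, None], df=[df], degree=[config.gam_degree]
            )
            gam = GLMGam(
                y,
                exog=np.ones((len(y), 1)),
                smoother=smoother,
                alpha=[config.gam_alpha],
                family=sm.families.Binomial(),
            )
            res = gam.fit(maxiter=100)
        if not np.all(np.isfinite(np.asarray(res.params))):
            raise RuntimeError("diverged")

        def predict(e, res=res, lo=lo, hi=hi):
            # spline basis is undefined outside the surveyed range; hold the
            # boundary value constant beyond it
            e = np.clip(np.asarray(e, dtype=float), lo, hi)
            with np.errstate(over="ignore"):
                return np.asarray(
                    res.predict(np.ones((e.size, 1)), exog_smooth=e[:, None])
                ).reshape(np.shape(e))

        return SpeciesModel(
            status=STATUS_FITTED, predict=predict, meta={"df": df, "alpha": config.gam_alpha}
        )
    except Exception:
        m = _fit_glm(env, y, config)
        m.meta["gam_fallback"] = "glm"
        return m


def _fit_rf(
    env: np.ndarray, y: np.ndarray, config: ModelConfig, rng: np.random.Generator
) -> SpeciesModel:
    X = env[:, None]
    grid = [leaf for leaf in config.rf_leaf_grid if leaf < len(y)] or [1]
    tune = len(grid) > 1  # OOB scoring only pays off when there is a choice
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for leaf in grid:
            rf = RandomForestClassifier(
                n_estimators=config.rf_n_estimators,
                min_samples_leaf=leaf,
                bootstrap=True,
                oob_score=tune,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            try:
                rf.fit(X, y)
                score = rf.oob_score_ if tune else float("nan")
            except Exception:
                continue
            if best is None or (tune and score > best[0]):
                best = (score, leaf, rf)
    if best is None:
        return _constant_model(float(y.mean()), STATUS_FITTED, fallback="constant")
    score, leaf, rf = best
    pos = int(np.flatnonzero(rf.classes_ == 1)[0])
    return SpeciesModel(
        status=STATUS_FITTED,
        predict=lambda e, rf=rf, pos=pos: rf.predict_proba(
            np.asarray(e, dtype=float)[:, None]
        )[:, pos],
        meta={"min_samples_leaf": leaf, "oob_score": float(score)},
    )


def fit_species_model(
    algorithm: str,
    env_surveyed: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SpeciesModel:
    """Fit one species' model on the surveyed cells.

    ``y`` must contain at least one presence — species with zero records
    must be excluded by the caller, since no model can be constructed for
    them.  An all-presence response has no absences to contrast and yields
    a constant predictor flagged ``degenerate_constant``.
    """
    config = config or ModelConfig()
    rng = rng or np.random.default_rng()
    env_surveyed = np.asarray(env_surveyed, dtype=float)
    y = np.asarray(y).astype(int)
    if env_surveyed.shape != y.shape:
        raise ValueError("env_surveyed and y must have the same length")
    n_pres = int(y.sum())
    if n_pres == 0:
        raise ValueError("species with zero presences must be excluded, not fitted")
    if n_pres == len(y):
        return _constant_model(1.0, STATUS_DEGENERATE, n_presences=n_pres)
    if algorithm == "glm":
        model = _fit_glm(env_surveyed, y, config)
    elif algorithm == "gam":
        model = _fit_gam(env_surveyed, y, config)
    elif algorithm == "rf":
        model = _fit_rf(env_surveyed, y, config, rng)
    else:
        raise ValueError(f"algorithm must be one of {ALGORITHMS}")
    model.meta["n_presences"] = n_pres
    return model


def fit_niche_models(
    observation: Observation,
    environment: np.ndarray,
    algorithm: str,
    config: ModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> NicheModelSet:
    """Fit every observed species and predict over the whole grid.

    Species with zero presence records in the survey are excluded (no row in
    the probability matrix); everything else gets a predictor evaluated at
    every cell's environment.
    """
    config = config or ModelConfig()
    rng = rng or np.random.default_rng()
    env_surveyed = environment[observation.design.surveyed]
    n_species = observation.observed.shape[0]
    n_sites = len(environment)
    prob = np.full((n_species, n_sites), np.nan)
    statuses: list[str] = []
    fit_meta: list[dict] = []
    included = np.zeros(n_species, dtype=bool)
    for s in range(n_species):
        y = observation.observed[s]
        if observation.observed_abundance[s] == 0:
            statuses.append(STATUS_EXCLUDED)
            fit_meta.append({"species": s, "status": STATUS_EXCLUDED})
            continue
        model = fit_species_model(algorithm, env_surveyed, y, config, rng)
        statuses.append(model.status)
        fit_meta.append({"species": s, "status": model.status, **model.meta})
        prob[s] = np.clip(model.predict(environment), 0.0, 1.0)
        included[s] = True
    return NicheModelSet(
        algorithm=algorithm,
        statuses=statuses,
        prob=prob,
        included=included,
        fit_meta=fit_meta,
    )


def predict_probabilities(
    models: Sequence[SpeciesModel], env_all: np.ndarray
) -> np.ndarray:
    """Stack per-species predictions into a probability matrix, clipped to [0, 1]."""
    env_all = np.asarray(env_all, dtype=float)
    return np.vstack([np.clip(m.predict(env_all), 0.0, 1.0) for m in models])


def write_probabilities(models: "NicheModelSet", path) -> None:
    """Dense CSV of the probability matrix (one row per species; excluded
    species have empty cells)."""
    n_sites = models.prob.shape[1]
    with open(path, "w") as fh:
        fh.write("species_id," + ",".join(f"site_{i}" for i in range(n_sites)) + "\n")
        for s in range(models.prob.shape[0]):
            if models.included[s]:
                row = ",".join(f"{p:.6g}" for p in models.prob[s])
            else:
                row = "," * (n_sites - 1)
            fh.write(f"{s},{row}\n")


def write_fit_meta(models: "NicheModelSet", path) -> None:
    """Per-species fit diagnostics as JSON lines."""
    import json

    with open(path, "w") as fh:
        for rec in models.fit_meta:
            fh.write(json.dumps(rec) + "\n")


def compute_auc(prob_row: np.ndarray, truth_row: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    Undefined — returned as NaN — when the truth is constant (all presences
    or all absences), since no presence/absence pair exists to rank.
    """
    prob_row = np.asarray(prob_row, dtype=float)
    truth_row = np.asarray(truth_row).astype(int)
    if prob_row.shape != truth_row.shape:
        raise ValueError("probability and truth rows must have the same length")
    if truth_row.min() == truth_row.max():
        return float("nan")
    return float(roc_auc_score(truth_row, prob_row))
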