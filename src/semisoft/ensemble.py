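"""Diverse semi-supervised base models, pruning, and PLS stacking.

A multi-model perturbation mechanism generates K = k1*k2*k3 settings (one
per point of the trade-off-weight grid), each carrying fresh NCLELM input
weights and a fresh random unlabeled subsample.  Every setting runs the
pseudo-label optimization and refits its M learners on the enlarged
labeled set, yielding K*M semi-supervised models alongside their
supervised counterparts (same frozen input layers, labeled data only).

Candidates are pruned by the performance improvement ratio on an
independent validation set,

    PIR = (RMSE_init - RMSE_ss) / RMSE_init,

keeping models with PIR >= threshold (0 by default: anything not worse
than its supervised twin survives).  The retained models are combined by
partial-least-squares stacking fitted on their validation predictions;
the query-time output is beta0 + sum_i beta_i * yhat_i.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .config import RunConfig
from .datasets import SSLDataset
from .elm import NCLELMModel, fit_nclelm, init_nclelm, predict_nclelm
from .metrics import rmse
from .pseudolabel import GAConfig, build_plo_problem, run_ga

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scaler:
    """Zero-mean / unit-variance input scaling shared by all models."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.mean) / self.scale


@dataclass(frozen=True)
class PerturbationSetting:
    """One point of the multi-model perturbation grid."""

    index: int
    gammas: tuple[float, float, float]
    model_seeds: tuple[int, ...]
    subsample_seed: int
    partition_seed: int
    ga_seed: int


@dataclass
class PrunedModelRecord:
    model: NCLELMModel           # semi-supervised (refit on labeled + pseudo-labeled)
    counterpart: NCLELMModel     # supervised twin, same input layers
    setting_index: int
    member_index: int
    init_rmse: float
    ss_rmse: float
    pir: float
    retained: bool
    val_pred: np.ndarray | None = None      # cached semi-supervised validation predictions
    val_pred_init: np.ndarray | None = None


@dataclass
class StackedEnsemble:
    """Retained base models plus PLS stacking coefficients.

    Prediction: beta0 + sum_i beta_i * predict_nclelm(model_i, X).  When a
    scaler is attached, raw inputs are standardized first.
    """

    models: tuple[NCLELMModel, ...]
    coef: np.ndarray
    intercept: float
    n_components: int
    scaler: Scaler | None = None
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def base_predictions(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = self.models[0].members[0].d
        if self.scaler is not None:
            if X.shape[1] != self.scaler.mean.shape[0]:
                raise ValueError(
                    f"query has {X.shape[1]} features, model expects "
                    f"{self.scaler.mean.shape[0]}"
                )
            X = self.scaler.transform(X)
        if X.shape[1] != d:
            raise ValueError(f"query has {X.shape[1]} features, model expects {d}")
        return np.column_stack([predict_nclelm(m, X) for m in self.models])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + self.base_predictions(X) @ self.coef


@dataclass
class BuildResult:
    """Output of one perturbation setting: M semi-supervised models, their
    supervised counterparts, and the optimized pseudo-labeled set."""

    setting: PerturbationSetting
    ss_models: list[NCLELMModel]
    sup_models: list[NCLELMModel]
    X_pl: np.ndarray
    y_pl: np.ndarray
    subsample_rows: np.ndarray
    best_objective: float
    ga_history: np.ndarray


@dataclass
class PipelineResult:
    ensemble: StackedEnsemble
    supervised_ensemble: StackedEnsemble
    records: list[PrunedModelRecord]
    n_settings: int
    n_built: int
    n_retained: int
    validation_rmse: float
    fallback_used: bool
    scaler: Scaler
    config: RunConfig
    builds: list[BuildResult] = field(default_factory=list)


def generate_settings(
    gamma_grids: tuple, m: int, base_seed: int
) -> list[PerturbationSetting]:
    """Enumerate the full Cartesian product of the three gamma grids, each
    entry with fresh deterministic seeds for models, subsampling, the
    partition and the GA."""
    g1, g2, g3 = (tuple(g) for g in gamma_grids)
    if not (g1 and g2 and g3):
        raise ValueError("gamma candidate grids must be non-empty")
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(base_seed)
    settings = []
    for k, gammas in enumerate(itertools.product(g1, g2, g3)):
        seeds = rng.integers(0, 2**31 - 1, size=m + 3)
        settings.append(
            PerturbationSetting(
                index=k,
                gammas=tuple(float(g) for g in gammas),
                model_seeds=tuple(int(s) for s in seeds[:m]),
                subsample_seed=int(seeds[m]),
                partition_seed=int(seeds[m + 1]),
                ga_seed=int(seeds[m + 2]),
            )
        )
    return settings


def build_ssnclelm(
    setting: PerturbationSetting,
    X_l: np.ndarray,
    y_l: np.ndarray,
    X_u_pool: np.ndarray,
    hyper,
    u_prime: int,
    ga_config: GAConfig,
    delta: float | str = "knn",
    ci_level: float = 0.95,
) -> BuildResult:
    """Run one setting end to end (inputs already standardized).

    Subsamples U' unlabeled rows without replacement, optimizes their
    pseudo labels, then refits the M learners on labeled + pseudo-labeled
    data and, with identical input layers, on the labeled data alone.
    """
    if u_prime <= 0:
        raise ValueError("u_prime must be positive (no decision variables otherwise)")
    if u_prime > X_u_pool.shape[0]:
        raise ValueError(
            f"u_prime={u_prime} exceeds the {X_u_pool.shape[0]}-row unlabeled pool"
        )
    d = X_l.shape[1]
    rng = np.random.default_rng(setting.subsample_seed)
    rows = np.sort(rng.choice(X_u_pool.shape[0], size=u_prime, replace=False))
    X_u = X_u_pool[rows]
    models = [
        init_nclelm(d, hyper.n_node, hyper.n_elm, hyper.lam, seed)
        for seed in setting.model_seeds
    ]
    problem = build_plo_problem(
        X_l, y_l, X_u, models, setting.gammas,
        partition_seed=setting.partition_seed, delta=delta, ci_level=ci_level,
    )
    ga = replace(ga_config, rng_seed=setting.ga_seed)
    best_y, best_F, history = run_ga(problem, ga)
    y_pl = problem.labels_in_row_order(best_y)
    X_aug = np.vstack([X_l, X_u])
    y_aug = np.concatenate([y_l, y_pl])
    ss_models = [fit_nclelm(m.members, X_aug, y_aug, hyper.lam) for m in models]
    sup_models = [fit_nclelm(m.members, X_l, y_l, hyper.lam) for m in models]
    return BuildResult(
        setting=setting,
        ss_models=ss_models,
        sup_models=sup_models,
        X_pl=X_u,
        y_pl=y_pl,
        subsample_rows=rows,
        best_objective=best_F,
        ga_history=history,
    )


def performance_improvement_ratio(init_rmse: float, ss_rmse: float) -> float:
    """PIR = (init - ss)/init; degenerate init_rmse = 0 maps to 0 when the
    semi-supervised model is also exact, else -inf."""
    if init_rmse == 0.0:
        return 0.0 if ss_rmse == 0.0 else float("-inf")
    return (init_rmse - ss_rmse) / init_rmse


def prune_by_pir(
    builds: list[BuildResult],
    X_val: np.ndarray,
    y_val: np.ndarray,
    pir_threshold: float = 0.0,
) -> list[PrunedModelRecord]:
    """Score every built model on validation data and flag retention.

    Retention is inclusive (PIR >= threshold).  If nothing survives, the
    single best-PIR model is kept with a warning so that an ensemble can
    still be formed.
    """
    if X_val.shape[0] == 0:
        raise ValueError("validation set must be non-empty")
    records: list[PrunedModelRecord] = []
    for build in builds:
        for j, (ss, sup) in enumerate(zip(build.ss_models, build.sup_models)):
            pred_ss = predict_nclelm(ss, X_val)
            pred_init = predict_nclelm(sup, X_val)
            init_rmse = rmse(y_val, pred_init)
            ss_rmse = rmse(y_val, pred_ss)
            pir = performance_improvement_ratio(init_rmse, ss_rmse)
            records.append(
                PrunedModelRecord(
                    model=ss,
                    counterpart=sup,
                    setting_index=build.setting.index,
                    member_index=j,
                    init_rmse=init_rmse,
                    ss_rmse=ss_rmse,
                    pir=pir,
                    retained=pir >= pir_threshold,
                    val_pred=pred_ss,
                    val_pred_init=pred_init,
                )
            )
    if records and not any(r.retained for r in records):
        best = max(records, key=lambda r: r.pir)
        best.retained = True
        logger.warning(
            "no model met PIR >= %g; retaining the single best (PIR=%.4f)",
            pir_threshold, best.pir,
        )
    return records


def fit_stacking(
    models: list[NCLELMModel],
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_components: int = 10,
    val_preds: np.ndarray | None = None,
) -> StackedEnsemble:
    """PLS-stack the retained models on their validation predictions.

    The component count is chosen by 5-fold cross-validation over
    1..min(S, max_components) with the one-standard-error rule (smallest
    count whose CV error is within one SE of the minimum), which guards
    against overfitting the small validation set; PLS tolerates collinear
    prediction columns.
    """
    if len(models) == 0:
        raise RuntimeError("no retained models to stack")
    y_val = np.asarray(y_val, dtype=float).ravel()
    if y_val.shape[0] < 2:
        raise ValueError("validation set must have more than one sample")
    if val_preds is None:
        X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
        val_preds = np.column_stack([predict_nclelm(m, X_val) for m in models])
    Z = np.asarray(val_preds, dtype=float)
    s = Z.shape[1]
    # cap at the effective rank so NIPALS never deflates to a zero block
    rank = int(np.linalg.matrix_rank(Z - Z.mean(axis=0)))
    max_nc = max(1, min(s, max_components, Z.shape[0] - 1, rank))
    best_nc = 1
    if max_nc > 1 and Z.shape[0] >= 4:
        n_splits = min(5, Z.shape[0])
        kf = KFold(n_splits=n_splits, shuffle=False)
        cv_mean, cv_se = [], []
        for nc in range(1, max_nc + 1):
            errs = []
            for tr, te in kf.split(Z):
                if len(tr) < nc + 1:
                    errs = None
                    break
            if errs is None:
                break
            try:
                for tr, te in kf.split(Z):
                    pls = PLSRegression(n_components=nc)
                    pls.fit(Z[tr], y_val[tr])
                    errs.append(np.mean((pls.predict(Z[te]).ravel() - y_val[te]) ** 2))
            except (ValueError, np.linalg.LinAlgError):
                break  # fold-level rank deficiency: stop growing nc
            cv_mean.append(float(np.mean(errs)))
            cv_se.append(float(np.std(errs) / np.sqrt(len(errs))))
        if cv_mean:
            i_min = int(np.argmin(cv_mean))
            limit = cv_mean[i_min] + cv_se[i_min]
            best_nc = 1 + next(i for i, e in enumerate(cv_mean) if e <= limit)
    pls = PLSRegression(n_components=best_nc)
    pls.fit(Z, y_val)
    coef = np.asarray(pls.coef_).reshape(-1)
    # fold the centering into the affine form beta0 + Z @ coef
    intercept = float(np.asarray(pls.intercept_).reshape(-1)[0] - pls._x_mean @ coef)
    return StackedEnsemble(
        models=tuple(models),
        coef=coef,
        intercept=intercept,
        n_components=best_nc,
    )


def average_ensemble(models: list[NCLELMModel], scaler: Scaler | None = None) -> StackedEnsemble:
    """Simple-average combination (beta0 = 0, beta_i = 1/S)."""
    s = len(models)
    return StackedEnsemble(
        models=tuple(models),
        coef=np.full(s, 1.0 / s),
        intercept=0.0,
        n_components=0,
        scaler=scaler,
    )


def predict_ensemble(ensemble: StackedEnsemble, X_q: np.ndarray) -> np.ndarray:
    return ensemble.predict(X_q)


def run_full_pipeline(data: SSLDataset, config: RunConfig) -> PipelineResult:
    """The complete soft-sensor workflow.

    Standardize inputs with labeled ∪ unlabeled statistics, run every
    perturbation setting (failed settings are logged and skipped), prune by
    PIR on the validation set, and PLS-stack the retained models.  A
    supervised stacked ensemble of all counterparts is built alongside for
    reference.  Fully reproducible under ``config.seed``.
    """
    scaler = Scaler.fit(np.vstack([data.X_l, data.X_u]))
    X_l = scaler.transform(data.X_l)
    X_u = scaler.transform(data.X_u)
    X_val = scaler.transform(data.X_val)
    grids = (config.plo.gamma1_grid, config.plo.gamma2_grid, config.plo.gamma3_grid)
    settings = generate_settings(grids, config.plo.m, base_seed=config.seed)
    logger.info("running %d perturbation settings (%d base models)",
                len(settings), len(settings) * config.plo.m)
    builds: list[BuildResult] = []
    for setting in settings:
        try:
            builds.append(
                build_ssnclelm(
                    setting, X_l, data.y_l, X_u, config.model,
                    u_prime=config.plo.u_prime, ga_config=config.ga,
                    delta=config.plo.delta, ci_level=config.plo.ci_level,
                )
            )
        except Exception:
            logger.exception("setting %d failed; skipping", setting.index)
    if not builds:
        raise RuntimeError("every perturbation setting failed; no models built")
    records = prune_by_pir(builds, X_val, data.y_val, config.pir_threshold)
    fallback = not any(r.pir >= config.pir_threshold for r in records)
    retained = [r for r in records if r.retained]
    ensemble = fit_stacking(
        [r.model for r in retained], X_val, data.y_val,
        max_components=config.max_components,
        val_preds=np.column_stack([r.val_pred for r in retained]),
    )
    ensemble.scaler = scaler
    ensemble.feature_names = list(data.feature_names)
    supervised = fit_stacking(
        [r.counterpart for r in retained], X_val, data.y_val,
        max_components=config.max_components,
        val_preds=np.column_stack([r.val_pred_init for r in retained]),
    )
    supervised.scaler = scaler
    supervised.feature_names = list(data.feature_names)
    val_rmse = rmse(data.y_val, ensemble.predict(data.X_val))
    best_single = min(r.ss_rmse for r in retained)
    if val_rmse > 1.05 * best_single:
        logger.warning(
            "stacked validation RMSE %.4f exceeds best single model %.4f by >5%%",
            val_rmse, best_single,
        )
    logger.info("built %d models, retained %d, PLS components %d",
                len(records), len(retained), ensemble.n_components)
    return PipelineResult(
        ensemble=ensemble,
        supervised_ensemble=supervised,
        records=records,
        n_settings=len(settings),
        n_built=len(records),
        n_retained=len(retained),
        validation_rmse=val_rmse,
        fallback_used=fallback,
        scaler=scaler,
        config=config,
        builds=builds,
    )
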