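"""Desk-scale studies on the packaged synthetic benchmark.

Two reproducible experiments back the package's claims:

* :func:`run_method_comparison` — fits the four-method ladder (single ELM,
  NCLELM, supervised PLS-stacked ensemble, semi-supervised PLS-stacked
  ensemble) on one scarce-label benchmark realization and scores test RMSE
  and R².  The study conditions are a reduced grid of K = 8 settings
  ({0, 0.1} per trade-off weight), M = 2 learners, U' = 60 and a 50x50 GA —
  small enough for a workstation while preserving the structure of the
  full-grid workflow.

* :func:`pseudo_label_recovery` — runs one pseudo-labeling optimization
  (M = 3 learners, U' = 30, GA 50x50) and compares the recovered labels
  against the withheld truth and against the midpoint of the GPR search
  box (equivalently the GPR posterior mean), the natural no-optimization
  baseline.
"""

from __future__ import annotations

import numpy as np

from .config import ModelHyper, PLOSettings, RunConfig
from .datasets import SyntheticConfig, make_benchmark, make_ssl_split, simulate_batches
from .elm import fit_elm, fit_nclelm, init_elm, init_nclelm, predict_elm, predict_nclelm
from .ensemble import Scaler, run_full_pipeline
from .metrics import r2, rmse
from .pseudolabel import GAConfig, build_plo_problem, run_ga, scale_balanced_gammas


def benchmark_config(seed: int) -> RunConfig:
    """Reduced-grid configuration used by the packaged benchmark."""
    return RunConfig(
        model=ModelHyper(n_elm=5, n_node=20, lam=0.6),
        plo=PLOSettings(
            m=2,
            u_prime=60,
            gamma1_grid=(0.0, 0.1),
            gamma2_grid=(0.0, 0.1),
            gamma3_grid=(0.0, 0.1),
        ),
        ga=GAConfig(npop=50, ngen=50),
        seed=seed,
    )


def run_method_comparison(seed: int, n_restarts: int = 20) -> dict:
    """Test-set RMSE/R² of ELM, NCLELM, EnNCLELM_pls and EnSSNCLELM on one
    benchmark realization, all trained under the same scaler and seed.

    The two single-model baselines are random in their input weights, so
    their accuracies are reported as the average over ``n_restarts``
    independent initializations — the fairness protocol the reference
    comparison uses for randomly initialized learners.
    """
    data, X_test, y_test = make_benchmark(seed)
    config = benchmark_config(seed)
    result = run_full_pipeline(data, config)
    scaler = result.scaler
    Xl = scaler.transform(data.X_l)
    Xt = scaler.transform(X_test)

    rmse_elm, r2_elm, rmse_ncl, r2_ncl = [], [], [], []
    for r in range(n_restarts):
        elm = fit_elm(
            init_elm(Xl.shape[1], config.model.n_node, rng_seed=seed + 11 + 1000 * r),
            Xl, data.y_l,
        )
        pred = predict_elm(elm, Xt)
        rmse_elm.append(rmse(y_test, pred))
        r2_elm.append(r2(y_test, pred))
        ncl = init_nclelm(
            Xl.shape[1], config.model.n_node, config.model.n_elm, config.model.lam,
            rng_seed=seed + 12 + 1000 * r,
        )
        ncl = fit_nclelm(ncl.members, Xl, data.y_l, config.model.lam)
        pred = predict_nclelm(ncl, Xt)
        rmse_ncl.append(rmse(y_test, pred))
        r2_ncl.append(r2(y_test, pred))

    pred_sup = result.supervised_ensemble.predict(X_test)
    pred_ss = result.ensemble.predict(X_test)

    return {
        "rmse_elm": float(np.mean(rmse_elm)),
        "rmse_nclelm": float(np.mean(rmse_ncl)),
        "rmse_ennclelm_pls": rmse(y_test, pred_sup),
        "rmse_enssnclelm": rmse(y_test, pred_ss),
        "r2_elm": float(np.mean(r2_elm)),
        "r2_nclelm": float(np.mean(r2_ncl)),
        "r2_ennclelm_pls": r2(y_test, pred_sup),
        "r2_enssnclelm": r2(y_test, pred_ss),
        "n_built": result.n_built,
        "n_retained": result.n_retained,
        "n_test": len(y_test),
    }


def pseudo_label_recovery(
    seed: int,
    n_labeled: int = 40,
    u_prime: int = 30,
    m: int = 3,
    noise_sd: float = 0.05,
    gammas: tuple[float, float, float] | None = None,
    ga: GAConfig | None = None,
    hyper: ModelHyper | None = None,
) -> dict:
    """One pseudo-labeling run scored against the withheld true labels.

    Returns the label RMSE of the optimized chromosome and of the
    search-box midpoint (the GPR posterior mean baseline).  By default the
    trade-off weights are scale-balanced at the midpoint candidate.
    """
    hyper = hyper or ModelHyper()
    ga = ga or GAConfig(npop=50, ngen=50, rng_seed=seed + 3)
    table = simulate_batches(
        SyntheticConfig(n_batches=6, samples_per_batch=30, noise_sd=noise_sd, rng_seed=seed)
    )
    data = make_ssl_split(table, n_labeled=n_labeled, n_val=20, rng_seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    rows = np.sort(rng.choice(data.X_u.shape[0], size=u_prime, replace=False))
    scaler = Scaler.fit(np.vstack([data.X_l, data.X_u]))
    Xl = scaler.transform(data.X_l)
    Xu = scaler.transform(data.X_u[rows])
    y_true = data.y_u_true[rows]
    models = [
        init_nclelm(Xl.shape[1], hyper.n_node, hyper.n_elm, hyper.lam, seed + 100 + i)
        for i in range(m)
    ]
    problem = build_plo_problem(
        Xl, data.y_l, Xu, models, gammas or (0.0, 0.0, 0.0), partition_seed=seed + 5
    )
    if gammas is None:
        problem.gammas = scale_balanced_gammas(problem)
    best_y, best_F, history = run_ga(problem, ga)
    rmse_opt = rmse(y_true, problem.labels_in_row_order(best_y))
    rmse_mid = rmse(y_true, problem.labels_in_row_order(problem.bounds_midpoint))
    return {
        "rmse_optimized": rmse_opt,
        "rmse_midpoint": rmse_mid,
        "best_objective": best_F,
        "history": history,
        "n_pseudo_labels": u_prime,
    }
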