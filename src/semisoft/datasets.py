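"""Synthetic fed-batch fermentation fixtures with a scarce-label split.

Real quality variables (product or substrate concentration) are sampled
rarely because they need offline assays, while process inputs (feed rate,
dissolved oxygen, volume, temperature, ...) are logged continuously.  The
generator reproduces that statistical shape — multi-batch, smoothly
varying, nonlinear input trajectories and a noisy nonlinear label — without
attempting mechanistic fermentation kinetics.

Per batch, each input variable follows one of four smooth trajectory styles
(logistic ramp, linear ramp, exponential decay, slow oscillation) with
batch-specific random parameters plus a small smooth perturbation.  The
label is a fixed, documented nonlinear function of the first six inputs:

    f(x) = 2 / (1 + exp(-2 x1)) + sin(x2) + 0.5 x3 x4 + 0.3 x5^2 - 0.4 x6

observed as y = f(x) + N(0, noise_sd^2).  Remaining inputs are nuisance
variables, as in real soft-sensor tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Total simulated culture duration in hours (fed-batch runs last ~400 h).
BATCH_DURATION_H = 400.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_batches: int = 10
    samples_per_batch: int = 100
    n_inputs: int = 12
    noise_sd: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_batches < 1 or self.samples_per_batch < 1 or self.n_inputs < 1:
            raise ValueError("sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SSLDataset:
    """Labeled / unlabeled / validation split sharing one feature space.

    ``y_u_true`` holds the withheld labels of the unlabeled pool so that
    pseudo-label recovery can be scored; a real plant would not have them.
    """

    X_l: np.ndarray
    y_l: np.ndarray
    X_u: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    y_u_true: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)
    indices: dict | None = None  # source-table row indices of each subset

    @property
    def d(self) -> int:
        return self.X_l.shape[1]


def label_function(X: np.ndarray) -> np.ndarray:
    """The generator's ground-truth label surface (noise-free)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    x = [X[:, j] if j < X.shape[1] else np.zeros(X.shape[0]) for j in range(6)]
    return (
        2.0 / (1.0 + np.exp(-2.0 * x[0]))
        + np.sin(x[1])
        + 0.5 * x[2] * x[3]
        + 0.3 * x[4] ** 2
        - 0.4 * x[5]
    )


#: Relative scale of batch-to-batch perturbation of the master trajectories.
#: Replicate fed-batch runs under fixed operating settings differ only
#: mildly, which is what makes labeled, unlabeled and validation batches
#: draws from one distribution — the assumption the method rests on.  The
#: level is calibrated so that a supervised single ELM on the scarce
#: labeled set reaches R^2 ~ 0.9 on held-out batches, the difficulty
#: regime where label scarcity actually bites.
BATCH_VARIATION = 0.1


def _master_params(style: int, rng: np.random.Generator) -> dict:
    """Process-level trajectory parameters, drawn once per variable."""
    if style == 0:  # logistic feed-up, like substrate feed rate or volume
        return {"a": rng.uniform(0.8, 1.6), "c": rng.uniform(0.3, 0.7),
                "w": rng.uniform(0.05, 0.2)}
    if style == 1:  # monotone ramp, like generated heat
        return {"slope": rng.uniform(-1.2, 1.2), "offset": rng.uniform(-0.5, 0.5)}
    if style == 2:  # exponential decay, like dissolved oxygen
        return {"a": rng.uniform(0.8, 1.5), "tau": rng.uniform(0.2, 0.8)}
    # slow oscillation, like controlled pH/temperature around a setpoint
    return {"a": rng.uniform(0.3, 0.8), "f": rng.uniform(0.5, 1.5),
            "phi": rng.uniform(0, 2 * np.pi)}


def _trajectory(
    style: int, params: dict, u: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One batch realization: master curve, mildly perturbed, plus wobble."""
    g = 1.0 + BATCH_VARIATION * rng.normal()
    shift = 0.02 * rng.normal()
    if style == 0:
        base = g * params["a"] / (1.0 + np.exp(-(u - params["c"] - shift) / params["w"]))
    elif style == 1:
        base = g * params["slope"] * u + params["offset"] + 0.05 * rng.normal()
    elif style == 2:
        base = g * params["a"] * np.exp(-u / (params["tau"] * (1.0 + shift)))
    else:
        base = g * params["a"] * np.sin(2.0 * np.pi * params["f"] * u + params["phi"] + shift)
    wobble = 0.05 * np.sin(2.0 * np.pi * rng.uniform(2, 4) * u + rng.uniform(0, 2 * np.pi))
    return base + wobble


def simulate_batches(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate the full labeled table: batch_id, time, x_1..x_d, y."""
    rng = np.random.default_rng(config.rng_seed)
    u = np.linspace(0.0, 1.0, config.samples_per_batch)
    masters = [_master_params(j % 4, rng) for j in range(config.n_inputs)]
    rows = []
    for b in range(config.n_batches):
        X = np.column_stack(
            [_trajectory(j % 4, masters[j], u, rng) for j in range(config.n_inputs)]
        )
        y = label_function(X)
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
        df = pd.DataFrame(X, columns=[f"x_{j + 1}" for j in range(config.n_inputs)])
        df.insert(0, "time", u * BATCH_DURATION_H)
        df.insert(0, "batch_id", f"B{b + 1:02d}")
        df["y"] = y
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def make_ssl_split(
    table: pd.DataFrame,
    n_labeled: int,
    n_val: int,
    rng_seed: int,
    n_val_batches: int | None = None,
) -> SSLDataset:
    """Split a fully labeled table into scarce-label / rich-unlabeled / validation.

    Validation rows come from batches disjoint from the training batches,
    mimicking held-out runs; by default they are spread over (at least)
    three such batches so the validation set represents batch-to-batch
    variability rather than a single run.  Labels of the unlabeled pool
    are withheld but kept in ``y_u_true`` for recovery scoring.
    """
    if n_labeled < 0 or n_val < 0 or n_labeled + n_val > len(table):
        raise ValueError(
            f"cannot draw {n_labeled} labeled + {n_val} validation rows "
            f"from a {len(table)}-row table"
        )
    rng = np.random.default_rng(rng_seed)
    feature_names = [c for c in table.columns if c.startswith("x_")]
    batches = list(pd.unique(table["batch_id"]))
    order = [batches[i] for i in rng.permutation(len(batches))]
    if n_val_batches is None:
        n_val_batches = min(3, max(1, len(batches) - 1)) if n_val > 0 else 0
    val_batches: list = []
    n_avail = 0
    while n_val > 0 and (n_avail < n_val or len(val_batches) < n_val_batches):
        if not order:
            raise ValueError("not enough batches to form a disjoint validation set")
        val_batches.append(order.pop())
        n_avail = int(table["batch_id"].isin(val_batches).sum())
    val_pool = table[table["batch_id"].isin(val_batches)]
    train_pool = table[~table["batch_id"].isin(val_batches)]
    if n_labeled > len(train_pool):
        raise ValueError("not enough non-validation rows for the labeled set")
    val_idx = rng.choice(val_pool.index.to_numpy(), size=n_val, replace=False)
    lab_idx = rng.choice(train_pool.index.to_numpy(), size=n_labeled, replace=False)
    unl_mask = ~table.index.isin(np.concatenate([val_idx, lab_idx]))
    unl = table[unl_mask & ~table["batch_id"].isin(val_batches)]
    indices = {
        "labeled": np.asarray(lab_idx),
        "validation": np.asarray(val_idx),
        "unlabeled": unl.index.to_numpy(),
    }
    return SSLDataset(
        X_l=table.loc[lab_idx, feature_names].to_numpy(float),
        y_l=table.loc[lab_idx, "y"].to_numpy(float),
        X_u=unl[feature_names].to_numpy(float),
        X_val=table.loc[val_idx, feature_names].to_numpy(float),
        y_val=table.loc[val_idx, "y"].to_numpy(float),
        y_u_true=unl["y"].to_numpy(float),
        feature_names=feature_names,
        indices=indices,
    )


def make_benchmark(
    seed: int,
    n_labeled: int = 22,
    n_val: int = 40,
    noise_sd: float = 0.05,
    n_inputs: int = 12,
) -> tuple[SSLDataset, np.ndarray, np.ndarray]:
    """The packaged scarce-label benchmark: an SSL split plus a held-out test set.

    One 20-batch x 60-sample process realization; 8 whole batches are held
    out as the test set and the remaining 12 feed the scarce-label split,
    so every subset comes from the same process distribution.
    """
    cfg = SyntheticConfig(
        n_batches=20, samples_per_batch=60, n_inputs=n_inputs,
        noise_sd=noise_sd, rng_seed=seed,
    )
    table = simulate_batches(cfg)
    rng = np.random.default_rng(seed + 1)
    batches = list(pd.unique(table["batch_id"]))
    test_batches = [batches[i] for i in rng.choice(len(batches), size=8, replace=False)]
    test = table[table["batch_id"].isin(test_batches)]
    rest = table[~table["batch_id"].isin(test_batches)].reset_index(drop=True)
    data = make_ssl_split(rest, n_labeled=n_labeled, n_val=n_val, rng_seed=seed + 2)
    X_test = test[data.feature_names].to_numpy(float)
    y_test = test["y"].to_numpy(float)
    return data, X_test, y_test
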