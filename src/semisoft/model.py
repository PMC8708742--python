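"""Top-level modelling surface: a Model built from data whose fit() returns
a Results object with estimates, diagnostics and a summary table."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import io as sio
from .config import RunConfig
from .datasets import SSLDataset
from .ensemble import PipelineResult, run_full_pipeline
from .metrics import r2, rmse


class EnsembleSoftSensor:
    """Semi-supervised ensemble soft sensor for a scarce-label process dataset.

    Parameters
    ----------
    data
        An :class:`~semisoft.datasets.SSLDataset` holding the labeled set,
        the unlabeled input pool and an independent labeled validation set.
    config
        A :class:`~semisoft.config.RunConfig`; defaults mirror the
        reference fermentation operating point.

    Examples
    --------
    >>> from semisoft import EnsembleSoftSensor, datasets
    >>> data, X_test, y_test = datasets.make_benchmark(seed=1)
    >>> model = EnsembleSoftSensor(data)          # doctest: +SKIP
    >>> res = model.fit(seed=1)                   # doctest: +SKIP
    >>> res.predict(X_test)                       # doctest: +SKIP
    """

    def __init__(self, data: SSLDataset, config: RunConfig | None = None):
        self.data = data
        self.config = config or RunConfig()

    @classmethod
    def from_dataframes(
        cls,
        labeled: pd.DataFrame,
        unlabeled: pd.DataFrame,
        validation: pd.DataFrame,
        config: RunConfig | None = None,
    ) -> "EnsembleSoftSensor":
        """Build from three frames in the dataset CSV dialect."""
        return cls(sio.dataframes_to_ssl(labeled, unlabeled, validation), config)

    def fit(self, seed: int | None = None) -> "EnsembleSoftSensorResults":
        """Run the full workflow; ``seed`` overrides the config seed."""
        config = self.config if seed is None else replace(self.config, seed=int(seed))
        result = run_full_pipeline(self.data, config)
        return EnsembleSoftSensorResults(self, result)


class EnsembleSoftSensorResults:
    """Fitted ensemble, stacking coefficients and pruning diagnostics."""

    def __init__(self, model: EnsembleSoftSensor, result: PipelineResult):
        self.model = model
        self._result = result
        self.ensemble = result.ensemble
        self.supervised_ensemble = result.supervised_ensemble
        self.n_settings = result.n_settings
        self.n_built = result.n_built
        self.n_retained = result.n_retained
        self.n_components = result.ensemble.n_components
        self.validation_rmse = result.validation_rmse
        self.fallback_used = result.fallback_used

    @property
    def params(self) -> pd.Series:
        """Stacking coefficients beta_0..beta_S."""
        names = ["beta_0"] + [f"beta_{i + 1}" for i in range(len(self.ensemble.coef))]
        return pd.Series(
            np.concatenate([[self.ensemble.intercept], self.ensemble.coef]), index=names
        )

    @property
    def pir_table(self) -> pd.DataFrame:
        """Per-model pruning diagnostics (validation RMSEs and PIR)."""
        rows = [
            {
                "setting": r.setting_index,
                "member": r.member_index,
                "init_rmse": r.init_rmse,
                "ss_rmse": r.ss_rmse,
                "pir": r.pir,
                "retained": r.retained,
            }
            for r in self._result.records
        ]
        return pd.DataFrame(rows)

    def predict(self, X) -> np.ndarray:
        return self.ensemble.predict(np.asarray(X, dtype=float))

    def evaluate(self, X, y_true) -> dict:
        pred = self.predict(X)
        return {"rmse": rmse(y_true, pred), "r2": r2(y_true, pred), "n": len(pred)}

    def save(self, path) -> None:
        meta = {
            "config": self.model.config.to_dict(),
            "n_settings": self.n_settings,
            "n_built": self.n_built,
            "n_retained": self.n_retained,
            "seed": self._result.config.seed,
        }
        sio.save_model(self.ensemble, path, meta=meta)

    def summary(self) -> str:
        t = self.pir_table
        lines = [
            "Ensemble semi-supervised soft sensor",
            "=" * 52,
            f"{'Perturbation settings (K)':35s}{self.n_settings:>12d}",
            f"{'Base models built (K x M)':35s}{self.n_built:>12d}",
            f"{'Models retained (S)':35s}{self.n_retained:>12d}",
            f"{'PLS stacking components':35s}{self.n_components:>12d}",
            f"{'Validation RMSE (stacked)':35s}{self.validation_rmse:>12.4f}",
            f"{'Median PIR of built models':35s}{t['pir'].median():>12.4f}",
            f"{'Master seed':35s}{self._result.config.seed:>12d}",
            "=" * 52,
        ]
        if self.fallback_used:
            lines.append("warning: no model met the PIR threshold; best single kept")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EnsembleSoftSensorResults: S={self.n_retained}/{self.n_built}, "
            f"val RMSE={self.validation_rmse:.4f}>"
        )
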