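"""JSON (de)serialization of fitted regression models.

Curve, MLR and LSSVM models are fully determined by their parameters (the
LSSVM stores its dual weights, kernel settings, standardization constants and
support points).  PLSR and RF models embed their (small) training matrices and
seeds and are refitted deterministically on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calib_models import (
    CurveModel, LSSVMModel, MLRModel, PLSRModel, RFModel,
    fit_plsr, fit_rf,
)
from .errors import ModelError

__all__ = ["save_model", "load_model", "model_to_dict", "model_from_dict"]


def model_to_dict(model, training: tuple | None = None) -> dict:
    """Serialize a fitted model.  PLSR/RF require ``training=(features, y)``."""
    kind = getattr(model, "kind", None)
    if kind == "curve":
        return {
            "kind": "curve",
            "slope": model.slope,
            "intercept": model.intercept,
            "feature_name": model.feature_name,
            "inverse_slope": model.inverse_slope,
            "inverse_sigma": model.inverse_sigma,
            "residual_sigma_conc": model.residual_sigma_conc,
        }
    if kind == "mlr":
        return {
            "kind": "mlr",
            "coefficients": list(map(float, model.coefficients)),
            "intercept": model.intercept,
            "feature_names": model.feature_names,
        }
    if kind == "lssvm":
        return {
            "kind": "lssvm",
            "alpha": model.alpha.tolist(),
            "bias": model.bias,
            "gamma": model.gamma,
            "sigma": model.sigma,
            "kernel": model.kernel,
            "X_train": model.X_train.tolist(),
            "x_mean": model.x_mean.tolist(),
            "x_scale": model.x_scale.tolist(),
            "feature_names": model.feature_names,
            "seed": model.seed,
        }
    if kind in ("plsr", "rf"):
        if training is None:
            raise ModelError(f"serializing a {kind} model requires the training data")
        F, y = training
        Fm = F.to_numpy(dtype=float) if isinstance(F, pd.DataFrame) else np.asarray(F, dtype=float)
        d = {
            "kind": kind,
            "feature_names": model.feature_names,
            "train_X": Fm.tolist(),
            "train_y": np.asarray(y, dtype=float).tolist(),
        }
        if kind == "plsr":
            d["n_components"] = model.n_components
        else:
            d["n_trees"] = model.estimator.n_estimators
            d["seed"] = model.seed
        return d
    raise ModelError(f"cannot serialize model of kind {kind!r}")


def model_from_dict(d: dict):
    kind = d.get("kind")
    if kind == "curve":
        return CurveModel(
            slope=d["slope"], intercept=d["intercept"], feature_name=d["feature_name"],
            inverse_slope=d["inverse_slope"], inverse_sigma=d["inverse_sigma"],
            residual_sigma_conc=d["residual_sigma_conc"],
        )
    if kind == "mlr":
        return MLRModel(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            feature_names=list(d["feature_names"]),
        )
    if kind == "lssvm":
        return LSSVMModel(
            alpha=np.asarray(d["alpha"], dtype=float),
            bias=float(d["bias"]),
            gamma=float(d["gamma"]),
            sigma=None if d["sigma"] is None else float(d["sigma"]),
            kernel=d["kernel"],
            X_train=np.asarray(d["X_train"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            feature_names=list(d["feature_names"]),
            seed=int(d.get("seed", 0)),
        )
    if kind in ("plsr", "rf"):
        F = pd.DataFrame(np.asarray(d["train_X"], dtype=float), columns=d["feature_names"])
        y = np.asarray(d["train_y"], dtype=float)
        if kind == "plsr":
            return fit_plsr(F, y, n_components=int(d["n_components"]))
        return fit_rf(F, y, n_trees=int(d["n_trees"]), seed=int(d["seed"]))
    raise ModelError(f"cannot deserialize model of kind {kind!r}")


def save_model(model, path: str | Path, training: tuple | None = None) -> Path:
    path = Path(path)
    path.write_text(json.dumps(model_to_dict(model, training)) + "\n")
    return path


def load_model(path: str | Path):
    return model_from_dict(json.loads(Path(path).read_text()))
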