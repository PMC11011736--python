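"""End-to-end crater-spectrum feature fusion.

A :class:`FusionSpec` names one modelling configuration: which crater
parameters enter (default: the subset retained by backward stepwise MLR on the
calibration set), which emission lines, which spectral correction is applied
before peak extraction (none / AsLS baseline / total-area normalization /
CPRC) and which regression model is fitted.  :func:`run_grid` fits every
configuration on the calibration groups only — ratio-correction fitting,
stepwise retention and hyperparameter CV never see a prediction-group sample —
and evaluates on the held-out group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calib_models import (
    EvaluationReport, fit_curve, fit_lssvm, fit_mlr, fit_plsr, fit_rf, evaluate,
)
from .core_data import (
    CD_LINES, CRATER_PARAM_NAMES, CalibrationDataset, EmissionLine, split_by_group,
)
from .cprc import CPRCModel, fit_cprc
from .crater_compensation import stepwise_backward
from .errors import ModelError, SelectionError
from .preprocess import area_normalize_set, asls_correct_set, peak_intensities

__all__ = ["FusionSpec", "build_features", "run_grid", "GridResult"]

_CORRECTIONS = ("none", "baseline", "normalization", "cprc")
_MODEL_KINDS = ("curve", "mlr", "plsr", "lssvm", "rf")


@dataclass(frozen=True)
class FusionSpec:
    """One fusion configuration.

    ``crater_vars=None`` means "use the stepwise-retained crater subset",
    recomputed on the calibration data of each run; ``()`` means no crater
    variables at all.  A ``curve`` model is only allowed with exactly one
    emission line and no crater variables.
    """

    name: str
    lines: tuple[EmissionLine, ...]
    correction: str = "none"
    model_kind: str = "curve"
    crater_vars: tuple[str, ...] | None = ()
    window_nm: float = 0.1

    def __post_init__(self) -> None:
        if self.correction not in _CORRECTIONS:
            raise ModelError(f"unknown correction {self.correction!r}; expected one of {_CORRECTIONS}")
        if self.model_kind not in _MODEL_KINDS:
            raise ModelError(f"unknown model kind {self.model_kind!r}; expected one of {_MODEL_KINDS}")
        if not self.lines:
            raise ModelError("a fusion spec needs at least one emission line")
        if self.crater_vars is not None:
            unknown = [v for v in self.crater_vars if v not in CRATER_PARAM_NAMES]
            if unknown:
                raise ModelError(f"unknown crater parameters {unknown}")
        if self.model_kind == "curve":
            if len(self.lines) != 1 or self.crater_vars is None or len(self.crater_vars) != 0:
                raise ModelError("a curve model takes exactly one line and no crater variables")


def _corrected_spectra(ds: CalibrationDataset, spec: FusionSpec,
                       cprc_models: dict[float, CPRCModel] | None):
    """Per-line corrected SpectrumSets (shared sets for global corrections)."""
    if spec.correction == "none":
        return {line.wavelength: ds.spectra for line in spec.lines}
    if spec.correction == "baseline":
        corrected = asls_correct_set(ds.spectra)
        return {line.wavelength: corrected for line in spec.lines}
    if spec.correction == "normalization":
        corrected = area_normalize_set(ds.spectra)
        return {line.wavelength: corrected for line in spec.lines}
    # cprc: every line is corrected by its own fitted model
    if not cprc_models:
        raise ModelError("correction='cprc' requires fitted per-line CPRC models")
    out = {}
    for line in spec.lines:
        model = cprc_models.get(line.wavelength)
        if model is None:
            raise ModelError(f"no CPRC model provided for line {line.label}")
        from .cprc import apply_cprc

        out[line.wavelength] = apply_cprc(model, ds.spectra)
    return out


def build_features(
    ds: CalibrationDataset,
    spec: FusionSpec,
    cprc_models: dict[float, CPRCModel] | None = None,
    crater_subset: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Assemble the named feature matrix: crater columns, then per-line intensities.

    ``crater_subset`` supplies the stepwise-retained names when
    ``spec.crater_vars`` is None (it must then be given by the caller, fitted
    on calibration data only).
    """
    crater_vars = spec.crater_vars
    if crater_vars is None:
        if crater_subset is None:
            raise ModelError("spec requests stepwise-retained craters but no subset was supplied")
        crater_vars = tuple(crater_subset)
    cols: dict[str, np.ndarray] = {}
    if crater_vars:
        frame = ds.crater_frame()
        for v in crater_vars:
            if v not in frame.columns:
                raise ModelError(f"missing crater column {v!r}")
            cols[v] = frame[v].to_numpy()
    corrected = _corrected_spectra(ds, spec, cprc_models)
    for line in spec.lines:
        cols[line.column] = peak_intensities(corrected[line.wavelength], line, spec.window_nm)
    return pd.DataFrame(cols, index=pd.Index(ds.sample_ids, name="sample_id"))


@dataclass
class GridResult:
    """One grid entry: the spec, its fitted model, and its evaluation report."""

    spec: FusionSpec
    report: EvaluationReport
    model: object
    crater_subset: tuple[str, ...] = ()


def _fit_model(kind: str, features: pd.DataFrame, y: np.ndarray, seed: int):
    if kind == "curve":
        return fit_curve(features, y)
    if kind == "mlr":
        return fit_mlr(features, y)
    if kind == "plsr":
        return fit_plsr(features, y, seed=seed)
    if kind == "lssvm":
        return fit_lssvm(features, y, seed=seed)
    if kind == "rf":
        return fit_rf(features, y, seed=seed)
    raise ModelError(f"unknown model kind {kind!r}")


def run_grid(
    ds: CalibrationDataset,
    specs: list[FusionSpec],
    calibration_groups,
    prediction_groups,
    seed: int = 0,
    stepwise_lines: tuple[EmissionLine, ...] = CD_LINES,
    cprc_max_m: int = 10,
    cprc_cv: int = 10,
) -> list[GridResult]:
    """Fit and evaluate every fusion spec on one calibration/prediction split.

    All data-dependent fitting — CPRC wavelength selection, stepwise crater
    retention, model hyperparameter CV — happens strictly on the calibration
    groups; the prediction group is only ever used to score predictions.
    """
    if not specs:
        return []
    cal, pred = split_by_group(ds, calibration_groups, prediction_groups)

    # stepwise-retained crater subset, fitted once per run on calibration data
    crater_subset: tuple[str, ...] = ()
    if any(s.crater_vars is None for s in specs):
        step_features = cal.crater_frame()
        for line in stepwise_lines:
            step_features[line.column] = peak_intensities(cal.spectra, line)
        retained = stepwise_backward(step_features, cal.references).retained
        crater_subset = tuple(v for v in CRATER_PARAM_NAMES if v in retained)
        if not crater_subset:
            raise SelectionError("stepwise elimination retained no crater parameters")

    # per-line CPRC models, fitted once per run on calibration data
    cprc_lines = {
        line.wavelength: line
        for s in specs if s.correction == "cprc"
        for line in s.lines
    }
    cprc_models = {
        wl: fit_cprc(cal.spectra, cal.references, line,
                     max_m=cprc_max_m, cv=cprc_cv, seed=seed)
        for wl, line in cprc_lines.items()
    }

    results = []
    for spec in specs:
        Fc = build_features(cal, spec, cprc_models, crater_subset)
        Fp = build_features(pred, spec, cprc_models, crater_subset)
        model = _fit_model(spec.model_kind, Fc, cal.references.values, seed)
        report = evaluate(model, (Fc, cal.references.values), (Fp, pred.references.values))
        results.append(GridResult(spec=spec, report=report, model=model,
                                  crater_subset=crater_subset if spec.crater_vars is None else tuple(spec.crater_vars or ())))
    return results
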