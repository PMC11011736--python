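"""Characteristic peak ratio correction (CPRC).

CPRC rescales every LIBS spectrum by the mean intensity of a few
"matrix-related" wavelengths chosen so that the ratio of the analyte's
characteristic peak to those wavelengths correlates maximally with the
reference concentration.  Because the correction divides each spectrum row by
a per-sample scalar, any per-sample multiplicative disturbance — matrix
effects on ablation efficiency, shot-to-shot laser energy drift — cancels
exactly, while concentration information carried by the peak is preserved.

Fitting proceeds in three steps:

1. For every wavelength bin ``j``, form the per-sample ratio
   ``B_j = x_N / z_j`` of the characteristic-peak intensity ``x_N`` to the
   intensity ``z_j`` at bin ``j``, and compute the Pearson correlation ``r_j``
   between ``B_j`` and the reference concentrations.
2. Rank bins by ``r`` descending.  For each prefix of the ranking (size 1..10)
   correct the full spectrum by the mean of the prefix intensities and
   cross-validate a PLSR model on the corrected spectra; keep the prefix size
   ``m`` that minimizes the CV-RMSE.
3. Correct any spectrum on the same axis by dividing its row by the mean of
   its own ``m`` selected intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .core_data import EmissionLine, ReferenceValues, SpectrumSet
from .errors import CorrectionError, SelectionError
from .preprocess import peak_intensities

__all__ = [
    "RatioCandidate",
    "CPRCModel",
    "ratio_candidates",
    "select_matrix_variables",
    "apply_cprc",
    "fit_cprc",
]

# relative-scale threshold below which a ratio column counts as constant
_ZERO_VAR_RTOL = 1e-10


@dataclass
class RatioCandidate:
    """One candidate matrix wavelength: bin, nm, per-sample ratios, correlation."""

    j: int
    wavelength: float
    B: np.ndarray
    r: float
    valid: bool


@dataclass
class CPRCModel:
    """A fitted peak-ratio correction for one characteristic peak."""

    peak: EmissionLine
    peak_window_nm: float
    selected_wavelengths: list[float]
    selected_bins: list[int]
    r_values: list[float]
    cv_rmse_path: list[float]
    m: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.m != len(self.selected_wavelengths):
            raise SelectionError(
                f"inconsistent model: m={self.m} but {len(self.selected_wavelengths)} selected wavelengths"
            )

    def to_dict(self) -> dict:
        return {
            "peak": {
                "element": self.peak.element,
                "stage": self.peak.stage,
                "wavelength": self.peak.wavelength,
            },
            "peak_window_nm": self.peak_window_nm,
            "selected_wavelengths": self.selected_wavelengths,
            "selected_bins": self.selected_bins,
            "r_values": self.r_values,
            "cv_rmse_path": self.cv_rmse_path,
            "m": self.m,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CPRCModel":
        return cls(
            peak=EmissionLine(**d["peak"]),
            peak_window_nm=float(d["peak_window_nm"]),
            selected_wavelengths=[float(v) for v in d["selected_wavelengths"]],
            selected_bins=[int(v) for v in d["selected_bins"]],
            r_values=[float(v) for v in d["r_values"]],
            cv_rmse_path=[float(v) for v in d["cv_rmse_path"]],
            m=int(d["m"]),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CPRCModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def ratio_candidates(
    ss: SpectrumSet,
    refs: ReferenceValues,
    peak: EmissionLine,
    peak_window_nm: float = 0.1,
) -> list[RatioCandidate]:
    """Peak-to-bin ratios and their correlations with the references, for every bin.

    Bins where any sample has zero intensity, or where the ratio has (numerically)
    zero variance — in particular the characteristic peak's own bin, whose ratio
    is identically 1 — are flagged invalid and can never be selected.
    """
    refs.check_aligned(ss)
    if ss.n < 3:
        raise SelectionError(f"need at least 3 samples to rank ratios, got {ss.n}")
    y = refs.values
    yc = y - y.mean()
    ss_y = float(np.sqrt(np.sum(yc**2)))
    if ss_y == 0.0:
        raise SelectionError("reference concentrations are constant; correlation undefined")

    x_peak = peak_intensities(ss, peak, peak_window_nm)
    zero_cols = np.any(ss.X == 0.0, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        B = x_peak[:, None] / ss.X
    B = np.where(zero_cols[None, :], np.nan, B)

    Bc = B - np.nanmean(B, axis=0, keepdims=True)
    ss_b = np.sqrt(np.nansum(Bc**2, axis=0))
    mean_abs = np.abs(np.nanmean(B, axis=0))
    degenerate = ss_b <= _ZERO_VAR_RTOL * np.maximum(1.0, mean_abs) * np.sqrt(ss.n)
    valid = ~zero_cols & ~degenerate

    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.nansum(Bc * yc[:, None], axis=0) / (ss_b * ss_y)

    out = []
    for j in range(ss.p):
        rj = float(r[j]) if valid[j] else float("nan")
        out.append(RatioCandidate(j, float(ss.wavelengths[j]), B[:, j], rj, bool(valid[j])))
    return out


def _divide_by_mean(X: np.ndarray, bins: list[int], sample_ids: list[str]) -> np.ndarray:
    zbar = X[:, bins].mean(axis=1)
    bad = np.nonzero(zbar <= 0)[0]
    if bad.size:
        raise CorrectionError(
            f"non-positive matrix-variable mean for sample {sample_ids[bad[0]]!r}"
        )
    return X / zbar[:, None]


def select_matrix_variables(
    candidates: list[RatioCandidate],
    ss: SpectrumSet,
    refs: ReferenceValues,
    peak: EmissionLine,
    max_m: int = 10,
    cv: int = 10,
    seed: int = 0,
    pls_components: int = 5,
    peak_window_nm: float = 0.1,
) -> CPRCModel:
    """Choose how many top-ranked matrix wavelengths to keep, by CV-RMSE.

    Valid candidates are ordered by ``r`` descending (ties toward the lower
    wavelength).  For every prefix size up to ``max_m`` the full spectrum is
    corrected with that prefix and a PLSR model is K-fold cross-validated
    against the references; the prefix minimizing the pooled CV-RMSE wins,
    with ties resolved toward the smaller prefix.
    """
    if max_m < 1:
        raise SelectionError(f"max_m must be >= 1, got {max_m}")
    if cv < 2 or cv > ss.n:
        raise SelectionError(f"cv folds must be in [2, n={ss.n}], got {cv}")
    valid = [c for c in candidates if c.valid]
    if not valid:
        raise SelectionError("no valid ratio candidates (all bins zero or constant)")
    valid.sort(key=lambda c: (-c.r, c.wavelength))
    prefix = valid[: min(max_m, len(valid))]

    y = refs.values
    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
    path: list[float] = []
    for m in range(1, len(prefix) + 1):
        bins = [c.j for c in prefix[:m]]
        Xc = _divide_by_mean(ss.X, bins, ss.sample_ids)
        sq_errs = np.empty_like(y)
        for train, test in folds.split(Xc):
            ncomp = min(pls_components, len(train) - 1, ss.p)
            pls = PLSRegression(n_components=ncomp, scale=False)
            pls.fit(Xc[train], y[train])
            pred = pls.predict(Xc[test]).ravel()
            sq_errs[test] = (pred - y[test]) ** 2
        path.append(float(np.sqrt(sq_errs.mean())))

    # smallest prefix within numerical tolerance of the minimum wins: prefix
    # sizes whose CV-RMSE differ only at machine-noise level count as ties
    best = min(path)
    tol = max(1e-12, 1e-6 * best)
    m_best = next(i + 1 for i, v in enumerate(path) if v <= best + tol)
    chosen = prefix[:m_best]
    return CPRCModel(
        peak=peak,
        peak_window_nm=peak_window_nm,
        selected_wavelengths=[c.wavelength for c in chosen],
        selected_bins=[c.j for c in chosen],
        r_values=[c.r for c in chosen],
        cv_rmse_path=path,
        m=m_best,
        seed=seed,
    )


def apply_cprc(model: CPRCModel, ss: SpectrumSet) -> SpectrumSet:
    """Correct a SpectrumSet: divide each row by the mean of its selected intensities.

    The model's selected wavelengths must exist on the target axis (matched to
    1e-6 nm); the per-sample mean must be positive.
    """
    bins = []
    for wl in model.selected_wavelengths:
        b = ss.nearest_bin(wl)
        if abs(ss.wavelengths[b] - wl) > 1e-6:
            raise CorrectionError(f"selected wavelength {wl} nm not on the target axis")
        bins.append(b)
    return ss.with_X(_divide_by_mean(ss.X, bins, ss.sample_ids))


def fit_cprc(
    ss: SpectrumSet,
    refs: ReferenceValues,
    peak: EmissionLine,
    max_m: int = 10,
    cv: int = 10,
    seed: int = 0,
    pls_components: int = 5,
    peak_window_nm: float = 0.1,
) -> CPRCModel:
    """Fit a CPRC model on a calibration set (ranking + prefix selection)."""
    cands = ratio_candidates(ss, refs, peak, peak_window_nm)
    return select_matrix_variables(
        cands, ss, refs, peak,
        max_m=max_m, cv=cv, seed=seed,
        pls_components=pls_components, peak_window_nm=peak_window_nm,
    )
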