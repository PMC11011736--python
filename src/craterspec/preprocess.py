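"""Comparison pretreatments and characteristic-peak extraction.

Two standard LIBS pretreatments are provided for benchmarking against the
ratio-correction method: asymmetric-least-squares (AsLS) baseline removal and
total-area normalization.  ``extract_peak`` reads the characteristic-peak
intensity of an emission line as the maximum inside a small wavelength window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .core_data import EmissionLine, Spectrum, SpectrumSet
from .errors import DataFormatError, NormalizationError

__all__ = [
    "PeakReading",
    "baseline_asls",
    "total_area_normalize",
    "extract_peak",
    "peak_intensities",
    "asls_correct_set",
    "area_normalize_set",
]


@dataclass(frozen=True)
class PeakReading:
    """Characteristic-peak intensity of one sample: line, axis bin, counts."""

    line: EmissionLine
    index: int
    intensity: float


def baseline_asls(
    s: Spectrum,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    max_iter: int = 20,
) -> tuple[Spectrum, Spectrum]:
    """Asymmetric-least-squares baseline estimate (Whittaker smoother).

    Minimizes ``sum_i w_i (y_i - z_i)^2 + smoothness * sum_i (d2 z)_i^2`` where
    the weight is ``asymmetry`` for points above the current baseline and
    ``1 - asymmetry`` below, re-iterated until the weights stop changing or
    ``max_iter`` passes.  Peaks (positive excursions) are thereby nearly
    ignored while the smooth background is tracked.

    Returns ``(baseline, corrected)`` with ``corrected = s - baseline`` exactly.
    """
    if not (0.0 < asymmetry < 1.0):
        raise DataFormatError(f"asymmetry must be in (0, 1), got {asymmetry}")
    if smoothness <= 0:
        raise DataFormatError(f"smoothness must be > 0, got {smoothness}")
    y = s.intensities
    p = y.size
    if p < 3:
        raise DataFormatError("AsLS needs at least 3 points")

    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(p - 2, p), format="csc")
    penalty = smoothness * (D.T @ D)
    w = np.ones(p)
    z = y
    for _ in range(max_iter):
        W = sparse.diags(w, format="csc")
        z = spsolve((W + penalty).tocsc(), w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    baseline = s.replace_intensities(z)
    corrected = s.replace_intensities(y - z)
    return baseline, corrected


def total_area_normalize(s: Spectrum) -> Spectrum:
    """Divide a spectrum by its total intensity so it sums to 1.

    Total-area normalization removes global scale fluctuations (laser energy,
    ablated mass) without singling out any particular wavelength.
    """
    total = float(np.sum(s.intensities))
    if total <= 0:
        raise NormalizationError(
            f"spectrum {s.sample_id!r} has non-positive total intensity {total}"
        )
    return s.replace_intensities(s.intensities / total)


def _window_indices(ss: SpectrumSet, line: EmissionLine, window_nm: float) -> np.ndarray:
    if window_nm < 0:
        raise DataFormatError(f"window_nm must be >= 0, got {window_nm}")
    lo, hi = line.wavelength - window_nm, line.wavelength + window_nm
    axis = ss.wavelengths
    if lo < axis[0] or hi > axis[-1]:
        raise DataFormatError(
            f"window {lo:.2f}-{hi:.2f} nm outside axis {axis[0]:.2f}-{axis[-1]:.2f} nm"
        )
    idx = np.nonzero((axis >= lo) & (axis <= hi))[0]
    if idx.size == 0:
        idx = np.array([ss.nearest_bin(line.wavelength)])
    return idx


def extract_peak(ss: SpectrumSet, line: EmissionLine, window_nm: float = 0.1) -> list[PeakReading]:
    """Per sample, the maximum intensity within ``+- window_nm`` of the line.

    Intensity ties are broken toward the bin nearest the nominal wavelength,
    then toward the lower wavelength.  ``window_nm = 0`` degenerates to the
    single bin nearest the nominal wavelength.
    """
    idx = _window_indices(ss, line, window_nm)
    sub = ss.X[:, idx]
    # tie-break ordering: sort window bins by (|wl - nominal|, wl), take first max
    dist = np.abs(ss.wavelengths[idx] - line.wavelength)
    order = np.lexsort((ss.wavelengths[idx], dist))
    sub_ord = sub[:, order]
    win_pos = np.argmax(sub_ord, axis=1)  # first occurrence wins, i.e. preferred tie-break
    bins = idx[order][win_pos]
    return [
        PeakReading(line, int(b), float(ss.X[i, b]))
        for i, b in enumerate(bins)
    ]


def peak_intensities(ss: SpectrumSet, line: EmissionLine, window_nm: float = 0.1) -> np.ndarray:
    """Vectorized convenience: the extracted peak intensity per sample."""
    return np.array([r.intensity for r in extract_peak(ss, line, window_nm)])


def asls_correct_set(
    ss: SpectrumSet,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    max_iter: int = 20,
) -> SpectrumSet:
    """AsLS-correct every row of a SpectrumSet."""
    rows = [
        baseline_asls(ss.spectrum(i), smoothness, asymmetry, max_iter)[1].intensities
        for i in range(ss.n)
    ]
    return ss.with_X(np.vstack(rows))


def area_normalize_set(ss: SpectrumSet) -> SpectrumSet:
    """Total-area normalize every row of a SpectrumSet."""
    rows = [total_area_normalize(ss.spectrum(i)).intensities for i in range(ss.n)]
    return ss.with_X(np.vstack(rows))
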