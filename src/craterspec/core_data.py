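"""Core containers for LIBS calibration data.

The central object is a :class:`SpectrumSet`: an ``n x p`` intensity matrix on
one shared, strictly ascending wavelength axis (nm).  Spectra are paired with
per-sample cadmium reference concentrations (:class:`ReferenceValues`, ug/g
from ICP-MS), ablation-crater morphology (:class:`CraterProfile`, nine
laser-microscope parameters in um-based units) and brand / split-group labels
in a :class:`CalibrationDataset`.  Alignment between containers is always by
explicit ``sample_id``; a mismatch is a hard error, never silently reordered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataFormatError

__all__ = [
    "EmissionLine",
    "CD_LINES",
    "Spectrum",
    "SpectrumSet",
    "ReferenceValues",
    "CraterProfile",
    "CRATER_PARAM_NAMES",
    "CalibrationDataset",
    "read_spectra",
    "write_spectra",
    "read_craters",
    "write_craters",
    "read_references",
    "write_references",
    "load_dataset",
    "split_by_group",
]


@dataclass(frozen=True)
class EmissionLine:
    """An atomic emission line: element symbol, ionization stage (I/II), wavelength in nm."""

    element: str
    stage: str
    wavelength: float

    @property
    def label(self) -> str:
        return f"{self.element} {self.stage} {self.wavelength:.2f} nm"

    @property
    def column(self) -> str:
        """Stable feature-column name, e.g. ``Cd_I_228.80nm``."""
        return f"{self.element}_{self.stage}_{self.wavelength:.2f}nm"


#: The three cadmium analytical lines inside the 210-231 nm window.
CD_LINES: tuple[EmissionLine, ...] = (
    EmissionLine("Cd", "II", 214.44),
    EmissionLine("Cd", "II", 226.50),
    EmissionLine("Cd", "I", 228.80),
)


def _check_axis(wavelengths: np.ndarray) -> np.ndarray:
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.ndim != 1 or wavelengths.size < 2:
        raise DataFormatError("wavelength axis must be 1-D with at least 2 points")
    if not np.all(np.isfinite(wavelengths)):
        raise DataFormatError("wavelength axis contains non-finite values")
    if np.any(np.diff(wavelengths) <= 0):
        raise DataFormatError("wavelength axis must be strictly ascending without duplicates")
    return wavelengths


@dataclass
class Spectrum:
    """One LIBS spectrum: intensities (arbitrary counts) on an ascending nm axis."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    brand: str = ""
    level_ug_g: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = _check_axis(self.wavelengths)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.wavelengths.shape:
            raise DataFormatError(
                f"intensities length {self.intensities.size} != axis length {self.wavelengths.size}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise DataFormatError(f"spectrum {self.sample_id!r} has non-finite intensities")

    def replace_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavelengths, intensities, self.sample_id, self.brand, self.level_ug_g)


@dataclass
class SpectrumSet:
    """``n x p`` intensity matrix ``X`` on one shared wavelength axis."""

    X: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.wavelengths = _check_axis(self.wavelengths)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DataFormatError("X must be a 2-D matrix")
        n, p = self.X.shape
        if n < 1 or p < 2:
            raise DataFormatError(f"need n >= 1 and p >= 2, got {n} x {p}")
        if p != self.wavelengths.size:
            raise DataFormatError(f"X has {p} columns but axis has {self.wavelengths.size} points")
        if not np.all(np.isfinite(self.X)):
            raise DataFormatError("X contains non-finite intensities")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise DataFormatError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise DataFormatError("sample ids are not unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.X[i], sample_id=self.sample_ids[i])

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        idx = list(indices)
        return SpectrumSet(self.X[idx], self.wavelengths, [self.sample_ids[i] for i in idx])

    def nearest_bin(self, wavelength_nm: float) -> int:
        """Index of the axis bin closest to ``wavelength_nm`` (lower bin wins ties)."""
        d = np.abs(self.wavelengths - wavelength_nm)
        return int(np.argmin(d))  # argmin returns the first (lower-wavelength) minimum

    def with_X(self, X: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(X, self.wavelengths, list(self.sample_ids))

    @classmethod
    def from_spectra(cls, spectra: Iterable[Spectrum]) -> "SpectrumSet":
        spectra = list(spectra)
        if not spectra:
            raise DataFormatError("no spectra given")
        axis = spectra[0].wavelengths
        for s in spectra[1:]:
            if s.wavelengths.shape != axis.shape or not np.array_equal(s.wavelengths, axis):
                raise DataFormatError(f"spectrum {s.sample_id!r} is not on the shared axis")
        return cls(
            np.vstack([s.intensities for s in spectra]),
            axis,
            [s.sample_id for s in spectra],
        )


@dataclass
class ReferenceValues:
    """Per-sample Cd reference concentrations (ug/g), aligned to a SpectrumSet by id."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataFormatError("reference values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise DataFormatError("reference values contain non-finite entries")
        if np.any(self.values < 0):
            raise DataFormatError("reference concentrations must be >= 0")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.size:
            raise DataFormatError("reference ids and values have different lengths")

    def subset(self, indices: Sequence[int]) -> "ReferenceValues":
        idx = list(indices)
        return ReferenceValues(self.values[idx], [self.sample_ids[i] for i in idx])

    def check_aligned(self, ss: SpectrumSet) -> None:
        if self.sample_ids != ss.sample_ids:
            raise AlignmentError("reference sample ids do not match the spectrum set")


#: The nine crater morphology parameters, in the field's reporting order.
CRATER_PARAM_NAMES: tuple[str, ...] = (
    "volume",
    "cross_sectional_area",
    "surface_area",
    "average_depth",
    "maximum_depth",
    "perimeter",
    "horizontal_feret",
    "vertical_feret",
    "circle_equivalent_diameter",
)


@dataclass(frozen=True)
class CraterProfile:
    """Nine morphology parameters of one ablation crater.

    Units: volume um^3; cross-sectional and surface areas um^2; depths,
    perimeter and the three diameters um.  All values are positive and the
    maximum depth cannot be smaller than the average depth.
    """

    volume: float
    cross_sectional_area: float
    surface_area: float
    average_depth: float
    maximum_depth: float
    perimeter: float
    horizontal_feret: float
    vertical_feret: float
    circle_equivalent_diameter: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise DataFormatError(f"crater parameter {f.name} must be finite and > 0, got {v}")
        if self.maximum_depth < self.average_depth:
            raise DataFormatError(
                f"maximum depth {self.maximum_depth} < average depth {self.average_depth}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in CRATER_PARAM_NAMES], dtype=float)


@dataclass
class CalibrationDataset:
    """Spectra + craters + references + brand/group labels, aligned by sample id."""

    spectra: SpectrumSet
    craters: list[CraterProfile]
    references: ReferenceValues
    brand: list[str]
    group: list[str]
    level_ug_g: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.spectra.n
        self.references.check_aligned(self.spectra)
        if len(self.craters) != n:
            raise AlignmentError(f"{len(self.craters)} craters for {n} spectra")
        if len(self.brand) != n or len(self.group) != n:
            raise AlignmentError("brand/group labels not aligned with spectra")
        if self.level_ug_g and len(self.level_ug_g) != n:
            raise AlignmentError("level labels not aligned with spectra")

    @property
    def n(self) -> int:
        return self.spectra.n

    @property
    def sample_ids(self) -> list[str]:
        return self.spectra.sample_ids

    def subset(self, indices: Sequence[int]) -> "CalibrationDataset":
        idx = list(indices)
        return CalibrationDataset(
            spectra=self.spectra.subset(idx),
            craters=[self.craters[i] for i in idx],
            references=self.references.subset(idx),
            brand=[self.brand[i] for i in idx],
            group=[self.group[i] for i in idx],
            level_ug_g=[self.level_ug_g[i] for i in idx] if self.level_ug_g else [],
        )

    def crater_frame(self) -> pd.DataFrame:
        """The nine crater parameters as an ``n x 9`` named DataFrame (index = sample id)."""
        return pd.DataFrame(
            np.vstack([c.as_array() for c in self.craters]),
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(CRATER_PARAM_NAMES),
        )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_numeric_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc


def read_spectra(path: str | Path, layout: str = "wide") -> SpectrumSet:
    """Read a spectra CSV.

    ``wide``: first column is the wavelength in nm, every further column is one
    sample (header = sample id).  ``long``: columns ``sample_id``,
    ``wavelength_nm``, ``intensity``.  Rows may appear in any wavelength order;
    the axis is sorted ascending.  Duplicate wavelengths and ragged axes
    (a sample missing a wavelength) are rejected.
    """
    df = _read_numeric_csv(path)
    if layout == "wide":
        if df.shape[1] < 2:
            raise DataFormatError(f"{path}: wide layout needs a wavelength column plus >= 1 sample")
        wl_col = df.columns[0]
        wide = df.set_index(wl_col)
    elif layout == "long":
        required = {"sample_id", "wavelength_nm", "intensity"}
        if not required.issubset(df.columns):
            raise DataFormatError(f"{path}: long layout needs columns {sorted(required)}")
        counts = df.groupby("sample_id")["wavelength_nm"].nunique()
        sizes = df.groupby("sample_id").size()
        if (counts != sizes).any():
            raise DataFormatError(f"{path}: duplicate wavelengths within a sample")
        if counts.nunique() != 1:
            raise DataFormatError(f"{path}: samples have ragged wavelength axes")
        wide = df.pivot(index="wavelength_nm", columns="sample_id", values="intensity")
        # preserve first-appearance sample order rather than pivot's lexicographic order
        order = list(dict.fromkeys(df["sample_id"].astype(str)))
        wide.columns = wide.columns.astype(str)
        wide = wide[order]
    else:
        raise DataFormatError(f"unknown layout {layout!r} (expected 'wide' or 'long')")

    try:
        values = wide.to_numpy(dtype=float)
        axis = wide.index.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"{path}: non-numeric cell: {exc}") from exc
    if np.any(np.isnan(values)):
        raise DataFormatError(f"{path}: missing intensity values (ragged axes across samples)")
    if pd.Index(axis).has_duplicates:
        raise DataFormatError(f"{path}: duplicate wavelength rows")
    order = np.argsort(axis)
    return SpectrumSet(values[order].T, axis[order], [str(c) for c in wide.columns])


def write_spectra(ss: SpectrumSet, path: str | Path, layout: str = "wide") -> Path:
    """Write a SpectrumSet to CSV; the default string formatting round-trips floats exactly."""
    path = Path(path)
    if layout == "wide":
        df = pd.DataFrame(ss.X.T, columns=ss.sample_ids)
        df.insert(0, "wavelength_nm", ss.wavelengths)
        df.to_csv(path, index=False, float_format="%.17g")
    elif layout == "long":
        rows = {
            "sample_id": np.repeat(ss.sample_ids, ss.p),
            "wavelength_nm": np.tile(ss.wavelengths, ss.n),
            "intensity": ss.X.ravel(),
        }
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    else:
        raise DataFormatError(f"unknown layout {layout!r}")
    return path


def read_craters(path: str | Path) -> tuple[list[CraterProfile], list[str]]:
    """Read a crater CSV: one row per sample, columns ``sample_id`` + the nine parameters."""
    df = _read_numeric_csv(path)
    missing = [c for c in ("sample_id", *CRATER_PARAM_NAMES) if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing crater columns {missing}")
    craters = [
        CraterProfile(**{name: float(row[name]) for name in CRATER_PARAM_NAMES})
        for _, row in df.iterrows()
    ]
    return craters, [str(s) for s in df["sample_id"]]


def write_craters(craters: Sequence[CraterProfile], sample_ids: Sequence[str], path: str | Path) -> Path:
    df = pd.DataFrame([c.as_array() for c in craters], columns=list(CRATER_PARAM_NAMES))
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_references(path: str | Path) -> ReferenceValues:
    """Read a reference CSV with columns ``sample_id`` and ``cd_ug_g``."""
    df = _read_numeric_csv(path)
    for col in ("sample_id", "cd_ug_g"):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing column {col!r}")
    return ReferenceValues(df["cd_ug_g"].to_numpy(dtype=float), [str(s) for s in df["sample_id"]])


def write_references(refs: ReferenceValues, path: str | Path) -> Path:
    pd.DataFrame({"sample_id": refs.sample_ids, "cd_ug_g": refs.values}).to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def load_dataset(directory: str | Path) -> CalibrationDataset:
    """Assemble a CalibrationDataset from a directory written by ``write_dataset``.

    Expects ``spectra.csv`` (wide), ``craters.csv``, ``refs.csv`` and
    ``labels.csv`` (sample_id, brand, group[, level_ug_g]), all keyed by the
    same sample ids in the same order.
    """
    directory = Path(directory)
    ss = read_spectra(directory / "spectra.csv", layout="wide")
    craters, crater_ids = read_craters(directory / "craters.csv")
    refs = read_references(directory / "refs.csv")
    labels = _read_numeric_csv(directory / "labels.csv")
    label_ids = [str(s) for s in labels["sample_id"]]
    if crater_ids != ss.sample_ids or label_ids != ss.sample_ids:
        raise AlignmentError(f"{directory}: sample ids differ across files")
    levels = (
        [float(v) for v in labels["level_ug_g"]] if "level_ug_g" in labels.columns else []
    )
    return CalibrationDataset(
        spectra=ss,
        craters=craters,
        references=refs,
        brand=[str(b) for b in labels["brand"]],
        group=[str(g) for g in labels["group"]],
        level_ug_g=levels,
    )


def split_by_group(
    ds: CalibrationDataset,
    calibration_groups: Iterable[str],
    prediction_groups: Iterable[str],
) -> tuple[CalibrationDataset, CalibrationDataset]:
    """Split a dataset into calibration and prediction subsets by group label.

    The requested label sets must be disjoint, each must be present in the
    dataset, and neither side may come out empty.  Alignment between spectra,
    craters and references is preserved.
    """
    cal_labels = set(map(str, calibration_groups))
    pred_labels = set(map(str, prediction_groups))
    present = set(ds.group)
    for lbl in sorted((cal_labels | pred_labels) - present):
        raise KeyError(f"unknown group label {lbl!r}; dataset has {sorted(present)}")
    if cal_labels & pred_labels:
        raise DataFormatError(f"groups {sorted(cal_labels & pred_labels)} requested on both sides")
    cal_idx = [i for i, g in enumerate(ds.group) if g in cal_labels]
    pred_idx = [i for i, g in enumerate(ds.group) if g in pred_labels]
    if not cal_idx or not pred_idx:
        raise DataFormatError("degenerate split: calibration or prediction set is empty")
    return ds.subset(cal_idx), ds.subset(pred_idx)


def dataset_manifest(config_dict: dict, directory: str | Path) -> Path:
    """Write a JSON manifest echoing the generator configuration (incl. seed)."""
    path = Path(directory) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(config_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
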