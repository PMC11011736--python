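"""Synthetic LIBS benchmark generator.

Emulates the statistical structure of a multi-brand spiking study of Cd in
*Panax notoginseng* powders: six brands with brand-dependent multiplicative
matrix effects, ten spike levels (0-70 ug/g) with four replicate tablets each
(one replicate per split group), three Cd analytical lines plus Fe/Al/Si/Ca
interferent lines on a 210-231 nm axis, a smooth baseline, multiplicative
log-normal noise, crater morphology correlated with ablation efficiency, and
ICP-MS-like reference noise.

The generative model per sample ``i`` of brand ``b``:

* true concentration ``c_i = level + native_b`` (small nonzero native Cd);
* ablation factor ``a_i = f_b * s_i * g1_i * g2_i * g3_i`` with brand factor
  ``f_b``, an unobservable shot-to-shot log-normal fluctuation ``s_i``
  (cv = ``noise_cv``) and three crater-visible log-normal ablation components
  ``g1..g3`` (cv = ``ablation_cv``): ablated-mass, mean-penetration and
  peak-penetration fluctuations;
* line areas: ``response_l * c_i`` for the Cd lines, brand-composition areas
  for the interferents, each multiplied by a per-line excitation jitter
  (cv = ``line_jitter_cv``) — plasma-state fluctuations move individual
  transitions semi-independently of the overall emission;
* spectrum ``x_i(w) = a_i * [ baseline(w) + sum_l A_l * N(w; w_l, sigma) ]``,
  then per-pixel log-normal noise (cv = ``noise_cv``) on every bin.

Because every term is multiplied by ``a_i``, background bins carry the full
per-sample matrix factor — this is precisely the structure peak-ratio
correction exploits, and the red tail of the axis (>= 229.5 nm, free of
emission lines) is the cleanest place to read it.  Crater volume reads the
ablated-mass component (``volume ~ f_b * g1^2``), the average and maximum
depths read the two penetration components (``~ sqrt(f_b) * g2`` and
``~ sqrt(f_b) * g3``; crater dimensions scale sub-linearly with ablation
efficiency) — looser texture means a higher brand factor, stronger ablation
and a bigger crater — so these three parameters jointly (and only jointly)
recover the crater-visible part of the matrix factor.  The remaining six
morphology parameters are ablation-independent shape noise around
brand-texture scales: they reproduce the dispersion regime of real crater
tables but carry no concentration signal, which is what makes them
eliminable by stepwise MLR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core_data import (
    CD_LINES,
    CalibrationDataset,
    CraterProfile,
    EmissionLine,
    ReferenceValues,
    SpectrumSet,
    dataset_manifest,
    write_craters,
    write_references,
    write_spectra,
)
from .errors import DataFormatError

__all__ = [
    "SyntheticConfig",
    "INTERFERENT_LINES",
    "SIGNAL_CRATER_PARAMS",
    "NOISE_CRATER_PARAMS",
    "generate",
    "write_dataset",
    "read_manifest",
]


#: Interferent emission lines of the plant matrix inside 210-231 nm
#: (Al, Si, Ca and Fe; Fe II 226.48 / Fe I 226.50 overlap Cd II 226.50).
INTERFERENT_LINES: tuple[EmissionLine, ...] = (
    EmissionLine("Al", "I", 221.00),
    EmissionLine("Al", "I", 226.35),
    EmissionLine("Al", "I", 226.91),
    EmissionLine("Si", "I", 212.41),
    EmissionLine("Si", "I", 220.80),
    EmissionLine("Si", "I", 221.09),
    EmissionLine("Si", "I", 221.17),
    EmissionLine("Si", "I", 221.67),
    EmissionLine("Si", "I", 221.81),
    EmissionLine("Ca", "II", 211.28),
    EmissionLine("Ca", "II", 212.30),
    EmissionLine("Ca", "II", 215.08),
    EmissionLine("Ca", "II", 227.55),
    EmissionLine("Fe", "II", 213.65),
    EmissionLine("Fe", "II", 213.70),
    EmissionLine("Fe", "II", 215.24),
    EmissionLine("Fe", "II", 215.59),
    EmissionLine("Fe", "I", 221.10),
    EmissionLine("Fe", "I", 221.71),
    EmissionLine("Fe", "II", 226.48),
    EmissionLine("Fe", "I", 226.50),
    EmissionLine("Fe", "I", 227.71),
)

# crater base scales (um-based units) and intrinsic log-normal measurement
# dispersion; volume/depths additionally track ablation components (below),
# the six shape parameters track only the brand texture scale
_CRATER_BASE: dict[str, tuple[float, float]] = {
    # name: (base, intrinsic cv)
    "volume": (6.0e7, 0.02),
    "cross_sectional_area": (6.3e5, 0.35),
    "surface_area": (9.1e5, 0.40),
    "average_depth": (88.0, 0.01),
    "maximum_depth": (278.0, 0.01),
    "perimeter": (5555.0, 0.30),
    "horizontal_feret": (1018.0, 0.20),
    "vertical_feret": (1049.0, 0.20),
    "circle_equivalent_diameter": (873.0, 0.18),
}

#: crater parameters that carry per-sample ablation signal
SIGNAL_CRATER_PARAMS: tuple[str, ...] = ("volume", "average_depth", "maximum_depth")
#: crater parameters that are ablation-independent shape noise
NOISE_CRATER_PARAMS: tuple[str, ...] = tuple(
    name for name in _CRATER_BASE if name not in SIGNAL_CRATER_PARAMS
)


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic benchmark (defaults = the study design)."""

    n_brands: int = 6
    # None -> the quantile midpoints of U[0.5, 1.5]: six fixed, distinct,
    # evenly spread matrix factors (the brands are a fixed panel, not a draw)
    brand_factors: tuple[float, ...] | None = None
    brand_textures: tuple[float, ...] | None = None  # None -> homogeneous (all 1)
    levels: tuple[float, ...] = (0.0, 0.5, 1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)
    replicates: int = 4
    grid_start_nm: float = 210.0
    grid_stop_nm: float = 231.0
    grid_step_nm: float = 0.02
    line_sigma_nm: float = 0.05
    baseline_amplitude: float = 200.0
    baseline_drift: float = 0.5  # fractional rise of the baseline across the range
    noise_cv: float = 0.02  # shot-to-shot and per-pixel multiplicative noise
    ablation_cv: float | None = None  # cv of each crater-visible ablation component; None -> 6 * noise_cv
    line_jitter_cv: float | None = None  # per-line excitation fluctuation; None -> 3 * noise_cv
    additive_noise: bool = False  # robustness switch: additive instead of multiplicative
    cd_response: dict[str, float] = field(
        default_factory=lambda: {"214.44": 30.0, "226.50": 18.0, "228.80": 40.0}
    )  # Gaussian line area (counts*nm-less) per ug/g
    interferent_area: dict[str, float] = field(
        default_factory=lambda: {"Al": 350.0, "Si": 250.0, "Ca": 400.0, "Fe": 300.0}
    )  # base line area per element; scaled by a per-brand composition factor
    native_offset_range: tuple[float, float] = (0.4, 1.6)  # ug/g native Cd per brand
    ref_cv: float = 0.01  # ICP-MS reference measurement noise
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("brand_factors", "brand_textures", "levels", "native_offset_range"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("brand_factors", "brand_textures", "levels", "native_offset_range"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def axis(self) -> np.ndarray:
        n_steps = round((self.grid_stop_nm - self.grid_start_nm) / self.grid_step_nm)
        if n_steps < 1:
            raise DataFormatError("empty wavelength grid")
        return self.grid_start_nm + self.grid_step_nm * np.arange(n_steps + 1)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean log-normal multipliers with the given coefficient of variation.

    Draws are winsorized at +-3 log-sd: real acquisition pipelines discard or
    re-measure gross outlier shots, so the tails of the effective noise are
    bounded.
    """
    if cv == 0.0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    s = np.sqrt(s2)
    z = np.clip(rng.normal(size=size), -3.0, 3.0)
    return np.exp(-s2 / 2.0 + s * z)


def generate(config: SyntheticConfig | None = None) -> CalibrationDataset:
    """Generate one synthetic calibration dataset (bit-reproducible from the seed)."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.axis()
    if axis[0] > min(l.wavelength for l in CD_LINES) or axis[-1] < max(l.wavelength for l in CD_LINES):
        raise DataFormatError("grid does not cover the Cd analytical lines")

    factors = (
        np.asarray(cfg.brand_factors, dtype=float)
        if cfg.brand_factors is not None
        else 0.5 + (np.arange(cfg.n_brands) + 0.5) / cfg.n_brands
    )
    if factors.size != cfg.n_brands or np.any(factors <= 0):
        raise DataFormatError("brand_factors must give one positive factor per brand")
    textures = (
        np.asarray(cfg.brand_textures, dtype=float)
        if cfg.brand_textures is not None
        else np.ones(cfg.n_brands)
    )
    lo, hi = cfg.native_offset_range
    native = rng.uniform(lo, hi, cfg.n_brands)
    # per-brand composition multipliers for each interferent element
    elements = sorted(cfg.interferent_area)
    composition = {el: rng.uniform(0.5, 1.5, cfg.n_brands) for el in elements}

    # sample bookkeeping: brand-major, level, replicate; replicate k -> Group k+1
    brands_idx, levels_v, reps = [], [], []
    for b in range(cfg.n_brands):
        for lv in cfg.levels:
            for k in range(cfg.replicates):
                brands_idx.append(b)
                levels_v.append(float(lv))
                reps.append(k)
    brands_idx = np.asarray(brands_idx)
    levels_v = np.asarray(levels_v)
    reps = np.asarray(reps)
    n = brands_idx.size

    sample_ids = [
        f"B{b + 1}-C{lv:g}-R{k + 1}" for b, lv, k in zip(brands_idx, levels_v, reps)
    ]
    conc = levels_v + native[brands_idx]
    shot = _lognormal_factors(rng, cfg.noise_cv, n)
    abl_cv = 6.0 * cfg.noise_cv if cfg.ablation_cv is None else cfg.ablation_cv
    g_mass = _lognormal_factors(rng, abl_cv, n)  # ablated-mass component -> volume
    g_mean = _lognormal_factors(rng, abl_cv, n)  # mean-penetration component -> average depth
    g_peak = _lognormal_factors(rng, abl_cv, n)  # peak-penetration component -> maximum depth
    ablation = factors[brands_idx] * shot * g_mass * g_mean * g_peak

    # spectra: baseline + Gaussian lines, all scaled by the ablation factor
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    baseline = cfg.baseline_amplitude * (1.0 + cfg.baseline_drift * t)

    lines: list[EmissionLine] = list(CD_LINES) + list(INTERFERENT_LINES)
    profiles = np.empty((len(lines), axis.size))
    for li, line in enumerate(lines):
        profiles[li] = np.exp(-((axis - line.wavelength) ** 2) / (2.0 * cfg.line_sigma_nm**2))
    profiles /= cfg.line_sigma_nm * np.sqrt(2.0 * np.pi)  # unit-area Gaussians

    jitter_cv = 3.0 * cfg.noise_cv if cfg.line_jitter_cv is None else cfg.line_jitter_cv
    areas = np.zeros((n, len(lines)))
    for li, line in enumerate(lines):
        if line.element == "Cd":
            resp = cfg.cd_response[f"{line.wavelength:.2f}"]
            areas[:, li] = resp * conc
        else:
            base = cfg.interferent_area[line.element]
            areas[:, li] = base * composition[line.element][brands_idx]
        # line-to-line excitation fluctuation: plasma-state variation moves
        # individual transitions semi-independently of the overall emission
        areas[:, li] *= _lognormal_factors(rng, jitter_cv, n)

    X = ablation[:, None] * (baseline[None, :] + areas @ profiles)
    if cfg.additive_noise:
        X = X + rng.normal(0.0, cfg.noise_cv * cfg.baseline_amplitude, X.shape)
        X = np.clip(X, 1e-9, None)
    else:
        X = X * _lognormal_factors(rng, cfg.noise_cv, X.shape)

    spectra = SpectrumSet(X, axis, sample_ids)

    # craters: volume/depths each read one ablation component (scaled by the
    # brand factor), the six shape parameters read only brand texture and
    # noise; pooled dispersions land in the regime of real morphology tables
    # (volume in the tens of percent, depths ~30%, diameters ~20%)
    crater_noise = {
        name: _lognormal_factors(rng, cv, n) for name, (_, cv) in _CRATER_BASE.items()
    }
    fb = factors[brands_idx]
    tb = textures[brands_idx]
    values: dict[str, np.ndarray] = {
        name: _CRATER_BASE[name][0] * tb * crater_noise[name] for name in NOISE_CRATER_PARAMS
    }
    values["volume"] = _CRATER_BASE["volume"][0] * fb * g_mass**2 * crater_noise["volume"]
    values["average_depth"] = _CRATER_BASE["average_depth"][0] * np.sqrt(fb) * g_mean * crater_noise["average_depth"]
    values["maximum_depth"] = _CRATER_BASE["maximum_depth"][0] * np.sqrt(fb) * g_peak * crater_noise["maximum_depth"]
    # keep the depth ordering physical
    values["maximum_depth"] = np.maximum(values["maximum_depth"], 1.05 * values["average_depth"])
    craters = [
        CraterProfile(**{name: float(values[name][i]) for name in _CRATER_BASE})
        for i in range(n)
    ]

    refs = ReferenceValues(
        conc * _lognormal_factors(rng, cfg.ref_cv, n),
        list(sample_ids),
    )

    return CalibrationDataset(
        spectra=spectra,
        craters=craters,
        references=refs,
        brand=[f"Brand-{b + 1}" for b in brands_idx],
        group=[f"Group{k + 1}" for k in reps],
        level_ug_g=[float(v) for v in levels_v],
    )


def write_dataset(ds: CalibrationDataset, directory: str | Path,
                  config: SyntheticConfig | None = None) -> Path:
    """Write spectra/craters/refs/labels CSVs plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_spectra(ds.spectra, directory / "spectra.csv", layout="wide")
    write_craters(ds.craters, ds.sample_ids, directory / "craters.csv")
    write_references(ds.references, directory / "refs.csv")
    import pandas as pd

    labels = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "brand": ds.brand,
            "group": ds.group,
        }
    )
    if ds.level_ug_g:
        labels["level_ug_g"] = ds.level_ug_g
    labels.to_csv(directory / "labels.csv", index=False)
    manifest = {"config": (config or SyntheticConfig()).to_dict(), "n_samples": ds.n}
    return dataset_manifest(manifest, directory)


def read_manifest(path: str | Path) -> SyntheticConfig:
    """Reload the generator configuration echoed in a dataset manifest."""
    d = json.loads(Path(path).read_text())
    return SyntheticConfig.from_dict(d["config"])
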