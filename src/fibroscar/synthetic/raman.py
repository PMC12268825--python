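"""Synthetic Raman microspectra of myocardial tissue classes.

Each spectrum is a sum of Lorentzian bands at the collagen/protein
wavenumbers seen in cardiac tissue (amide I/III, CH deformation modes,
proline and collagen-backbone C–C stretches, cytochrome, CH-stretch
region), on top of a low-order polynomial autofluorescence baseline,
plus Gaussian noise. Band amplitudes trend with fibrosis stage: the
collagen-associated fingerprint bands grow monotonically along
muscle → necrotic → granulated → fibrotic, while the CH-stretch bands at
2880/2920 cm⁻¹ shrink; the amide I band at 1650 cm⁻¹ carries the largest
inter-class amplitude range, reflecting its sensitivity to collagen
fiber packing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ..tissue import CLASS_NAMES, CLASS_ORDER, TissueClass

#: Band centers (cm^-1): proline C-C, cytochrome, choline/collagen C-C,
#: collagen backbone C-C, amide III, CH2 twist, CH2/CH3 wag, CH2/CH3
#: deformation, amide I, asym CH2 stretch, sym CH3 stretch.
BAND_CENTERS = (728.0, 750.0, 869.0, 937.0, 1260.0, 1302.0, 1338.0,
                1446.0, 1650.0, 2880.0, 2920.0)

COLLAGEN_BANDS = (728.0, 869.0, 937.0, 1260.0, 1302.0, 1338.0, 1446.0, 1650.0)
CH_BANDS = (2880.0, 2920.0)

_DEFAULT_WIDTHS = (8.0, 8.0, 10.0, 10.0, 14.0, 12.0, 12.0, 14.0, 16.0, 30.0, 30.0)

# rows = bands (BAND_CENTERS order), cols = classes (muscle, necrotic,
# granulated, fibrotic). Collagen bands non-decreasing, CH bands
# non-increasing along the class order; amide I has the widest range.
# Increments are band-dependent (collagen deposition first raises the
# proline/amide-III/CH2-twist bands in necrosis, then the backbone C-C and
# wagging bands with granulation) so class mean shapes are not collinear.
_DEFAULT_AMPLITUDES = np.array([
    [0.10, 0.22, 0.24, 0.30],   # 728 proline C-C: early rise
    [0.30, 0.18, 0.14, 0.10],   # 750 cytochrome: muscle marker
    [0.12, 0.14, 0.32, 0.36],   # 869 choline/collagen C-C: late rise
    [0.15, 0.18, 0.40, 0.45],   # 937 collagen backbone C-C: late rise
    [0.20, 0.36, 0.38, 0.52],   # 1260 amide III: early rise
    [0.30, 0.48, 0.50, 0.62],   # 1302 CH2 twist: early rise
    [0.25, 0.28, 0.46, 0.56],   # 1338 CH2/CH3 wag: late rise
    [0.50, 0.70, 0.85, 1.06],   # 1446 CH2/CH3 deformation
    [0.60, 0.92, 1.18, 1.56],   # 1650 amide I, largest range
    [1.40, 1.15, 1.10, 0.80],   # 2880
    [1.80, 1.50, 1.40, 1.05],   # 2920
])


def default_axis(spacing: float = 2.0) -> np.ndarray:
    """Fingerprint (600-1800) plus CH-stretch (2700-3100) grid, cm^-1.

    The silent region between the two windows is omitted.
    """
    fp = np.arange(600.0, 1800.0 + spacing / 2, spacing)
    ch = np.arange(2700.0, 3100.0 + spacing / 2, spacing)
    return np.concatenate([fp, ch])


@dataclasses.dataclass(frozen=True)
class RamanBandModel:
    """Band-mixture model of class-dependent Raman spectra."""

    centers: tuple[float, ...] = BAND_CENTERS
    widths: tuple[float, ...] = _DEFAULT_WIDTHS
    amplitudes: np.ndarray = dataclasses.field(
        default_factory=lambda: _DEFAULT_AMPLITUDES.copy())
    baseline_scale: float = 0.05
    noise_sd: float = 0.01
    amplitude_jitter_sd: float = 0.03
    axis: np.ndarray = dataclasses.field(default_factory=default_axis)

    def validate(self) -> None:
        A = np.asarray(self.amplitudes, dtype=float)
        if A.shape != (len(self.centers), len(CLASS_ORDER)):
            raise ValueError("amplitude matrix must be n_bands x 4 classes")
        if np.any(A < 0):
            raise ValueError("amplitudes must be non-negative")
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        for b, center in enumerate(self.centers):
            if center in COLLAGEN_BANDS and np.any(np.diff(A[b]) < 0):
                raise ValueError(f"collagen band {center} must be non-decreasing")
            if center in CH_BANDS and np.any(np.diff(A[b]) > 0):
                raise ValueError(f"CH band {center} must be non-increasing")

    def class_amplitudes(self, cls: TissueClass) -> np.ndarray:
        return np.asarray(self.amplitudes, dtype=float)[:, CLASS_ORDER.index(cls)]


def lorentzian(nu: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-peak Lorentzian line shape with half width at half maximum ``width``."""
    return width**2 / ((nu - center) ** 2 + width**2)


def clean_spectrum(model: RamanBandModel, cls: TissueClass) -> np.ndarray:
    """Noise-free, baseline-free class spectrum (the band mixture itself)."""
    amps = model.class_amplitudes(cls)
    spec = np.zeros_like(model.axis)
    for a, c, w in zip(amps, model.centers, model.widths):
        spec += a * lorentzian(model.axis, c, w)
    return spec


@dataclasses.dataclass
class RamanSpectrumSet:
    """A wavenumber axis, an (n_spectra, n_channels) intensity matrix, labels."""

    axis: np.ndarray
    intensities: np.ndarray
    labels: list[TissueClass]
    preprocessing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.axis.size:
            raise ValueError("intensity column count must equal axis length")
        if len(self.labels) != self.intensities.shape[0]:
            raise ValueError("one label per spectrum required")
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def label_names(self) -> np.ndarray:
        return np.array([c.value for c in self.labels])

    def class_mean(self, cls: TissueClass) -> np.ndarray:
        sel = np.array([lab is cls for lab in self.labels])
        return self.intensities[sel].mean(axis=0)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(spectra frame: wavenumber_cm1 + one column per spectrum, label frame)."""
        ids = [f"spec{i:04d}" for i in range(self.n_spectra)]
        spectra = pd.DataFrame({"wavenumber_cm1": self.axis})
        for i, sid in enumerate(ids):
            spectra[sid] = self.intensities[i]
        labels = pd.DataFrame({"spectrum_id": ids,
                               "tissue_class": self.label_names()})
        return spectra, labels

    @classmethod
    def from_frames(cls, spectra: pd.DataFrame,
                    labels: pd.DataFrame) -> "RamanSpectrumSet":
        from ..tissue import as_tissue_class

        axis = spectra["wavenumber_cm1"].to_numpy(dtype=float)
        ids = list(labels["spectrum_id"])
        X = np.stack([spectra[sid].to_numpy(dtype=float) for sid in ids])
        labs = [as_tissue_class(t) for t in labels["tissue_class"]]
        return cls(axis=axis, intensities=X, labels=labs)


def generate_raman_set(n_per_class: int = 40,
                       band_model: RamanBandModel | None = None,
                       seed: int = 0) -> RamanSpectrumSet:
    """Generate a seeded synthetic four-class Raman spectrum set.

    Each spectrum is ``baseline + Σ_b A[b,c]·Lorentzian(ν; ν_b, w_b) + noise``
    with a per-spectrum cubic-polynomial baseline (small random
    coefficients, scaled by ``baseline_scale``) emulating autofluorescence
    background, and i.i.d. Gaussian channel noise of sd ``noise_sd``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    model = band_model or RamanBandModel()
    model.validate()
    nu = model.axis
    rng = np.random.default_rng(seed)
    # reduced axis in [-1, 1] keeps polynomial baselines well-scaled
    u = 2 * (nu - nu.min()) / (nu.max() - nu.min()) - 1
    spectra, labels = [], []
    for cls in CLASS_ORDER:
        base_shape = clean_spectrum(model, cls)
        for _ in range(n_per_class):
            coeffs = rng.normal(0.0, 1.0, 4) * model.baseline_scale
            baseline = np.polynomial.polynomial.polyval(u, coeffs) + 2 * model.baseline_scale
            amp_jitter = rng.normal(1.0, model.amplitude_jitter_sd)
            spec = (baseline + amp_jitter * base_shape
                    + rng.normal(0.0, model.noise_sd, nu.size))
            spectra.append(spec)
            labels.append(cls)
    return RamanSpectrumSet(axis=nu, intensities=np.asarray(spectra),
                            labels=labels)
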