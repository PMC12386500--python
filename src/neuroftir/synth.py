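"""Synthetic ATR-FTIR spectra of differentiating cortical neuron cultures.

Generates absorbance spectra on a uniform descending wavenumber grid
(mid-IR, default 4000-600 cm^-1) with the replicate structure of the study
design: 7 sampling days (DIV 2-14) x 8 biological replicates x 3 technical
replicates.  Each spectrum is a sum of Gaussian absorption bands whose
amplitudes drift linearly with days in vitro (DIV), plus a random polynomial
baseline, a per-spectrum multiplicative gain, additive white noise, and a
per-(band-class, biological-replicate) lognormal amplitude multiplier that
mimics the biological-vs-technical variance hierarchy.

The default band library encodes the qualitative maturation trends reported
for this system: total protein, CH2 lipids, lipid esters, acyl chain length,
alpha-helix and intermolecular beta-sheet content rise with DIV, while
antiparallel beta-sheet, =CH unsaturation and RNA ribose signals fall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BandSpec",
    "SynthConfig",
    "Spectrum",
    "default_band_library",
    "simulate_dataset",
    "corrupt_spectrum",
    "write_dataset",
    "read_dataset",
    "spectra_to_matrix",
]

_DIV_MIN, _DIV_MAX = 2.0, 14.0


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``div_slope`` is the fractional amplitude change per day in vitro,
    applied as ``base_amplitude * (1 + div_slope * (DIV - 2))``.
    ``band_class`` groups bands that share a biological-replicate amplitude
    multiplier (protein, lipid, ester, phosphate, nucleic, ...).
    """

    name: str
    center: float
    width: float
    base_amplitude: float
    div_slope: float = 0.0
    band_class: str = "other"

    def __post_init__(self) -> None:
        if not (600.0 <= self.center <= 4000.0):
            raise ValueError(f"band {self.name}: center {self.center} outside [600, 4000]")
        if not self.width > 0:
            raise ValueError(f"band {self.name}: width must be > 0")
        if self.base_amplitude < 0:
            raise ValueError(f"band {self.name}: base_amplitude must be >= 0")
        for d in (_DIV_MIN, _DIV_MAX):
            if self.amplitude(d) < 0:
                raise ValueError(
                    f"band {self.name}: amplitude negative at DIV {d:g} "
                    f"(base {self.base_amplitude}, slope {self.div_slope})"
                )

    def amplitude(self, div: float) -> float:
        """Band amplitude at a given DIV under the linear trend model."""
        return self.base_amplitude * (1.0 + self.div_slope * (div - _DIV_MIN))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings for one synthetic dataset."""

    div_levels: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14)
    n_bio: int = 8
    n_tech: int = 3
    grid: tuple[float, float, float] = (4000.0, 600.0, 4.0)  # start, stop, step
    bands: tuple[BandSpec, ...] = ()
    baseline_order: int = 2
    baseline_scale: float = 0.02
    noise_sd: float = 0.003
    mult_noise_sd: float = 0.02
    bio_sd: float = 0.05
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1 or len(self.div_levels) < 1:
            raise ValueError("replicate counts and div_levels must be >= 1")
        if list(self.div_levels) != sorted(self.div_levels):
            raise ValueError("div_levels must be sorted ascending")
        start, stop, step = self.grid
        if step <= 0 or start <= stop:
            raise ValueError("grid must be (start, stop, step) with start > stop, step > 0")
        for name in ("baseline_scale", "noise_sd", "mult_noise_sd", "bio_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if not self.bands:
            object.__setattr__(self, "bands", tuple(default_band_library()))

    def wavenumbers(self) -> np.ndarray:
        start, stop, step = self.grid
        n = int(round((start - stop) / step)) + 1
        return start - step * np.arange(n)

    @property
    def n_spectra(self) -> int:
        return len(self.div_levels) * self.n_bio * self.n_tech


@dataclass
class Spectrum:
    """A single absorbance spectrum with sample metadata.

    ``wavenumbers`` is a strictly monotone (conventionally descending)
    uniform grid in cm^-1; ``absorbance`` holds matching values in A.U.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape or self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be 1-D and equal length")
        d = np.diff(self.wavenumbers)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def copy_with(self, absorbance=None, wavenumbers=None, **meta) -> "Spectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(
            self.wavenumbers.copy() if wavenumbers is None else wavenumbers,
            self.absorbance.copy() if absorbance is None else absorbance,
            new_meta,
        )


def default_band_library() -> list[BandSpec]:
    """Gaussian band library with the study system's maturation trends.

    Centers follow the standard mid-IR assignments for cellular material;
    amplitudes are in the relative proportions of a typical whole-cell
    spectrum.  Positive ``div_slope`` encodes bands that strengthen with
    neuronal maturation (protein backbone, CH2 lipids, esters), negative
    slopes encode declining signals (=CH unsaturation, antiparallel
    beta-sheet, RNA ribose).
    """
    return [
        # lipid CH stretch region, 3050-2800 cm^-1
        BandSpec("unsat_CH", 3013.0, 6.0, 0.05, -0.030, "lipid"),
        BandSpec("ch3_asym", 2959.0, 8.0, 0.22, 0.015, "lipid"),
        BandSpec("ch2_asym", 2922.0, 9.0, 0.32, 0.045, "lipid"),
        BandSpec("ch3_sym", 2871.0, 8.0, 0.13, 0.015, "lipid"),
        BandSpec("ch2_sym", 2851.0, 8.0, 0.22, 0.045, "lipid"),
        # carbonyl / amide region, 1800-1500 cm^-1
        BandSpec("lipid_ester", 1740.0, 8.0, 0.12, 0.055, "ester"),
        BandSpec("antiparallel_beta", 1693.0, 7.0, 0.45, -0.035, "protein"),
        BandSpec("beta_sheet", 1682.0, 7.0, 0.40, -0.005, "protein"),
        BandSpec("beta_turn", 1656.0, 7.0, 0.35, 0.030, "protein"),
        BandSpec("amide_I", 1655.0, 26.0, 0.30, 0.030, "protein"),  # broad envelope
        BandSpec("alpha_helix", 1651.0, 7.0, 0.32, 0.055, "protein"),
        BandSpec("parallel_beta", 1639.0, 7.0, 0.25, 0.030, "protein"),
        BandSpec("intermolecular_beta", 1628.0, 7.0, 0.25, 0.050, "protein"),
        BandSpec("amide_II", 1545.0, 18.0, 0.50, 0.050, "protein"),
        # fingerprint region, 1500-900 cm^-1
        BandSpec("ch_bend", 1455.0, 9.0, 0.15, 0.025, "lipid"),
        BandSpec("po2_asym", 1240.0, 10.0, 0.22, 0.000, "phosphate"),
        BandSpec("carbohydrate", 1155.0, 9.0, 0.10, 0.015, "carbohydrate"),
        BandSpec("po2_sym", 1080.0, 12.0, 0.30, 0.000, "phosphate"),
        BandSpec("rna_ribose", 991.0, 6.0, 0.12, -0.040, "nucleic"),
    ]


def _band_sum(nu: np.ndarray, bands, div: float, class_mult) -> np.ndarray:
    out = np.zeros_like(nu)
    for b in bands:
        amp = b.amplitude(div) * class_mult.get(b.band_class, 1.0)
        if amp < 0:
            raise ValueError(f"negative amplitude for band {b.name} at DIV {div}")
        out += amp * np.exp(-((nu - b.center) ** 2) / (2.0 * b.width**2))
    return out


def _lognormal_unit_mean(rng: np.random.Generator, sigma: float, size=None):
    """Lognormal draw with mean exactly 1 (sigma is the log-scale SD)."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def corrupt_spectrum(spec: Spectrum, magnitude: float, rng: np.random.Generator) -> Spectrum:
    """Apply a gross acquisition artifact: offset + tilt + gain + fringes.

    The sinusoidal fringe component (interference-fringe-like ripple of the
    stated magnitude across the whole grid) is what survives rubber-band
    baseline correction and area normalization in every analysis region and
    makes the spectrum stand out in PCA score/residual space.
    """
    nu = spec.wavenumbers
    x = (nu - nu.mean()) / ((nu.max() - nu.min()) / 2.0)
    offset = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
    tilt = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
    gain = 1.0 + rng.uniform(0.2, 0.5)
    freq = rng.uniform(4.0, 8.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    fringe = rng.uniform(0.8, 1.2) * np.sin(np.pi * freq * x + phase)
    a = gain * spec.absorbance + magnitude * (offset + tilt * x + fringe)
    return spec.copy_with(absorbance=a, injected_outlier=True)


def simulate_dataset(cfg: SynthConfig) -> list[Spectrum]:
    """Simulate the full replicate structure; deterministic given ``cfg.seed``.

    Returns ``len(div_levels) * n_bio * n_tech`` spectra, ordered by
    (DIV, biological replicate, technical replicate).
    """
    rng = np.random.default_rng(cfg.seed)
    nu = cfg.wavenumbers()
    x = (nu - nu.mean()) / ((nu.max() - nu.min()) / 2.0)  # in [-1, 1]
    classes = sorted({b.band_class for b in cfg.bands})

    # biological replicate effect: one multiplier per (band class, bio rep),
    # shared by all technical replicates of that biological sample
    bio_mult = {
        (div, bio): {
            c: _lognormal_unit_mean(rng, cfg.bio_sd) for c in classes
        }
        for div in cfg.div_levels
        for bio in range(1, cfg.n_bio + 1)
    }

    outlier_mag = max(10.0 * cfg.baseline_scale, 0.2)
    spectra: list[Spectrum] = []
    for div in cfg.div_levels:
        for bio in range(1, cfg.n_bio + 1):
            clean = _band_sum(nu, cfg.bands, float(div), bio_mult[(div, bio)])
            for tech in range(1, cfg.n_tech + 1):
                coefs = rng.normal(0.0, cfg.baseline_scale, size=cfg.baseline_order + 1)
                baseline = np.polynomial.polynomial.polyval(x, coefs)
                gain = _lognormal_unit_mean(rng, cfg.mult_noise_sd)
                noise = rng.normal(0.0, cfg.noise_sd, size=nu.shape) if cfg.noise_sd else 0.0
                a = gain * clean + baseline + noise
                spec = Spectrum(
                    nu.copy(),
                    a,
                    {
                        "sample_id": f"DIV{div:02d}_B{bio}_T{tech}",
                        "div": int(div),
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "injected_outlier": False,
                    },
                )
                if cfg.outlier_fraction and rng.random() < cfg.outlier_fraction:
                    spec = corrupt_spectrum(spec, outlier_mag, rng)
                spectra.append(spec)
    return spectra


def spectra_to_matrix(spectra: list[Spectrum]) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack spectra sharing one grid into (wavenumbers, n x p matrix, metadata)."""
    if not spectra:
        raise ValueError("no spectra")
    nu = spectra[0].wavenumbers
    for s in spectra[1:]:
        if len(s) != len(nu) or not np.array_equal(s.wavenumbers, nu):
            raise ValueError("spectra have inconsistent wavenumber grids")
    X = np.vstack([s.absorbance for s in spectra])
    meta = pd.DataFrame([s.meta for s in spectra])
    return nu, X, meta


_META_COLS = ["sample_id", "div", "bio_rep", "tech_rep", "injected_outlier"]


def write_dataset(spectra: list[Spectrum], path) -> None:
    """Write a wide spectrum table + metadata table under directory ``path``.

    ``spectra.csv``: first column ``wavenumber``, one column per sample_id.
    ``metadata.csv``: one row per sample_id.  Values keep full precision so
    a read round-trips to >= 12 significant digits.
    """
    from pathlib import Path

    path = Path(path)
    nu, X, meta = spectra_to_matrix(spectra)
    ids = [s.meta["sample_id"] for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids")
    path.mkdir(parents=True, exist_ok=True)
    wide = pd.DataFrame(X.T, columns=ids)
    wide.insert(0, "wavenumber", nu)
    wide.to_csv(path / "spectra.csv", index=False, float_format="%.17g")
    cols = [c for c in _META_COLS if c in meta.columns]
    meta[cols].to_csv(path / "metadata.csv", index=False)


def read_dataset(path) -> list[Spectrum]:
    """Read a dataset written by :func:`write_dataset`.

    Ascending wavenumber tables are accepted and reordered to the descending
    convention with values permuted consistently.
    """
    from pathlib import Path

    path = Path(path)
    with open(path / "spectra.csv") as fh:
        header = fh.readline().rstrip("\n").split(",")
    ids = header[1:]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids in spectrum table")
    wide = pd.read_csv(path / "spectra.csv")
    meta = pd.read_csv(path / "metadata.csv")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in metadata table")
    missing = set(ids) - set(meta["sample_id"])
    if missing:
        raise ValueError(f"metadata rows missing for samples: {sorted(missing)}")

    nu = wide["wavenumber"].to_numpy(dtype=float)
    order = np.arange(len(nu))
    if len(nu) > 1 and nu[1] > nu[0]:  # ascending on disk -> flip
        order = order[::-1]
        nu = nu[order]
    meta_by_id = meta.set_index("sample_id")
    spectra = []
    for sid in ids:
        row = meta_by_id.loc[sid]
        m = {"sample_id": sid}
        for c in _META_COLS[1:]:
            if c in meta_by_id.columns:
                v = row[c]
                m[c] = bool(v) if c == "injected_outlier" else int(v)
        spectra.append(Spectrum(nu.copy(), wide[sid].to_numpy(dtype=float)[order], m))
    return spectra
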