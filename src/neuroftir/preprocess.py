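"""Spectral pre-processing: region extraction, baseline correction,
area normalization, Savitzky-Golay second derivative.

Processing is always per analysis region (lipid CH stretch 3050-2800,
protein carbonyl/amide 1800-1500, fingerprint 1500-900 cm^-1), in the order
baseline correction -> area normalization -> (optional) second derivative.
The derivative keeps the raw sign convention: absorption bands appear as
negative-going minima in d2A/dnu2.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal import savgol_filter

from .synth import Spectrum

__all__ = [
    "Region",
    "PreprocessParams",
    "extract_region",
    "baseline_correct",
    "area_normalize",
    "second_derivative",
    "preprocess_pipeline",
]


class Region(Enum):
    """Closed wavenumber intervals of the three analysis regions (cm^-1)."""

    LIPID = (3050.0, 2800.0)
    PROTEIN = (1800.0, 1500.0)
    FINGERPRINT = (1500.0, 900.0)

    @property
    def high(self) -> float:
        return self.value[0]

    @property
    def low(self) -> float:
        return self.value[1]


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable pre-processing settings.

    ``sg_points_per_side=3`` gives the conventional 7-point quadratic
    Savitzky-Golay second-derivative filter ("three smoothing points" in the
    per-side convention of common chemometrics software).
    """

    baseline_method: str = "rubber_band"  # or "polynomial"
    baseline_order: int = 2
    sg_points_per_side: int = 3
    sg_polyorder: int = 2
    normalization: str = "area"  # or "none"

    def __post_init__(self) -> None:
        if self.baseline_method not in ("rubber_band", "polynomial"):
            raise ValueError(f"unknown baseline method {self.baseline_method!r}")
        if self.normalization not in ("area", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.sg_points_per_side < 1 or self.sg_polyorder < 2:
            raise ValueError("sg_points_per_side >= 1 and sg_polyorder >= 2 required")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("SG window must exceed the polynomial order")

    @property
    def sg_window(self) -> int:
        return 2 * self.sg_points_per_side + 1


def extract_region(spectrum: Spectrum, region: Region) -> Spectrum:
    """Return the points inside the closed region interval, order preserved."""
    nu = spectrum.wavenumbers
    span_hi, span_lo = nu.max(), nu.min()
    if region.high > span_hi or region.low < span_lo:
        raise ValueError(
            f"region {region.name} [{region.low}, {region.high}] outside grid span "
            f"[{span_lo}, {span_hi}]"
        )
    mask = (nu >= region.low) & (nu <= region.high)
    if not mask.any():
        raise ValueError(f"no grid points inside region {region.name}")
    return spectrum.copy_with(
        wavenumbers=nu[mask], absorbance=spectrum.absorbance[mask], region=region.name
    )


def _lower_hull_baseline(nu_asc: np.ndarray, a_asc: np.ndarray) -> np.ndarray:
    """Lower convex hull of (nu, A), evaluated along the grid (rubber band)."""
    hull: list[int] = []
    for i in range(len(nu_asc)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # keep turn strictly convex-down: pop i2 if it lies on/above chord i1-i
            cross = (nu_asc[i2] - nu_asc[i1]) * (a_asc[i] - a_asc[i1]) - (
                a_asc[i2] - a_asc[i1]
            ) * (nu_asc[i] - nu_asc[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(nu_asc, nu_asc[hull], a_asc[hull])


def baseline_correct(spectrum: Spectrum, params: PreprocessParams = PreprocessParams()) -> Spectrum:
    """Subtract the rubber-band (lower convex hull) or least-squares polynomial baseline."""
    a = spectrum.absorbance
    nu = spectrum.wavenumbers
    if len(a) < 4:
        raise ValueError("baseline correction needs at least 4 points")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite absorbance")
    if params.baseline_method == "rubber_band":
        asc = np.argsort(nu)
        base = np.empty_like(a)
        base[asc] = _lower_hull_baseline(nu[asc], a[asc])
    else:
        coefs = np.polynomial.polynomial.polyfit(nu, a, params.baseline_order)
        base = np.polynomial.polynomial.polyval(nu, coefs)
    return spectrum.copy_with(absorbance=a - base, baseline=params.baseline_method)


def area_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale so the trapezoidal integral of |A| over the region equals 1.

    Using |A| keeps the operation well-defined for derivative-shaped inputs.
    """
    nu = spectrum.wavenumbers
    area = abs(np.trapezoid(np.abs(spectrum.absorbance), nu))
    if area < 1e-12:
        raise ValueError("spectral area below 1e-12; cannot area-normalize")
    return spectrum.copy_with(absorbance=spectrum.absorbance / area, normalized=True)


def second_derivative(
    spectrum: Spectrum, params: PreprocessParams = PreprocessParams()
) -> Spectrum:
    """Savitzky-Golay second derivative d2A/dnu2, in A.U./cm^-2.

    The filter is scaled by the actual grid step; edge points come from
    one-sided polynomial fits (``mode='interp'``).
    """
    n = len(spectrum)
    if params.sg_window > n:
        raise ValueError(f"SG window {params.sg_window} longer than region ({n} points)")
    step = abs(float(np.diff(spectrum.wavenumbers).mean()))
    d2 = savgol_filter(
        spectrum.absorbance,
        window_length=params.sg_window,
        polyorder=params.sg_polyorder,
        deriv=2,
        delta=step,
        mode="interp",
    )
    return spectrum.copy_with(absorbance=d2, derivative=2)


def preprocess_pipeline(
    spectra: list[Spectrum],
    region: Region,
    params: PreprocessParams = PreprocessParams(),
    derivative: bool = False,
) -> list[Spectrum]:
    """extract_region -> baseline_correct -> area_normalize -> [second_derivative].

    Applied per spectrum; applied steps are recorded in ``meta['steps']``.
    """
    out = []
    for s in spectra:
        steps = ["extract_region", f"baseline:{params.baseline_method}"]
        r = baseline_correct(extract_region(s, region), params)
        if params.normalization == "area":
            r = area_normalize(r)
            steps.append("area_normalize")
        if derivative:
            r = second_derivative(r, params)
            steps.append(f"sg_second_derivative(w={params.sg_window},o={params.sg_polyorder})")
        r.meta["steps"] = steps
        out.append(r)
    return out
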