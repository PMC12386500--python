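"""Band intensity extraction and the metabolomic band-ratio metrics.

Each metric is a named ratio (or plain intensity) of band intensities read
from preprocessed spectra.  Secondary-structure and small-band intensities
come from second-derivative spectra, where an absorption band is a
negative-going minimum whose magnitude is reported as a positive intensity.
The amide I and amide II intensities used by the protein-level metrics are
window maxima of the non-derivative (baseline-corrected, area-normalized)
spectra, robust to the few-cm^-1 peak shifts typical of these envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .preprocess import Region
from .synth import Spectrum

__all__ = [
    "BandAssignment",
    "MetricDefinition",
    "BandIntensity",
    "band_intensity",
    "default_band_assignments",
    "default_metrics",
    "compute_metric_table",
]

MODE_RAW = "raw"
MODE_DERIV = "second_derivative"


@dataclass(frozen=True)
class BandAssignment:
    """Where and how to read one band intensity.

    ``polarity`` defaults to the only sensible choice for the mode: maxima
    on raw spectra, minima on second-derivative spectra.
    """

    name: str
    center: float
    half_window: float = 8.0
    mode: str = MODE_DERIV
    polarity: str = ""

    def __post_init__(self) -> None:
        if self.half_window <= 0:
            raise ValueError(f"{self.name}: half_window must be > 0")
        if self.mode not in (MODE_RAW, MODE_DERIV):
            raise ValueError(f"{self.name}: unknown mode {self.mode!r}")
        if not self.polarity:
            object.__setattr__(
                self, "polarity", "minimum" if self.mode == MODE_DERIV else "maximum"
            )
        if self.mode == MODE_DERIV and self.polarity != "minimum":
            raise ValueError(
                f"{self.name}: second-derivative bands are minima; polarity must be 'minimum'"
            )

    @property
    def region(self) -> Region:
        for r in Region:
            if r.low <= self.center <= r.high:
                return r
        raise ValueError(f"{self.name}: center {self.center} outside all analysis regions")


class BandIntensity(NamedTuple):
    value: float
    wavenumber: float


def band_intensity(spectrum: Spectrum, assignment: BandAssignment) -> BandIntensity:
    """Extremum intensity within ``center +- half_window``.

    Raw mode returns the value of the maximum; second-derivative mode the
    magnitude of the minimum (reported positive).  The wavenumber where the
    extremum was found is returned alongside.
    """
    nu = spectrum.wavenumbers
    mask = np.abs(nu - assignment.center) <= assignment.half_window
    if not mask.any():
        raise ValueError(
            f"band {assignment.name}: window {assignment.center}+-{assignment.half_window} "
            "outside spectrum grid"
        )
    a = spectrum.absorbance[mask]
    if not np.all(np.isfinite(a)):
        raise ValueError(f"band {assignment.name}: non-finite values in window")
    if assignment.polarity == "maximum":
        i = int(np.argmax(a))
        value = float(a[i])
    else:
        i = int(np.argmin(a))
        value = float(a[i])
        if assignment.mode == MODE_DERIV:
            value = abs(value)
    return BandIntensity(value, float(nu[mask][i]))


@dataclass(frozen=True)
class MetricDefinition:
    """numerator-sum / denominator-sum of named band intensities.

    An empty denominator means a plain intensity.  The mode of each band is
    carried by its :class:`BandAssignment`, so mixed metrics (raw amide
    intensities over derivative PO2- intensities) need no special casing.
    """

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...] = ()


def default_band_assignments() -> dict[str, BandAssignment]:
    """Assignments backing the default metrics.

    Canonical centers 1740 (esters), 3013 (=CH), 1651 (alpha-helix) with
    +-8 cm^-1 windows wide enough to cover the alternate printed positions
    (1733, 3010, 1648).  Amide I/II raw intensities are window maxima over
    1700-1600 and 1580-1500 cm^-1.
    """
    d = [
        BandAssignment("I3013", 3013.0),
        BandAssignment("I2959", 2959.0),
        BandAssignment("I2922", 2922.0),
        BandAssignment("I2871", 2871.0),
        BandAssignment("I2851", 2851.0),
        BandAssignment("I1740", 1740.0),
        BandAssignment("I1693", 1693.0),
        BandAssignment("I1682", 1682.0),
        BandAssignment("I1651", 1651.0),
        BandAssignment("I1628", 1628.0),
        BandAssignment("I1240", 1240.0),
        BandAssignment("I1080", 1080.0),
        BandAssignment("I991", 991.0),
        BandAssignment("IAmideI", 1650.0, half_window=50.0, mode=MODE_RAW),
        BandAssignment("IAmideII", 1540.0, half_window=40.0, mode=MODE_RAW),
    ]
    return {a.name: a for a in d}


def default_metrics() -> list[MetricDefinition]:
    """The eleven metabolomic metrics of the study's figure panels."""
    return [
        MetricDefinition("total_protein", ("IAmideI", "IAmideII")),
        MetricDefinition("filamentous", ("IAmideII",), ("IAmideI",)),
        MetricDefinition("intermolecular_beta", ("I1628",), ("I1693", "I1682", "I1628")),
        MetricDefinition("antiparallel_beta", ("I1693",), ("I1693", "I1682", "I1628")),
        MetricDefinition("alpha_helix", ("I1651",)),
        MetricDefinition("phosphorylation", ("IAmideI", "IAmideII"), ("I1240", "I1080")),
        MetricDefinition("total_lipids", ("I2851", "I2922")),
        MetricDefinition("acyl_chain", ("I2851", "I2922"), ("I2959", "I2871")),
        MetricDefinition("lipid_esters", ("I1740",)),
        MetricDefinition("unsaturation", ("I3013",), ("I2851", "I2922")),
        MetricDefinition("rna", ("I991",)),
    ]


def compute_metric_table(
    raw_by_region: dict[Region, list[Spectrum]],
    deriv_by_region: dict[Region, list[Spectrum]],
    metrics: list[MetricDefinition] | None = None,
    assignments: dict[str, BandAssignment] | None = None,
) -> pd.DataFrame:
    """One row per analysis unit, one column per metric (plus metadata).

    ``raw_by_region`` / ``deriv_by_region`` map each analysis region to its
    preprocessed spectra, sample-aligned across regions.  Denominators below
    1e-12 flag the cell invalid (NaN), never a silent zero.
    """
    metrics = default_metrics() if metrics is None else metrics
    assignments = default_band_assignments() if assignments is None else assignments
    for m in metrics:
        for n in m.numerator + m.denominator:
            if n not in assignments:
                raise KeyError(f"metric {m.name}: band {n!r} not in assignments")

    regions = list(raw_by_region) or list(deriv_by_region)
    n_samples = len(next(iter(raw_by_region.values()))) if raw_by_region else len(
        next(iter(deriv_by_region.values()))
    )
    for store in (raw_by_region, deriv_by_region):
        for r, lst in store.items():
            if len(lst) != n_samples:
                raise ValueError(f"region {r} has {len(lst)} spectra, expected {n_samples}")

    def lookup(sample_idx: int, band_name: str) -> float:
        a = assignments[band_name]
        store = raw_by_region if a.mode == MODE_RAW else deriv_by_region
        if a.region not in store:
            raise ValueError(f"band {band_name}: region {a.region.name} not provided")
        return band_intensity(store[a.region][sample_idx], a).value

    meta_src = next(iter(raw_by_region.values() if raw_by_region else deriv_by_region.values()))
    rows = []
    for i in range(n_samples):
        row = {
            k: meta_src[i].meta[k]
            for k in ("sample_id", "div", "bio_rep")
            if k in meta_src[i].meta
        }
        for m in metrics:
            num = sum(lookup(i, b) for b in m.numerator)
            if m.denominator:
                den = sum(lookup(i, b) for b in m.denominator)
                row[m.name] = num / den if abs(den) >= 1e-12 else np.nan
            else:
                row[m.name] = num
        rows.append(row)
    return pd.DataFrame(rows)
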