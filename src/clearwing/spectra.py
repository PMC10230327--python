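"""Spectrum container, CSV I/O and spectral analytics.

The :class:`Spectrum` is the currency passed between every stage of the
package: transfer-matrix and FDTD solvers emit reflectance/transmittance
spectra, the synthetic generators emulate measured ones, and the extremum
analytics below implement the single canonical definition of "peak" and
"dip" used throughout (scanned with a light moving-average smoothing that is
applied for detection only, never to stored data).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ValidationError

SpectrumKind = Literal[
    "reflectance", "transmittance", "absorbance", "field-magnitude", "extinction"
]

#: Conventional visible band (nm) used for all "visible regime" statistics.
VISIBLE_BAND = (400.0, 700.0)

#: Default centered moving-average window (points) for extremum detection.
DEFAULT_SMOOTHING_WINDOW = 5

#: Default absolute prominence threshold suppressing numerical ripple.
DEFAULT_PROMINENCE = 0.005

_BOUNDED_KINDS = ("reflectance", "transmittance")


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed optical quantity.

    Parameters
    ----------
    wavelength_nm:
        Strictly increasing wavelength grid, >= 2 points.
    value:
        Quantity per wavelength. Reflectance/transmittance must lie in
        [0, 1] (within ``tol``); absorbance and field magnitudes must be
        non-negative.
    kind:
        One of ``reflectance | transmittance | absorbance | field-magnitude
        | extinction``.
    meta:
        Free-form provenance (model name, replicate count, method, ...).
    tol:
        Upper-bound slack for bounded kinds. The default 1e-9 is the
        analytic-solver contract; FDTD results carry their accuracy floor.
    """

    wavelength_nm: np.ndarray
    value: np.ndarray
    kind: str = "reflectance"
    meta: dict = field(default_factory=dict)
    tol: float = 1e-9

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        val = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "value", val)
        if wl.ndim != 1 or wl.size < 2:
            raise ValidationError("wavelength grid needs >= 2 points")
        if val.shape != wl.shape:
            raise ValidationError("value and wavelength shapes differ")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(val)):
            raise ValidationError("non-finite spectrum values")
        if self.kind in _BOUNDED_KINDS:
            if val.min() < -self.tol or val.max() > 1.0 + self.tol:
                raise ValidationError(
                    f"{self.kind} outside [0, 1] by more than tol={self.tol:g}"
                )
        elif self.kind in ("absorbance", "field-magnitude", "extinction"):
            if val.min() < -1e-12:
                raise ValidationError(f"{self.kind} must be non-negative")

    # -- basic manipulation -------------------------------------------------

    def slice_band(self, band: tuple[float, float]) -> "Spectrum":
        lo, hi = band
        if lo < self.wavelength_nm[0] - 1e-9 or hi > self.wavelength_nm[-1] + 1e-9:
            raise ValidationError(
                f"band {band} outside spectrum grid "
                f"[{self.wavelength_nm[0]}, {self.wavelength_nm[-1]}]"
            )
        m = (self.wavelength_nm >= lo - 1e-9) & (self.wavelength_nm <= hi + 1e-9)
        if m.sum() < 2:
            raise ValidationError("band contains fewer than 2 grid points")
        return replace(self, wavelength_nm=self.wavelength_nm[m], value=self.value[m])

    def interp(self, wavelength_nm: np.ndarray) -> "Spectrum":
        wl = np.asarray(wavelength_nm, dtype=float)
        val = np.interp(wl, self.wavelength_nm, self.value)
        return replace(self, wavelength_nm=wl, value=val)

    def at(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at a single wavelength."""
        return float(np.interp(wavelength_nm, self.wavelength_nm, self.value))


# -- CSV dialect -------------------------------------------------------------


def write_spectrum_csv(spec: Spectrum, path) -> None:
    """Two-column CSV ``wavelength_nm,value`` with the kind in a header comment."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# kind: {spec.kind}\n")
        for key, v in sorted(spec.meta.items()):
            fh.write(f"# {key}: {v}\n")
        pd.DataFrame(
            {"wavelength_nm": spec.wavelength_nm, "value": spec.value}
        ).to_csv(fh, index=False)


def read_spectrum_csv(path, kind: str | None = None) -> Spectrum:
    meta = {}
    header_kind = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line[1:].strip()
            if ":" in stripped:
                key, _, v = stripped.partition(":")
                key, v = key.strip(), v.strip()
                if key == "kind":
                    header_kind = v
                else:
                    meta[key] = v
        else:
            body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)))
    if "wavelength_nm" not in df.columns or "value" not in df.columns:
        raise ValidationError(f"{path}: expected columns wavelength_nm,value")
    return Spectrum(
        df["wavelength_nm"].to_numpy(),
        df["value"].to_numpy(),
        kind=kind or header_kind or "reflectance",
        meta=meta,
        tol=1e-6,
    )


# -- extremum analytics -------------------------------------------------------


@dataclass(frozen=True)
class Extremum:
    wavelength_nm: float
    value: float
    type: Literal["max", "min"]
    prominence: float


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    pad = window // 2
    padded = np.pad(values, pad, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def find_extrema(
    spec: Spectrum,
    band: tuple[float, float] | None = None,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    prominence: float = DEFAULT_PROMINENCE,
) -> list[Extremum]:
    """Local maxima and minima of a spectrum, sorted by wavelength.

    Detection runs on a lightly smoothed copy (centered moving average,
    ``smoothing_window`` points); reported values are taken from the raw
    spectrum at the detected wavelength. Plateaus report their midpoint.
    Band endpoints are never reported as extrema.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValidationError("smoothing_window must be an odd count >= 1")
    s = spec.slice_band(band) if band is not None else spec
    y = _smooth(s.value, smoothing_window)
    out: list[Extremum] = []
    for sign, label in ((1.0, "max"), (-1.0, "min")):
        idx, props = find_peaks(sign * y, prominence=prominence, plateau_size=1)
        for j, i in enumerate(idx):
            left, right = props["left_edges"][j], props["right_edges"][j]
            mid = (left + right) // 2  # plateau midpoint
            out.append(
                Extremum(
                    wavelength_nm=float(s.wavelength_nm[mid]),
                    value=float(s.value[mid]),
                    type=label,
                    prominence=float(props["prominences"][j]),
                )
            )
    out.sort(key=lambda e: e.wavelength_nm)
    return out


@dataclass(frozen=True)
class BimodalExtrema:
    """The two most prominent maxima of a band and the dip between them."""

    short_peak: Extremum
    dip: Extremum
    long_peak: Extremum


def bimodal_extrema(
    spec: Spectrum,
    band: tuple[float, float] | None = None,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    prominence: float = DEFAULT_PROMINENCE,
) -> BimodalExtrema:
    """Characterize a bimodal spectrum: two dominant peaks and their dip.

    The two maxima with the largest prominences are selected; the dip is the
    most prominent local minimum between them (ties broken toward the deeper
    minimum). Secondary fringes between the dominant peaks are thereby
    ignored without any extra smoothing.
    """
    ext = find_extrema(spec, band, smoothing_window, prominence)
    maxima = [e for e in ext if e.type == "max"]
    if len(maxima) < 2:
        raise ValidationError("spectrum does not have two prominent maxima")
    top2 = sorted(
        sorted(maxima, key=lambda e: e.prominence)[-2:],
        key=lambda e: e.wavelength_nm,
    )
    inner = [
        e
        for e in ext
        if e.type == "min"
        and top2[0].wavelength_nm < e.wavelength_nm < top2[1].wavelength_nm
    ]
    if not inner:
        raise ValidationError("no interior minimum between the two dominant maxima")
    dip = max(inner, key=lambda e: (e.prominence, -e.value))
    return BimodalExtrema(short_peak=top2[0], dip=dip, long_peak=top2[1])


def count_dominant_maxima(
    spec: Spectrum,
    band: tuple[float, float] | None = None,
    rel_threshold: float = 0.5,
    **extrema_kw,
) -> int:
    """Number of maxima whose prominence rivals the strongest one.

    A maximum counts as dominant when its prominence is at least
    ``rel_threshold`` times the largest prominence in the band. This is
    the modality statistic separating a multi-fringe spectrum (all fringes
    equally strong) from a bimodal one (interior fringes suppressed by an
    envelope).
    """
    maxima = [e for e in find_extrema(spec, band, **extrema_kw) if e.type == "max"]
    if not maxima:
        return 0
    top = max(e.prominence for e in maxima)
    return sum(1 for e in maxima if e.prominence >= rel_threshold * top)


def band_stat(
    spec: Spectrum,
    band: tuple[float, float],
    stat: Literal["mean", "min", "max"] = "mean",
) -> float:
    """Band statistic; the mean is trapezoid-weighted over the band."""
    s = spec.slice_band(band)
    if stat == "mean":
        return float(
            np.trapezoid(s.value, s.wavelength_nm)
            / (s.wavelength_nm[-1] - s.wavelength_nm[0])
        )
    if stat == "min":
        return float(s.value.min())
    if stat == "max":
        return float(s.value.max())
    raise ValidationError(f"unknown stat {stat!r}")


@dataclass(frozen=True)
class SpectrumComparison:
    max_abs_diff: float
    rms_diff: float
    extrema_offsets_nm: tuple[float, ...]


def compare_spectra(a: Spectrum, b: Spectrum, **extrema_kw) -> SpectrumComparison:
    """Difference metrics between two spectra on their common band.

    Both spectra are resampled to the coarser grid by linear interpolation.
    ``extrema_offsets_nm`` pairs each maximum of ``a`` with the nearest
    maximum of ``b`` (wavelength difference b - a); symmetric metrics first.
    """
    lo = max(a.wavelength_nm[0], b.wavelength_nm[0])
    hi = min(a.wavelength_nm[-1], b.wavelength_nm[-1])
    if hi <= lo:
        raise ValidationError("spectra have disjoint wavelength bands")
    ga = a.slice_band((lo, hi))
    gb = b.slice_band((lo, hi))
    grid = ga.wavelength_nm if ga.wavelength_nm.size <= gb.wavelength_nm.size else gb.wavelength_nm
    va = ga.interp(grid).value
    vb = gb.interp(grid).value
    diff = va - vb
    max_abs = float(np.abs(diff).max())
    rms = float(np.sqrt(np.mean(diff**2)))
    pa = [e for e in find_extrema(ga, **extrema_kw) if e.type == "max"]
    pb = [e for e in find_extrema(gb, **extrema_kw) if e.type == "max"]
    offsets = []
    for ea in pa:
        if pb:
            nearest = min(pb, key=lambda e: abs(e.wavelength_nm - ea.wavelength_nm))
            offsets.append(nearest.wavelength_nm - ea.wavelength_nm)
    return SpectrumComparison(max_abs, rms, tuple(offsets))


def wavelength_grid(
    start: float = VISIBLE_BAND[0], stop: float = VISIBLE_BAND[1], step: float = 1.0
) -> np.ndarray:
    """Inclusive wavelength grid in nm."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)
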