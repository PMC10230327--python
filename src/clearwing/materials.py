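"""Optical materials and pigment extinction from absorbance.

The wing cuticle is treated as lossless chitin (n = 1.56); the pigmented
mesocuticle carries melanin, described by a complex refractive index
n + i·k with real part 1.74 and a small extinction coefficient estimated
from decadic absorbance via the Beer-Lambert relation

    k(lambda) = ln(10) * A(lambda) * lambda / (4 * pi * d),

where d is the thickness the absorbance was measured through. In the
visible range k stays below 0.012 for this membrane, which is what makes
the wing transparent despite the pigment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .spectra import Spectrum

log = logging.getLogger(__name__)


def _as_table(x) -> tuple[np.ndarray, np.ndarray] | float:
    """Normalize a scalar or (wavelength, value) table input."""
    if np.isscalar(x):
        return float(x)
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("tabulated index must be an (N, 2) array of (nm, value)")
    wl, v = arr[:, 0], arr[:, 1]
    if not np.all(np.diff(wl) > 0):
        raise ValidationError("tabulated wavelengths must be strictly increasing")
    return wl, v


def _evaluate(table, wavelength_nm, name: str, what: str) -> np.ndarray:
    lam = np.asarray(wavelength_nm, dtype=float)
    if isinstance(table, float):
        return np.full(lam.shape, table)
    wl, v = table
    if lam.min() < wl[0] or lam.max() > wl[-1]:
        log.warning(
            "%s: %s evaluated outside tabulated range [%g, %g] nm; clamping",
            name, what, wl[0], wl[-1],
        )
    return np.interp(lam, wl, v)  # np.interp clamps to endpoints


@dataclass(frozen=True)
class OpticalMaterial:
    """A medium with (possibly wavelength-dependent) complex index n + i·k.

    ``n_real`` and ``k_imag`` are either scalars or (N, 2) tables of
    ``(wavelength_nm, value)``. Outside a tabulated range evaluation clamps
    to the nearest endpoint (logged), never extrapolates.
    """

    name: str
    n_real: object = 1.0
    k_imag: object = 0.0

    def __post_init__(self):
        n = _as_table(self.n_real)
        k = _as_table(self.k_imag)
        n_vals = np.atleast_1d(n if isinstance(n, float) else n[1])
        k_vals = np.atleast_1d(k if isinstance(k, float) else k[1])
        if n_vals.min() < 1.0:
            raise ValidationError(f"{self.name}: n_real must be >= 1 everywhere")
        if k_vals.min() < 0.0:
            raise ValidationError(f"{self.name}: k_imag must be >= 0 everywhere")
        object.__setattr__(self, "_n", n)
        object.__setattr__(self, "_k", k)

    def n(self, wavelength_nm) -> np.ndarray:
        return _evaluate(self._n, wavelength_nm, self.name, "n")

    def k(self, wavelength_nm) -> np.ndarray:
        return _evaluate(self._k, wavelength_nm, self.name, "k")

    def index(self, wavelength_nm) -> np.ndarray:
        """Complex refractive index n + i·k (absorption for k > 0)."""
        return self.n(wavelength_nm) + 1j * self.k(wavelength_nm)

    @property
    def is_lossless(self) -> bool:
        k = self._k
        return (k == 0.0) if isinstance(k, float) else bool(np.all(k[1] == 0.0))


def make_material(name: str, n_real, k_imag=0.0) -> OpticalMaterial:
    """Construct a material; constant inputs yield wavelength-independent media."""
    return OpticalMaterial(name=name, n_real=n_real, k_imag=k_imag)


#: Ambient air.
AIR = make_material("air", 1.0, 0.0)

#: Wing cuticle, modelled as lossless chitin.
CHITIN = make_material("chitin", 1.56, 0.0)

#: Default pigmented mesocuticle: real index 1.74 and a small constant
#: extinction k = 0.010, consistent with the measured visible-range bound
#: (< 0.012); a tabulated k can be supplied instead.
PIGMENT = make_material("pigment", 1.74, 0.010)


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Decadic absorbance A(lambda) measured through ``path_thickness_nm``."""

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    path_thickness_nm: float

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "absorbance", a)
        if wl.ndim != 1 or a.shape != wl.shape:
            raise ValidationError("absorbance and wavelength shapes differ")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if wl.min() < 200.0 or wl.max() > 1200.0:
            raise ValidationError("wavelengths must lie within [200, 1200] nm")
        if a.min() < 0.0:
            raise ValidationError("absorbance values must be >= 0")
        if not self.path_thickness_nm > 0:
            raise ValidationError("path_thickness_nm must be > 0")


def k_from_absorbance(spec: AbsorbanceSpectrum) -> Spectrum:
    """Extinction coefficient from decadic absorbance (Beer-Lambert).

    k(lambda) = ln(10) * A(lambda) * lambda / (4*pi*d); linear in A and
    inversely proportional to the path thickness d.
    """
    k = (
        np.log(10.0)
        * spec.absorbance
        * spec.wavelength_nm
        / (4.0 * np.pi * spec.path_thickness_nm)
    )
    return Spectrum(
        spec.wavelength_nm,
        k,
        kind="extinction",
        meta={"path_thickness_nm": spec.path_thickness_nm},
    )


def absorbance_from_k(k_spec: Spectrum, path_thickness_nm: float) -> AbsorbanceSpectrum:
    """Inverse of :func:`k_from_absorbance` (round-trip helper)."""
    if not path_thickness_nm > 0:
        raise ValidationError("path_thickness_nm must be > 0")
    a = 4.0 * np.pi * k_spec.value * path_thickness_nm / (
        np.log(10.0) * k_spec.wavelength_nm
    )
    return AbsorbanceSpectrum(k_spec.wavelength_nm, a, path_thickness_nm)


def pigment_from_absorbance(
    spec: AbsorbanceSpectrum, n_real: float = 1.74, name: str = "pigment"
) -> OpticalMaterial:
    """Pigment material with measured k(lambda) and the standard real part."""
    k = k_from_absorbance(spec)
    table = np.column_stack([k.wavelength_nm, k.value])
    return make_material(name, n_real, table)


def load_materials_yaml(path) -> dict[str, OpticalMaterial]:
    """Material definitions from YAML: {name: {n: ..., k: ...}}.

    ``n``/``k`` may be scalars or lists of [wavelength_nm, value] pairs.
    """
    raw = yaml.safe_load(Path(path).read_text())
    out = {}
    for name, entry in raw.items():
        n = entry.get("n", 1.0)
        k = entry.get("k", 0.0)
        out[name] = make_material(name, n, k)
    return out
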