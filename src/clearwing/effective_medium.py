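"""Effective-medium homogenization of subwavelength structures.

Two wing structures are far smaller than visible wavelengths and can be
replaced by homogenized layers for the transfer-matrix solver:

* the anti-reflective **nipple array** on the membrane surface — half
  ellipsoids (height 142 nm, diameter 135 nm, pitch 300 nm) sliced into a
  graded-index profile, and
* the **microribs** of the scale's interridge region — parallel chitin
  struts homogenized into a single layer with fill w / (w + gap).

Fill conventions. The nipple array is a two-dimensional lattice of
half-ellipsoids on the surface, so the physically appropriate fill at
height z is the *areal* fraction pi*r(z)^2 / p^2 (the default). A *line*
fill w(z)/p is also provided: it is the fill of the corrugated 2D
cross-section and is the consistent choice when comparing against the
package's own 2D FDTD rasters. Microribs are translation-invariant ridges,
for which the line fill is exact.

The mixing rule defaults to volume-weighted permittivity; Maxwell Garnett
is available. Full-wave FDTD remains the ground truth for the structured
layers — the EMT layers are the fast TMM-compatible surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ValidationError
from .materials import AIR, CHITIN, OpticalMaterial, make_material
from .multilayer import Layer

FillConvention = Literal["areal", "line"]
MixingRule = Literal["volume", "maxwell-garnett"]

DEFAULT_N_SLICES = 32


@dataclass(frozen=True)
class NippleArray:
    """Half-ellipsoid nipple array described by height, diameter and pitch."""

    height_nm: float = 142.0
    diameter_nm: float = 135.0
    pitch_nm: float = 300.0
    n_slices: int = DEFAULT_N_SLICES
    fill: FillConvention = "areal"
    rule: MixingRule = "volume"

    def __post_init__(self):
        if not 0 < self.diameter_nm <= self.pitch_nm:
            raise ValidationError("need 0 < diameter_nm <= pitch_nm")
        if not self.height_nm > 0:
            raise ValidationError("height_nm must be > 0")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        if self.fill not in ("areal", "line"):
            raise ValidationError(f"unknown fill convention {self.fill!r}")

    def width_at(self, z_nm) -> np.ndarray:
        """Half-ellipse width w(z) at height z above the base."""
        z = np.asarray(z_nm, dtype=float)
        frac = np.clip(1.0 - (z / self.height_nm) ** 2, 0.0, None)
        return self.diameter_nm * np.sqrt(frac)

    def fill_at(self, z_nm) -> np.ndarray:
        """Fill fraction at height z under the array's fill convention."""
        w = self.width_at(z_nm)
        if self.fill == "line":
            return w / self.pitch_nm
        return np.pi * (w / 2.0) ** 2 / self.pitch_nm**2


@dataclass(frozen=True)
class MicroribLayer:
    """Parallel microrib struts: thickness, width and gap, all in nm."""

    thickness_nm: float = 45.0
    width_nm: float = 62.0
    gap_nm: float = 58.0
    material: OpticalMaterial = CHITIN

    def __post_init__(self):
        for label, v in (
            ("thickness_nm", self.thickness_nm),
            ("width_nm", self.width_nm),
            ("gap_nm", self.gap_nm),
        ):
            if not v > 0:
                raise ValidationError(f"{label} must be > 0")

    @property
    def fill_fraction(self) -> float:
        return self.width_nm / (self.width_nm + self.gap_nm)


def fill_fraction_profile(nipples: NippleArray) -> list[tuple[float, float]]:
    """(sublayer thickness, fill fraction) from base to tip.

    Fill fractions are evaluated at slice centers; they decrease
    monotonically from base to tip and the thicknesses sum to the height.
    """
    dz = nipples.height_nm / nipples.n_slices
    centers = (np.arange(nipples.n_slices) + 0.5) * dz
    fills = nipples.fill_at(centers)
    return [(dz, float(f)) for f in fills]


def emt_mix(
    f: float,
    inclusion: OpticalMaterial,
    host: OpticalMaterial,
    wavelength_nm,
    rule: MixingRule = "volume",
) -> np.ndarray:
    """Effective complex index of an inclusion/host mixture at fill f.

    ``volume``: eps_eff = f*eps_inc + (1-f)*eps_host.
    ``maxwell-garnett``: dilute spherical inclusions in the host.
    The result lies between the constituent indices and is continuous in f.
    """
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"fill fraction must be in [0, 1], got {f}")
    eps_i = inclusion.index(wavelength_nm) ** 2
    eps_h = host.index(wavelength_nm) ** 2
    if rule == "volume":
        eps = f * eps_i + (1.0 - f) * eps_h
    elif rule == "maxwell-garnett":
        eps = eps_h * (
            eps_i + 2 * eps_h + 2 * f * (eps_i - eps_h)
        ) / (eps_i + 2 * eps_h - f * (eps_i - eps_h))
    else:
        raise ValidationError(f"unknown mixing rule {rule!r}")
    return np.sqrt(eps)


def graded_index_layers(
    nipples: NippleArray,
    inclusion: OpticalMaterial = CHITIN,
    host: OpticalMaterial = AIR,
    reference_wavelength_nm: float = 550.0,
) -> tuple[Layer, ...]:
    """Homogenized sublayers of the nipple array, ordered tip first.

    Each slice becomes a homogeneous layer at the effective index of its
    fill fraction. The tip-first order means the returned tuple can be
    prepended directly to a stack illuminated from the nipple side.
    Wavelength-independent constituents yield wavelength-independent
    slices, so a single reference wavelength suffices for the mixing.
    """
    slices = fill_fraction_profile(nipples)  # base -> tip
    layers = []
    for i, (dz, f) in enumerate(reversed(slices)):  # tip -> base
        n_eff = complex(
            np.atleast_1d(
                emt_mix(f, inclusion, host, reference_wavelength_nm, nipples.rule)
            )[0]
        )
        mat = make_material(
            f"{inclusion.name}_nipple_slice_{i}",
            max(n_eff.real, 1.0),
            max(n_eff.imag, 0.0),
        )
        layers.append(Layer(mat, dz))
    return tuple(layers)


def microrib_effective_layer(
    mr: MicroribLayer,
    host: OpticalMaterial = AIR,
    reference_wavelength_nm: float = 550.0,
    rule: MixingRule = "volume",
) -> Layer:
    """Single homogenized layer replacing the microrib grating.

    Line fill f = w / (w + gap) — exact for translation-invariant ridges.
    """
    f = mr.fill_fraction
    n_eff = complex(
        np.atleast_1d(emt_mix(f, mr.material, host, reference_wavelength_nm, rule))[0]
    )
    mat = make_material("microrib_effective", max(n_eff.real, 1.0), max(n_eff.imag, 0.0))
    return Layer(mat, mr.thickness_nm)
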