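"""Transfer-matrix optics for planar multilayers at normal incidence.

The characteristic-matrix (Abelès) formalism gives the exact reflectance
and transmittance of an ordered stack of homogeneous layers between two
semi-infinite lossless media. The sign convention is n + i·k with a
time dependence such that k > 0 means absorption. Normal incidence only:
the measurements and simulations this package mirrors all use a normally
incident plane wave.

:func:`airy_slab_oracle` computes single-slab reflectance by summing the
Airy multiple-reflection series directly; it shares no code with the matrix
path and serves as an independent cross-check in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .materials import AIR, OpticalMaterial, make_material
from .spectra import Spectrum


@dataclass(frozen=True)
class Layer:
    """A homogeneous planar layer of finite physical thickness (nm)."""

    material: OpticalMaterial
    thickness_nm: float

    def __post_init__(self):
        if not (np.isfinite(self.thickness_nm) and self.thickness_nm > 0):
            raise ValidationError(
                f"layer thickness must be finite and > 0, got {self.thickness_nm}"
            )


@dataclass(frozen=True)
class Stack:
    """Ordered planar multilayer between two semi-infinite lossless media.

    The first layer is struck first by light coming from the ambient side.
    """

    ambient: OpticalMaterial = AIR
    layers: tuple[Layer, ...] = ()
    substrate: OpticalMaterial = AIR
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))

    def reversed(self) -> "Stack":
        """Illumination from the substrate side."""
        return Stack(
            ambient=self.substrate,
            layers=self.layers[::-1],
            substrate=self.ambient,
            name=self.name + "_reversed",
        )

    def total_thickness_nm(self) -> float:
        return float(sum(l.thickness_nm for l in self.layers))


def _check_semi_infinite(mat: OpticalMaterial, wavelengths: np.ndarray, side: str):
    if np.any(mat.k(wavelengths) != 0.0):
        raise ValidationError(
            f"{side} medium {mat.name!r} is absorbing; R and T are only "
            "well defined for lossless semi-infinite media"
        )


def tmm_amplitudes(stack: Stack, wavelengths) -> tuple[np.ndarray, np.ndarray]:
    """Complex reflection and transmission amplitude coefficients (r, t)."""
    lam = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    if lam.size == 0:
        raise ValidationError("empty wavelength grid")
    _check_semi_infinite(stack.ambient, lam, "ambient")
    _check_semi_infinite(stack.substrate, lam, "substrate")
    n_a = stack.ambient.n(lam).astype(complex)
    n_s = stack.substrate.n(lam).astype(complex)
    # characteristic matrix product, broadcast over wavelength
    m11 = np.ones_like(lam, dtype=complex)
    m12 = np.zeros_like(m11)
    m21 = np.zeros_like(m11)
    m22 = np.ones_like(m11)
    k0 = 2.0 * np.pi / lam
    for layer in stack.layers:
        # public convention is n + i*k absorbing; the matrix orientation
        # below corresponds to the e^{+i w t} time dependence, so conjugate
        n = np.conj(layer.material.index(lam))
        delta = k0 * n * layer.thickness_nm
        c, s = np.cos(delta), np.sin(delta)
        a11, a12 = c, 1j * s / n
        a21, a22 = 1j * n * s, c
        m11, m12, m21, m22 = (
            m11 * a11 + m12 * a21,
            m11 * a12 + m12 * a22,
            m21 * a11 + m22 * a21,
            m21 * a12 + m22 * a22,
        )
    den = n_a * m11 + n_a * n_s * m12 + m21 + n_s * m22
    r = (n_a * m11 + n_a * n_s * m12 - m21 - n_s * m22) / den
    t = 2.0 * n_a / den
    return r, t


def tmm_spectrum(stack: Stack, wavelengths) -> tuple[Spectrum, Spectrum, Spectrum]:
    """Normal-incidence (R, T, A) of a stack over a wavelength grid (nm).

    Energy conservation R + T + A = 1 holds to machine precision; A = 0 for
    lossless stacks.
    """
    lam = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    r, t = tmm_amplitudes(stack, lam)
    n_a = stack.ambient.n(lam)
    n_s = stack.substrate.n(lam)
    R = np.abs(r) ** 2
    T = (n_s / n_a) * np.abs(t) ** 2
    A = 1.0 - R - T
    meta = {"model": stack.name, "method": "tmm"} if stack.name else {"method": "tmm"}
    return (
        Spectrum(lam, R, kind="reflectance", meta=meta),
        Spectrum(lam, T, kind="transmittance", meta=meta),
        Spectrum(lam, np.clip(A, 0.0, None), kind="absorbance", meta=meta),
    )


def airy_slab_oracle(n: float, d_nm: float, wavelength_nm: float, n_ambient: float = 1.0) -> float:
    """Single-slab reflectance by explicit Airy multiple-reflection summation.

    The geometric series of internal bounces is summed term by term until
    convergence — a route independent of the matrix formalism.
    """
    if n < 1.0:
        raise ValidationError("slab index must be >= 1")
    if d_nm <= 0:
        raise ValidationError("slab thickness must be > 0")
    r12 = (n_ambient - n) / (n_ambient + n)
    t12 = 2.0 * n_ambient / (n_ambient + n)
    t21 = 2.0 * n / (n_ambient + n)
    r21 = -r12
    r23 = (n - n_ambient) / (n + n_ambient)
    phase = np.exp(2j * np.pi * n * d_nm / wavelength_nm * 2.0)  # round trip
    total = complex(r12)
    bounce = t12 * r23 * phase * t21
    ratio = r21 * r23 * phase
    term = bounce
    for _ in range(10_000):
        total += term
        term = term * ratio
        if abs(term) < 1e-16:
            break
    return float(abs(total) ** 2)


# -- stack I/O ----------------------------------------------------------------


def load_stack_yaml(path, materials: dict[str, OpticalMaterial] | None = None) -> Stack:
    """Stack definition from YAML.

    Schema::

        name: ...
        ambient: air            # material name
        substrate: air
        materials:              # optional inline material definitions
          chitin: {n: 1.56, k: 0.0}
        layers:
          - {material: chitin, thickness_nm: 436}
    """
    raw = yaml.safe_load(Path(path).read_text())
    mats = dict(materials or {})
    for name, entry in (raw.get("materials") or {}).items():
        mats[name] = make_material(name, entry.get("n", 1.0), entry.get("k", 0.0))
    mats.setdefault("air", AIR)

    def resolve(name: str) -> OpticalMaterial:
        if name not in mats:
            raise ValidationError(f"unknown material {name!r} in {path}")
        return mats[name]

    layers = tuple(
        Layer(resolve(entry["material"]), float(entry["thickness_nm"]))
        for entry in raw.get("layers", [])
    )
    return Stack(
        ambient=resolve(raw.get("ambient", "air")),
        layers=layers,
        substrate=resolve(raw.get("substrate", "air")),
        name=raw.get("name", Path(path).stem),
    )
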