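"""Builders for the wing-membrane and scale optical models.

All geometry comes from the electron-microscopy measurements collected in
:data:`DEFAULT_REGISTRY`: a three-layer membrane (dorsal exocuticle 436 nm /
pigmented mesocuticle 194 nm / ventral exocuticle 412 nm) whose exocuticle
faces carry a half-ellipsoid nipple array (height 142 nm, diameter 135 nm,
pitch 300 nm), and two scale models — the interridge region (a microrib
grating over the 225 nm lower lamina) and the ridge (a chitin lamella over
an air gap over the lower lamina).

Each membrane builder returns a :class:`MembraneModel` exposing both a
transfer-matrix :class:`~clearwing.multilayer.Stack` (nipple array
homogenized into a graded-index profile) and FDTD rasters — either the
same graded profile or the corrugated 2D cross-section with explicit
half-ellipse bumps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .effective_medium import (
    MicroribLayer,
    NippleArray,
    graded_index_layers,
    microrib_effective_layer,
)
from .errors import ValidationError
from .materials import AIR, CHITIN, OpticalMaterial, make_material
from .multilayer import Layer, Stack, tmm_spectrum
from .fdtd2d import DEFAULT_DX_NM, StructureRaster, raster_from_profile
from .spectra import Spectrum, find_extrema, wavelength_grid

MembraneVariant = Literal["one-layer", "three-layer"]
NippleFaces = Literal["none", "dorsal", "both"]


@dataclass(frozen=True)
class RegistryValue:
    value: float
    sd: float | None = None  # printed +/- uncertainty, retained as metadata


@dataclass(frozen=True)
class ParameterRegistry:
    """All printed structural measurements and optical constants (nm)."""

    h_n: RegistryValue = RegistryValue(142.0, 10.0)      # nipple height
    d_n: RegistryValue = RegistryValue(135.0, 11.0)      # nipple diameter
    pitch: RegistryValue = RegistryValue(300.0, None)    # nipple pitch
    h_de: RegistryValue = RegistryValue(436.0, 20.0)     # dorsal exocuticle
    h_m: RegistryValue = RegistryValue(194.0, 7.0)       # pigmented mesocuticle
    h_ve: RegistryValue = RegistryValue(412.0, 10.0)     # ventral exocuticle
    h_mr: RegistryValue = RegistryValue(45.0, 2.0)       # microrib thickness
    w_mr: RegistryValue = RegistryValue(62.0, 4.0)       # microrib width
    gap_mr: RegistryValue = RegistryValue(58.0, 3.0)     # microrib gap
    h_LL: RegistryValue = RegistryValue(225.0, 12.0)     # lower lamina
    n_chitin: float = 1.56
    n_air: float = 1.0
    n_pigment_real: float = 1.74
    k_pigment: float = 0.010

    def __post_init__(self):
        for name in ("h_n", "d_n", "pitch", "h_de", "h_m", "h_ve",
                     "h_mr", "w_mr", "gap_mr", "h_LL"):
            rv = getattr(self, name)
            if not rv.value > 0:
                raise ValidationError(f"registry length {name} must be > 0")

    def with_overrides(self, **kw) -> "ParameterRegistry":
        """New registry with selected values replaced (lengths as floats)."""
        updates = {}
        for name, v in kw.items():
            current = getattr(self, name)
            if isinstance(current, RegistryValue):
                updates[name] = (
                    v if isinstance(v, RegistryValue) else RegistryValue(float(v), current.sd)
                )
            else:
                updates[name] = float(v)
        return replace(self, **updates)

    def chitin(self) -> OpticalMaterial:
        return CHITIN if self.n_chitin == 1.56 else make_material("chitin", self.n_chitin)

    def pigment(self, k=None) -> OpticalMaterial:
        return make_material(
            "pigment", self.n_pigment_real, self.k_pigment if k is None else k
        )

    def nipple_array(self, **kw) -> NippleArray:
        return NippleArray(
            height_nm=self.h_n.value,
            diameter_nm=self.d_n.value,
            pitch_nm=self.pitch.value,
            **kw,
        )

    def microrib_layer(self) -> MicroribLayer:
        return MicroribLayer(
            thickness_nm=self.h_mr.value,
            width_nm=self.w_mr.value,
            gap_nm=self.gap_mr.value,
            material=self.chitin(),
        )

    def as_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            out[name] = v.value if isinstance(v, RegistryValue) else v
        return out


DEFAULT_REGISTRY = ParameterRegistry()


# -- membrane -----------------------------------------------------------------


@dataclass(frozen=True)
class MembraneModel:
    """A membrane structure with matched TMM and FDTD representations."""

    variant: MembraneVariant
    nipples: NippleFaces
    stack: Stack
    registry: ParameterRegistry
    nipple_array: NippleArray | None = None

    def raster(
        self, dx_nm: float = DEFAULT_DX_NM, mode: Literal["graded", "corrugated"] = "graded"
    ) -> StructureRaster:
        """FDTD raster of the same geometry.

        ``graded``: the homogenized index profile, laterally uniform (the
        surrogate for the full 3D nipple lattice, exactly matching the TMM
        stack). ``corrugated``: explicit half-ellipse bumps, one nipple per
        300 nm period — the true 2D cross-section.
        """
        if mode == "graded":
            return _raster_from_stack(self.stack, dx_nm, name=self.stack.name)
        if mode != "corrugated":
            raise ValidationError(f"unknown raster mode {mode!r}")
        return _corrugated_membrane_raster(self, dx_nm)


def _raster_from_stack(stack: Stack, dx_nm: float, nx: int = 4, name: str = "") -> StructureRaster:
    lam_ref = 550.0
    n_prof = [float(np.atleast_1d(l.material.n(lam_ref))[0]) for l in stack.layers]
    k_prof = [float(np.atleast_1d(l.material.k(lam_ref))[0]) for l in stack.layers]
    t_prof = [l.thickness_nm for l in stack.layers]
    return raster_from_profile(n_prof, k_prof, t_prof, dx_nm, nx=nx, name=name)


def _corrugated_membrane_raster(model: MembraneModel, dx_nm: float) -> StructureRaster:
    reg = model.registry
    arr = model.nipple_array
    pitch = reg.pitch.value
    nx = int(round(pitch / dx_nm))
    core_layers = _membrane_core(model.variant, reg)
    nip_cells = int(round(arr.height_nm / dx_nm)) if arr and model.nipples != "none" else 0
    n_core_cells = sum(int(round(t / dx_nm)) for _, _, t in core_layers)
    top = nip_cells if model.nipples in ("dorsal", "both") else 0
    bottom = nip_cells if model.nipples == "both" else 0
    nz = top + n_core_cells + bottom
    n_map = np.ones((nz, nx))
    k_map = np.zeros((nz, nx))
    xc = (np.arange(nx) + 0.5) * dx_nm
    n_ch = reg.n_chitin

    def paint_nipples(rows, upward: bool):
        for j, row in enumerate(rows):
            # height above the nipple base at this row's cell centers
            z = (len(rows) - j - 0.5) * dx_nm if upward else (j + 0.5) * dx_nm
            half = 0.5 * arr.width_at(z)
            if half <= 0:
                continue
            mask = np.abs(xc - pitch / 2.0) <= half
            n_map[row, mask] = n_ch

    if top:
        paint_nipples(list(range(0, top)), upward=True)
    z = top
    for n, k, t in core_layers:
        cells = int(round(t / dx_nm))
        n_map[z : z + cells] = n
        k_map[z : z + cells] = k
        z += cells
    if bottom:
        paint_nipples(list(range(z, z + bottom)), upward=False)
    return StructureRaster(
        n_map, k_map, dx_nm, name=f"membrane_{model.variant}_nipples_{model.nipples}"
    )


def _membrane_core(variant: MembraneVariant, reg: ParameterRegistry):
    """(n, k, thickness) triples of the planar membrane core."""
    if variant == "one-layer":
        total = reg.h_de.value + reg.h_m.value + reg.h_ve.value
        return [(reg.n_chitin, 0.0, total)]
    if variant == "three-layer":
        return [
            (reg.n_chitin, 0.0, reg.h_de.value),
            (reg.n_pigment_real, reg.k_pigment, reg.h_m.value),
            (reg.n_chitin, 0.0, reg.h_ve.value),
        ]
    raise ValidationError(f"unknown membrane variant {variant!r}")


def build_membrane(
    variant: MembraneVariant = "three-layer",
    nipples: NippleFaces | NippleArray = "both",
    registry: ParameterRegistry = DEFAULT_REGISTRY,
    n_slices: int | None = None,
) -> MembraneModel:
    """Membrane model in air, with the nipple array on the chosen faces.

    The default places the array on both faces: the dorsal and ventral
    exocuticles are the same tissue and both carry the nanostructure.
    ``nipples`` may also be a custom :class:`NippleArray` (applied to both
    faces) for sensitivity studies.
    """
    if isinstance(nipples, NippleArray):
        arr: NippleArray | None = nipples
        faces: NippleFaces = "both"
    elif nipples in ("none", "dorsal", "both"):
        faces = nipples
        kw = {"n_slices": n_slices} if n_slices else {}
        arr = registry.nipple_array(**kw) if faces != "none" else None
    else:
        raise ValidationError(f"unknown nipple specification {nipples!r}")

    chitin = registry.chitin()
    pigment = registry.pigment()
    core: tuple[Layer, ...]
    if variant == "one-layer":
        total = registry.h_de.value + registry.h_m.value + registry.h_ve.value
        core = (Layer(chitin, total),)
    elif variant == "three-layer":
        core = (
            Layer(chitin, registry.h_de.value),
            Layer(pigment, registry.h_m.value),
            Layer(chitin, registry.h_ve.value),
        )
    else:
        raise ValidationError(f"unknown membrane variant {variant!r}")

    layers: tuple[Layer, ...] = core
    if arr is not None:
        graded = graded_index_layers(arr, inclusion=chitin, host=AIR)
        if faces in ("dorsal", "both"):
            layers = graded + layers
        if faces == "both":
            layers = layers + graded[::-1]
    stack = Stack(
        ambient=AIR, layers=layers, substrate=AIR,
        name=f"membrane_{variant}_nipples_{faces}",
    )
    return MembraneModel(
        variant=variant, nipples=faces, stack=stack, registry=registry, nipple_array=arr
    )


# -- scale models -------------------------------------------------------------


@dataclass(frozen=True)
class ScaleModel:
    kind: Literal["interridge", "ridge"]
    stack: Stack
    registry: ParameterRegistry

    def raster(self, dx_nm: float = DEFAULT_DX_NM) -> StructureRaster:
        return _raster_from_stack(self.stack, dx_nm, name=self.stack.name)


def build_interridge(registry: ParameterRegistry = DEFAULT_REGISTRY) -> ScaleModel:
    """Interridge model: homogenized microrib layer over the lower lamina."""
    mr_layer = microrib_effective_layer(registry.microrib_layer())
    stack = Stack(
        ambient=AIR,
        layers=(mr_layer, Layer(registry.chitin(), registry.h_LL.value)),
        substrate=AIR,
        name="interridge",
    )
    return ScaleModel(kind="interridge", stack=stack, registry=registry)


def build_ridge(
    h_air_nm: float | None = None,
    lamella_thickness_nm: float | None = None,
    registry: ParameterRegistry = DEFAULT_REGISTRY,
) -> ScaleModel:
    """Ridge model: chitin lamella / air gap / lower lamina multilayer.

    The air-gap and lamella thicknesses are not part of the measured
    registry and must be supplied explicitly.
    """
    if h_air_nm is None:
        raise ValidationError("ridge model requires h_air_nm (no default exists)")
    if lamella_thickness_nm is None:
        raise ValidationError("ridge model requires lamella_thickness_nm")
    chitin = registry.chitin()
    stack = Stack(
        ambient=AIR,
        layers=(
            Layer(chitin, float(lamella_thickness_nm)),
            Layer(AIR_GAP, float(h_air_nm)),
            Layer(chitin, registry.h_LL.value),
        ),
        substrate=AIR,
        name="ridge",
    )
    return ScaleModel(kind="ridge", stack=stack, registry=registry)


AIR_GAP = make_material("air_gap", 1.0, 0.0)


# -- spectral summaries -------------------------------------------------------


def peak_wavelength(spec: Spectrum, band=(400.0, 700.0)) -> float:
    """Wavelength of the most prominent reflectance maximum in the band."""
    maxima = [e for e in find_extrema(spec, band) if e.type == "max"]
    if not maxima:
        raise ValidationError("no prominent maximum in band")
    return max(maxima, key=lambda e: e.prominence).wavelength_nm


def microrib_spacing_sweep(
    gaps_nm,
    registry: ParameterRegistry = DEFAULT_REGISTRY,
    band=(400.0, 700.0),
    step_nm: float = 1.0,
):
    """Peak wavelength of the interridge reflectance versus microrib gap.

    Returns a list of (gap_nm, peak_nm) pairs; increasing the gap dilutes
    the microrib layer and blue-shifts the single interridge peak.
    """
    gaps = list(gaps_nm)
    if any(g <= 0 for g in gaps):
        raise ValidationError("gaps must be > 0")
    if any(b > a for a, b in zip(gaps[1:], gaps[:-1])):
        raise ValidationError("gaps must be ascending")
    lam = wavelength_grid(band[0], band[1], step_nm)
    out = []
    for gap in gaps:
        reg = registry.with_overrides(gap_mr=gap)
        R, _, _ = tmm_spectrum(build_interridge(reg).stack, lam)
        out.append((float(gap), peak_wavelength(R, band)))
    return out


# -- membrane thickness fitting ----------------------------------------------


def fit_membrane_thicknesses(
    target: Spectrum,
    bounds: dict[str, tuple[float, float]] | None = None,
    registry: ParameterRegistry = DEFAULT_REGISTRY,
    nipples: NippleFaces = "none",
    n_grid: int = 5,
) -> tuple[ParameterRegistry, float]:
    """Least-squares fit of (h_de, h_m, h_ve) to a reflectance spectrum.

    A coarse grid over the bounds (defaulting to the printed +/- sd of each
    thickness) seeds a bounded local refinement. Deterministic for fixed
    inputs; the returned residual (RMS reflectance misfit) never exceeds
    the residual at the registry defaults.
    """
    names = ("h_de", "h_m", "h_ve")
    if bounds is None:
        bounds = {
            n: (
                getattr(registry, n).value - (getattr(registry, n).sd or 0.0),
                getattr(registry, n).value + (getattr(registry, n).sd or 0.0),
            )
            for n in names
        }
    for n in names:
        lo, hi = bounds.get(n, (None, None))
        if lo is None or hi is None or not (0 < lo <= hi):
            raise ValidationError(f"invalid bounds for {n}: {bounds.get(n)}")
    lam = target.wavelength_nm

    def model_R(th):
        reg = registry.with_overrides(**dict(zip(names, th)))
        R, _, _ = tmm_spectrum(build_membrane("three-layer", nipples, reg).stack, lam)
        return R.value

    def rms(th):
        return float(np.sqrt(np.mean((model_R(th) - target.value) ** 2)))

    default_th = [getattr(registry, n).value for n in names]
    best_th, best = list(default_th), rms(default_th)
    axes = [np.linspace(bounds[n][0], bounds[n][1], n_grid) for n in names]
    for a in axes[0]:
        for b in axes[1]:
            for c in axes[2]:
                r = rms([a, b, c])
                if r < best:
                    best, best_th = r, [a, b, c]
    lo = [bounds[n][0] for n in names]
    hi = [bounds[n][1] for n in names]
    if any(h > l for l, h in zip(lo, hi)):
        sol = least_squares(
            lambda th: model_R(th) - target.value,
            x0=best_th, bounds=(lo, hi), xtol=1e-10, ftol=1e-12,
        )
        if rms(sol.x) <= best:
            best_th, best = list(sol.x), rms(sol.x)
    fitted = registry.with_overrides(**dict(zip(names, best_th)))
    return fitted, best
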