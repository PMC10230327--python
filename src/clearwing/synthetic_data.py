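"""Seeded generators emulating the study's measurements.

Three generators produce every input the analysis stages consume, so the
whole pipeline is testable without the microscope:

* :func:`synth_measured_spectrum` emulates microspectrophotometer spectra —
  per-replicate multiplicative gain and additive noise, averaged over three
  replicates the way the bench protocol averages three sample locations;
* :func:`synth_droplet_contour` samples points on a circular cap at a
  prescribed contact angle with coordinate noise, emulating goniometry
  silhouettes;
* :func:`synth_structure_jitter` resamples the structural registry inside
  the printed +/- uncertainties (truncated normal, +/- 3 sd) to probe how
  membrane non-uniformity moves the spectral extrema.

Every stochastic output requires an explicit seed; one private generator
stream per call, no global state. The default noise magnitudes (1 %
multiplicative gain sd, 0.002 additive reflectance sd) are declared
assumptions about the instrument, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .spectra import Spectrum
from .wettability import DropletContour
from .wing_models import ParameterRegistry, RegistryValue


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise model and replication for the synthetic instrument."""

    seed: int
    gain_sd: float = 0.01        # sd of the per-replicate multiplicative gain
    additive_sd: float = 0.002   # per-point additive sd, reflectance units
    n_replicates: int = 3        # bench protocol: average of three locations

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed is required and must be an integer")
        if self.gain_sd < 0 or self.additive_sd < 0:
            raise ValidationError("noise sds must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), salt]))


def synth_measured_spectrum(model: Spectrum, cfg: GeneratorConfig) -> Spectrum:
    """Noisy replicate-averaged measurement of a model spectrum.

    value = mean_r(gain_r * model + eps_r), clipped to the physical range
    of the spectrum kind. With zero noise the model is returned exactly;
    identical seeds give identical spectra.
    """
    rng = cfg.rng(salt=1)
    if cfg.gain_sd == 0.0 and cfg.additive_sd == 0.0:
        meta = dict(model.meta, synthetic=True, seed=int(cfg.seed))
        return Spectrum(model.wavelength_nm, model.value.copy(), kind=model.kind, meta=meta)
    reps = np.empty((cfg.n_replicates, model.value.size))
    for r in range(cfg.n_replicates):
        gain = rng.normal(1.0, cfg.gain_sd)
        eps = rng.normal(0.0, cfg.additive_sd, size=model.value.size)
        reps[r] = gain * model.value + eps
    mean = reps.mean(axis=0)
    if model.kind in ("reflectance", "transmittance"):
        mean = np.clip(mean, 0.0, 1.0)
    else:
        mean = np.clip(mean, 0.0, None)
    meta = dict(model.meta)
    meta.update(
        {"synthetic": True, "seed": int(cfg.seed), "n_replicates": cfg.n_replicates}
    )
    return Spectrum(model.wavelength_nm, mean, kind=model.kind, meta=meta)


def synth_droplet_contour(
    theta_deg: float,
    radius: float,
    n_points: int,
    cfg: GeneratorConfig,
    noise_frac: float = 0.0,
) -> DropletContour:
    """Points on a circular cap at contact angle ``theta_deg``.

    The cap's circle has its center at height c = r*sin(theta - 90 deg)
    above the baseline (y = 0), so a noiseless contour inverts exactly
    under :func:`clearwing.wettability.contact_angle`. ``noise_frac``
    scales isotropic Gaussian coordinate noise by the droplet radius.
    """
    if not 0.0 < theta_deg < 180.0:
        raise ValidationError("theta_deg must lie in (0, 180)")
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    c = radius * np.sin(np.radians(theta_deg - 90.0))
    # cap spans polar angles phi where y = c + r sin(phi) >= 0
    phi_lo = -np.arcsin(np.clip(c / radius, -1, 1))
    phi = np.linspace(phi_lo, np.pi - phi_lo, n_points)
    x = radius * np.cos(phi)
    y = c + radius * np.sin(phi)
    if noise_frac > 0:
        rng = cfg.rng(salt=2)
        x = x + rng.normal(0.0, noise_frac * radius, size=x.size)
        y = y + rng.normal(0.0, noise_frac * radius, size=y.size)
    return DropletContour(np.column_stack([x, y]), baseline=0.0)


_JITTERED_LENGTHS = ("h_n", "d_n", "h_de", "h_m", "h_ve", "h_mr", "w_mr", "gap_mr", "h_LL")


def synth_structure_jitter(
    registry: ParameterRegistry,
    cfg: GeneratorConfig,
    sd_scale: float = 1.0,
) -> ParameterRegistry:
    """Registry resampled within the printed uncertainties.

    Each length with a printed sd is drawn from a normal centered at the
    printed mean, truncated at +/- 3 sd and at positivity; ``sd_scale = 0``
    returns the registry unchanged.
    """
    if sd_scale < 0:
        raise ValidationError("sd_scale must be >= 0")
    if sd_scale == 0.0:
        return registry
    rng = cfg.rng(salt=3)
    updates = {}
    for name in _JITTERED_LENGTHS:
        rv: RegistryValue = getattr(registry, name)
        if rv.sd is None:
            continue
        sd = rv.sd * sd_scale
        for _ in range(1000):
            draw = rng.normal(rv.value, sd)
            if abs(draw - rv.value) <= 3.0 * sd and draw > 0:
                break
        else:  # pragma: no cover - unreachable for printed geometries
            raise ValidationError(f"could not draw a valid {name}")
        updates[name] = RegistryValue(float(draw), rv.sd)
    return registry.with_overrides(**updates)
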