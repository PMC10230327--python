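"""Sessile-drop contact-angle extraction and group comparison.

A 1 ul water droplet on the wing is small enough for gravity to be
negligible, so its silhouette is a spherical cap. The static contact angle
is extracted by least-squares circle fitting of the contour points above a
user-defined baseline: for a fitted circle of radius r centered a height c
above the baseline, the angle through the liquid at each baseline
intersection is

    theta = 90 deg + asin(c / r)        (c < 0 for sub-hemispherical caps).

Wings are classed hydrophobic above 90 deg and superhydrophobic above
150 deg (both exclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import FitError, NoContactError, ValidationError

#: Contour points closer to the baseline than this fraction of the droplet
#: height are excluded from the circle fit (reflection artifacts cluster
#: near the contact line in real goniometry images).
CONTACT_LINE_EXCLUSION_FRACTION = 0.02


@dataclass(frozen=True)
class DropletContour:
    """Ordered droplet silhouette coordinates and the substrate baseline.

    Any consistent length unit works; the extracted angle is unit-free.
    """

    points: np.ndarray  # (N, 2) of (x, y)
    baseline: float

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("points must be an (N, 2) array")
        above = pts[pts[:, 1] > self.baseline]
        if len(above) < 10:
            raise ValidationError("need >= 10 contour points above the baseline")
        if np.ptp(above[:, 0]) <= 0:
            raise ValidationError("contour x-extent must be positive")


@dataclass(frozen=True)
class ContactAngleResult:
    theta_left_deg: float
    theta_right_deg: float
    theta_mean_deg: float
    rms_residual: float
    radius: float
    center: tuple[float, float]

    def __post_init__(self):
        for th in (self.theta_left_deg, self.theta_right_deg, self.theta_mean_deg):
            if not 0.0 < th < 180.0:
                raise ValidationError(f"contact angle {th} outside (0, 180)")
        if abs(self.theta_mean_deg - 0.5 * (self.theta_left_deg + self.theta_right_deg)) > 1e-9:
            raise ValidationError("mean angle inconsistent with left/right")


def _fit_circle(pts: np.ndarray) -> tuple[float, float, float]:
    """Least-squares circle (xc, yc, r): algebraic seed + geometric refinement."""
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    try:
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise FitError("circle fit failed") from exc
    xc, yc = coef[0], coef[1]
    r2 = coef[2] + xc**2 + yc**2
    if not np.isfinite(r2) or r2 <= 0:
        raise FitError("degenerate (collinear) contour points")
    r = math.sqrt(r2)
    span = max(np.ptp(x), np.ptp(y))
    if r > 1e3 * span:
        raise FitError("degenerate (collinear) contour points")

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    sol = least_squares(resid, x0=[xc, yc, r], xtol=1e-14, ftol=1e-14)
    r_fit = float(abs(sol.x[2]))
    if r_fit > 1e3 * span:  # refinement diverging to a straight line
        raise FitError("degenerate (collinear) contour points")
    return float(sol.x[0]), float(sol.x[1]), r_fit


def contact_angle(
    contour: DropletContour,
    exclusion_fraction: float = CONTACT_LINE_EXCLUSION_FRACTION,
) -> ContactAngleResult:
    """Static contact angle from a circular-cap fit of the contour.

    Points above the baseline (excluding a thin band near the contact
    line) are fitted by a circle; the angle between baseline and circle
    tangent, measured through the liquid, is reported for the left and
    right intersections (identical by construction for a single circle)
    along with the RMS radial fit residual.
    """
    pts = contour.points
    above = pts[pts[:, 1] > contour.baseline]
    height = above[:, 1].max() - contour.baseline
    keep = above[above[:, 1] > contour.baseline + exclusion_fraction * height]
    if len(keep) < 3:
        raise ValidationError("too few contour points after contact-line exclusion")
    xc, yc, r = _fit_circle(keep)
    c = yc - contour.baseline
    if abs(c) >= r:
        raise NoContactError(
            "fitted circle does not intersect the baseline (|center height| >= r)"
        )
    theta = 90.0 + math.degrees(math.asin(c / r))
    resid = float(np.sqrt(np.mean((np.hypot(keep[:, 0] - xc, keep[:, 1] - yc) - r) ** 2)))
    return ContactAngleResult(
        theta_left_deg=theta,
        theta_right_deg=theta,
        theta_mean_deg=theta,
        rms_residual=resid,
        radius=r,
        center=(xc, yc),
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def compare_groups(a, b, paired: bool = True) -> TTestResult:
    """Two-sided t-test between contact-angle groups.

    Paired (default, d.f. = n - 1) or unpaired with pooled variance
    (d.f. = n_a + n_b - 2). The t statistic and degrees of freedom come
    from the explicit textbook formulas; the p-value from the Student-t
    survival function. Degenerate data (zero variance): identical groups
    give p = 1 by convention, a nonzero mean difference raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need n >= 2 per group")
    if paired:
        if len(a) != len(b):
            raise ValidationError("paired test requires equal group sizes")
        d = a - b
        n = len(d)
        sd = d.std(ddof=1)
        df = n - 1
        if sd == 0.0:
            if d.mean() == 0.0:
                return TTestResult(t=0.0, df=df, p=1.0)
            raise ValidationError("zero variance with nonzero mean difference")
        t = d.mean() / (sd / math.sqrt(n))
    else:
        na, nb = len(a), len(b)
        df = na + nb - 2
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        if sp2 == 0.0:
            if a.mean() == b.mean():
                return TTestResult(t=0.0, df=df, p=1.0)
            raise ValidationError("zero variance with nonzero mean difference")
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=int(df), p=min(p, 1.0))


def classify_wettability(theta_mean_deg: float) -> str:
    """hydrophilic (<= 90), hydrophobic (> 90), superhydrophobic (> 150)."""
    if not 0.0 < theta_mean_deg < 180.0:
        raise ValidationError("contact angle must lie in (0, 180)")
    if theta_mean_deg > 150.0:
        return "superhydrophobic"
    if theta_mean_deg > 90.0:
        return "hydrophobic"
    return "hydrophilic"


def read_contour_csv(path, baseline: float | None = None) -> DropletContour:
    """Contour from a CSV with x,y columns; baseline from header comment
    ``# baseline: <y>`` unless given explicitly."""
    import pandas as pd

    header_baseline = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("baseline"):
                header_baseline = float(stripped.split(":", 1)[1])
        else:
            body.append(line)
    import io

    df = pd.read_csv(io.StringIO("".join(body)))
    if baseline is None:
        baseline = header_baseline
    if baseline is None:
        raise ValidationError(f"{path}: no baseline given or found in header")
    return DropletContour(df[["x", "y"]].to_numpy(), float(baseline))
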