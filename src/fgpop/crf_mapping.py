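"""Classical-receptive-field estimation from grating position-response maps.

The mean spike-count map over grid positions is fitted with an elliptical
2D Gaussian plus a constant offset,

    f(x, y) = offset + A * exp(-(x'^2 / (2 sx^2) + y'^2 / (2 sy^2)))

where (x', y') are the coordinates rotated by the ellipse orientation about
the fitted centre.  The CRF extent is the diameter of the circle whose area
equals the area enclosed by the half-height contour of the Gaussian.  That
contour is an ellipse of area 2*pi*ln(2)*sx*sy, so

    extent_diameter = 2 * sqrt(2 * ln(2) * sx * sy)

in closed form (no numerical contouring).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

_HALF_HEIGHT = 2.0 * np.log(2.0)


class CRFFitError(ValueError):
    """Raised when no receptive field can be recovered from a map."""


@dataclass(frozen=True)
class CRFEstimate:
    center: tuple[float, float]       # degrees
    sigma: tuple[float, float]        # (sx, sy) degrees
    orientation: float                # radians
    extent_diameter: float            # degrees, half-height-area diameter
    fit_quality: float                # coefficient of determination
    amplitude: float                  # peak response above offset (counts)
    offset: float
    valid: bool = True


def _gauss2d(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x0, y0, sx, sy, th, amp, off = params
    c, s = np.cos(th), np.sin(th)
    xr = c * (x - x0) + s * (y - y0)
    yr = -s * (x - x0) + c * (y - y0)
    return off + amp * np.exp(-(xr**2 / (2 * sx**2) + yr**2 / (2 * sy**2)))


def fit_crf(
    positions: np.ndarray,
    values: np.ndarray,
    *,
    isotropic: bool = False,
    fit_offset: bool = True,
) -> CRFEstimate:
    """Least-squares 2D-Gaussian fit of a position-response map.

    ``positions`` is (P, 2) in degrees, ``values`` the mean spike counts.
    The solver uses a deterministic multi-start: the centre is initialised
    at the map argmax and the widths at multiples of the grid spacing.
    Raises :class:`CRFFitError` on degenerate input; a failed or
    non-positive-amplitude fit is returned flagged invalid.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float).ravel()
    if positions.shape[0] < 6:
        raise CRFFitError("need at least 6 distinct positions")
    if np.ptp(values) <= 0:
        raise CRFFitError("constant map: no receptive field recoverable")
    x, y = positions[:, 0], positions[:, 1]
    spacing = np.median(np.diff(np.unique(np.round(x, 9)))) if len(np.unique(x)) > 1 \
        else np.median(np.diff(np.unique(np.round(y, 9))))
    vmin, vmax = values.min(), values.max()
    imax = int(np.argmax(values))
    span = max(np.ptp(x), np.ptp(y))

    def residuals(p):
        return _gauss2d(p, x, y) - values

    best = None
    for s_init in (0.5 * spacing, spacing, 2.0 * spacing):
        p0 = np.array([x[imax], y[imax], s_init, s_init, 0.0,
                       vmax - vmin, vmin if fit_offset else 0.0])
        lb = [x.min() - spacing, y.min() - spacing, 1e-3, 1e-3,
              -np.pi / 2, 1e-9, 0.0 if fit_offset else -1e-12]
        ub = [x.max() + spacing, y.max() + spacing, 2 * span, 2 * span,
              np.pi / 2, 10 * max(vmax - vmin, 1e-9),
              vmax if fit_offset else 1e-12]
        try:
            sol = least_squares(residuals, p0, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return CRFEstimate((np.nan, np.nan), (np.nan, np.nan), 0.0, np.nan,
                           0.0, np.nan, np.nan, valid=False)
    x0, y0, sx, sy, th, amp, off = best.x
    if isotropic:
        sx = sy = float(np.sqrt(sx * sy))
        th = 0.0
    sse = 2.0 * best.cost
    sst = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    valid = bool(amp > 1e-6 and best.success)
    return CRFEstimate(
        center=(float(x0), float(y0)),
        sigma=(float(sx), float(sy)),
        orientation=float(th),
        extent_diameter=float(2.0 * np.sqrt(_HALF_HEIGHT * sx * sy)),
        fit_quality=float(r2),
        amplitude=float(amp),
        offset=float(off),
        valid=valid,
    )


def fit_population(maps, **kwargs) -> list[CRFEstimate]:
    """Fit every neuron in a :class:`~fgpop.synthetic_population.GratingMaps`."""
    out = []
    for i in range(maps.maps.shape[0]):
        try:
            out.append(fit_crf(maps.positions, maps.maps[i], **kwargs))
        except CRFFitError:
            out.append(CRFEstimate((np.nan, np.nan), (np.nan, np.nan), 0.0,
                                   np.nan, 0.0, np.nan, np.nan, valid=False))
    return out


def crf_ellipse(
    estimate: CRFEstimate, level: float = 0.5
) -> Callable[[np.ndarray], np.ndarray]:
    """Region predicate for the Gaussian's ``level`` contour (default the
    half-height ellipse used by overlap-based FG labelling)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    x0, y0 = estimate.center
    sx, sy = estimate.sigma
    th = estimate.orientation
    c, s = np.cos(th), np.sin(th)
    q_max = -2.0 * np.log(level)

    def inside(points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        dx, dy = p[..., 0] - x0, p[..., 1] - y0
        xr = c * dx + s * dy
        yr = -s * dx + c * dy
        return xr**2 / sx**2 + yr**2 / sy**2 <= q_max

    return inside


def ellipse_area(estimate: CRFEstimate, level: float = 0.5) -> float:
    """Closed-form area of the ``level`` contour ellipse (deg^2)."""
    sx, sy = estimate.sigma
    return float(np.pi * sx * sy * (-2.0 * np.log(level)))
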