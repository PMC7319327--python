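"""Synthetic contour-patch stimuli with veridical figure-ground geometry.

A stimulus patch is a square frame of ``scale`` degrees of visual angle,
centred at (0, 0), x right / y up, carrying a contour that passes through
the patch centre and splits the frame into a *figure* region and a *ground*
region.  The contour family is analytic: on each side of the centre the
contour is a circular arc (shared radius, per-side turn angle) continued by
a straight ray along its end tangent; a zero-turn contour is a straight
line.  The 69x69 raster lattice used for masks maps onto the frame with
pixel centres.

Shape descriptors (stand-ins; the field has no canonical numeric scales):

* ``closure`` in [0, 1]: total tangent turning of the contour / 2*pi
  (0 = straight line, 1 = full circle).
* ``convexity`` in [-1, 1]: bounded signed curvature at the centre,
  ``sign * kappa*s / (1 + kappa*s)``; positive when the figure is on the
  concave (enclosed) side.
* ``symmetry`` in [0, 1]: intersection-over-union of the figure mask with
  its reflection about the contour normal at the centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

GRID = 69
DEFAULT_SCALE = 8.0  # degrees per patch side
DEFAULT_TRANSLATION_FRACTION = 0.25  # of the patch side

# perceptual FG-judgment consistency (Beta moments): natural 0.69 +- 0.11,
# filled 0.77 +- 0.14
CONSISTENCY_PARAMS = {"natural": (0.69, 0.11), "filled": (0.77, 0.14)}

Family = Literal["natural", "filled", "square", "grating"]


class DescriptorError(ValueError):
    """Raised when a descriptor target triple cannot be realised."""


# ---------------------------------------------------------------------------
# base geometries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContourPatch:
    """An analytic contour patch with a veridical figure mask.

    The contour lives in the tangent frame (u along the tangent at the
    centre, v along the normal pointing into the canonical figure side) and
    consists of two circular arcs through the origin with per-side radii
    ``radius_left`` / ``radius_right`` and turn angles ``theta_left`` /
    ``theta_right``, each continued by its end-tangent ray.  Unequal radii
    break mirror symmetry while keeping the contour C1 at the centre.
    """

    id: str
    scale: float
    tangent_angle: float          # radians, direction of the tangent at centre
    theta_left: float             # arc turn on the u<0 side, [0, pi]
    theta_right: float            # arc turn on the u>0 side, [0, pi]
    radius_left: float            # arc radius; np.inf for a straight side
    radius_right: float
    figure_side: int = 1          # +1: figure is the pocket (concave) side
    consistency: float = 0.69     # P(canonical figure side judged figure)
    descriptors: dict = field(default_factory=dict)

    # -- coordinate helpers -------------------------------------------------

    def _to_tangent_frame(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c, s = np.cos(self.tangent_angle), np.sin(self.tangent_angle)
        u = c * points[..., 0] + s * points[..., 1]
        v = -s * points[..., 0] + c * points[..., 1]
        return u, v

    def normal(self) -> np.ndarray:
        """Unit normal at the centre, pointing to the canonical figure side."""
        return np.array([-np.sin(self.tangent_angle), np.cos(self.tangent_angle)])

    def tangent(self) -> np.ndarray:
        return np.array([np.cos(self.tangent_angle), np.sin(self.tangent_angle)])

    # -- region test --------------------------------------------------------

    def figure_at(self, points: np.ndarray) -> np.ndarray:
        """Boolean figure membership for an (..., 2) array of positions."""
        points = np.asarray(points, dtype=float)
        u, v = self._to_tangent_frame(points)
        pocket = _pocket_side(
            u, v, self.theta_left, self.theta_right,
            self.radius_left, self.radius_right,
        )
        return pocket if self.figure_side > 0 else ~pocket

    def mask(self) -> np.ndarray:
        """Figure mask on the GRID x GRID lattice (index [iy, ix], y up)."""
        return self.figure_at(lattice_points(self.scale))

    # -- contour ------------------------------------------------------------

    def polyline(self, points_per_unit_turn: int = 400) -> np.ndarray:
        """Rasterised contour in patch coordinates, clipped to the frame."""
        half = 0.5 * self.scale
        ray_len = 3.0 * self.scale

        def side(theta: float, radius: float, sign: float) -> np.ndarray:
            if theta <= 0 or not np.isfinite(radius):
                ts = np.linspace(0.0, ray_len, 200)
                return np.stack([sign * ts, np.zeros_like(ts)], axis=1)
            n = max(8, int(points_per_unit_turn * theta))
            t = np.linspace(0.0, theta, n)
            arc = np.stack(
                [sign * radius * np.sin(t), radius * (1.0 - np.cos(t))],
                axis=1,
            )
            end = arc[-1]
            direction = np.array([sign * np.cos(theta), np.sin(theta)])
            ls = np.linspace(0.0, ray_len, 200)[1:]
            ray = end[None, :] + ls[:, None] * direction[None, :]
            return np.concatenate([arc, ray], axis=0)

        right = side(self.theta_right, self.radius_right, +1.0)
        left = side(self.theta_left, self.radius_left, -1.0)
        pts = np.concatenate([left[::-1], right[1:]], axis=0)
        # rotate into the patch frame
        c, s = np.cos(self.tangent_angle), np.sin(self.tangent_angle)
        rot = np.array([[c, -s], [s, c]])
        pts = pts @ rot.T
        # clip: walk outward from the centre on each branch, stop at exit
        centre_idx = len(left) - 1
        inside = np.max(np.abs(pts), axis=1) <= half
        lo = centre_idx
        while lo - 1 >= 0 and inside[lo - 1]:
            lo -= 1
        hi = centre_idx
        while hi + 1 < len(pts) and inside[hi + 1]:
            hi += 1
        return pts[lo : hi + 1]


def lattice_points(scale: float) -> np.ndarray:
    """Pixel-centre coordinates of the GRID x GRID lattice, shape (G, G, 2)."""
    coords = (np.arange(GRID) + 0.5) / GRID * scale - scale / 2.0
    x, y = np.meshgrid(coords, coords)  # x varies along axis 1, y along axis 0
    return np.stack([x, y], axis=-1)


def _pocket_side(u, v, theta_l, theta_r, radius_l, radius_r) -> np.ndarray:
    """True where (u, v) lies on the pocket (canonical figure) side."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    out = np.zeros(np.broadcast(u, v).shape, dtype=bool)

    def half(uu, vv, theta, radius):
        # uu >= 0 by construction
        if theta <= 0 or not np.isfinite(radius):
            return vv > 0
        # angle of the point about the arc centre (0, R), from the -v axis
        psi = np.arctan2(uu, radius - vv)
        inside_sector = (psi >= 0) & (psi <= theta)
        in_circle = uu**2 + (vv - radius) ** 2 < radius**2
        res = inside_sector & in_circle
        # beyond the arc end: left of the end-tangent ray
        px = radius * np.sin(theta)
        py = radius * (1.0 - np.cos(theta))
        dx, dy = np.cos(theta), np.sin(theta)
        cross = dx * (vv - py) - dy * (uu - px)
        res |= ~inside_sector & (cross > 0)
        return res

    right = u >= 0
    out[right] = half(u[right], v[right], theta_r, radius_r)
    out[~right] = half(-u[~right], v[~right], theta_l, radius_l)
    return out


@dataclass(frozen=True)
class SquareBase:
    """Canonical square stimulus: a square figure with one edge through the
    patch centre (the central border, tangent along y)."""

    id: str
    scale: float
    consistency: float = 1.0  # square FG judgments are essentially certain

    @property
    def side(self) -> float:
        return self.scale / 3.0

    def figure_at(self, points: np.ndarray, pair: bool = False) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        a = self.side
        x, y = points[..., 0], points[..., 1]
        fig = (x >= 0) & (x <= a) & (np.abs(y) <= a / 2.0)
        if pair:
            # second (partly occluded) square offset diagonally behind
            fig = fig | (
                (x >= a / 2.0) & (x <= 1.5 * a) & (y >= -a) & (y <= 0.0)
            )
        return fig

    def normal(self) -> np.ndarray:
        return np.array([1.0, 0.0])

    def tangent(self) -> np.ndarray:
        return np.array([0.0, 1.0])


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusVariant:
    """A displayed stimulus: a base patch plus variant flags.

    ``contrast`` names the polarity of the *canonical* figure ('dark' or
    'light'); mirrored variants carry a colour inversion so that polarity
    stays constant with respect to the central border (figure/ground flips,
    the colour of each spatial side does not).
    """

    id: str
    base: ContourPatch | SquareBase
    family: Family
    mirrored: bool = False
    translated: bool = False
    offset: float = 0.0           # signed, degrees, along the border normal
    contrast: str | None = None   # 'dark' | 'light' | None (natural)
    rotation: int = 0             # quarter turns (square family)
    single_or_pair: str | None = None
    color_inverted: bool = False  # natural mirrors only
    consistency: float = 0.69

    @property
    def base_id(self) -> str:
        return self.base.id

    @property
    def scale(self) -> float:
        return self.base.scale

    # -- geometry -----------------------------------------------------------

    def _base_coords(self, points: np.ndarray) -> np.ndarray:
        """Map display coordinates back to canonical base coordinates."""
        q = np.asarray(points, dtype=float).copy()
        if self.translated:
            n = self.base.normal()
            if self.rotation:
                ang = self.rotation * np.pi / 2.0
                c, s = np.cos(ang), np.sin(ang)
                n = np.array([c * n[0] - s * n[1], s * n[0] + c * n[1]])
            q = q - self.offset * n
        if self.rotation:
            ang = -self.rotation * np.pi / 2.0
            c, s = np.cos(ang), np.sin(ang)
            q = np.stack(
                [c * q[..., 0] - s * q[..., 1], s * q[..., 0] + c * q[..., 1]],
                axis=-1,
            )
        if self.mirrored:
            phi = (
                self.base.tangent_angle
                if isinstance(self.base, ContourPatch)
                else np.pi / 2.0
            )
            c2, s2 = np.cos(2 * phi), np.sin(2 * phi)
            q = np.stack(
                [c2 * q[..., 0] + s2 * q[..., 1], s2 * q[..., 0] - c2 * q[..., 1]],
                axis=-1,
            )
        return q

    def figure_at(self, points: np.ndarray) -> np.ndarray:
        q = self._base_coords(points)
        if isinstance(self.base, SquareBase):
            return self.base.figure_at(q, pair=self.single_or_pair == "pair")
        return self.base.figure_at(q)

    def polarity_at(self, points: np.ndarray) -> np.ndarray | None:
        """'dark' / 'light' at each point; None for the natural family."""
        if self.family == "natural":
            return None
        fig = self.figure_at(points)
        dark = fig ^ (self.contrast == "light") ^ self.mirrored
        return np.where(dark, "dark", "light")

    def mask(self) -> np.ndarray:
        return self.figure_at(lattice_points(self.scale))


def fg_at(variant: StimulusVariant, point) -> tuple[str, str]:
    """Region and polarity labels at a point (degrees, patch frame).

    Returns ``(fg, polarity)`` with fg in {'figure', 'ground'} and polarity
    in {'dark', 'light', 'na'}.  Raises ValueError outside the frame.
    """
    p = np.asarray(point, dtype=float)
    half = variant.scale / 2.0
    if np.any(np.abs(p) > half):
        raise ValueError(
            f"point {tuple(np.atleast_1d(p))} outside the +-{half} deg patch frame"
        )
    fig = bool(variant.figure_at(p))
    fg = "figure" if fig else "ground"
    pol = variant.polarity_at(p)
    return fg, ("na" if pol is None else str(pol))


# ---------------------------------------------------------------------------
# descriptor measurement (oracle-checkable)
# ---------------------------------------------------------------------------


def measure_closure(patch: ContourPatch) -> float:
    """Closure recomputed from the rasterised contour: total turning / 2*pi."""
    pts = patch.polyline()
    seg = np.diff(pts, axis=0)
    seg = seg[np.linalg.norm(seg, axis=1) > 1e-12]
    ang = np.arctan2(seg[:, 1], seg[:, 0])
    turn = np.diff(ang)
    turn = (turn + np.pi) % (2 * np.pi) - np.pi
    return float(np.sum(np.abs(turn)) / (2 * np.pi))


def measure_symmetry(patch: ContourPatch) -> float:
    """IoU of the figure mask with its reflection about the centre normal."""
    pts = lattice_points(patch.scale)
    u, v = patch._to_tangent_frame(pts)
    a = patch.figure_at(pts)
    # reflected coordinates: u -> -u in the tangent frame
    t, n = patch.tangent(), patch.normal()
    refl = (-u)[..., None] * t + v[..., None] * n
    b = patch.figure_at(refl)
    union = np.sum(a | b)
    if union == 0:
        return 1.0
    return float(np.sum(a & b) / union)


def measure_convexity(patch: ContourPatch) -> float:
    """Bounded signed mean curvature at the centre (one-sided mean)."""
    if (patch.theta_left + patch.theta_right) <= 0:
        return 0.0
    kl = 0.0 if not np.isfinite(patch.radius_left) else 1.0 / patch.radius_left
    kr = 0.0 if not np.isfinite(patch.radius_right) else 1.0 / patch.radius_right
    ks = patch.scale * 0.5 * (kl + kr)
    if ks <= 0:
        return 0.0
    return float(patch.figure_side * ks / (1.0 + ks))


def measure_descriptors(patch: ContourPatch) -> dict:
    return {
        "convexity": measure_convexity(patch),
        "closure": measure_closure(patch),
        "symmetry": measure_symmetry(patch),
    }


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1 - mean) / sd**2 - 1.0
    return mean * nu, (1 - mean) * nu


def _draw_consistency(rng: np.random.Generator, family: str) -> float:
    a, b = _beta_params(*CONSISTENCY_PARAMS[family])
    return float(rng.beta(a, b))


def generate_patch(
    seed: int,
    descriptor_targets: tuple[float, float, float],
    *,
    scale: float = DEFAULT_SCALE,
    id: str | None = None,
    tol: float = 0.05,
) -> ContourPatch:
    """Construct a patch whose measured descriptors match the targets.

    ``descriptor_targets`` is (convexity, closure, symmetry).  Convexity and
    closure are realised analytically; symmetry is matched by a bounded
    bisection on the arc-turn imbalance, measuring mask IoU.  Deterministic
    given ``seed``.  Raises :class:`DescriptorError` when the triple is
    unreachable in this contour family (e.g. nonzero closure with ~zero
    curvature, or an arc too large for the frame).
    """
    conv, clos, symm = map(float, descriptor_targets)
    if not (-1 <= conv <= 1 and 0 <= clos <= 1 and 0 <= symm <= 1):
        raise DescriptorError(f"descriptor targets out of range: {(conv, clos, symm)}")
    rng = np.random.default_rng(seed)
    phi = float(rng.uniform(0, 2 * np.pi))
    consistency = _draw_consistency(rng, "natural")
    pid = id or f"patch-{seed}"

    theta_tot = 2 * np.pi * clos
    if theta_tot <= 1e-9:
        if abs(conv) > tol:
            raise DescriptorError(
                f"unreachable descriptors {(conv, clos, symm)}: straight contour "
                "(closure 0) cannot have nonzero convexity"
            )
        if symm < 1 - tol:
            raise DescriptorError(
                f"unreachable descriptors {(conv, clos, symm)}: straight contour "
                "is mirror-symmetric"
            )
        return ContourPatch(pid, scale, phi, 0.0, 0.0, np.inf, np.inf, 1,
                            consistency,
                            {"convexity": 0.0, "closure": 0.0, "symmetry": 1.0})

    if abs(conv) < 1e-3:
        raise DescriptorError(
            f"unreachable descriptors {(conv, clos, symm)}: nonzero closure "
            "requires nonzero convexity in the arc family"
        )
    kappa = abs(conv) / (scale * (1.0 - abs(conv)))
    side_sign = 1 if conv > 0 else -1
    theta_side = theta_tot / 2.0
    if theta_side > np.pi:
        raise DescriptorError(f"unreachable descriptors {(conv, clos, symm)}")
    # an arc of turn theta_side and curvature k must end inside the frame:
    # endpoint distance 2 sin(theta/2) / k <= 0.48 * scale
    kappa_min = 2 * np.sin(theta_side / 2.0) / (0.48 * scale)
    if kappa < kappa_min:
        raise DescriptorError(
            f"unreachable descriptors {(conv, clos, symm)}: arc of curvature "
            f"{kappa:.3f}/deg with turn {theta_side:.2f} rad exceeds the frame "
            f"(needs >= {kappa_min:.3f}/deg)"
        )

    def build(a: float) -> ContourPatch:
        # joint turn/curvature imbalance preserving the total turn (closure)
        # and the mean curvature (convexity)
        th_l, th_r = theta_side * (1 - a), theta_side * (1 + a)
        kl, kr = kappa * (1 - a), kappa * (1 + a)
        return ContourPatch(pid, scale, phi, th_l, th_r,
                            1.0 / kl if kl > 0 else np.inf,
                            1.0 / kr, side_sign, consistency)

    def feasible(a: float) -> bool:
        p = build(a)
        for th, r in ((p.theta_left, p.radius_left),
                      (p.theta_right, p.radius_right)):
            if th > np.pi:
                return False
            if th > 0 and np.isfinite(r) and 2 * r * np.sin(th / 2) > 0.48 * scale:
                return False
        return True

    # bisection on the imbalance a for the symmetry target
    a_max = 0.95
    while a_max > 0 and not feasible(a_max):
        a_max -= 0.05
    lo, hi = 0.0, max(a_max, 0.0)
    s_lo = measure_symmetry(build(lo))
    if symm >= s_lo - tol:
        best = build(lo)
    else:
        s_hi = measure_symmetry(build(hi))
        if symm < s_hi - tol:
            raise DescriptorError(
                f"unreachable descriptors {(conv, clos, symm)}: minimum "
                f"attainable symmetry is {s_hi:.3f}"
            )
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if measure_symmetry(build(mid)) > symm:
                lo = mid
            else:
                hi = mid
        best = build(0.5 * (lo + hi))

    patch = ContourPatch(
        best.id, best.scale, best.tangent_angle, best.theta_left,
        best.theta_right, best.radius_left, best.radius_right,
        best.figure_side, best.consistency, measure_descriptors(best),
    )
    m = patch.mask()
    if not (0 < m.sum() < m.size):
        raise DescriptorError(
            f"unreachable descriptors {(conv, clos, symm)}: degenerate figure mask"
        )
    return patch


def random_patch(seed: int, *, scale: float = DEFAULT_SCALE,
                 id: str | None = None) -> ContourPatch:
    """Draw a patch with descriptor targets sampled uniformly over the
    feasible range of the arc family (the stimulus-set default)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    for attempt in range(20):
        clos = float(rng.uniform(0.02, 0.55))
        theta_side = np.pi * clos
        # minimum curvature keeping the arc inside the frame
        kmin = 2 * np.sin(theta_side / 2.0) / (0.48 * scale)
        cmin = kmin * scale / (1 + kmin * scale)
        if cmin > 0.85:
            continue
        mag = float(rng.uniform(min(cmin + 0.03, 0.85), 0.9))
        conv = mag * (1 if rng.random() < 0.5 else -1)
        # sample the symmetry target within the attainable band for this
        # (conv, clos): measure the asymmetric extreme, then draw between
        kappa = mag / (scale * (1.0 - mag))
        a_probe = 0.9
        probe_hi = ContourPatch("probe", scale, 0.0,
                                theta_side * (1 - a_probe),
                                theta_side * (1 + a_probe),
                                1.0 / (kappa * (1 - a_probe)),
                                1.0 / (kappa * (1 + a_probe)),
                                1 if conv > 0 else -1)
        s_min = measure_symmetry(probe_hi)
        symm = float(rng.uniform(min(s_min + 0.05, 1.0), 1.0))
        try:
            return generate_patch(
                int(rng.integers(2**31)), (conv, clos, symm), scale=scale, id=id
            )
        except DescriptorError:
            continue
    raise DescriptorError(f"random_patch: no feasible patch after 20 draws (seed {seed})")


# ---------------------------------------------------------------------------
# variant enumeration
# ---------------------------------------------------------------------------


def make_variants(
    patch: ContourPatch | SquareBase,
    family: Family,
    *,
    translation_fraction: float = DEFAULT_TRANSLATION_FRACTION,
    consistency: float | None = None,
) -> list[StimulusVariant]:
    """Enumerate the displayed variants of one base for a stimulus family.

    natural: original + mirrored (colour-inverted) -> 2
    filled:  contrast(2) x mirror(2) x translation(2) -> 8
    square:  single/pair(2) x contrast(2) x translation(2) x mirror(2)
             x rotation(4) -> 64
    """
    if family not in ("natural", "filled", "square"):
        raise ValueError(f"make_variants: unsupported family {family!r}")
    offset = translation_fraction * patch.scale
    cons = consistency if consistency is not None else patch.consistency
    out: list[StimulusVariant] = []
    if family == "natural":
        for mir in (False, True):
            out.append(StimulusVariant(
                id=f"{patch.id}:nat:m{int(mir)}", base=patch, family="natural",
                mirrored=mir, color_inverted=mir, consistency=cons,
            ))
    elif family == "filled":
        for contrast in ("dark", "light"):
            for mir in (False, True):
                for tr in (False, True):
                    out.append(StimulusVariant(
                        id=f"{patch.id}:fil:c{contrast[0]}m{int(mir)}t{int(tr)}",
                        base=patch, family="filled", mirrored=mir,
                        translated=tr, offset=offset if tr else 0.0,
                        contrast=contrast, consistency=cons,
                    ))
    else:
        for sp in ("single", "pair"):
            for contrast in ("dark", "light"):
                for tr in (False, True):
                    for mir in (False, True):
                        for rot in range(4):
                            out.append(StimulusVariant(
                                id=(f"{patch.id}:sq:{sp[0]}c{contrast[0]}"
                                    f"t{int(tr)}m{int(mir)}r{rot}"),
                                base=patch, family="square", mirrored=mir,
                                translated=tr, offset=offset if tr else 0.0,
                                contrast=contrast, rotation=rot,
                                single_or_pair=sp, consistency=cons,
                            ))
    return out


@dataclass(frozen=True)
class GratingStimulus:
    """A grating probe for CRF mapping (no FG content)."""

    id: str
    frequency: float      # cycles / degree
    orientation: float    # radians
    position: tuple[float, float]  # degrees


def grating_set(
    *,
    scale: float = DEFAULT_SCALE,
    n_frequencies: int = 3,
    n_orientations: int = 4,
    grid: int = 5,
) -> list[GratingStimulus]:
    """Gratings at frequency x orientation variations on a grid of positions
    (default 3 x 4 x 25 = 300)."""
    freqs = np.array([0.5, 1.0, 2.0])[:n_frequencies]
    oris = np.arange(n_orientations) * np.pi / n_orientations
    coords = np.linspace(-0.3 * scale, 0.3 * scale, grid)
    out = []
    for i, f in enumerate(freqs):
        for j, o in enumerate(oris):
            for k, y in enumerate(coords):
                for l, x in enumerate(coords):
                    out.append(GratingStimulus(
                        id=f"grat:f{i}o{j}p{k * grid + l}",
                        frequency=float(f), orientation=float(o),
                        position=(float(x), float(y)),
                    ))
    return out


@dataclass
class StimulusSet:
    """Ordered variants over all bases, plus grating probes."""

    variants: list[StimulusVariant]
    gratings: list[GratingStimulus] = field(default_factory=list)

    @property
    def family_counts(self) -> dict:
        counts: dict = {}
        for v in self.variants:
            counts[v.family] = counts.get(v.family, 0) + 1
        if self.gratings:
            counts["grating"] = len(self.gratings)
        return counts

    @property
    def ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def scale(self) -> float:
        return self.variants[0].scale if self.variants else DEFAULT_SCALE

    def subset(self, family: Family) -> "StimulusSet":
        return StimulusSet([v for v in self.variants if v.family == family])


def enumerate_set(
    bases: Sequence[ContourPatch],
    families: Iterable[Family],
    *,
    seed: int = 0,
    include_gratings: bool | None = None,
    scale: float | None = None,
) -> StimulusSet:
    """Build the full stimulus set for the requested families.

    With 105 bases the default counts are natural 210, filled 840, square 64
    (one base configuration), grating 300.
    """
    families = list(families)
    scale = scale if scale is not None else (bases[0].scale if bases else DEFAULT_SCALE)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    variants: list[StimulusVariant] = []
    for fam in families:
        if fam == "natural":
            for p in bases:
                variants.extend(make_variants(p, "natural"))
        elif fam == "filled":
            for p in bases:
                variants.extend(make_variants(
                    p, "filled", consistency=_draw_consistency(rng, "filled")
                ))
        elif fam == "square":
            variants.extend(make_variants(SquareBase("square-0", scale), "square"))
        elif fam == "grating":
            pass  # handled below
        else:
            raise ValueError(f"unknown family {fam!r}")
    gratings: list[GratingStimulus] = []
    if "grating" in families or include_gratings:
        gratings = grating_set(scale=scale)
    return StimulusSet(variants, gratings)


def default_bases(
    n: int = 105, *, seed: int = 0, scale: float = DEFAULT_SCALE
) -> list[ContourPatch]:
    """The default 105 synthetic contour bases (deterministic given seed)."""
    ss = np.random.SeedSequence(seed, spawn_key=(11,))
    child_seeds = ss.generate_state(n)
    return [
        random_patch(int(s) % (2**31), scale=scale, id=f"base-{i:03d}")
        for i, s in enumerate(child_seeds)
    ]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def manifest(stimset: StimulusSet) -> str:
    """JSON manifest of variant metadata (masks are regenerated, not stored)."""
    rows = [
        {
            "id": v.id, "base_id": v.base_id, "family": v.family,
            "mirrored": v.mirrored, "translated": v.translated,
            "offset": v.offset, "contrast": v.contrast, "rotation": v.rotation,
            "single_or_pair": v.single_or_pair, "scale": v.scale,
            "consistency": round(v.consistency, 6),
        }
        for v in stimset.variants
    ]
    return json.dumps(
        {"family_counts": stimset.family_counts, "variants": rows},
        indent=1, sort_keys=True,
    )
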