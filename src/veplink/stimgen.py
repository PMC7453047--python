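"""Gaborized ellipse display generation.

A display is a field of non-overlapping Gabor elements on a grey background
in which an ellipsoid shape is defined by a contour cue (elements tangent to
the ellipse outline), a surface cue (iso-oriented elements inside the
outline), or both.  Cue reliability is degraded by adding Gaussian
orientation jitter to the cue-carrying elements.  A density check removes
displays in which local element density differs between the contour,
surface, and background regions, so that density itself cannot be used to
find the shape.

Orientation convention: degrees away from vertical, positive clockwise.
Gabor orientation is 180-degree periodic; stored orientations are kept
unwrapped so that jitter draws can be recovered exactly from the element
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "StimulusConfig",
    "GaborElement",
    "StimulusDisplay",
    "DensityReport",
    "generate_display",
    "generate_accepted_display",
    "density_check",
    "render_display",
    "make_noise_mask",
    "PackingError",
]

CONDITIONS = ("contour_only", "surface_only", "combined")
ORIENTATIONS = ("vertical", "horizontal")


class PackingError(RuntimeError):
    """Raised when elements cannot be packed at the minimum spacing."""


@dataclass
class StimulusConfig:
    """Parameters of one Gaborized display.

    Defaults reproduce the published display design: 590 elements split
    43 (contour) / 150 (surface) / 397 (background), ellipse axis ratio 1.2,
    50% Michelson contrast, and a centre displaced by 0.69 degrees along one
    meridian.
    """

    display_px: int = 1000
    px_per_deg: float = 1000.0 / 17.0
    n_contour: int = 43
    n_surface: int = 150
    n_background: int = 397
    # default ellipse sized so interior/exterior element densities balance
    # under dart-throwing (the density screen then rejects only unlucky draws)
    ellipse_major_deg: float = 11.8
    axis_ratio: float = 1.2
    ellipse_orientation: str = "vertical"
    condition: str = "combined"
    contour_jitter_sd_deg: float = 1.0
    surface_jitter_sd_deg: float = 1.0
    surface_base_orientation_deg: float = -45.0
    nonsurface_base_orientation_deg: float = 45.0
    center_offset_deg: float = 0.69
    gabor_sf_cyc_per_deg: float = 3.0 / 0.7
    gabor_contrast: float = 0.5
    gabor_envelope_sd_arcmin: float = 3.8
    min_center_spacing_px: float = 26.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.ellipse_orientation not in ORIENTATIONS:
            raise ValueError(f"ellipse_orientation must be one of {ORIENTATIONS}")
        if self.axis_ratio <= 1:
            raise ValueError("axis_ratio must be > 1")
        if not 0 <= self.gabor_contrast <= 1:
            raise ValueError("gabor_contrast must lie in [0, 1]")
        if self.contour_jitter_sd_deg < 0 or self.surface_jitter_sd_deg < 0:
            raise ValueError("jitter SDs must be >= 0")
        for name in ("n_contour", "n_surface", "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_contour + self.n_surface + self.n_background


@dataclass
class GaborElement:
    x_px: float
    y_px: float
    orientation_deg: float
    region: str  # contour | surface | background
    tangent_deg: float = math.nan  # defined for contour elements only


@dataclass
class StimulusDisplay:
    config: StimulusConfig
    elements: list[GaborElement]
    center_px: tuple[float, float]
    density_report: "DensityReport | None" = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.elements])

    def positions(self) -> np.ndarray:
        return np.array([[e.x_px, e.y_px] for e in self.elements])

    def region_counts(self) -> dict[str, int]:
        counts = {"contour": 0, "surface": 0, "background": 0}
        for e in self.elements:
            counts[e.region] += 1
        return counts


@dataclass
class DensityReport:
    mean_nn4_by_region: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    accepted: bool
    alpha: float = 0.1


def _ellipse_axes_px(config: StimulusConfig) -> tuple[float, float]:
    """Semi-axes (a along major, b along minor) in pixels."""
    a = 0.5 * config.ellipse_major_deg * config.px_per_deg
    b = a / config.axis_ratio
    return a, b


def _ellipse_xy(theta: np.ndarray, a: float, b: float, vertical: bool) -> tuple[np.ndarray, np.ndarray]:
    """Ellipse points; major axis vertical (y) or horizontal (x). y is up."""
    if vertical:
        return b * np.cos(theta), a * np.sin(theta)
    return a * np.cos(theta), b * np.sin(theta)


def _equal_arc_points(n: int, a: float, b: float, vertical: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """n outline points at equal arc-length spacing, plus tangent orientations.

    Tangent orientation is degrees from vertical, clockwise positive, in
    [0, 180).
    """
    theta = np.linspace(0.0, 2 * np.pi, 20000, endpoint=False)
    x, y = _ellipse_xy(theta, a, b, vertical)
    dx = np.diff(np.append(x, x[0]))
    dy = np.diff(np.append(y, y[0]))
    seg = np.hypot(dx, dy)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]
    targets = np.arange(n) * perimeter / n
    idx = np.searchsorted(cum, targets, side="right") - 1
    px, py = x[idx], y[idx]
    # analytic tangent at the sampled parameter
    th = theta[idx]
    if vertical:
        tx, ty = -b * np.sin(th), a * np.cos(th)
    else:
        tx, ty = -a * np.sin(th), b * np.cos(th)
    tangent_deg = np.degrees(np.arctan2(tx, ty)) % 180.0
    return px, py, tangent_deg


def _inside_ellipse(x: np.ndarray, y: np.ndarray, a: float, b: float, vertical: bool, shrink: float = 1.0) -> np.ndarray:
    if vertical:
        return (x / (b * shrink)) ** 2 + (y / (a * shrink)) ** 2 < 1.0
    return (x / (a * shrink)) ** 2 + (y / (b * shrink)) ** 2 < 1.0


def _dart_throw(
    rng: np.random.Generator,
    n: int,
    accept_fn,
    existing: np.ndarray,
    half: float,
    min_spacing: float,
    max_tries: int,
    region_name: str,
) -> np.ndarray:
    """Place n points uniformly in the display square subject to a region
    predicate and a global minimum-spacing constraint (dart throwing).

    ``max_tries`` bounds the number of consecutive rejected candidates: once
    that many darts in a row fail, the region is deemed too dense to pack and
    a PackingError is raised (fast failure even for absurd requests)."""
    pts = list(existing)
    placed = []
    consecutive = 0
    while len(placed) < n:
        if consecutive >= max_tries:
            raise PackingError(
                f"could not place {n} elements in region {region_name!r} at "
                f"min spacing {min_spacing} px ({max_tries} consecutive "
                f"rejected candidates after {len(placed)} placements)"
            )
        consecutive += 1
        cand = rng.uniform(-half, half, size=2)
        if not accept_fn(cand[0], cand[1]):
            continue
        if pts:
            arr = np.asarray(pts)
            if np.min(np.sum((arr - cand) ** 2, axis=1)) < min_spacing**2:
                continue
        pts.append(cand)
        placed.append(cand)
        consecutive = 0
    return np.asarray(placed)


def generate_display(config: StimulusConfig) -> StimulusDisplay:
    """Generate one Gaborized ellipse display.

    Contour elements sit at equal arc-length spacing on the displaced
    ellipse outline; surface elements are dart-thrown inside the outline and
    background elements outside, all respecting the global minimum centre
    spacing.  Orientations follow the condition: cue-carrying elements take
    their base orientation (outline tangent for contour, the iso-orientation
    for surface) plus i.i.d. Gaussian jitter; non-cue elements are uniform
    random, except in the surface-only condition where contour and
    background elements take the non-surface base orientation.
    """
    rng = np.random.default_rng(config.seed)
    half = config.display_px / 2.0
    a, b = _ellipse_axes_px(config)
    vertical = config.ellipse_orientation == "vertical"

    # displaced center: one of 4 meridian offsets, seeded
    off = config.center_offset_deg * config.px_per_deg
    direction = rng.integers(4)
    center = [(off, 0.0), (-off, 0.0), (0.0, off), (0.0, -off)][direction]
    cx, cy = center

    # contour ring
    px, py, tangent = _equal_arc_points(config.n_contour, a, b, vertical)
    px, py = px + cx, py + cy
    contour_xy = np.column_stack([px, py])
    extent = np.max(np.abs(contour_xy))
    if extent > half:
        raise ValueError("ellipse (with center offset) exceeds the display square")

    def inside(x, y):
        return bool(_inside_ellipse(np.asarray(x - cx), np.asarray(y - cy), a, b, vertical, shrink=0.97))

    def outside(x, y):
        return not _inside_ellipse(np.asarray(x - cx), np.asarray(y - cy), a, b, vertical, shrink=1.03)

    max_tries_per_el = 4000
    surface_xy = _dart_throw(
        rng, config.n_surface, inside, contour_xy, half,
        config.min_center_spacing_px, max_tries_per_el, "surface",
    )
    existing = np.vstack([contour_xy, surface_xy]) if len(surface_xy) else contour_xy
    background_xy = _dart_throw(
        rng, config.n_background, outside, existing, half,
        config.min_center_spacing_px, max_tries_per_el, "background",
    )

    # orientations
    cond = config.condition
    contour_active = cond in ("contour_only", "combined")
    surface_active = cond in ("surface_only", "combined")

    if contour_active:
        contour_ori = tangent + rng.normal(0.0, config.contour_jitter_sd_deg, size=config.n_contour)
    elif cond == "surface_only":
        contour_ori = np.full(config.n_contour, config.nonsurface_base_orientation_deg)
    else:
        contour_ori = rng.uniform(0.0, 180.0, size=config.n_contour)

    if surface_active:
        surface_ori = config.surface_base_orientation_deg + rng.normal(
            0.0, config.surface_jitter_sd_deg, size=config.n_surface
        )
    else:
        surface_ori = rng.uniform(0.0, 180.0, size=config.n_surface)

    if cond == "surface_only":
        background_ori = np.full(config.n_background, config.nonsurface_base_orientation_deg)
    else:
        background_ori = rng.uniform(0.0, 180.0, size=config.n_background)

    elements = [
        GaborElement(x, y, o, "contour", t)
        for (x, y), o, t in zip(contour_xy, contour_ori, tangent)
    ]
    elements += [GaborElement(x, y, o, "surface") for (x, y), o in zip(surface_xy, surface_ori)]
    elements += [GaborElement(x, y, o, "background") for (x, y), o in zip(background_xy, background_ori)]
    return StimulusDisplay(config=config, elements=elements, center_px=(cx, cy))


def density_check(display: StimulusDisplay, alpha: float = 0.1, within_region: bool = False) -> DensityReport:
    """Welch-t screen for local density differences between regions.

    For each element, the mean Euclidean distance to its 4 nearest
    neighbors is computed (over all elements by default; ``within_region``
    restricts the neighbor search to the element's own region).  Each region
    pair is compared with an unequal-variance two-sample t-test; the display
    is accepted iff every pairwise p exceeds ``alpha``.
    """
    frame = display.to_frame()
    regions = ("contour", "surface", "background")
    for r in regions:
        if (frame["region"] == r).sum() < 5:
            raise ValueError(f"region {r!r} has fewer than 5 elements")
    xy = frame[["x_px", "y_px"]].to_numpy()
    per_element = np.empty(len(frame))
    if within_region:
        for r in regions:
            mask = (frame["region"] == r).to_numpy()
            tree = cKDTree(xy[mask])
            d, _ = tree.query(xy[mask], k=5)
            per_element[mask] = d[:, 1:].mean(axis=1)
    else:
        tree = cKDTree(xy)
        d, _ = tree.query(xy, k=5)
        per_element = d[:, 1:].mean(axis=1)

    samples = {r: per_element[(frame["region"] == r).to_numpy()] for r in regions}
    pairwise = {}
    for i in range(3):
        for j in range(i + 1, 3):
            ri, rj = regions[i], regions[j]
            res = stats.ttest_ind(samples[ri], samples[rj], equal_var=False)
            pairwise[(ri, rj)] = float(res.pvalue)
    accepted = all(p > alpha for p in pairwise.values())
    means = {r: float(samples[r].mean()) for r in regions}
    return DensityReport(mean_nn4_by_region=means, pairwise_p=pairwise, accepted=accepted, alpha=alpha)


def generate_accepted_display(config: StimulusConfig, alpha: float = 0.1, max_attempts: int = 50) -> StimulusDisplay:
    """Generate displays until one passes the density check."""
    for attempt in range(max_attempts):
        cfg = StimulusConfig(**{**asdict(config), "seed": config.seed + attempt})
        disp = generate_display(cfg)
        report = density_check(disp, alpha=alpha)
        if report.accepted:
            disp.density_report = report
            return disp
    raise PackingError(f"no display passed the density check in {max_attempts} attempts")


def _render_gabor_patch(
    size: int,
    orientation_deg: float,
    sf_cyc_per_px: float,
    sigma_px: float,
    contrast: float,
    phase: float,
) -> np.ndarray:
    """Signed Gabor patch (values in [-contrast/2 .. +contrast/2] * ...).

    The grating is an oriented sine wave; ``phase`` = pi/2 puts a luminance
    peak at the patch centre.  Bars run along the element orientation (0 =
    vertical, clockwise positive); the wave vector is perpendicular to them.
    """
    r = size // 2
    yy, xx = np.mgrid[-r : size - r, -r : size - r].astype(float)
    # image rows increase downward; convert to math coords with y up
    y = -yy
    x = xx
    th = math.radians(orientation_deg)
    # coordinate along the wave vector (perpendicular to the bars)
    u = x * math.cos(th) - y * math.sin(th)
    grating = np.sin(2 * np.pi * sf_cyc_per_px * u + phase)
    envelope = np.exp(-(x**2 + y**2) / (2 * sigma_px**2))
    return 0.5 * contrast * grating * envelope


def render_display(display: StimulusDisplay, phases: np.ndarray | None = None) -> np.ndarray:
    """Render the display to a grayscale matrix in [0, 1].

    Each Gabor is the product of an oriented sine grating (Michelson
    contrast ``gabor_contrast``, uniform-random phase seeded from the
    config) and a circular Gaussian envelope, added onto a mid-grey
    background and clipped to [0, 1].
    """
    cfg = display.config
    n = cfg.display_px
    img = np.full((n, n), 0.5)
    sigma_px = cfg.gabor_envelope_sd_arcmin / 60.0 * cfg.px_per_deg
    sf_px = cfg.gabor_sf_cyc_per_deg / cfg.px_per_deg
    patch_size = int(2 * math.ceil(4 * sigma_px)) + 1
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    if phases is None:
        phases = rng.uniform(0, 2 * np.pi, size=len(display.elements))
    half = n / 2.0
    r = patch_size // 2
    for el, ph in zip(display.elements, phases):
        patch = _render_gabor_patch(patch_size, el.orientation_deg, sf_px, sigma_px, cfg.gabor_contrast, ph)
        # element coords are centered, y up; image row 0 is the top
        col = int(round(el.x_px + half))
        row = int(round(half - el.y_px))
        r0, r1 = max(row - r, 0), min(row - r + patch_size, n)
        c0, c1 = max(col - r, 0), min(col - r + patch_size, n)
        img[r0:r1, c0:c1] += patch[r0 - (row - r) : r1 - (row - r), c0 - (col - r) : c1 - (col - r)]
    return np.clip(img, 0.0, 1.0)


def make_noise_mask(seed: int, size: int = 1000) -> np.ndarray:
    """Uniform-random pixel-noise mask of the given side length."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(size, size))
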