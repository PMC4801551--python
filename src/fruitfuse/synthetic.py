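"""Synthetic tomato-canopy scenes with ground truth.

Real greenhouse imagery of ripening tomatoes is dominated by two
disturbances: spatially varying illumination (strong sunlight washes color
toward white and casts specular highlights) and occlusion of the ripe fruit
by clusters of immature fruit whose hue overlaps the foliage. This module
renders small RGB scenes that exercise exactly those failure modes, with
per-object ground-truth masks, so the recognition pipeline can be evaluated
without a field dataset.

A scene is composed back-to-front: a dull greenhouse backdrop, warm-brown
clutter (dried leaves, equipment), green foliage ellipses, then fruit.
Mature fruit are radially shaded red discs; immature fruit are pale
yellow-green discs that may be placed to overlap a mature fruit. Varying
illumination is a directional multiplicative gain plus a desaturating blend
toward white ("washout") that rises along the light direction; this is what
degrades chromaticity-based features in sunlit scenes, since a purely
multiplicative gain would leave chromaticity untouched. Gaussian pixel
noise is added last.

Every scene is a pure function of its configuration (including the seed):
byte-level reproducibility is part of the contract.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage import draw

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "generate_scene",
    "generate_batch",
    "DISTURBANCE_TAGS",
]

DISTURBANCE_TAGS = ("none", "illumination", "overlap")

# Fruit surface palettes (8-bit channel ranges). Mature fruit is red with
# radial shading. Immature fruit is pale yellow-green: G exceeds R (it is
# green) but R is high, which makes it bright in luma-coupled features and
# hence the pipeline's hardest distractor. Foliage channels are sampled as
# fractions of a green base so leaves stay in a narrow chrominance band,
# while dried-leaf clutter is rendered as small warm specks whose I value
# sits near the fruit's — exactly the noise the area filter must remove.
_MATURE_R = (160.0, 230.0)
_MATURE_G = (30.0, 90.0)
_MATURE_B = (30.0, 70.0)
_FOLIAGE_G = (95.0, 140.0)
_FOLIAGE_RB_FRAC = (0.40, 0.52)  # R and B as fractions of the green base
_CLUTTER_R = (150.0, 190.0)
_CLUTTER_G_FRAC = (0.60, 0.70)
_CLUTTER_B_FRAC = (0.30, 0.40)
_IMMATURE_R = (155.0, 195.0)
_IMMATURE_G_OFFSET = (10.0, 30.0)  # G = R + offset keeps the fruit green
_IMMATURE_B = (70.0, 105.0)

# Greenish greenhouse backdrop: close to foliage in both chrominance
# features so the background stays unimodal for a global threshold.
_BACKDROP = np.array([60.0, 95.0, 70.0])
_HIGHLIGHT = np.array([250.0, 250.0, 245.0])
_WASHOUT_MAX = 0.65  # white-blend fraction at full gradient strength
_GAIN_SPAN = 0.5  # multiplicative gain spans 1 +/- strength * span
_SHADING_DEPTH = 0.35  # fruit rim darkening fraction


@dataclass
class SceneConfig:
    """Parameters of one synthetic canopy scene.

    The default 388 x 260 frame matches a low-cost CMOS harvesting-robot
    camera. ``overlap_fraction`` is the fraction by which an immature
    fruit's center is pulled from external tangency toward the mature
    fruit's center (0 = disjoint, 1 = concentric).
    """

    width: int = 388
    height: int = 260
    n_mature: int = 1
    n_immature: int = 2
    fruit_radius_range: tuple[int, int] = (26, 44)
    overlap_fraction: float = 0.0
    illumination_gradient_strength: float = 0.0
    highlight_probability: float = 0.0
    foliage_density: float = 0.5
    noise_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("scene dimensions must be positive")
        lo, hi = self.fruit_radius_range
        if lo > hi or lo < 1:
            raise ValueError("invalid fruit_radius_range")
        if 2 * hi >= min(self.width, self.height):
            raise ValueError("fruit larger than image")
        for name in (
            "overlap_fraction",
            "illumination_gradient_strength",
            "highlight_probability",
            "foliage_density",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SceneTruth:
    """Rendered scene plus per-object ground truth.

    ``mature_masks`` hold the *visible* (non-occluded) pixels of each mature
    fruit, which is what a pixel classifier can recover; they are pairwise
    disjoint by construction.
    """

    image: np.ndarray  # H x W x 3 uint8
    mature_masks: list[np.ndarray]
    immature_masks: list[np.ndarray]
    disturbance_tag: str
    config: SceneConfig


def _disc(cy: float, cx: float, r: float, shape) -> tuple[np.ndarray, np.ndarray]:
    return draw.disk((cy, cx), r, shape=shape)


def _paint_shaded_disc(canvas, cy, cx, r, color) -> None:
    rr, cc = _disc(cy, cx, r, canvas.shape[:2])
    rho2 = ((rr - cy) ** 2 + (cc - cx) ** 2) / (r * r)
    shade = 1.0 - _SHADING_DEPTH * rho2
    canvas[rr, cc] = np.asarray(color)[None, :] * shade[:, None]


def _sample_positions(rng, cfg, n, radii, existing):
    """Random non-overlapping fruit placements with an in-frame margin."""
    placed = []
    for r in radii:
        for _ in range(200):
            cy = rng.uniform(r + 4, cfg.height - r - 4)
            cx = rng.uniform(r + 4, cfg.width - r - 4)
            if all(
                np.hypot(cy - py, cx - px) >= r + pr + 2 for py, px, pr in existing + placed
            ):
                placed.append((cy, cx, r))
                break
        else:
            raise ValueError("could not place fruit without overlap; scene too crowded")
    return placed


def generate_scene(cfg: SceneConfig) -> SceneTruth:
    """Render one scene; fully determined by ``cfg`` (including its seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    canvas = np.tile(_BACKDROP, (h, w, 1)).astype(np.float64)

    def ellipse(ax_lo, ax_hi):
        return draw.ellipse(
            rng.uniform(0, h),
            rng.uniform(0, w),
            rng.uniform(ax_lo, ax_hi),
            rng.uniform(ax_lo, ax_hi),
            rotation=rng.uniform(0, np.pi),
            shape=(h, w),
        )

    # Foliage strokes (dense enough to hide most of the backdrop), then
    # small dried-leaf specks on top.
    for _ in range(int(cfg.foliage_density * 400)):
        g = rng.uniform(*_FOLIAGE_G)
        color = np.array(
            [g * rng.uniform(*_FOLIAGE_RB_FRAC), g, g * rng.uniform(*_FOLIAGE_RB_FRAC)]
        )
        rr, cc = ellipse(5, 28)
        canvas[rr, cc] = color
    for _ in range(int(cfg.foliage_density * 12)):
        r_col = rng.uniform(*_CLUTTER_R)
        color = np.array(
            [r_col, r_col * rng.uniform(*_CLUTTER_G_FRAC), r_col * rng.uniform(*_CLUTTER_B_FRAC)]
        )
        rr, cc = ellipse(3, 7)
        canvas[rr, cc] = color

    r_lo, r_hi = cfg.fruit_radius_range
    mature_radii = rng.uniform(r_lo, r_hi, size=cfg.n_mature)
    mature_pos = _sample_positions(rng, cfg, cfg.n_mature, mature_radii, [])

    mature_masks = [np.zeros((h, w), dtype=bool) for _ in range(cfg.n_mature)]
    for mask, (cy, cx, r) in zip(mature_masks, mature_pos):
        color = np.array(
            [rng.uniform(*_MATURE_R), rng.uniform(*_MATURE_G), rng.uniform(*_MATURE_B)]
        )
        _paint_shaded_disc(canvas, cy, cx, r, color)
        rr, cc = _disc(cy, cx, r, (h, w))
        mask[rr, cc] = True

    # Immature fruit: attached to a mature fruit when overlapping, placed
    # clear of all fruit otherwise. Drawn after mature fruit so they occlude.
    immature_masks = []
    immature_radii = rng.uniform(r_lo, r_hi, size=cfg.n_immature)
    for idx, r_im in enumerate(immature_radii):
        if cfg.overlap_fraction > 0 and cfg.n_mature > 0:
            # Occluders are no larger than their host and sit at a center
            # distance interpolated from tangency toward the host center,
            # so a moderate overlap never hides the host's center.
            hy, hx, hr = mature_pos[int(rng.integers(cfg.n_mature))]
            r_im = hr * rng.uniform(0.6, 0.9)
            immature_radii[idx] = r_im
            dist = (1.0 - cfg.overlap_fraction) * (hr + r_im)
            for _ in range(60):
                theta = rng.uniform(0, 2 * np.pi)
                cy = hy + dist * np.sin(theta)
                cx = hx + dist * np.cos(theta)
                if r_im + 2 <= cy <= h - r_im - 2 and r_im + 2 <= cx <= w - r_im - 2:
                    break
            cy = float(np.clip(cy, r_im + 2, h - r_im - 2))
            cx = float(np.clip(cx, r_im + 2, w - r_im - 2))
        else:
            occupied = mature_pos + [
                (m.nonzero()[0].mean(), m.nonzero()[1].mean(), rr)
                for m, rr in zip(immature_masks, immature_radii)
                if m.any()
            ]
            cy, cx, _ = _sample_positions(rng, cfg, 1, [r_im], occupied)[0]
        r_col = rng.uniform(*_IMMATURE_R)
        color = np.array(
            [r_col, r_col + rng.uniform(*_IMMATURE_G_OFFSET), rng.uniform(*_IMMATURE_B)]
        )
        _paint_shaded_disc(canvas, cy, cx, r_im, color)
        m = np.zeros((h, w), dtype=bool)
        rr, cc = _disc(cy, cx, r_im, (h, w))
        m[rr, cc] = True
        immature_masks.append(m)
        for mask in mature_masks:  # occluded pixels leave the visible mask
            mask &= ~m

    # Specular highlights: small near-white discs on fruit surfaces.
    all_fruit = mature_pos + [
        ((m.nonzero()[0].mean() if m.any() else 0), (m.nonzero()[1].mean() if m.any() else 0), r)
        for m, r in zip(immature_masks, immature_radii)
    ]
    for cy, cx, r in all_fruit:
        if rng.uniform() < cfg.highlight_probability:
            theta = rng.uniform(0, 2 * np.pi)
            hy = cy + 0.4 * r * np.sin(theta)
            hx = cx + 0.4 * r * np.cos(theta)
            rr, cc = _disc(hy, hx, max(2.0, 0.18 * r), (h, w))
            canvas[rr, cc] = _HIGHLIGHT

    # Directional illumination: multiplicative gain plus desaturating
    # washout toward white, both rising along a random direction.
    s = cfg.illumination_gradient_strength
    if s > 0:
        phi = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        proj = np.cos(phi) * xx / max(w - 1, 1) + np.sin(phi) * yy / max(h - 1, 1)
        t = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)
        gain = 1.0 + s * _GAIN_SPAN * (2.0 * t - 1.0)
        canvas *= gain[..., None]
        wash = (s * _WASHOUT_MAX * t)[..., None]
        canvas = (1.0 - wash) * canvas + wash * 255.0

    if cfg.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, cfg.noise_sigma, size=canvas.shape)

    image = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    tag = _infer_tag(cfg)
    return SceneTruth(
        image=image,
        mature_masks=mature_masks,
        immature_masks=immature_masks,
        disturbance_tag=tag,
        config=cfg,
    )


def _infer_tag(cfg: SceneConfig) -> str:
    if cfg.overlap_fraction > 0:
        return "overlap"
    if cfg.illumination_gradient_strength > 0:
        return "illumination"
    return "none"


# Group presets: each disturbance is studied in isolation, mirroring a
# two-group contrast design. The clean and illumination groups render no
# immature fruit; the overlap group renders a cluster of pale immature
# fruit covering the mature one, with no illumination gradient.
_GROUP_OVERRIDES = {
    "none": dict(
        n_immature=0,
        overlap_fraction=0.0,
        illumination_gradient_strength=0.0,
        highlight_probability=0.0,
    ),
    "illumination": dict(
        n_immature=0,
        overlap_fraction=0.0,
        illumination_gradient_strength=0.8,
        highlight_probability=0.7,
    ),
    "overlap": dict(
        n_immature=2,
        overlap_fraction=0.35,
        illumination_gradient_strength=0.0,
        highlight_probability=0.0,
    ),
}


def generate_batch(
    n: int,
    disturbance_tag: str = "none",
    base_cfg: SceneConfig | None = None,
    seed: int = 0,
) -> list[SceneTruth]:
    """Render ``n`` scenes of one disturbance group with derived seeds.

    Scene i uses seed ``seed + i`` on top of ``base_cfg`` with the group's
    disturbance overrides applied, so batches are reproducible and scenes
    within a batch are independent draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if disturbance_tag not in _GROUP_OVERRIDES:
        raise ValueError(
            f"unknown disturbance {disturbance_tag!r}; expected one of {DISTURBANCE_TAGS}"
        )
    base = base_cfg if base_cfg is not None else SceneConfig()
    overrides = _GROUP_OVERRIDES[disturbance_tag]
    return [
        generate_scene(dataclasses.replace(base, seed=seed + i, **overrides))
        for i in range(n)
    ]
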