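"""Synthetic maximum-intensity-projection scenes with known ground truth.

Each scene emulates the structures the extractor is built for: a candelabra
("menorah") dendritic arbor -- a gently undulating primary branch, equally
spaced perpendicular secondary branches ending in tertiary cross-bars with
short quaternary teeth -- dilated to a tubular tree and rendered over a
noisy, unevenly illuminated background with bright isotropic
"gut granule" blobs.  Granules share the intensity range of the tree but not
its tubular texture, which is exactly the confound that separates a
texture-based extractor from plain intensity thresholding.

The defaults put plain intensity thresholding in a regime of substantial
class overlap (tree 0.55 vs background 0.30 at noise SD 0.15, granules at
0.80) while leaving the tubular texture intact.  All randomness flows from
``SceneConfig.seed``; the same config is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import closing, dilation, disk

from .io_core import BinaryMask, MIPImage, TrainingSet, save_image, save_mask


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene (defaults are the study conditions)."""

    image_size: tuple[int, int] = (512, 512)
    n_secondary: int = 8
    branch_width_px: int = 2  # dilation radius; limbs are ~2*w+1 px wide
    tree_intensity: float = 0.55
    background_level: float = 0.30
    noise_sd: float = 0.15
    n_granules: int = 40
    granule_radius_px: tuple[float, float] = (2.0, 4.0)
    granule_intensity: float = 0.80
    illumination_gradient: float = 0.25
    blur_sigma_px: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tree_intensity <= self.background_level:
            raise ValueError("tree_intensity must exceed background_level")
        lo, hi = self.granule_radius_px
        if not 0 < lo <= hi:
            raise ValueError("granule radius range must satisfy max >= min > 0")
        if self.noise_sd < 0 or self.illumination_gradient < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise, gradient and blur must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(d["image_size"])
        d["granule_radius_px"] = list(d["granule_radius_px"])
        return d


@dataclass
class SyntheticScene:
    """A rendered scene with every ground-truth layer the pipeline can use."""

    image: MIPImage
    truth: BinaryMask
    soma: BinaryMask
    skeleton_truth: BinaryMask
    config: SceneConfig
    granule_centers: np.ndarray  # (n, 2) float (row, col)


def _draw_polyline(canvas: np.ndarray, points: list[tuple[int, int]]) -> None:
    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        canvas[rr, cc] = True


def _menorah_skeleton(
    cfg: SceneConfig, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[int, int], int]:
    """Draw the candelabra skeleton; return (skeleton, soma center, soma radius)."""
    rows, cols = cfg.image_size
    margin = max(6, cfg.branch_width_px + 4)
    skel = np.zeros((rows, cols), dtype=bool)

    # primary: horizontal curve in the lower part with mild undulation
    base_row = int(rows * 0.70)
    c_axis = np.arange(margin, cols - margin)
    amp = rows * 0.012
    phases = rng.uniform(0, 2 * np.pi, size=2)
    undulation = amp * np.sin(2 * np.pi * c_axis / (cols / 1.7) + phases[0]) + (
        amp * 0.6
    ) * np.sin(2 * np.pi * c_axis / (cols / 3.1) + phases[1])
    primary_rows = np.round(base_row + undulation).astype(int)
    pts = list(zip(primary_rows.tolist(), c_axis.tolist()))
    _draw_polyline(skel, pts)

    # secondaries: equally spaced verticals going up, jittered lengths,
    # each capped by a tertiary cross-bar carrying quaternary teeth
    span = cols - 2 * margin
    spacing = span / (cfg.n_secondary + 1)
    sec_len_base = rows * 0.34
    tooth_len = max(5, int(rows * 0.02))
    for k in range(cfg.n_secondary):
        c = int(margin + (k + 1) * spacing)
        r_top_of_primary = int(primary_rows[c - margin])
        length = int(sec_len_base * rng.uniform(0.85, 1.15))
        r_tip = r_top_of_primary - length
        if r_tip - tooth_len - cfg.branch_width_px < 1:
            raise ValueError("tree does not fit in image_size")
        _draw_polyline(skel, [(r_top_of_primary, c), (r_tip, c)])
        # tertiary cross-bar, parallel to the primary
        half_bar = int(spacing * 0.35)
        c0, c1 = max(margin, c - half_bar), min(cols - margin - 1, c + half_bar)
        _draw_polyline(skel, [(r_tip, c0), (r_tip, c1)])
        # quaternary teeth pointing up, spaced to stay resolvable
        tooth_step = max(2 * tooth_len, 12)
        for ct in range(c0 + 3, c1 - 2, tooth_step):
            _draw_polyline(skel, [(r_tip, ct), (r_tip - tooth_len, ct)])

    soma_radius = max(4, rows // 50)
    soma_col = int(margin + 0.18 * span)
    soma_row = int(primary_rows[soma_col - margin])
    return skel, (soma_row, soma_col), soma_radius


def generate_scene(config: SceneConfig | None = None, **overrides) -> SyntheticScene:
    """Render one scene deterministically from its config.

    Pipeline: draw the skeleton, place the soma disk on the primary, dilate
    to the tubular truth, render two-level intensities, add granules, apply
    the illumination ramp, blur, add Gaussian noise, clip to [0, 1].
    """
    cfg = replace(config or SceneConfig(), **overrides)
    rows, cols = cfg.image_size
    rng = np.random.default_rng(cfg.seed)

    skel, (soma_r, soma_c), soma_radius = _menorah_skeleton(cfg, rng)
    # soma rendered as disk(1)-dilation of a smaller disk: a morphologically
    # smooth blob, like the real cell body, with no single-pixel protrusions
    soma = np.zeros((rows, cols), dtype=bool)
    rr, cc = draw_disk((soma_r, soma_c), max(soma_radius - 1, 2), shape=(rows, cols))
    soma[rr, cc] = True
    soma = dilation(soma, disk(1))

    # tubular tree = skeleton dilated to the branch radius; junctions are
    # then webbed by a closing at branch-radius scale, mimicking the smooth
    # fillets where real branches meet (and making the truth a fixed point
    # of tubular-scale morphological smoothing)
    w = cfg.branch_width_px
    tubes = dilation(skel, disk(w)) | soma
    truth = closing(tubes, np.ones((2 * w + 1, 2 * w + 1), dtype=bool))

    img = np.where(truth, cfg.tree_intensity, cfg.background_level).astype(np.float64)

    centers = np.empty((0, 2))
    if cfg.n_granules > 0:
        centers = np.column_stack(
            [
                rng.uniform(2, rows - 2, size=cfg.n_granules),
                rng.uniform(2, cols - 2, size=cfg.n_granules),
            ]
        )
        on_tree = truth[
            centers[:, 0].astype(int).clip(0, rows - 1),
            centers[:, 1].astype(int).clip(0, cols - 1),
        ]
        if on_tree.all():  # guarantee at least one off-tree confound
            bg_locs = np.argwhere(~truth)
            centers[0] = bg_locs[rng.integers(len(bg_locs))]
        radii = rng.uniform(*cfg.granule_radius_px, size=cfg.n_granules)
        rgrid, cgrid = np.mgrid[0:rows, 0:cols]
        blob_field = np.zeros_like(img)
        for (gr, gc), rad in zip(centers, radii):
            sigma = rad / 1.5
            win = int(np.ceil(4 * sigma))
            r0, r1 = max(0, int(gr) - win), min(rows, int(gr) + win + 1)
            c0, c1 = max(0, int(gc) - win), min(cols, int(gc) + win + 1)
            d2 = (rgrid[r0:r1, c0:c1] - gr) ** 2 + (cgrid[r0:r1, c0:c1] - gc) ** 2
            prof = cfg.granule_intensity * np.exp(-d2 / (2 * sigma**2))
            blob_field[r0:r1, c0:c1] = np.maximum(blob_field[r0:r1, c0:c1], prof)
        img = np.maximum(img, blob_field)

    if cfg.illumination_gradient > 0:
        angle = rng.uniform(0, 2 * np.pi)
        rgrid, cgrid = np.mgrid[0:rows, 0:cols]
        proj = (np.cos(angle) * cgrid + np.sin(angle) * rgrid).astype(np.float64)
        proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)
        img = img * (1.0 + cfg.illumination_gradient * (proj - 0.5))

    if cfg.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, cfg.blur_sigma_px)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    return SyntheticScene(
        image=MIPImage(pixels=img, source_id=f"synthetic-{cfg.seed}"),
        truth=BinaryMask(labels=truth.astype(np.uint8), role="ground_truth"),
        soma=BinaryMask(labels=soma.astype(np.uint8), role="soma"),
        skeleton_truth=BinaryMask(labels=skel.astype(np.uint8), role="ground_truth"),
        config=cfg,
        granule_centers=centers,
    )


def generate_dataset(
    n_scenes: int,
    base_config: SceneConfig | None = None,
    jitter: bool = True,
    out_dir: str | Path | None = None,
) -> tuple[TrainingSet, list[BinaryMask]]:
    """Generate a dataset of scenes with per-scene jittered imaging conditions.

    Per-scene seeds derive from ``base_config.seed``; noise SD, granule count
    and illumination gradient are jittered scene-to-scene (like a real
    acquisition series) when ``jitter`` is on.  With ``out_dir`` given, the
    scenes are written in the directory layout the CLI consumes
    (``images/``, ``masks/``, ``somas/`` plus a ``manifest.json``).
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    base = base_config or SceneConfig()
    master = np.random.default_rng(base.seed)
    seeds = master.integers(0, 2**31, size=n_scenes)
    pairs, somas, scenes = [], [], []
    for i in range(n_scenes):
        scene_rng = np.random.default_rng(seeds[i])
        cfg = replace(base, seed=int(seeds[i]))
        if jitter:
            cfg = replace(
                cfg,
                noise_sd=base.noise_sd * scene_rng.uniform(0.8, 1.2),
                n_granules=int(round(base.n_granules * scene_rng.uniform(0.75, 1.25))),
                illumination_gradient=base.illumination_gradient
                * scene_rng.uniform(0.8, 1.2),
            )
        scene = generate_scene(cfg)
        scene.image.source_id = f"scene_{i:02d}"
        pairs.append((scene.image, scene.truth))
        somas.append(scene.soma)
        scenes.append(scene)

    if out_dir is not None:
        out = Path(out_dir)
        for sub in ("images", "masks", "somas"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        manifest = []
        for i, scene in enumerate(scenes):
            name = f"scene_{i:02d}"
            save_image(scene.image, out / "images" / f"{name}.tif")
            save_mask(scene.truth, out / "masks" / f"{name}.png")
            save_mask(scene.soma, out / "somas" / f"{name}.png")
            manifest.append({"name": name, "config": scene.config.to_dict()})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return TrainingSet(pairs), somas
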