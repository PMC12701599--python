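"""Synthetic germination scenes with exactly known root lengths.

Generates petri-dish-style germination images: pea seeds rendered as
ellipses on a filter-paper-like textured background, each with a primary
root drawn as a smooth random cubic spline of configurable pixel width.
The ground-truth arc length of every root is computed at generation time by
dense polyline integration of the generating spline, converted to
millimetres through the pixels-per-mm calibration, so the downstream
contour-based measurement can be validated against an exact reference.

The defaults mirror the acquisition protocol the generator emulates:
30 seeds per dish, pixels-per-mm r = 7 (so a 7-8 mm pea seed spans about
50 px and roots of 2-16 mm span 14-112 px), and a 1024 x 1024 canvas.

What the generator does NOT emulate: photoreal lighting, touching or
crossing roots, lateral roots, and condensation artefacts; an optional
specular-speckle toggle approximates water-surface reflections only
coarsely.  Conclusions from these scenes therefore cover the geometry and
bookkeeping of the pipeline, not segmentation difficulty on real imagery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from skimage import draw as skdraw

from .maskgeom import BinaryMask, Calibration, extract_contours

__all__ = [
    "SceneInstance",
    "SyntheticScene",
    "AugmentationConfig",
    "generate_scene",
    "generate_dataset",
    "augment",
    "split_dataset",
    "export_annotations",
    "import_labelme",
    "import_coco",
    "import_png_masks",
]


@dataclass(frozen=True)
class SceneInstance:
    """One rendered object with its mask, outer polygon and length truths.

    Roots carry two ground-truth lengths: ``true_arc_length_mm`` is the
    dense polyline integral of the continuous generating spline divided by
    r, and ``pixel_arc_length_mm`` is the arc length of the rasterised
    centreline chain (inter-pixel-centre distances) divided by r.  The two
    differ by the chain-code digitisation factor (up to ~8% at 22.5 deg
    orientation, ~5.5% mean over uniform orientations); the half-perimeter
    measurement estimates the latter.
    """

    instance_id: str
    class_label: Literal["seed", "root"]
    mask: BinaryMask
    polygon: tuple[tuple[int, int], ...]  # outer contour, (x, y) pixels
    true_arc_length_mm: float | None = None  # roots only
    pixel_arc_length_mm: float | None = None  # roots only
    truncated: bool = False


@dataclass
class SyntheticScene:
    scene_id: str
    image: np.ndarray  # H x W x 3 uint8
    instances: list[SceneInstance]
    calibration: Calibration
    rng_seed: int

    @property
    def roots(self) -> list[SceneInstance]:
        return [i for i in self.instances if i.class_label == "root"]

    @property
    def seeds(self) -> list[SceneInstance]:
        return [i for i in self.instances if i.class_label == "seed"]


@dataclass(frozen=True)
class AugmentationConfig:
    """Brightness / flip / Gaussian-noise augmentation settings."""

    brightness_delta: float = 0.0
    flip: Literal["none", "mirror", "horizontal"] = "none"
    gaussian_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.gaussian_noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.flip not in ("none", "mirror", "horizontal"):
            raise ValueError(f"unknown flip mode {self.flip!r}")


def _paper_background(shape: tuple[int, int], rng: np.random.Generator,
                      speckle: bool) -> np.ndarray:
    """Light textured field resembling wet filter paper."""
    h, w = shape
    base = np.full((h, w), 205.0)
    # low-frequency mottling
    coarse = rng.normal(0, 1, (max(h // 32, 1), max(w // 32, 1)))
    reps = (math.ceil(h / coarse.shape[0]), math.ceil(w / coarse.shape[1]))
    mottle = np.kron(coarse, np.ones(reps))[:h, :w]
    base += 6.0 * mottle + rng.normal(0, 2.5, (h, w))
    if speckle:
        n_spots = max(1, h * w // 8000)
        ys = rng.integers(0, h, n_spots)
        xs = rng.integers(0, w, n_spots)
        for y, x in zip(ys, xs):
            rr, cc = skdraw.disk((y, x), rng.uniform(1, 3), shape=(h, w))
            base[rr, cc] = 250.0
    img = np.clip(base, 0, 255)
    return np.stack([img, img, np.clip(img - 6, 0, 255)], axis=-1)


def _spline_polyline(ctrl: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Densely sampled cubic spline through control points, (m, 2) array."""
    seglen = np.hypot(*np.diff(ctrl, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seglen)])
    cs = CubicSpline(t, ctrl, axis=0)
    tt = np.linspace(0, t[-1], max(int(t[-1] / step), 2))
    return cs(tt)


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.hypot(*np.diff(poly, axis=0).T).sum())


def _draw_root(poly: np.ndarray, width_px: int,
               shape: tuple[int, int]) -> np.ndarray:
    """Rasterise the spline polyline as a tube of the given pixel width."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    pts = np.round(poly).astype(int)
    if width_px <= 1:
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr, cc = skdraw.line(y0, x0, y1, x1)
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            mask[rr[ok], cc[ok]] = True
    else:
        radius = width_px / 2.0
        for x, y in pts[:: max(1, int(radius))]:
            rr, cc = skdraw.disk((y, x), radius, shape=(h, w))
            mask[rr, cc] = True
        x, y = pts[-1]
        rr, cc = skdraw.disk((y, x), radius, shape=(h, w))
        mask[rr, cc] = True
    return mask


def _grow_root(rng: np.random.Generator, start: np.ndarray, theta0: float,
               target_len_px: float) -> np.ndarray:
    """Random smooth spline polyline of roughly the target arc length."""
    n_ctrl = 5
    seg = target_len_px / (n_ctrl - 1)
    pts = [start.astype(float)]
    theta = theta0
    for _ in range(n_ctrl - 1):
        theta += rng.normal(0, 0.45)
        pts.append(pts[-1] + seg * np.array([math.cos(theta), math.sin(theta)]))
    return _spline_polyline(np.array(pts))


def _in_canvas(poly: np.ndarray, canvas: tuple[int, int],
               margin: float = 2.0) -> bool:
    h, w = canvas
    return bool(
        poly[:, 0].min() >= margin and poly[:, 0].max() <= w - 1 - margin
        and poly[:, 1].min() >= margin and poly[:, 1].max() <= h - 1 - margin
    )


def _clip_polyline(poly: np.ndarray, canvas: tuple[int, int],
                   margin: float = 2.0) -> np.ndarray:
    h, w = canvas
    inside = ((poly[:, 0] >= margin) & (poly[:, 0] <= w - 1 - margin)
              & (poly[:, 1] >= margin) & (poly[:, 1] <= h - 1 - margin))
    if inside.all():
        return poly
    cut = int(np.argmin(inside))  # first sample outside
    return poly[: max(cut, 2)]


def generate_scene(
    n_seeds: int = 30,
    root_length_range_mm: tuple[float, float] = (2.0, 16.0),
    calibration: Calibration = Calibration(),
    rng_seed: int = 0,
    canvas: tuple[int, int] = (1024, 1024),
    root_width_px: tuple[int, int] = (1, 5),
    root_probability: float = 0.9,
    seed_diameter_mm: float = 7.2,
    speckle: bool = False,
    scene_id: str | None = None,
    max_retries: int = 8,
) -> SyntheticScene:
    """Render one germination scene; deterministic given ``rng_seed``.

    Each seed is an ellipse; with probability ``root_probability`` it grows
    one root whose target length is drawn uniformly from
    ``root_length_range_mm``.  Roots that would exit the canvas are redrawn
    up to ``max_retries`` times, then truncated with the truncated arc
    length recorded as the truth.
    """
    if n_seeds < 0:
        raise ValueError("n_seeds must be >= 0")
    lo, hi = root_length_range_mm
    if not (0 < lo <= hi):
        raise ValueError("root length range must be positive")
    rng = np.random.default_rng(rng_seed)
    h, w = canvas
    image = _paper_background((h, w), rng, speckle)
    r = calibration.r
    seed_diam = seed_diameter_mm * r  # px
    margin = seed_diam / 2 + 2
    if 2 * margin >= min(h, w):
        raise ValueError("canvas too small for the configured seed size")

    # place seed centres by rejection sampling with a minimum separation
    centres: list[np.ndarray] = []
    min_sep = 1.3 * seed_diam
    for _ in range(n_seeds * 60):
        if len(centres) >= n_seeds:
            break
        c = rng.uniform([margin, margin], [w - 1 - margin, h - 1 - margin])
        if all(np.hypot(*(c - o)) > min_sep for o in centres):
            centres.append(c)

    instances: list[SceneInstance] = []
    for si, c in enumerate(centres):
        ax_a = seed_diam / 2 * rng.uniform(0.9, 1.1)
        ax_b = seed_diam / 2 * rng.uniform(0.75, 0.95)
        rot = rng.uniform(0, math.pi)
        rr, cc = skdraw.ellipse(c[1], c[0], ax_a, ax_b,
                                shape=(h, w), rotation=rot)
        seed_mask = np.zeros((h, w), dtype=bool)
        seed_mask[rr, cc] = True
        image[seed_mask] = (
            np.array([196.0, 188.0, 120.0]) + rng.normal(0, 4, 3)
        ).clip(0, 255)

        root_inst = None
        if rng.uniform() < root_probability:
            target_mm = rng.uniform(lo, hi)
            theta0 = rng.uniform(0, 2 * math.pi)
            # emerge just outside the seed ellipse
            edge = c + (max(ax_a, ax_b) + 1.5) * np.array(
                [math.cos(theta0), math.sin(theta0)]
            )
            poly, truncated = None, False
            for _ in range(max_retries):
                theta_try = rng.uniform(0, 2 * math.pi)
                edge = c + (max(ax_a, ax_b) + 1.5) * np.array(
                    [math.cos(theta_try), math.sin(theta_try)]
                )
                cand = _grow_root(rng, edge, theta_try, target_mm * r)
                if _in_canvas(cand, (h, w)):
                    poly = cand
                    break
            if poly is None:  # retries exhausted: truncate at the canvas edge
                poly = _clip_polyline(cand, (h, w))
                truncated = True
            width = int(rng.integers(root_width_px[0], root_width_px[1] + 1))
            root_mask = _draw_root(poly, width, (h, w))
            root_mask &= ~seed_mask  # the root mask is the region outside the seed
            chain = np.round(poly).astype(int)
            keep = np.ones(len(chain), dtype=bool)
            keep[1:] = (np.diff(chain, axis=0) != 0).any(axis=1)
            pixel_arc = _polyline_length(chain[keep].astype(float))
            if root_mask.any():
                image[root_mask] = (
                    np.array([236.0, 233.0, 224.0]) + rng.normal(0, 3, 3)
                ).clip(0, 255)
                root_inst = SceneInstance(
                    instance_id=f"root-{si}",
                    class_label="root",
                    mask=BinaryMask(root_mask),
                    polygon=_outer_polygon(root_mask),
                    true_arc_length_mm=_polyline_length(poly) / r,
                    pixel_arc_length_mm=pixel_arc / r,
                    truncated=truncated,
                )
        instances.append(
            SceneInstance(
                instance_id=f"seed-{si}",
                class_label="seed",
                mask=BinaryMask(seed_mask),
                polygon=_outer_polygon(seed_mask),
            )
        )
        if root_inst is not None:
            instances.append(root_inst)

    return SyntheticScene(
        scene_id=scene_id or f"scene-{rng_seed}",
        image=image.astype(np.uint8),
        instances=instances,
        calibration=calibration,
        rng_seed=rng_seed,
    )


def _outer_polygon(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    contours = extract_contours(BinaryMask(mask))
    return contours[0].points if contours else ()


def generate_dataset(
    n_scenes: int,
    rng_seed: int = 0,
    **scene_kwargs,
) -> list[SyntheticScene]:
    """A list of scenes with per-scene seeds spawned from one master seed."""
    ss = np.random.SeedSequence(rng_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_scenes)]
    return [
        generate_scene(rng_seed=s, scene_id=f"scene-{i:04d}", **scene_kwargs)
        for i, s in enumerate(child_seeds)
    ]


def _flip_instance(inst: SceneInstance, mode: str, w: int, h: int) -> SceneInstance:
    if mode == "mirror":  # left-right
        grid = inst.mask.grid[:, ::-1]
        poly = tuple((w - 1 - x, y) for x, y in inst.polygon)
    else:  # horizontal axis flip = up-down
        grid = inst.mask.grid[::-1, :]
        poly = tuple((x, h - 1 - y) for x, y in inst.polygon)
    return replace(inst, mask=BinaryMask(grid.copy()), polygon=poly)


def augment(scene: SyntheticScene, config: AugmentationConfig,
            rng_seed: int = 0) -> SyntheticScene:
    """Apply brightness / flip / Gaussian-noise augmentation.

    Flips transform the label geometry consistently with the image;
    brightness and noise touch pixels only.  True arc lengths are invariant
    under all three.
    """
    rng = np.random.default_rng(rng_seed)
    img = scene.image.astype(float)
    instances = scene.instances
    h, w = img.shape[:2]
    if config.flip == "mirror":
        img = img[:, ::-1]
        instances = [_flip_instance(i, "mirror", w, h) for i in instances]
    elif config.flip == "horizontal":
        img = img[::-1, :]
        instances = [_flip_instance(i, "horizontal", w, h) for i in instances]
    if config.brightness_delta:
        img = img + config.brightness_delta
    if config.gaussian_noise_sigma > 0:
        img = img + rng.normal(0, config.gaussian_noise_sigma, img.shape)
    return SyntheticScene(
        scene_id=f"{scene.scene_id}-aug",
        image=np.clip(img, 0, 255).astype(np.uint8),
        instances=list(instances),
        calibration=scene.calibration,
        rng_seed=scene.rng_seed,
    )


def split_dataset(
    scenes: Sequence,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    rng_seed: int = 0,
) -> tuple[list, list, list]:
    """Deterministic shuffled train/val/test split.

    Validation and test sizes are ``round(fraction * N)``; the remainder
    goes to the training set.  The three parts are disjoint and exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(scenes)
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("fractions leave no room for the training set")
    order = np.random.default_rng(rng_seed).permutation(n)
    train = [scenes[i] for i in order[:n_train]]
    val = [scenes[i] for i in order[n_train : n_train + n_val]]
    test = [scenes[i] for i in order[n_train + n_val :]]
    return train, val, test


# ---------------------------------------------------------------------------
# annotation export / import


def _rle_encode(grid: np.ndarray) -> dict:
    """COCO-style uncompressed RLE (column-major, counts start with zeros)."""
    flat = np.asarray(grid, dtype=np.uint8).flatten(order="F")
    changes = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate([[0], changes, [flat.size]]))
    counts = list(map(int, runs))
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(grid.shape[0]), int(grid.shape[1])], "counts": counts}


def _rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for run in rle["counts"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape((h, w), order="F")


def _rasterise_polygon(points: Sequence[Sequence[float]],
                       shape: tuple[int, int]) -> np.ndarray:
    """Fill a pixel-boundary polygon: interior plus the boundary chain."""
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(points)
    if len(pts) == 0:
        return mask
    rr, cc = skdraw.polygon(pts[:, 1], pts[:, 0], shape=shape)
    mask[rr, cc] = True
    for (x0, y0), (x1, y1) in zip(pts, np.roll(pts, -1, axis=0)):
        rr, cc = skdraw.line(int(y0), int(x0), int(y1), int(x1))
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[ok], cc[ok]] = True
    return mask


def export_annotations(
    scenes: Sequence[SyntheticScene],
    out_dir: str | Path,
    format: Literal["labelme-json", "coco-json", "png-masks"] = "coco-json",
) -> list[Path]:
    """Write scene annotations in the requested dialect; returns the files.

    ``coco-json`` (one file, uncompressed RLE masks) round-trips masks
    exactly; ``png-masks`` writes one label raster per scene; ``labelme-json``
    writes one polygon-annotation file per scene (shapes[].points).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "coco-json":
        images, annotations = [], []
        ann_id = 1
        for i, sc in enumerate(scenes):
            h, w = sc.image.shape[:2]
            images.append({"id": i, "file_name": f"{sc.scene_id}.png",
                           "height": h, "width": w})
            for inst in sc.instances:
                annotations.append({
                    "id": ann_id,
                    "image_id": i,
                    "category_id": 1 if inst.class_label == "seed" else 2,
                    "segmentation": _rle_encode(inst.mask.grid),
                    "area": inst.mask.area,
                    "iscrowd": 0,
                    "true_arc_length_mm": inst.true_arc_length_mm,
                })
                ann_id += 1
        doc = {
            "images": images,
            "annotations": annotations,
            "categories": [{"id": 1, "name": "seed"}, {"id": 2, "name": "root"}],
        }
        path = out_dir / "annotations.json"
        path.write_text(json.dumps(doc))
        written.append(path)
    elif format == "labelme-json":
        for sc in scenes:
            h, w = sc.image.shape[:2]
            doc = {
                "version": "5.0.1",
                "imagePath": f"{sc.scene_id}.png",
                "imageHeight": h,
                "imageWidth": w,
                "shapes": [
                    {
                        "label": inst.class_label,
                        "points": [[float(x), float(y)] for x, y in inst.polygon],
                        "shape_type": "polygon",
                    }
                    for inst in sc.instances
                ],
            }
            path = out_dir / f"{sc.scene_id}.json"
            path.write_text(json.dumps(doc))
            written.append(path)
    elif format == "png-masks":
        # one binary raster per instance: a shared label raster could not
        # represent overlapping instances (root crossing a foreign seed)
        import imageio.v3 as iio

        for sc in scenes:
            meta = []
            for k, inst in enumerate(sc.instances):
                path = out_dir / f"{sc.scene_id}_{k:03d}_mask.png"
                iio.imwrite(path, inst.mask.grid.astype(np.uint8) * 255)
                written.append(path)
                meta.append({"file": path.name, "label": inst.class_label})
            meta_path = out_dir / f"{sc.scene_id}_masks.json"
            meta_path.write_text(json.dumps(meta))
            written.append(meta_path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return written


def import_coco(path: str | Path) -> dict[str, list[tuple[str, BinaryMask]]]:
    """Read a COCO-style file back into {image file name: [(class, mask)]}."""
    doc = json.loads(Path(path).read_text())
    cats = {c["id"]: c["name"] for c in doc["categories"]}
    imgs = {i["id"]: i["file_name"] for i in doc["images"]}
    out: dict[str, list[tuple[str, BinaryMask]]] = {v: [] for v in imgs.values()}
    for ann in doc["annotations"]:
        out[imgs[ann["image_id"]]].append(
            (cats[ann["category_id"]], BinaryMask(_rle_decode(ann["segmentation"])))
        )
    return out


def import_labelme(path: str | Path) -> list[tuple[str, BinaryMask]]:
    """Rasterise a polygon-annotation file back into (class, mask) pairs."""
    doc = json.loads(Path(path).read_text())
    shape = (doc["imageHeight"], doc["imageWidth"])
    return [
        (s["label"], BinaryMask(_rasterise_polygon(s["points"], shape)))
        for s in doc["shapes"]
    ]


def import_png_masks(meta_json: str | Path) -> list[tuple[str, BinaryMask]]:
    """Read one scene's per-instance mask rasters via its _masks.json."""
    import imageio.v3 as iio

    meta_json = Path(meta_json)
    out = []
    for entry in json.loads(meta_json.read_text()):
        raster = iio.imread(meta_json.parent / entry["file"])
        out.append((entry["label"], BinaryMask(raster > 0)))
    return out
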