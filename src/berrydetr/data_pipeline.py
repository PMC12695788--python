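"""Dataset construction: splits, offline augmentation, annotation I/O, synthetic scenes.

Annotations use the YOLO convention: one ``cls cx cy w h`` line per box with
coordinates normalized to [0,1], or COCO JSON with absolute ``[x, y, w, h]``
pixel boxes. The synthetic-scene generator stands in for field photographs of
fruit-laden trees: many small, near-circular red/green berries on a cluttered
green-textured background, with leaf-shaped occluders, dense clusters, and
global illumination variation, with pixel-accurate box labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, rotate as nd_rotate, shift as nd_shift


@dataclass
class AnnotatedImage:
    image_id: str
    image: np.ndarray | None  # HxWx3 uint8 (None for label-only records)
    boxes: list = field(default_factory=list)  # (class, cx, cy, w, h), normalized
    split: str | None = None

    def __post_init__(self):
        for b in self.boxes:
            _, cx, cy, w, h = b
            if not (0 <= cx <= 1 and 0 <= cy <= 1 and 0 < w <= 1 and 0 < h <= 1):
                raise ValueError(f"box out of range or degenerate: {b}")


# ---------------------------------------------------------------------------
# Split


def split_dataset(items, ratios=(0.7, 0.2, 0.1), seed: int = 0):
    """Deterministic 7:2:1-style split: train floor, val round, test remainder."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    items = list(items)
    n = len(items)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(n * ratios[0]))
    n_val = int(np.round(n * ratios[1]))
    n_val = min(n_val, n - n_train)
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train : n_train + n_val]]
    test = [items[i] for i in order[n_train + n_val :]]
    for part, name in ((train, "train"), (val, "val"), (test, "test")):
        for it in part:
            if isinstance(it, AnnotatedImage):
                it.split = name
    return train, val, test


# ---------------------------------------------------------------------------
# Geometry helpers for box transforms


def _clip_boxes(boxes, min_visible: float = 0.2):
    """Clip normalized boxes to the frame; drop those mostly outside."""
    out = []
    for cls, cx, cy, w, h in boxes:
        x1, y1 = cx - w / 2, cy - h / 2
        x2, y2 = cx + w / 2, cy + h / 2
        cx1, cy1 = max(x1, 0.0), max(y1, 0.0)
        cx2, cy2 = min(x2, 1.0), min(y2, 1.0)
        if cx2 <= cx1 or cy2 <= cy1:
            continue
        if (cx2 - cx1) * (cy2 - cy1) < min_visible * w * h:
            continue
        out.append((cls, (cx1 + cx2) / 2, (cy1 + cy2) / 2, cx2 - cx1, cy2 - cy1))
    return out


def flip_horizontal(item: AnnotatedImage) -> AnnotatedImage:
    boxes = [(c, 1.0 - cx, cy, w, h) for c, cx, cy, w, h in item.boxes]
    return AnnotatedImage(item.image_id + "_hflip", item.image[:, ::-1].copy(), boxes, item.split)


def flip_vertical(item: AnnotatedImage) -> AnnotatedImage:
    boxes = [(c, cx, 1.0 - cy, w, h) for c, cx, cy, w, h in item.boxes]
    return AnnotatedImage(item.image_id + "_vflip", item.image[::-1].copy(), boxes, item.split)


def rotate_image(item: AnnotatedImage, angle_deg: float, min_visible=0.2) -> AnnotatedImage:
    img = nd_rotate(item.image, angle_deg, axes=(1, 0), reshape=False, order=1, mode="constant")
    th = np.deg2rad(angle_deg)
    cos, sin = np.cos(th), np.sin(th)
    boxes = []
    for c, cx, cy, w, h in item.boxes:
        xs = np.array([cx - w / 2, cx + w / 2, cx + w / 2, cx - w / 2]) - 0.5
        ys = np.array([cy - h / 2, cy - h / 2, cy + h / 2, cy + h / 2]) - 0.5
        # image rotation by +angle moves content by -angle in coordinates
        xr = cos * xs + sin * ys + 0.5
        yr = -sin * xs + cos * ys + 0.5
        boxes.append((c, (xr.min() + xr.max()) / 2, (yr.min() + yr.max()) / 2,
                      xr.max() - xr.min(), yr.max() - yr.min()))
    return AnnotatedImage(item.image_id + "_rot", img.astype(np.uint8),
                          _clip_boxes(boxes, min_visible), item.split)


def translate_image(item: AnnotatedImage, dx: float, dy: float, min_visible=0.2):
    H, W = item.image.shape[:2]
    img = nd_shift(item.image, (dy * H, dx * W, 0), order=0, mode="constant")
    boxes = [(c, cx + dx, cy + dy, w, h) for c, cx, cy, w, h in item.boxes]
    return AnnotatedImage(item.image_id + "_shift", img.astype(np.uint8),
                          _clip_boxes(boxes, min_visible), item.split)


def random_crop(item: AnnotatedImage, rng, min_visible=0.2) -> AnnotatedImage:
    H, W = item.image.shape[:2]
    frac = rng.uniform(0.7, 0.9)
    ch, cw = int(H * frac), int(W * frac)
    y0 = rng.integers(0, H - ch + 1)
    x0 = rng.integers(0, W - cw + 1)
    crop = item.image[y0 : y0 + ch, x0 : x0 + cw]
    from PIL import Image

    img = np.asarray(Image.fromarray(crop).resize((W, H), Image.BILINEAR))
    boxes = []
    for c, cx, cy, w, h in item.boxes:
        boxes.append((c, (cx * W - x0) / cw, (cy * H - y0) / ch, w * W / cw, h * H / ch))
    return AnnotatedImage(item.image_id + "_crop", img, _clip_boxes(boxes, min_visible),
                          item.split)


def _photometric(item: AnnotatedImage, rng, kind: str) -> AnnotatedImage:
    img = item.image.astype(float)
    if kind == "blur":
        img = gaussian_filter(img, sigma=(rng.uniform(0.8, 2.0),) * 2 + (0,))
    elif kind == "noise":
        img = img + rng.normal(0, rng.uniform(5, 15), img.shape)
    elif kind == "brightness":
        img = img * rng.uniform(0.6, 1.4)
    elif kind == "occlusion":
        H, W = img.shape[:2]
        for _ in range(rng.integers(1, 4)):
            ph, pw = int(H * rng.uniform(0.05, 0.2)), int(W * rng.uniform(0.05, 0.2))
            y0 = rng.integers(0, max(H - ph, 1))
            x0 = rng.integers(0, max(W - pw, 1))
            img[y0 : y0 + ph, x0 : x0 + pw] = rng.uniform(20, 90, 3)
    return AnnotatedImage(item.image_id + "_" + kind,
                          np.clip(img, 0, 255).astype(np.uint8),
                          list(item.boxes), item.split)


AUGMENT_OPS = ("rotate", "hflip", "vflip", "translate", "blur", "noise",
               "brightness", "crop", "occlusion")


def augment_offline(items, factor: int = 4, seed: int = 0, min_visible: float = 0.2):
    """Offline expansion to factor x |items| (originals included in the total).

    Each extra copy applies one operation drawn from the menu: geometric
    (rotation, flips, translation, crop) with box-consistent transforms, or
    photometric (Gaussian blur/noise, brightness, local occlusion).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    out = list(items)
    for item in items:
        for _ in range(factor - 1):
            op = AUGMENT_OPS[rng.integers(len(AUGMENT_OPS))]
            if op == "rotate":
                aug = rotate_image(item, rng.uniform(-25, 25), min_visible)
            elif op == "hflip":
                aug = flip_horizontal(item)
            elif op == "vflip":
                aug = flip_vertical(item)
            elif op == "translate":
                aug = translate_image(item, rng.uniform(-0.2, 0.2), rng.uniform(-0.2, 0.2),
                                      min_visible)
            elif op == "crop":
                aug = random_crop(item, rng, min_visible)
            else:
                aug = _photometric(item, rng, op)
            out.append(aug)
    return out


# ---------------------------------------------------------------------------
# Annotation I/O


def write_yolo(item: AnnotatedImage, path):
    lines = [
        f"{int(c)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}" for c, cx, cy, w, h in item.boxes
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo(path, image: np.ndarray | None = None, image_id: str | None = None):
    path = Path(path)
    boxes = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        raw = raw.strip()
        if not raw:
            continue
        parts = raw.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 'cls cx cy w h', got {raw!r}")
        try:
            cls = int(parts[0])
            cx, cy, w, h = map(float, parts[1:])
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: unparseable number in {raw!r}") from e
        boxes.append((cls, cx, cy, w, h))
    return AnnotatedImage(image_id or path.stem, image, boxes)


def yolo_to_coco_box(box, width: int, height: int):
    """(cls, cx, cy, w, h) normalized -> absolute [x, y, w, h]."""
    _, cx, cy, w, h = box
    return [(cx - w / 2) * width, (cy - h / 2) * height, w * width, h * height]


def write_coco(items, path, image_sizes=None, category_names=("berry",)):
    """items: AnnotatedImage list; image_sizes: {image_id: (H, W)} if images absent."""
    images, anns = [], []
    aid = 1
    for i, item in enumerate(items, start=1):
        if item.image is not None:
            H, W = item.image.shape[:2]
        else:
            H, W = image_sizes[item.image_id]
        images.append({"id": i, "file_name": f"{item.image_id}.png", "height": H, "width": W})
        for box in item.boxes:
            x, y, w, h = yolo_to_coco_box(box, W, H)
            anns.append({
                "id": aid, "image_id": i, "category_id": int(box[0]) + 1,
                "bbox": [round(v, 4) for v in (x, y, w, h)], "area": round(w * h, 4),
                "iscrowd": 0,
            })
            aid += 1
    cats = [{"id": c + 1, "name": n} for c, n in enumerate(category_names)]
    Path(path).write_text(
        json.dumps({"images": images, "annotations": anns, "categories": cats})
    )


def read_coco(path):
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed COCO JSON ({e})") from e
    by_img = {im["id"]: im for im in data["images"]}
    boxes = {im_id: [] for im_id in by_img}
    for a in data["annotations"]:
        im = by_img[a["image_id"]]
        x, y, w, h = a["bbox"]
        boxes[a["image_id"]].append(
            (a["category_id"] - 1, (x + w / 2) / im["width"], (y + h / 2) / im["height"],
             w / im["width"], h / im["height"])
        )
    return [
        AnnotatedImage(Path(im["file_name"]).stem, None, boxes[i])
        for i, im in sorted(by_img.items())
    ]


# ---------------------------------------------------------------------------
# Synthetic orchard scenes


@dataclass
class SceneParams:
    size: int = 640
    berries_mean: float = 18.0  # Poisson mean of berries per image
    radius_range: tuple = (6, 16)  # pixels
    occlusion_fraction: float = 0.3  # fraction of berries partially covered by a leaf
    illumination_range: tuple = (0.6, 1.3)  # global gain (backlight .. frontlight)
    clutter: int = 25  # background leaf/branch shapes
    red_fraction: float = 0.6  # ripe (red) vs green berries
    min_visible: float = 0.25  # drop berries occluded below this visible fraction
    seed: int = 0

    def __post_init__(self):
        if self.radius_range[0] < 2:
            raise ValueError("berry radius must be at least 2 px")
        if not 0 <= self.occlusion_fraction < 1:
            raise ValueError("occlusion fraction must lie in [0,1)")


def _draw_ellipse(img, cy, cx, ry, rx, angle, color, alpha=1.0):
    H, W = img.shape[:2]
    yy, xx = np.mgrid[0:H, 0:W]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    mask = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    img[mask] = (1 - alpha) * img[mask] + alpha * np.asarray(color, dtype=float)
    return mask


def generate_scene(p: SceneParams) -> AnnotatedImage:
    """Render one synthetic orchard image with exact box labels."""
    rng = np.random.default_rng(p.seed)
    S = p.size
    # textured green background
    base = np.zeros((S, S, 3))
    base[..., 1] = 80
    base[..., 0] = 40
    base[..., 2] = 30
    tex = gaussian_filter(rng.normal(0, 1, (S, S)), sigma=S / 40)
    tex = tex / (np.abs(tex).max() + 1e-9)
    img = base + tex[..., None] * np.array([15, 35, 10])
    # background clutter: leaf/branch shapes
    for _ in range(p.clutter):
        cy, cx = rng.uniform(0, S, 2)
        ry = rng.uniform(S / 40, S / 10)
        shade = rng.uniform(0.5, 1.5)
        color = np.array([35, 95, 25]) * shade
        _draw_ellipse(img, cy, cx, ry, ry * rng.uniform(0.2, 0.6), rng.uniform(0, np.pi),
                      color, alpha=rng.uniform(0.5, 0.9))
    # berries (some in dense clusters)
    n = max(0, int(rng.poisson(p.berries_mean)))
    centers = []
    while len(centers) < n:
        if centers and rng.uniform() < 0.35:  # cluster around an existing berry
            base_c = centers[rng.integers(len(centers))]
            c = base_c + rng.normal(0, p.radius_range[1] * 1.5, 2)
        else:
            c = rng.uniform(p.radius_range[1], S - p.radius_range[1], 2)
        if 0 + 2 <= c[0] < S - 2 and 2 <= c[1] < S - 2:
            centers.append(np.asarray(c))
    yy, xx = np.mgrid[0:S, 0:S]
    boxes = []
    berry_masks = []
    for c in centers:
        r = rng.uniform(*p.radius_range)
        red = rng.uniform() < p.red_fraction
        color = (np.array([170, 30, 45]) if red else np.array([120, 150, 60]))
        color = color * rng.uniform(0.8, 1.15)
        d2 = ((yy - c[0]) ** 2 + (xx - c[1]) ** 2) / r**2
        mask = d2 <= 1.0
        # radial shading + specular highlight
        shade = np.clip(1.15 - 0.5 * d2[mask], 0.4, 1.2)
        img[mask] = color[None, :] * shade[:, None]
        hl = ((yy - (c[0] - 0.4 * r)) ** 2 + (xx - (c[1] - 0.4 * r)) ** 2) <= (0.22 * r) ** 2
        img[hl & mask] = np.minimum(img[hl & mask] + 70, 255)
        berry_masks.append((c, r, int(not red), mask))
    # leaf occluders over a fraction of berries
    occluded = np.zeros((S, S), dtype=bool)
    for c, r, cls, mask in berry_masks:
        if rng.uniform() < p.occlusion_fraction:
            off = rng.normal(0, r * 0.8, 2)
            leaf = _draw_ellipse(img, c[0] + off[0], c[1] + off[1],
                                 rng.uniform(r * 0.8, r * 1.8), rng.uniform(r * 0.4, r),
                                 rng.uniform(0, np.pi), np.array([30, 90, 22]), alpha=1.0)
            occluded |= leaf
    for c, r, cls, mask in berry_masks:
        visible = (mask & ~occluded).sum() / max(mask.sum(), 1)
        if visible < p.min_visible:
            continue
        cx, cy = c[1] / S, c[0] / S
        w = h = 2 * r / S
        x1, y1 = max(cx - w / 2, 0), max(cy - h / 2, 0)
        x2, y2 = min(cx + w / 2, 1), min(cy + h / 2, 1)
        boxes.append((cls, (x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1))
    # illumination gain
    gain = rng.uniform(*p.illumination_range)
    img = np.clip(img * gain, 0, 255).astype(np.uint8)
    return AnnotatedImage(f"scene_{p.seed}", img, boxes)


def generate_dataset(n_images: int, params: SceneParams | None = None, seed: int = 0):
    """n_images independent scenes with per-image derived seeds."""
    params = params or SceneParams()
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_images)
    return [generate_scene(replace(params, seed=int(s))) for s in seeds]
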