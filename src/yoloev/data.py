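"""Annotation I/O, augmentation and the synthetic weed-scene generator.

Labels are YOLO text format: one ``class cx cy w h`` line per object,
centre-size normalized to the unit square.  Internally boxes are corner
format in pixels; :mod:`yoloev.boxes` holds the only converters.

The scene generator emulates the structure of field weed/crop datasets —
textured soil-and-foliage backgrounds, many small lobed plant-like objects
of 2-20 classes, partial occlusion — without attempting photorealism.
Labels record each object's painted extent *before* later paints occlude
it, as annotation of occluded objects does in the real datasets.
"""

from __future__ import annotations

import hashlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .boxes import xywhn_to_xyxy, xyxy_to_xywhn

__all__ = ["Sample", "SceneParams", "AugmentParams", "read_yolo_labels",
           "write_yolo_labels", "read_voc_xml", "augment", "generate_scene",
           "generate_dataset", "load_dataset_yaml", "LabelParseError"]


class LabelParseError(ValueError):
    pass


@dataclass
class Sample:
    """An image (H,W,3 uint8) plus normalized centre-size boxes."""
    image: np.ndarray
    boxes: list  # of (class_id, cx, cy, w, h)

    def __post_init__(self):
        for b in self.boxes:
            _, cx, cy, w, h = b
            if not (0 <= cx <= 1 and 0 <= cy <= 1 and 0 < w <= 1 and 0 < h <= 1):
                raise ValueError(f"box outside the unit square: {b}")


@dataclass
class SceneParams:
    image_size: int = 256
    n_classes: int = 3
    objects_min: int = 2
    objects_max: int = 8
    scale_min: float = 0.06     # object size as fraction of image edge
    scale_max: float = 0.35     # log-uniform between min and max
    occlusion_rate: float = 0.3
    texture_cells: int = 8

    def __post_init__(self):
        if not (0 < self.scale_min <= self.scale_max <= 1):
            raise ValueError("need 0 < scale_min <= scale_max <= 1")
        if not 0 <= self.occlusion_rate <= 1:
            raise ValueError("occlusion_rate must lie in [0,1]")
        if self.objects_min > self.objects_max or self.objects_min < 0:
            raise ValueError("invalid objects_per_image range")
        if not 2 <= self.n_classes <= 20:
            raise ValueError("n_classes must lie in 2..20")


@dataclass
class AugmentParams:
    hflip_p: float = 0.5
    vflip_p: float = 0.5
    crop_p: float = 0.5
    crop_min: float = 0.6       # crop edge as fraction of original
    scale_jitter: float = 0.25  # resize factor in [1-j, 1+j]
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.3
    hue: float = 0.03
    min_box_px: float = 2.0
    min_visible_area: float = 0.25


# ------------------------------------------------------------- label io
def read_yolo_labels(path) -> list:
    """Parse a YOLO label file into (class_id, cx, cy, w, h) tuples."""
    out = []
    with open(path) as f:
        for ln, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise LabelParseError(
                    f"{path}: line {ln}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                vals = [float(v) for v in parts[1:]]
            except ValueError as e:
                raise LabelParseError(f"{path}: line {ln}: {e}") from None
            if cid < 0:
                raise LabelParseError(
                    f"{path}: line {ln}: negative class id {cid}")
            if not all(0 <= v <= 1 for v in vals):
                raise LabelParseError(
                    f"{path}: line {ln}: coordinates outside [0,1]: {vals}")
            out.append((cid, *vals))
    return out


def write_yolo_labels(boxes: list, path):
    with open(path, "w") as f:
        for cid, cx, cy, w, h in boxes:
            f.write(f"{int(cid)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}\n")


def read_voc_xml(path, class_names: list) -> list:
    """Read a VOC-layout XML annotation into normalized YOLO tuples."""
    root = ET.parse(path).getroot()
    size = root.find("size")
    w = float(size.findtext("width"))
    h = float(size.findtext("height"))
    out = []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        if name not in class_names:
            raise LabelParseError(f"{path}: unknown class {name!r}")
        bb = obj.find("bndbox")
        x1, y1 = float(bb.findtext("xmin")), float(bb.findtext("ymin"))
        x2, y2 = float(bb.findtext("xmax")), float(bb.findtext("ymax"))
        (cx, cy, bw, bh), = xyxy_to_xywhn(np.array([[x1, y1, x2, y2]]), w, h)
        out.append((class_names.index(name), cx, cy, bw, bh))
    return out


# ------------------------------------------------------------ augmentation
def _rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    x = img.astype(np.float32) / 255.0
    mx, mn = x.max(axis=-1), x.min(axis=-1)
    d = mx - mn
    h = np.zeros_like(mx)
    r, g, b = x[..., 0], x[..., 1], x[..., 2]
    mask = d > 0
    rm = mask & (mx == r)
    gm = mask & (mx == g) & ~rm
    bm = mask & ~rm & ~gm
    h[rm] = ((g - b)[rm] / d[rm]) % 6
    h[gm] = (b - r)[gm] / d[gm] + 2
    h[bm] = (r - g)[bm] / d[bm] + 4
    h /= 6.0
    s = np.where(mx > 0, d / np.maximum(mx, 1e-12), 0.0)
    return np.stack([h, s, mx], axis=-1)


def _hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    h, s, v = hsv[..., 0] % 1.0, hsv[..., 1], hsv[..., 2]
    i = np.floor(h * 6).astype(int) % 6
    f = h * 6 - np.floor(h * 6)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.clip(np.stack([r, g, b], axis=-1) * 255, 0, 255).astype(np.uint8)


def _resize_nearest(img: np.ndarray, h: int, w: int) -> np.ndarray:
    hi = (np.arange(h) * img.shape[0] / h).astype(int)
    wi = (np.arange(w) * img.shape[1] / w).astype(int)
    return img[hi][:, wi]


def augment(sample: Sample, params: AugmentParams | None = None,
            seed: int = 0, return_meta: bool = False):
    """Seeded geometric + photometric augmentation.

    Geometric operations (flips, scale, crop) transform the boxes with the
    pixels; boxes clipped by the crop are dropped when they fall below
    ``min_box_px`` on a side or below ``min_visible_area`` of their
    original area.  Identical seeds give byte-identical outputs.  With
    ``return_meta`` the applied geometric transform is also returned.
    """
    p = params or AugmentParams()
    rng = np.random.default_rng(seed)
    img = sample.image.copy()
    h, w = img.shape[:2]
    meta = {"hflip": False, "vflip": False, "scale": 1.0, "crop": None,
            "orig_hw": (h, w)}
    boxes = xywhn_to_xyxy(np.array([b[1:] for b in sample.boxes]), w, h) \
        if sample.boxes else np.zeros((0, 4))
    cls = np.array([b[0] for b in sample.boxes], dtype=int)
    areas0 = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])

    if rng.random() < p.hflip_p:
        meta["hflip"] = True
        img = img[:, ::-1]
        boxes = boxes[:, [2, 1, 0, 3]] * np.array([-1, 1, -1, 1]) + \
            np.array([w, 0, w, 0])
    if rng.random() < p.vflip_p:
        meta["vflip"] = True
        img = img[::-1]
        boxes = boxes[:, [0, 3, 2, 1]] * np.array([1, -1, 1, -1]) + \
            np.array([0, h, 0, h])

    sc = 1.0 + rng.uniform(-p.scale_jitter, p.scale_jitter)
    nh, nw = max(8, int(round(h * sc))), max(8, int(round(w * sc)))
    meta["scale"] = sc
    if (nh, nw) != (h, w):
        img = _resize_nearest(img, nh, nw)
        boxes = boxes * np.array([nw / w, nh / h, nw / w, nh / h])
        h, w = nh, nw

    if rng.random() < p.crop_p:
        ce = rng.uniform(p.crop_min, 1.0)
        ch, cw = max(8, int(round(h * ce))), max(8, int(round(w * ce)))
        y0 = int(rng.integers(0, h - ch + 1))
        x0 = int(rng.integers(0, w - cw + 1))
        meta["crop"] = (x0, y0, cw, ch)
        img = img[y0:y0 + ch, x0:x0 + cw]
        boxes = boxes - np.array([x0, y0, x0, y0])
        boxes = np.clip(boxes, 0, [cw, ch, cw, ch])
        h, w = ch, cw

    if len(boxes):
        bw = boxes[:, 2] - boxes[:, 0]
        bh = boxes[:, 3] - boxes[:, 1]
        areas = bw * bh
        keep = (bw >= p.min_box_px) & (bh >= p.min_box_px) & \
            (areas >= p.min_visible_area * np.maximum(
                areas0 * (h * w) / max(sample.image.shape[0] *
                                       sample.image.shape[1], 1), 1e-9))
        boxes, cls = boxes[keep], cls[keep]

    if p.hue or p.saturation or p.brightness:
        hsv = _rgb_to_hsv(img)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-p.hue, p.hue)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] *
                              (1 + rng.uniform(-p.saturation, p.saturation)),
                              0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] *
                              (1 + rng.uniform(-p.brightness, p.brightness)),
                              0, 1)
        img = _hsv_to_rgb(hsv)
    if p.contrast:
        mean = img.mean()
        img = np.clip((img - mean) *
                      (1 + rng.uniform(-p.contrast, p.contrast)) + mean,
                      0, 255).astype(np.uint8)

    out_boxes = []
    if len(boxes):
        for c, row in zip(cls, xyxy_to_xywhn(boxes, w, h)):
            out_boxes.append((int(c),) + tuple(np.clip(row, 1e-6, 1.0)))
    result = Sample(np.ascontiguousarray(img), out_boxes)
    return (result, meta) if return_meta else result


# --------------------------------------------------------- scene generator
_CLASS_HUES = np.linspace(0.16, 0.42, 20)  # yellow-green..green palette


def _paint_blob(img, cx, cy, rx, ry, lobes, hue, phase, rng):
    """Paint a lobed plant-like blob; returns its painted extent (xyxy)."""
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = (xx - cx) / rx, (yy - cy) / ry
    r = np.sqrt(dx ** 2 + dy ** 2)
    theta = np.arctan2(dy, dx)
    wobble = 1.0 + 0.35 * np.cos(lobes * theta + phase)
    mask = r <= wobble
    if not mask.any():
        return None
    shade = 0.75 + 0.25 * np.cos(3 * theta + phase)[mask]
    rgb = _hsv_to_rgb(np.stack([
        np.full(mask.sum(), hue, dtype=np.float32),
        np.full(mask.sum(), 0.65, dtype=np.float32),
        (0.45 + 0.3 * shade).astype(np.float32)], axis=-1)[None])[0]
    img[mask] = rgb
    ys, xs = np.nonzero(mask)
    return float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1)


def generate_scene(params: SceneParams | None = None, seed: int = 0) -> Sample:
    """One synthetic field scene with exact pre-occlusion labels."""
    p = params or SceneParams()
    rng = np.random.default_rng(seed)
    s = p.image_size
    # low-frequency soil texture
    cells = rng.uniform(0.25, 0.55, size=(p.texture_cells, p.texture_cells, 3))
    cells[..., 0] *= 1.25  # brownish
    base = _resize_nearest((cells * 255).astype(np.uint8), s, s)
    img = base.astype(np.float32)
    # random elliptical foliage patches
    for _ in range(rng.integers(2, 6)):
        cx, cy = rng.uniform(0, s, 2)
        rx, ry = rng.uniform(s * 0.1, s * 0.35, 2)
        yy, xx = np.mgrid[0:s, 0:s]
        m = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1
        img[m] = img[m] * 0.6 + np.array([40, 90, 35]) * 0.4
    img = np.clip(img, 0, 255).astype(np.uint8)

    n_obj = int(rng.integers(p.objects_min, p.objects_max + 1))
    entries = []
    for _ in range(n_obj):
        frac = np.exp(rng.uniform(np.log(p.scale_min), np.log(p.scale_max)))
        rx = frac * s / 2 * rng.uniform(0.7, 1.3)
        ry = frac * s / 2 * rng.uniform(0.7, 1.3)
        cx = rng.uniform(rx, s - rx)
        cy = rng.uniform(ry, s - ry)
        cid = int(rng.integers(0, p.n_classes))
        lobes = 3 + cid % 5
        ext = _paint_blob(img, cx, cy, rx, ry, lobes,
                          float(_CLASS_HUES[cid]), rng.uniform(0, 2 * np.pi),
                          rng)
        if ext is not None:
            entries.append((cid, ext))
    # occlusion: repaint over a fraction of earlier objects
    n_occ = int(round(p.occlusion_rate * len(entries)))
    for k in range(n_occ):
        cid, (x1, y1, x2, y2) = entries[k]
        ox = (x1 + x2) / 2 + (x2 - x1) * rng.uniform(0.2, 0.5)
        oy = (y1 + y2) / 2 + (y2 - y1) * rng.uniform(-0.3, 0.3)
        orr = max((x2 - x1), (y2 - y1)) * rng.uniform(0.25, 0.45)
        _paint_blob(img, ox, oy, orr, orr, 6, 0.30,
                    rng.uniform(0, 2 * np.pi), rng)

    boxes = []
    for cid, (x1, y1, x2, y2) in entries:
        (cx, cy, bw, bh), = xyxy_to_xywhn(
            np.array([[x1, y1, x2, y2]]), s, s)
        boxes.append((cid, float(np.clip(cx, 0, 1)), float(np.clip(cy, 0, 1)),
                      float(min(bw, 1.0)), float(min(bh, 1.0))))
    return Sample(img, boxes)


# ------------------------------------------------------------ dataset io
def _write_ppm(img: np.ndarray, path):
    """Plain binary PPM writer (dependency-free raster output)."""
    with open(path, "wb") as f:
        f.write(f"P6\n{img.shape[1]} {img.shape[0]}\n255\n".encode())
        f.write(np.ascontiguousarray(img[..., :3], dtype=np.uint8).tobytes())


def read_ppm(path) -> np.ndarray:
    with open(path, "rb") as f:
        assert f.readline().strip() == b"P6"
        w, h = map(int, f.readline().split())
        f.readline()
        return np.frombuffer(f.read(w * h * 3),
                             dtype=np.uint8).reshape(h, w, 3)


def generate_dataset(params: SceneParams, n_train: int, n_val: int,
                     out_dir, seed: int = 0, force: bool = False) -> Path:
    """Write images/{train,val}, labels/{train,val} and a dataset YAML."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty; use force")
    rng = np.random.default_rng(seed)
    for split, n in (("train", n_train), ("val", n_val)):
        (out / "images" / split).mkdir(parents=True, exist_ok=True)
        (out / "labels" / split).mkdir(parents=True, exist_ok=True)
        for i in range(n):
            sample = generate_scene(params, seed=int(rng.integers(2 ** 31)))
            _write_ppm(sample.image, out / "images" / split / f"{i:05d}.ppm")
            write_yolo_labels(sample.boxes,
                              out / "labels" / split / f"{i:05d}.txt")
    meta = {"path": str(out), "train": "images/train", "val": "images/val",
            "nc": params.n_classes,
            "names": [f"plant{c}" for c in range(params.n_classes)],
            "image_size": params.image_size}
    with open(out / "dataset.yaml", "w") as f:
        yaml.safe_dump(meta, f, sort_keys=False)
    return out / "dataset.yaml"


def load_dataset_yaml(path):
    """Load a dataset YAML; returns (meta, split loader).

    The loader maps a split name to a list of (image HxWx3 uint8, labels).
    """
    path = Path(path)
    with open(path) as f:
        meta = yaml.safe_load(f)
    root = Path(meta.get("path", path.parent))
    if not root.is_absolute():
        root = path.parent

    def load_split(split: str):
        img_dir = root / meta[split]
        lbl_dir = root / meta[split].replace("images", "labels")
        out = []
        for img_path in sorted(img_dir.glob("*.ppm")):
            labels = read_yolo_labels(lbl_dir / (img_path.stem + ".txt"))
            out.append((read_ppm(img_path), labels, img_path.stem))
        return out

    return meta, load_split


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
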