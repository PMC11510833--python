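"""Annotation I/O, augmentation geometry and the synthetic scene generator."""

import numpy as np
import pytest

from yoloev.data import (AugmentParams, LabelParseError, Sample, SceneParams,
                         augment, file_checksum, generate_dataset,
                         generate_scene, load_dataset_yaml, read_ppm,
                         read_voc_xml, read_yolo_labels, write_yolo_labels)


# --------------------------------------------------------------- label io
def test_yolo_label_roundtrip(tmp_path, rng):
    boxes = [(int(rng.integers(0, 5)),
              *np.round(rng.uniform(0.2, 0.8, 4), 6)) for _ in range(3)]
    path = tmp_path / "l.txt"
    write_yolo_labels(boxes, path)
    back = read_yolo_labels(path)
    for a, b in zip(boxes, back):
        assert a[0] == b[0]
        assert np.allclose(a[1:], b[1:], atol=1e-6)


def test_empty_label_file(tmp_path):
    (tmp_path / "e.txt").write_text("")
    assert read_yolo_labels(tmp_path / "e.txt") == []
    write_yolo_labels([], tmp_path / "e2.txt")
    assert read_yolo_labels(tmp_path / "e2.txt") == []


@pytest.mark.parametrize("line,msg", [
    ("1 0.5 0.5", "line 1"),                      # wrong arity
    ("-2 0.5 0.5 0.1 0.1", "negative class"),
    ("0 0.5 1.5 0.1 0.1", "outside"),
    ("x 0.5 0.5 0.1 0.1", "line 1"),
])
def test_malformed_label_lines(tmp_path, line, msg):
    p = tmp_path / "bad.txt"
    p.write_text(line + "\n")
    with pytest.raises(LabelParseError, match=msg):
        read_yolo_labels(p)


def test_voc_xml_reader(tmp_path):
    xml = """<annotation><size><width>200</width><height>100</height>
    <depth>3</depth></size>
    <object><name>weed</name><bndbox><xmin>50</xmin><ymin>20</ymin>
    <xmax>150</xmax><ymax>70</ymax></bndbox></object></annotation>"""
    p = tmp_path / "a.xml"
    p.write_text(xml)
    boxes = read_voc_xml(p, ["crop", "weed"])
    assert boxes[0][0] == 1
    assert np.allclose(boxes[0][1:], (0.5, 0.45, 0.5, 0.5))
    with pytest.raises(LabelParseError, match="unknown class"):
        read_voc_xml(p, ["crop"])


# ------------------------------------------------------------ augmentation
def _plain_params(**kw):
    base = dict(hflip_p=0, vflip_p=0, crop_p=0, scale_jitter=0,
                brightness=0, contrast=0, saturation=0, hue=0)
    base.update(kw)
    return AugmentParams(**base)


def test_horizontal_flip_maps_cx(rng):
    img = rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
    s = Sample(img, [(0, 0.3, 0.6, 0.2, 0.1)])
    out = augment(s, _plain_params(hflip_p=1.0), seed=0)
    cid, cx, cy, w, h = out.boxes[0]
    assert np.isclose(cx, 0.7, atol=1e-6)
    assert np.allclose((cy, w, h), (0.6, 0.2, 0.1), atol=1e-6)
    assert np.array_equal(out.image, img[:, ::-1])


def test_vertical_flip_maps_cy(rng):
    img = rng.integers(0, 255, size=(32, 32, 3)).astype(np.uint8)
    s = Sample(img, [(1, 0.5, 0.25, 0.4, 0.3)])
    out = augment(s, _plain_params(vflip_p=1.0), seed=0)
    assert np.isclose(out.boxes[0][2], 0.75, atol=1e-6)


def test_augment_deterministic(rng):
    s = generate_scene(SceneParams(image_size=96), seed=5)
    a = augment(s, seed=42)
    b = augment(s, seed=42)
    assert np.array_equal(a.image, b.image)
    assert a.boxes == b.boxes


def test_crop_inverse_transform_oracle(rng):
    """Un-cropping surviving boxes lands within a pixel of the originals."""
    s = generate_scene(SceneParams(image_size=128, objects_min=3,
                                   objects_max=6, occlusion_rate=0.0), seed=2)
    out, meta = augment(s, _plain_params(crop_p=1.0, crop_min=0.7), seed=9,
                        return_meta=True)
    assert meta["crop"] is not None
    x0, y0, cw, ch = meta["crop"]
    from yoloev.boxes import xywhn_to_xyxy
    H0, W0 = meta["orig_hw"]
    origs = xywhn_to_xyxy(np.array([b[1:] for b in s.boxes]), W0, H0)
    crop_edges = np.array([x0, y0, x0 + cw, y0 + ch], dtype=float)
    for b in out.boxes:
        (x1, y1, x2, y2), = xywhn_to_xyxy(np.array([b[1:]]), cw, ch)
        restored = np.array([x1 + x0, y1 + y0, x2 + x0, y2 + y0])
        # coordinates clipped onto the crop boundary are exempt: the crop
        # legitimately cut them
        free = np.abs(restored - crop_edges) > 1.0
        err = min(np.abs(restored - o)[free].max(initial=0.0) for o in origs)
        assert err <= 1.0


def test_augment_never_adds_boxes_and_preserves_dtype(rng):
    s = generate_scene(SceneParams(image_size=96), seed=11)
    for seed in range(5):
        out = augment(s, seed=seed)
        assert len(out.boxes) <= len(s.boxes)
        assert out.image.dtype == np.uint8 and out.image.shape[2] == 3


# ------------------------------------------------------------ generator
def test_scene_exact_object_count_without_occlusion():
    p = SceneParams(image_size=128, objects_min=5, objects_max=5,
                    occlusion_rate=0.0)
    s = generate_scene(p, seed=3)
    assert len(s.boxes) == 5


def test_scene_determinism_and_validity():
    p = SceneParams(image_size=96)
    a, b = generate_scene(p, seed=7), generate_scene(p, seed=7)
    assert np.array_equal(a.image, b.image) and a.boxes == b.boxes
    for cid, cx, cy, w, h in a.boxes:
        assert 0 <= cx <= 1 and 0 <= cy <= 1 and w > 0 and h > 0


def test_scene_labels_roundtrip_through_file(tmp_path):
    s = generate_scene(SceneParams(image_size=96), seed=1)
    write_yolo_labels(s.boxes, tmp_path / "l.txt")
    assert len(read_yolo_labels(tmp_path / "l.txt")) == len(s.boxes)


def test_generator_class_balance():
    """Across many scenes each class frequency stays within 3 sigma of
    uniform."""
    p = SceneParams(image_size=32, n_classes=4, objects_min=2, objects_max=6,
                    occlusion_rate=0.0, texture_cells=4)
    counts = np.zeros(4)
    for seed in range(400):
        for b in generate_scene(p, seed=seed).boxes:
            counts[b[0]] += 1
    n = counts.sum()
    expected = n / 4
    sigma = np.sqrt(n * 0.25 * 0.75)
    assert (np.abs(counts - expected) < 3 * sigma).all(), counts


def test_scene_params_validation():
    with pytest.raises(ValueError):
        SceneParams(scale_min=0.5, scale_max=0.2)
    with pytest.raises(ValueError):
        SceneParams(occlusion_rate=1.5)
    with pytest.raises(ValueError):
        SceneParams(n_classes=1)


# ------------------------------------------------------------ dataset io
def test_generate_dataset_layout_and_reload(tmp_path):
    p = SceneParams(image_size=64, n_classes=3)
    yaml_path = generate_dataset(p, n_train=4, n_val=2, out_dir=tmp_path / "d",
                                 seed=0)
    meta, load_split = load_dataset_yaml(yaml_path)
    assert meta["nc"] == 3 and len(meta["names"]) == 3
    train = load_split("train")
    val = load_split("val")
    assert len(train) == 4 and len(val) == 2
    img, labels, stem = train[0]
    assert img.shape == (64, 64, 3) and img.dtype == np.uint8
    # refuses to overwrite without force
    with pytest.raises(FileExistsError):
        generate_dataset(p, 1, 1, tmp_path / "d", seed=0)


def test_generate_dataset_checksum_determinism(tmp_path):
    p = SceneParams(image_size=48, n_classes=2)
    y1 = generate_dataset(p, 2, 1, tmp_path / "a", seed=5)
    y2 = generate_dataset(p, 2, 1, tmp_path / "b", seed=5)
    f1 = sorted((tmp_path / "a").rglob("*.ppm"))
    f2 = sorted((tmp_path / "b").rglob("*.ppm"))
    assert [file_checksum(f) for f in f1] == [file_checksum(f) for f in f2]


def test_ppm_roundtrip(tmp_path, rng):
    from yoloev.data import _write_ppm
    img = rng.integers(0, 255, size=(20, 30, 3)).astype(np.uint8)
    _write_ppm(img, tmp_path / "x.ppm")
    assert np.array_equal(read_ppm(tmp_path / "x.ppm"), img)
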