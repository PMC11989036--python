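import math

import numpy as np
import pytest

from iccquant.errors import GenerationError, ValidationError
from iccquant.geometry import obb_iou
from iccquant.imgio import read_labels
from iccquant.synthdata import (AUGMENTATIONS, SynthSpec, augment,
                                generate_image, make_dataset, transform_box)


SMALL = SynthSpec(seed=0, width=384, height=384, n_cells=8, n_distractors=10)


class TestGenerateImage:
    def test_no_cells(self):
        img, boxes, _ = generate_image(SynthSpec(seed=1, width=256, height=256,
                                                 n_cells=0, n_distractors=5))
        assert boxes == []
        assert img.pixels.shape == (256, 256, 3)

    def test_deterministic(self):
        a_img, a_boxes, a_mask = generate_image(SMALL)
        b_img, b_boxes, b_mask = generate_image(SMALL)
        np.testing.assert_array_equal(a_img.pixels, b_img.pixels)
        assert a_boxes == b_boxes
        np.testing.assert_array_equal(a_mask, b_mask)

    def test_tissue_fraction_on_target(self):
        spec = SynthSpec(seed=0, width=512, height=512, n_cells=10,
                         tissue_fraction=0.6)
        _, _, mask = generate_image(spec)
        assert mask.mean() == pytest.approx(0.6, abs=0.02)

    def test_boxes_inside_tissue(self):
        img, boxes, mask = generate_image(SMALL)
        for b in boxes:
            # rasterize the box and check >= 95% of it lies on tissue
            yy, xx = np.mgrid[0:384, 0:384]
            c, s = math.cos(b.theta), math.sin(b.theta)
            dx, dy = xx + 0.5 - b.cx, yy + 0.5 - b.cy
            u = dx * c + dy * s
            v = -dx * s + dy * c
            inside = (np.abs(u) <= b.w / 2) & (np.abs(v) <= b.h / 2)
            assert mask[inside].mean() >= 0.95

    def test_pairwise_overlap_bounded(self):
        _, boxes, _ = generate_image(SynthSpec(seed=3, width=512, height=512,
                                               n_cells=20))
        for i, a in enumerate(boxes):
            for b in boxes[i + 1:]:
                assert obb_iou(a, b) < 0.3

    def test_overdense_request_fails(self):
        spec = SynthSpec(seed=0, width=256, height=256, n_cells=500,
                         tissue_fraction=0.3)
        with pytest.raises(GenerationError, match="density"):
            generate_image(spec)

    def test_invalid_spec(self):
        with pytest.raises(ValidationError):
            SynthSpec(tissue_fraction=0.0)
        with pytest.raises(ValidationError):
            SynthSpec(cell_len_range=(50, 20))

    def test_glass_is_near_white(self):
        img, _, mask = generate_image(SMALL)
        glass = img.pixels[~mask]
        assert glass.mean() > 240


class TestAugment:
    def test_seven_transforms(self):
        img, boxes, _ = generate_image(SMALL)
        out = augment(img, boxes)
        assert [name for name, _, _ in out] == [
            "rot90", "rot180", "rot270", "fliph", "flipv",
            "transpose", "antitranspose"]

    def test_rot180_center_mapping(self):
        from iccquant.geometry import canonicalize
        box = canonicalize(10, 10, 6, 3, 0.2)
        affine = dict((n, a) for n, _, a in AUGMENTATIONS)["rot180"]
        t = transform_box(box, affine, 100.0)
        assert (t.cx, t.cy) == (90, 90)
        assert (t.w, t.h) == (6, 3)
        assert t.theta == pytest.approx(0.2)

    def test_flip_reverses_theta(self):
        from iccquant.geometry import canonicalize
        box = canonicalize(30, 40, 8, 4, 0.3)
        affines = dict((n, a) for n, _, a in AUGMENTATIONS)
        for name in ("fliph", "flipv"):
            t = transform_box(box, affines[name], 100.0)
            assert t.theta == pytest.approx(-0.3)

    def test_inverse_recovers_boxes(self, rng):
        # composing each transform with its group inverse is the identity
        from conftest import random_boxes
        inverses = {"rot90": "rot270", "rot270": "rot90"}
        affines = dict((n, a) for n, _, a in AUGMENTATIONS)
        for name, affine in affines.items():
            inv = affines[inverses.get(name, name)]  # others are involutions
            for b in random_boxes(rng, 5, field=100.0):
                back = transform_box(transform_box(b, affine, 100.0), inv, 100.0)
                np.testing.assert_allclose(
                    [back.cx, back.cy, back.w, back.h, back.theta],
                    [b.cx, b.cy, b.w, b.h, b.theta], atol=1e-9)

    def test_box_transform_commutes_with_corner_transform(self, rng):
        # mapping the box then taking corners == mapping the corners
        from conftest import random_boxes
        for name, _, (A, t) in AUGMENTATIONS:
            for b in random_boxes(rng, 5, field=100.0):
                tb = transform_box(b, (A, t), 100.0)
                direct = b.corners() @ A.T + t * 100.0
                np.testing.assert_allclose(
                    sorted(map(tuple, tb.corners())),
                    sorted(map(tuple, direct)), atol=1e-6,
                    err_msg=name)

    def test_image_and_boxes_stay_consistent(self):
        # the transformed ground truth matches what a detector sees in
        # the transformed image: check via the DAB mass inside each box
        from iccquant.detect import separate_stains
        img, boxes, _ = generate_image(SMALL)
        total = separate_stains(img).dab_od.sum()
        for name, aug_img, aug_boxes in augment(img, boxes):
            dab = separate_stains(aug_img).dab_od
            assert dab.sum() == pytest.approx(total, rel=1e-6), name
            for b in aug_boxes:
                yy, xx = np.mgrid[0:384, 0:384]
                c, s = math.cos(b.theta), math.sin(b.theta)
                dx, dy = xx + 0.5 - b.cx, yy + 0.5 - b.cy
                u = dx * c + dy * s
                v = -dx * s + dy * c
                inside = (np.abs(u) <= b.w / 2) & (np.abs(v) <= b.h / 2)
                # every transformed box still sits on strong DAB signal
                assert dab[inside].mean() > 0.1

    def test_preserves_count_and_sides(self):
        img, boxes, _ = generate_image(SMALL)
        for name, _, aug_boxes in augment(img, boxes):
            assert len(aug_boxes) == len(boxes), name
            for a, b in zip(aug_boxes, boxes):
                assert (a.w, a.h) == (b.w, b.h)

    def test_non_square_rejected(self):
        from iccquant.imgio import RasterImage
        img = RasterImage(np.zeros((10, 20, 3), dtype=np.uint8))
        with pytest.raises(ValidationError):
            augment(img, [])


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("ds")
    spec = SynthSpec(seed=0, width=192, height=192, n_cells=3,
                     n_distractors=4)
    info = make_dataset(spec, n_images=10, val_fraction=0.2, out_dir=str(out))
    return out, info


class TestMakeDataset:
    def test_split_counts(self, dataset):
        out, info = dataset
        assert info["n_val"] == 2
        assert info["n_train_bases"] == 8
        assert info["n_train_files"] == 64
        assert len(list((out / "val").glob("*.tif"))) == 2
        assert len(list((out / "train").glob("*.tif"))) == 64

    def test_val_not_augmented(self, dataset):
        out, _ = dataset
        stems = [p.stem for p in (out / "val").glob("*.tif")]
        assert all("_" not in s.replace("img_", "") for s in stems)

    def test_labels_parse_back(self, dataset):
        out, _ = dataset
        for split in ("train", "val"):
            for lab in (out / split).glob("*.txt"):
                boxes = read_labels(str(lab), 192, 192)
                assert all(b.w > 0 and b.h > 0 for b in boxes)

    def test_index_lists_every_file(self, dataset):
        out, info = dataset
        import csv
        with open(info["index"]) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 2 + 64
        assert {r["split"] for r in rows} == {"train", "val"}

    def test_ceiling_rule_tiny_dataset(self, tmp_path):
        spec = SynthSpec(seed=0, width=128, height=128, n_cells=1,
                         n_distractors=0)
        info = make_dataset(spec, n_images=1, val_fraction=0.5,
                            out_dir=str(tmp_path))
        assert info["n_val"] == 1 and info["n_train_bases"] == 0

    def test_deterministic_bytes(self, tmp_path):
        spec = SynthSpec(seed=4, width=128, height=128, n_cells=2,
                         n_distractors=3)
        a, b = tmp_path / "a", tmp_path / "b"
        make_dataset(spec, 2, 0.5, str(a))
        make_dataset(spec, 2, 0.5, str(b))
        for rel in sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file()):
            assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel
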