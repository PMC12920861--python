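"""Dataset I/O, preprocessing, augmentation and patient-grouped folds."""

import json

import numpy as np
import pytest

from conftest import ScriptedRng
from vfpose.data import (
    FrameRecord,
    augment,
    load_dataset,
    make_patient_folds,
    preprocess,
    resize_frame,
    save_dataset,
)
from vfpose.geometry import Keypoint, KeypointTriplet
from vfpose.heatmaps import decode_heatmaps, encode_heatmaps


def tri(lv, rv, a, vis=2):
    return KeypointTriplet(
        LV=Keypoint(*lv, vis), RV=Keypoint(*rv, vis), A=Keypoint(*a, vis)
    )


class TestCocoRoundtrip:
    def test_save_load_preserves_everything(self, tiny_records, tmp_path):
        json_path = save_dataset(tiny_records, tmp_path)
        loaded = load_dataset(tmp_path / "images", json_path)
        assert len(loaded) == len(tiny_records)
        for orig, got in zip(tiny_records, loaded):
            assert got.frame_id == orig.frame_id
            assert got.patient_id == orig.patient_id
            assert got.oncologic == orig.oncologic
            assert got.modality == orig.modality
            assert np.array_equal(got.image, orig.image)
            for name in ("LV", "RV", "A"):
                o, g = getattr(orig.triplet, name), getattr(got.triplet, name)
                assert (g.x, g.y, g.visibility) == (o.x, o.y, o.visibility)

    def test_visibility_zero_rejected_with_frame_id(self, tmp_path):
        rec = FrameRecord(
            image=np.zeros((40, 60, 3), np.uint8),
            triplet=tri((10, 10), (50, 12), (30, 30), vis=2),
            patient_id="p1",
            frame_id="bad_frame",
        )
        path = save_dataset([rec], tmp_path)
        coco = json.loads(path.read_text())
        coco["annotations"][0]["keypoints"][2] = 0  # LV visibility -> 0
        path.write_text(json.dumps(coco))
        with pytest.raises(ValueError, match="bad_frame"):
            load_dataset(tmp_path / "images", path)
        # configurable: explicitly allowing invisible keypoints reads fine
        assert len(load_dataset(tmp_path / "images", path, allow_invisible=True)) == 1

    def test_missing_image_error_names_file(self, tiny_records, tmp_path):
        path = save_dataset(tiny_records[:2], tmp_path)
        victim = tmp_path / "images" / f"{tiny_records[0].frame_id}.png"
        victim.unlink()
        with pytest.raises(FileNotFoundError, match=victim.name):
            load_dataset(tmp_path / "images", path)

    def test_malformed_json_raises(self, tmp_path):
        bad = tmp_path / "annotations.json"
        bad.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            load_dataset(tmp_path, bad)

    def test_wrong_keypoint_count_raises(self, tiny_records, tmp_path):
        path = save_dataset(tiny_records[:1], tmp_path)
        coco = json.loads(path.read_text())
        coco["annotations"][0]["keypoints"] = coco["annotations"][0]["keypoints"][:6]
        path.write_text(json.dumps(coco))
        with pytest.raises(ValueError, match="3 keypoints"):
            load_dataset(tmp_path / "images", path)


class TestPreprocess:
    def _record(self):
        img = np.random.default_rng(0).integers(0, 255, (480, 640, 3), dtype=np.uint8)
        return FrameRecord(
            image=img,
            triplet=tri((320, 240), (0, 0), (100, 100)),
            patient_id="p",
            frame_id="f",
        )

    def test_midpoint_and_origin_map_correctly(self):
        _, t = preprocess(self._record(), target=224)
        assert (t.LV.x, t.LV.y) == (112.0, 112.0)
        assert (t.RV.x, t.RV.y) == (0.0, 0.0)

    def test_channel_means_removed(self):
        img, _ = preprocess(self._record(), target=224)
        assert np.allclose(img.mean(axis=(0, 1)), 0.0, atol=1e-6)

    def test_idempotent_on_normalized_frame(self):
        img, t = preprocess(self._record(), target=224)
        img2, t2 = preprocess((img, t), target=224)
        assert np.allclose(img, img2, atol=1e-6)
        assert (t2.LV.x, t2.LV.y) == (t.LV.x, t.LV.y)


class TestAugment:
    def _frame(self, rng):
        img = rng.random((96, 96, 3)).astype(np.float32)
        return img, tri((60, 70), (30, 68), (46, 20))

    def test_double_horizontal_flip_is_identity(self, rng):
        img, t = self._frame(rng)
        # script: hflip on, everything else off
        script = lambda: ScriptedRng([0.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        img1, t1 = augment(img, t, script())
        img2, t2 = augment(img1, t1, script())
        assert np.allclose(img2, img)
        for name in ("LV", "RV", "A"):
            a, b = getattr(t, name), getattr(t2, name)
            assert (a.x, a.y) == (b.x, b.y)

    def test_horizontal_flip_swaps_lv_rv(self, rng):
        img, t = self._frame(rng)
        _, tf = augment(img, t, ScriptedRng([0.0, 1.0, 1.0, 1.0, 1.0, 1.0]))
        assert (tf.LV.x, tf.LV.y) == (95 - t.RV.x, t.RV.y)
        assert (tf.RV.x, tf.RV.y) == (95 - t.LV.x, t.LV.y)

    def test_rotation_fixes_center_keypoint(self, rng):
        img = rng.random((97, 97, 3)).astype(np.float32)
        t = tri((48, 48), (30, 68), (46, 20))
        # rotation only, 30 degrees
        _, tr = augment(img, t, ScriptedRng([1.0, 1.0, 0.0, 1.0, 1.0, 1.0], [30.0]))
        assert tr.LV.x == pytest.approx(48.0, abs=1e-9)
        assert tr.LV.y == pytest.approx(48.0, abs=1e-9)

    def test_seeded_rng_is_deterministic(self, rng):
        img, t = self._frame(rng)
        out1 = augment(img, t, np.random.default_rng(99))
        out2 = augment(img, t, np.random.default_rng(99))
        assert np.array_equal(out1[0], out2[0])
        assert out1[1] == out2[1]

    @pytest.mark.parametrize("hflip", [0.0, 1.0])
    @pytest.mark.parametrize("vflip", [0.0, 1.0])
    @pytest.mark.parametrize("angle", [None, -27.0, 12.5])
    def test_image_and_keypoint_transforms_agree(self, hflip, vflip, angle):
        """Heatmap consistency under the geometric transforms: augmenting
        an encoded peak image moves its argmax to (within 1 px of) the
        augmented keypoint. The heatmap channel order follows the LV/RV
        label swap on horizontal flip, so decoding after augmentation must
        agree channel-by-channel."""
        t = tri((60, 70), (30, 68), (46, 20))
        stack = encode_heatmaps(t, 96, 96, sigma=3).astype(np.float32)
        rot = 1.0 if angle is None else 0.0
        script = ScriptedRng(
            [hflip, vflip, rot, 1.0, 1.0, 1.0], [] if angle is None else [angle]
        )
        img_aug, t_aug = augment(stack, t, script)
        if hflip == 0.0:
            # the image is a channel stack, not anatomy: flipping swaps the
            # LV/RV labels but not the channels, so swap back for decoding
            img_aug = img_aug[:, :, [0, 1, 2]]
            t_aug = type(t_aug)(LV=t_aug.RV, RV=t_aug.LV, A=t_aug.A)
        dec = decode_heatmaps(np.ascontiguousarray(img_aug), warn_flat=False)
        for name in ("LV", "RV", "A"):
            d, w = getattr(dec, name), getattr(t_aug, name)
            assert abs(d.x - w.x) <= 1.0 + 1e-6
            assert abs(d.y - w.y) <= 1.0 + 1e-6


class TestPatientFolds:
    def _records(self, n_patients, frames_per_patient=3):
        recs = []
        img = np.zeros((24, 32, 3), np.uint8)
        t = tri((5, 5), (20, 6), (12, 18))
        for p in range(n_patients):
            for f in range(frames_per_patient):
                recs.append(
                    FrameRecord(
                        image=img, triplet=t,
                        patient_id=f"p{p}", frame_id=f"p{p}_f{f}",
                    )
                )
        return recs

    def test_no_patient_overlap_many_seeds(self):
        records = self._records(17)
        for seed in range(20):
            for fold in make_patient_folds(records, k=5, seed=seed):
                fold.validate(records)  # disjointness + coverage

    def test_balanced_test_groups_124_patients(self):
        records = self._records(124, frames_per_patient=1)
        folds = make_patient_folds(records, k=5, seed=0)
        sizes = [len(f.test_ids) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 124

    def test_k_equal_patients_gives_single_test_patient(self):
        records = self._records(5)
        folds = make_patient_folds(records, k=5, seed=1)
        for f in folds:
            test_pats = {fid.split("_")[0] for fid in f.test_ids}
            assert len(test_pats) == 1

    def test_same_seed_identical_splits(self):
        records = self._records(12)
        a = make_patient_folds(records, k=4, seed=7)
        b = make_patient_folds(records, k=4, seed=7)
        assert a == b

    def test_k_exceeding_patients_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_patient_folds(self._records(3), k=5)


def test_resize_frame_scales_keypoints_anisotropically():
    img = np.zeros((480, 640, 3), np.uint8)
    _, t = resize_frame(img, tri((640 - 1e-9, 0), (320, 240), (0, 480 - 1e-9)), 224)
    assert t.LV.x == pytest.approx(224, rel=1e-6)
    assert t.A.y == pytest.approx(224, rel=1e-6)
    assert (t.RV.x, t.RV.y) == (112.0, 112.0)
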