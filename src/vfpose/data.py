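"""Frame/annotation I/O, preprocessing, augmentation and CV splitting.

Annotations follow the COCO Keypoint format with a single 3-keypoint
category (LV, RV, A) and visibility flags 0/1/2. Frames are RGB PNG/JPEG.
Cross-validation folds are grouped by patient: no patient contributes
frames to both the test set and the train/validation sets of a fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize as _sk_resize

from .geometry import Keypoint, KeypointTriplet

__all__ = [
    "FrameRecord",
    "FoldSplit",
    "KEYPOINT_NAMES",
    "load_dataset",
    "save_dataset",
    "preprocess",
    "resize_frame",
    "augment",
    "make_patient_folds",
]

KEYPOINT_NAMES = ("LV", "RV", "A")
CATEGORY = {
    "id": 1,
    "name": "glottis",
    "keypoints": list(KEYPOINT_NAMES),
    "skeleton": [[1, 3], [2, 3]],
}


@dataclass
class FrameRecord:
    """One annotated laryngoscopy frame."""

    image: np.ndarray  # (H, W, 3) uint8 RGB
    triplet: KeypointTriplet
    patient_id: str
    frame_id: str
    oncologic: bool = False
    modality: Literal["white_light", "narrow_band"] = "white_light"

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        h, w = self.image.shape[:2]
        for name in KEYPOINT_NAMES:
            kp = getattr(self.triplet, name)
            if not (0 <= kp.x < w and 0 <= kp.y < h):
                raise ValueError(
                    f"frame {self.frame_id}: keypoint {name} ({kp.x}, {kp.y}) "
                    f"outside {w}x{h} image"
                )


@dataclass(frozen=True)
class FoldSplit:
    """Frame-id partition for one cross-validation fold."""

    fold_index: int
    train_ids: frozenset[str]
    val_ids: frozenset[str]
    test_ids: frozenset[str]

    def validate(self, records: Sequence[FrameRecord]) -> None:
        sets = (self.train_ids, self.val_ids, self.test_ids)
        all_ids = {r.frame_id for r in records}
        if set().union(*sets) != all_ids:
            raise ValueError("fold does not cover all frames")
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("fold role sets overlap")
        by_id = {r.frame_id: r.patient_id for r in records}
        test_pat = {by_id[f] for f in self.test_ids}
        dev_pat = {by_id[f] for f in self.train_ids | self.val_ids}
        if test_pat & dev_pat:
            raise ValueError("patient overlap between test and train/val")


# ---------------------------------------------------------------------------
# COCO I/O


def load_dataset(
    images_dir: str | Path,
    annotations_path: str | Path,
    allow_invisible: bool = False,
) -> list[FrameRecord]:
    """Read frames and COCO keypoint annotations into FrameRecords.

    With the default ``allow_invisible=False`` any keypoint flagged
    visibility 0 (annotated as absent) is rejected with a descriptive
    error, since a missing landmark leaves the AGA undefined.
    """
    images_dir = Path(images_dir)
    try:
        with open(annotations_path) as fh:
            coco = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed COCO JSON {annotations_path}: {exc}") from exc

    ann_by_image: dict[int, dict] = {}
    for ann in coco.get("annotations", []):
        ann_by_image[ann["image_id"]] = ann

    records = []
    for img_entry in coco.get("images", []):
        frame_id = str(img_entry.get("frame_id") or Path(img_entry["file_name"]).stem)
        path = images_dir / img_entry["file_name"]
        if not path.exists():
            raise FileNotFoundError(f"frame {frame_id}: image file {path} not found")
        ann = ann_by_image.get(img_entry["id"])
        if ann is None:
            raise ValueError(f"frame {frame_id}: no annotation entry")
        flat = ann["keypoints"]
        if len(flat) != 9:
            raise ValueError(
                f"frame {frame_id}: expected 3 keypoints (9 values), got {len(flat)}"
            )
        kps = {}
        for c, name in enumerate(KEYPOINT_NAMES):
            x, y, v = flat[3 * c : 3 * c + 3]
            if v == 0 and not allow_invisible:
                raise ValueError(
                    f"frame {frame_id}: keypoint {name} has visibility 0 (absent)"
                )
            kps[name] = Keypoint(float(x), float(y), int(v))
        image = np.asarray(Image.open(path).convert("RGB"))
        records.append(
            FrameRecord(
                image=image,
                triplet=KeypointTriplet(LV=kps["LV"], RV=kps["RV"], A=kps["A"]),
                patient_id=str(img_entry.get("patient_id", f"p{img_entry['id']}")),
                frame_id=frame_id,
                oncologic=bool(img_entry.get("oncologic", False)),
                modality=img_entry.get("modality", "white_light"),
            )
        )
    return records


def save_dataset(records: Sequence[FrameRecord], out_dir: str | Path) -> Path:
    """Write frames as PNG plus a COCO keypoint JSON; returns the JSON path."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    images, annotations = [], []
    for i, rec in enumerate(records):
        fname = f"{rec.frame_id}.png"
        Image.fromarray(rec.image).save(img_dir / fname)
        h, w = rec.image.shape[:2]
        images.append(
            {
                "id": i,
                "file_name": fname,
                "width": w,
                "height": h,
                "frame_id": rec.frame_id,
                "patient_id": rec.patient_id,
                "oncologic": rec.oncologic,
                "modality": rec.modality,
            }
        )
        flat: list[float] = []
        for name in KEYPOINT_NAMES:
            kp = getattr(rec.triplet, name)
            flat += [kp.x, kp.y, kp.visibility]
        annotations.append(
            {
                "id": i,
                "image_id": i,
                "category_id": 1,
                "keypoints": flat,
                "num_keypoints": 3,
            }
        )
    coco = {"images": images, "annotations": annotations, "categories": [CATEGORY]}
    json_path = out_dir / "annotations.json"
    with open(json_path, "w") as fh:
        json.dump(coco, fh)
    return json_path


# ---------------------------------------------------------------------------
# preprocessing


def _to_float01(image: np.ndarray) -> np.ndarray:
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    return image.astype(np.float32)


def resize_frame(
    image: np.ndarray, triplet: KeypointTriplet, target: int = 224
) -> tuple[np.ndarray, KeypointTriplet]:
    """Anisotropic bilinear resize to target x target with matching keypoint
    scaling; intensities returned in [0, 1]. Aspect ratio is not preserved
    (640x480 frames map to a square), so pixel errors measured afterwards
    live in target-space."""
    img = _to_float01(image)
    h, w = img.shape[:2]
    if (h, w) != (target, target):
        img = _sk_resize(img, (target, target), order=1, anti_aliasing=h > target)
        img = img.astype(np.float32)
    return img, triplet.scaled(target / w, target / h)


def preprocess(
    record: FrameRecord | tuple[np.ndarray, KeypointTriplet], target: int = 224
) -> tuple[np.ndarray, KeypointTriplet]:
    """Resize to target x target and remove the per-channel mean intensity.

    Accepts a FrameRecord or a raw (image, triplet) pair. Idempotent on an
    already target-sized zero-mean frame.
    """
    if isinstance(record, FrameRecord):
        image, triplet = record.image, record.triplet
    else:
        image, triplet = record
    img, tri = resize_frame(image, triplet, target)
    mean = img.mean(axis=(0, 1), keepdims=True, dtype=np.float64)
    return (img - mean).astype(np.float32), tri


# ---------------------------------------------------------------------------
# augmentation


def _rotate_keypoints(tri: KeypointTriplet, angle_deg: float, h: int, w: int):
    """Rotate keypoints by the same transform skimage applies to the image
    (visually counter-clockwise about the pixel-center image center)."""
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    # y points down, so a visually-CCW image rotation corresponds to a
    # clockwise rotation in (x, y): use angle with flipped sign
    th = np.deg2rad(-angle_deg)
    ct, st = np.cos(th), np.sin(th)
    out = []
    for name in KEYPOINT_NAMES:
        kp = getattr(tri, name)
        dx, dy = kp.x - cx, kp.y - cy
        out.append(
            Keypoint(cx + ct * dx - st * dy, cy + st * dx + ct * dy, kp.visibility)
        )
    return KeypointTriplet(LV=out[0], RV=out[1], A=out[2])


def augment(
    image: np.ndarray,
    triplet: KeypointTriplet,
    rng: np.random.Generator,
    rotation_limit: float = 30.0,
) -> tuple[np.ndarray, KeypointTriplet]:
    """Stochastic training augmentation on a [0, 1] RGB image.

    Each transform fires independently with probability 0.5: horizontal
    flip (which also swaps the LV/RV identities — anatomical left and right
    exchange), vertical flip, rotation up to +-30 deg about the image
    center (resampled up to 5 times, then skipped, if a keypoint would
    leave the frame), brightness shift in [-0.1, 0.1], hue shift in
    [-0.2, 0.2] and saturation scaling in [0.5, 1.5]. Deterministic given
    the generator state.
    """
    from skimage.transform import rotate as _sk_rotate

    img = _to_float01(image).copy()
    tri = triplet
    h, w = img.shape[:2]

    if rng.random() < 0.5:  # horizontal flip: x -> W-1-x, LV <-> RV
        img = img[:, ::-1].copy()
        tri = KeypointTriplet(
            LV=Keypoint(w - 1 - tri.RV.x, tri.RV.y, tri.RV.visibility),
            RV=Keypoint(w - 1 - tri.LV.x, tri.LV.y, tri.LV.visibility),
            A=Keypoint(w - 1 - tri.A.x, tri.A.y, tri.A.visibility),
        )
    if rng.random() < 0.5:  # vertical flip: y -> H-1-y
        img = img[::-1].copy()
        tri = KeypointTriplet(
            LV=Keypoint(tri.LV.x, h - 1 - tri.LV.y, tri.LV.visibility),
            RV=Keypoint(tri.RV.x, h - 1 - tri.RV.y, tri.RV.visibility),
            A=Keypoint(tri.A.x, h - 1 - tri.A.y, tri.A.visibility),
        )
    if rng.random() < 0.5:  # rotation
        for _ in range(5):
            angle = float(rng.uniform(-rotation_limit, rotation_limit))
            cand = _rotate_keypoints(tri, angle, h, w)
            ok = all(
                0 <= getattr(cand, n).x <= w - 1 and 0 <= getattr(cand, n).y <= h - 1
                for n in KEYPOINT_NAMES
            )
            if ok:
                img = _sk_rotate(img, angle, order=1, mode="edge").astype(np.float32)
                tri = cand
                break

    if rng.random() < 0.5:  # brightness
        img = np.clip(img + rng.uniform(-0.1, 0.1), 0.0, 1.0)
    hue_on = rng.random() < 0.5
    sat_on = rng.random() < 0.5
    if hue_on or sat_on:
        hsv = rgb2hsv(img)
        if hue_on:
            hsv[:, :, 0] = (hsv[:, :, 0] + rng.uniform(-0.2, 0.2)) % 1.0
        if sat_on:
            hsv[:, :, 1] = np.clip(hsv[:, :, 1] * rng.uniform(0.5, 1.5), 0.0, 1.0)
        img = hsv2rgb(hsv).astype(np.float32)
    return img.astype(np.float32), tri


# ---------------------------------------------------------------------------
# cross-validation splitting


def make_patient_folds(
    records: Sequence[FrameRecord],
    k: int = 5,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> list[FoldSplit]:
    """Patient-grouped k-fold splits with a held-out validation subset.

    Patients are shuffled with the seed and partitioned into k near-equal
    test groups; within each fold, ``val_fraction`` of the remaining
    training patients (at least one) are held out for early stopping.
    """
    patients = sorted({r.patient_id for r in records})
    if k > len(patients):
        raise ValueError(f"k={k} exceeds the number of patients ({len(patients)})")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(patients, dtype=object)[rng.permutation(len(patients))])
    groups = [list(g) for g in np.array_split(np.array(shuffled, dtype=object), k)]

    frames_by_patient: dict[str, list[str]] = {}
    for r in records:
        frames_by_patient.setdefault(r.patient_id, []).append(r.frame_id)

    folds = []
    for i in range(k):
        test_pat = set(groups[i])
        dev_pat = [p for p in shuffled if p not in test_pat]
        n_val = max(1, int(round(val_fraction * len(dev_pat))))
        val_pat = set(dev_pat[:n_val])
        train_pat = set(dev_pat[n_val:])
        if not train_pat:
            raise ValueError("no training patients left; reduce k or val_fraction")

        def ids(pats):
            return frozenset(f for p in pats for f in frames_by_patient[p])

        folds.append(
            FoldSplit(
                fold_index=i,
                train_ids=ids(train_pat),
                val_ids=ids(val_pat),
                test_ids=ids(test_pat),
            )
        )
    return folds


def export_folds_csv(
    folds: Sequence[FoldSplit], records: Sequence[FrameRecord], path: str | Path
) -> None:
    """Write the fold assignment as CSV (frame_id, patient_id, fold, role)."""
    import csv

    by_id = {r.frame_id: r.patient_id for r in records}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_id", "patient_id", "fold", "role"])
        for fold in folds:
            for role, idset in (
                ("train", fold.train_ids),
                ("val", fold.val_ids),
                ("test", fold.test_ids),
            ):
                for fid in sorted(idset):
                    writer.writerow([fid, by_id[fid], fold.fold_index, role])
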