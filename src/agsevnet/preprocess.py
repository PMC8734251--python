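"""I/O and preprocessing for multi-modal volumes.

Arrays are ordered ``(depth, height, width[, channel])`` with the four
MRI modalities stacked channels-last in the order T1, T1-CE, T2, FLAIR.
On disk, cases follow the BraTS file layout: one NIfTI file per
modality plus an optional segmentation, named ``<case>_<modality>.nii.gz``
and ``<case>_seg.nii.gz``. NIfTI stores axes as (x, y, z) = (width,
height, depth); they are permuted on read and inverted on write, with
the affine carried through unchanged.

Label semantics (BraTS): 0 background, 1 necrotic/gangrene core,
2 peritumoral edema, 4 enhancing tumor. One-hot targets use channel
order (background, gangrene, edema, enhancing), i.e. the label-to-
channel map 0->0, 1->1, 2->2, 4->3. Evaluation regions nest:
ET = {4}, TC = {1, 4}, WT = {1, 2, 4}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantoms import MODALITIES, PhantomCase

LEGAL_LABELS = (0, 1, 2, 4)
#: channel index per label value in one-hot targets
LABEL_TO_CHANNEL = {0: 0, 1: 1, 2: 2, 4: 3}
CHANNEL_TO_LABEL = {v: k for k, v in LABEL_TO_CHANNEL.items()}


@dataclass
class MultiModalVolume:
    """4-channel volume with voxel spacing (mm) and a voxel-to-world affine."""

    data: np.ndarray  # (D, H, W, 4) float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[-1] != 4:
            raise ValueError(
                f"expected (D, H, W, 4) array, got shape {self.data.shape}"
            )


@dataclass
class RegionMasks:
    """Nested binary evaluation regions: et ⊆ tc ⊆ wt."""

    et: np.ndarray
    tc: np.ndarray
    wt: np.ndarray

    REGIONS = ("ET", "TC", "WT")

    def __getitem__(self, region: str) -> np.ndarray:
        return {"ET": self.et, "TC": self.tc, "WT": self.wt}[region.upper()]


@dataclass
class PatchSet:
    """Sliding-window patches with the origins needed for restitching."""

    patches: list  # of (image_patch, target_patch, origin)
    stride: tuple[int, int, int]
    patch_shape: tuple[int, int, int]
    volume_shape: tuple[int, int, int]


def validate_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    bad = sorted(set(np.unique(labels)) - set(LEGAL_LABELS))
    if bad:
        raise ValueError(f"illegal label values {bad}; legal set is {LEGAL_LABELS}")
    return labels


def zscore_normalize(volume: MultiModalVolume,
                     mask_nonzero: bool = True) -> MultiModalVolume:
    """Per-modality z-score normalization, (X - mu) / sigma.

    By default mu and sigma are computed over nonzero voxels only (the
    standard for skull-stripped data, where zeros are air); normalized
    values are written everywhere. Set ``mask_nonzero=False`` for
    whole-volume statistics. A constant channel raises, naming the
    modality.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    out = np.empty_like(data)
    for m, name in enumerate(MODALITIES):
        chan = data[..., m]
        sel = chan[chan != 0] if mask_nonzero else chan.ravel()
        if sel.size == 0:
            raise ValueError(f"modality {name!r}: no voxels selected for statistics")
        mu, sigma = float(sel.mean()), float(sel.std())
        if sigma == 0.0:
            raise ValueError(
                f"modality {name!r} is constant (sigma=0); cannot normalize"
            )
        out[..., m] = (chan - mu) / sigma
    return MultiModalVolume(out, spacing=volume.spacing, affine=volume.affine)


def labels_to_onehot(labels: np.ndarray) -> np.ndarray:
    """One-hot target (D, H, W, 4), channels (bg, gangrene, edema, enhancing)."""
    labels = validate_labels(labels)
    onehot = np.zeros(labels.shape + (4,), dtype=np.float32)
    for lab, chan in LABEL_TO_CHANNEL.items():
        onehot[..., chan] = labels == lab
    return onehot


def onehot_to_labels(onehot: np.ndarray) -> np.ndarray:
    """Inverse of :func:`labels_to_onehot` via channel argmax."""
    onehot = np.asarray(onehot)
    if onehot.shape[-1] != 4:
        raise ValueError("expected 4 channels")
    chan = onehot.argmax(axis=-1)
    lut = np.array([CHANNEL_TO_LABEL[c] for c in range(4)], dtype=np.int16)
    return lut[chan]


def labels_to_regions(labels: np.ndarray) -> RegionMasks:
    """Nested evaluation masks: wt = {1,2,4}, tc = {1,4}, et = {4}."""
    labels = validate_labels(labels)
    return RegionMasks(
        et=labels == 4,
        tc=np.isin(labels, (1, 4)),
        wt=np.isin(labels, (1, 2, 4)),
    )


# ---------------------------------------------------------------------
# patch extraction / restitching
# ---------------------------------------------------------------------

def _axis_origins(size: int, patch: int, stride: int) -> list[int]:
    if size <= patch:
        return [0]
    n = int(np.ceil((size - patch) / stride)) + 1
    return [i * stride for i in range(n)]


def extract_patches(image: np.ndarray, target: np.ndarray | None,
                    patch_shape: tuple[int, int, int] = (64, 128, 128),
                    stride: tuple[int, int, int] | None = None) -> PatchSet:
    """Sliding-window patches with zero padding past the border.

    Patch count per axis is ``ceil((size - patch)/stride) + 1`` (one
    patch when the volume fits). Origins are recorded half-open and
    0-based so the stitcher can reassemble the exact volume.
    """
    image = np.asarray(image)
    if image.ndim != 4:
        raise ValueError("image must be (D, H, W, C)")
    stride = tuple(stride) if stride is not None else tuple(patch_shape)
    if any(s < 1 for s in stride):
        raise ValueError("stride must be positive")
    vol_shape = image.shape[:3]
    origins = [_axis_origins(n, ps, st)
               for n, ps, st in zip(vol_shape, patch_shape, stride)]
    pad_to = [max(n, o[-1] + ps)
              for n, o, ps in zip(vol_shape, origins, patch_shape)]
    pad = [(0, pt - n) for pt, n in zip(pad_to, vol_shape)]
    img_p = np.pad(image, pad + [(0, 0)])
    tgt_p = np.pad(np.asarray(target), pad + [(0, 0)] * (np.asarray(target).ndim - 3)) \
        if target is not None else None
    patches = []
    for oz in origins[0]:
        for oy in origins[1]:
            for ox in origins[2]:
                sl = (slice(oz, oz + patch_shape[0]),
                      slice(oy, oy + patch_shape[1]),
                      slice(ox, ox + patch_shape[2]))
                tp = tgt_p[sl] if tgt_p is not None else None
                patches.append((img_p[sl], tp, (oz, oy, ox)))
    return PatchSet(patches=patches, stride=stride,
                    patch_shape=tuple(patch_shape), volume_shape=vol_shape)


def stitch_patches(patches, volume_shape: tuple[int, int, int],
                   channels: int) -> np.ndarray:
    """Average overlapping patch values back onto the full volume.

    ``patches`` iterates over (array (pz, py, px, C), origin) pairs.
    Non-overlapping tilings reduce to exact reassembly; overlaps are
    averaged (the mean-of-probabilities aggregation used at inference).
    """
    acc = np.zeros(tuple(volume_shape) + (channels,), dtype=np.float64)
    cnt = np.zeros(tuple(volume_shape) + (1,), dtype=np.float64)
    for arr, origin in patches:
        oz, oy, ox = origin
        pz, py, px = arr.shape[:3]
        ez = min(oz + pz, volume_shape[0])
        ey = min(oy + py, volume_shape[1])
        ex = min(ox + px, volume_shape[2])
        acc[oz:ez, oy:ey, ox:ex] += arr[: ez - oz, : ey - oy, : ex - ox]
        cnt[oz:ez, oy:ey, ox:ex] += 1.0
    if np.any(cnt == 0):
        raise ValueError("patch origins do not cover the volume")
    return acc / cnt


# ---------------------------------------------------------------------
# NIfTI / NPY I/O
# ---------------------------------------------------------------------

def _to_nifti_order(arr: np.ndarray) -> np.ndarray:
    """(D, H, W) -> NIfTI (x, y, z) = (W, H, D)."""
    return np.transpose(arr, (2, 1, 0))


def _from_nifti_order(arr: np.ndarray) -> np.ndarray:
    return np.transpose(arr, (2, 1, 0))


def write_case(case_dir, case: PhantomCase,
               affine: np.ndarray | None = None) -> Path:
    """Write one case as BraTS-style NIfTI files; returns the case dir."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else np.asarray(affine)
    for m, mod in enumerate(MODALITIES):
        img = nib.Nifti1Image(
            _to_nifti_order(case.image[..., m]).astype(np.float32), affine)
        nib.save(img, case_dir / f"{case.case_id}_{mod}.nii.gz")
    seg = nib.Nifti1Image(
        _to_nifti_order(case.labels).astype(np.int16), affine)
    nib.save(seg, case_dir / f"{case.case_id}_seg.nii.gz")
    return case_dir


def read_case(case_dir, case_id: str | None = None
              ) -> tuple[MultiModalVolume, np.ndarray | None, str]:
    """Read a BraTS-style case directory.

    Returns (volume, labels-or-None, case_id). Raises if a modality file
    is missing or modalities disagree in shape.
    """
    case_dir = Path(case_dir)
    if case_id is None:
        segs = sorted(case_dir.glob("*_seg.nii*"))
        t1s = sorted(case_dir.glob("*_t1.nii*"))
        stem = segs[0].name if segs else (t1s[0].name if t1s else None)
        if stem is None:
            raise FileNotFoundError(f"no case files found in {case_dir}")
        case_id = stem.split("_seg.nii")[0].split("_t1.nii")[0]
    chans, affine = [], None
    for mod in MODALITIES:
        matches = sorted(case_dir.glob(f"{case_id}_{mod}.nii*"))
        if not matches:
            raise FileNotFoundError(
                f"missing modality {mod!r} for case {case_id} in {case_dir}"
            )
        img = nib.load(matches[0])
        if affine is None:
            affine = img.affine
        chans.append(_from_nifti_order(np.asarray(img.dataobj, dtype=np.float64)))
    shapes = {c.shape for c in chans}
    if len(shapes) > 1:
        raise ValueError(f"modalities of case {case_id} differ in shape: {shapes}")
    data = np.stack(chans, axis=-1)
    spacing = tuple(float(s) for s in np.abs(np.diag(affine))[:3][::-1])
    volume = MultiModalVolume(data, spacing=spacing, affine=affine)
    labels = None
    seg_matches = sorted(case_dir.glob(f"{case_id}_seg.nii*"))
    if seg_matches:
        labels = validate_labels(_from_nifti_order(
            np.asarray(nib.load(seg_matches[0]).dataobj).astype(np.int16)))
        if labels.shape != data.shape[:3]:
            raise ValueError("segmentation shape differs from modalities")
    return volume, labels, case_id


def save_patches_npy(out_dir, case_id: str, patch_set: PatchSet) -> list[Path]:
    """Serialize (image, target) patches as .npy pairs, one per origin."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for img, tgt, origin in patch_set.patches:
        tag = "_".join(str(o) for o in origin)
        p_img = out_dir / f"{case_id}_img_{tag}.npy"
        np.save(p_img, np.asarray(img, dtype=np.float32))
        paths.append(p_img)
        if tgt is not None:
            p_tgt = out_dir / f"{case_id}_tgt_{tag}.npy"
            np.save(p_tgt, np.asarray(tgt, dtype=np.float32))
            paths.append(p_tgt)
    return paths


def load_patch_pairs(patch_dir, case_ids=None):
    """Yield (image_patch, target_patch) arrays saved by save_patches_npy."""
    patch_dir = Path(patch_dir)
    for img_path in sorted(patch_dir.glob("*_img_*.npy")):
        cid = img_path.name.split("_img_")[0]
        if case_ids is not None and cid not in case_ids:
            continue
        tgt_path = patch_dir / img_path.name.replace("_img_", "_tgt_")
        if not tgt_path.exists():
            raise FileNotFoundError(f"no target patch for {img_path.name}")
        yield np.load(img_path), np.load(tgt_path)
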