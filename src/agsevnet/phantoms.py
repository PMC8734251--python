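"""Synthetic 4-modality brain-tumor phantoms.

Each phantom is a "brain" ellipsoid of normal tissue inside an air
background, with three nested tumor compartments following the BraTS
label convention: an edema shell (label 2) containing a necrotic core
shell (label 1) containing the enhancing tumor (label 4). The three
compartment radii are strictly decreasing, so the evaluation regions
nest by construction: ET (4) ⊂ TC (1∪4) ⊂ WT (1∪2∪4).

Compartments are concentric ellipsoids with independent per-axis radii
— deliberately simple shapes whose voxel counts and surfaces have
brute-force-checkable ground truth. Modality intensity profiles follow
the usual BraTS contrast pattern (FLAIR-bright edema, T1-CE-bright
enhancing tumor, T1-dark necrosis); the absolute values are arbitrary
units and fully configurable. Two noise models are provided: additive
voxelwise Gaussian noise, and complex Gaussian noise injected in the
frequency domain (k-space), the way scanner noise enters an MR
acquisition.

Generation is bit-reproducible: case ``index`` under seed ``s`` is
drawn from ``default_rng([s, index])`` regardless of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MODALITIES = ("t1", "t1ce", "t2", "flair")
TISSUE_CLASSES = ("air", "brain", "necrotic", "edema", "enhancing")

#: Mean intensity (arbitrary units) per modality and tissue class.
DEFAULT_PROFILES: dict[str, dict[str, float]] = {
    "t1":    {"air": 0.0, "brain": 100.0, "necrotic": 55.0, "edema": 80.0, "enhancing": 90.0},
    "t1ce":  {"air": 0.0, "brain": 100.0, "necrotic": 50.0, "edema": 90.0, "enhancing": 180.0},
    "t2":    {"air": 0.0, "brain": 100.0, "necrotic": 120.0, "edema": 140.0, "enhancing": 110.0},
    "flair": {"air": 0.0, "brain": 100.0, "necrotic": 90.0, "edema": 160.0, "enhancing": 120.0},
}

#: label value per tumor tissue class (BraTS convention)
LABEL_OF_CLASS = {"air": 0, "brain": 0, "edema": 2, "necrotic": 1, "enhancing": 4}


@dataclass
class PhantomConfig:
    """Study conditions for phantom generation.

    volume_shape: voxels per axis (depth, height, width).
    region_radii: strictly decreasing per-region ellipsoid radii, outer
        to inner (edema, necrotic core, enhancing); each entry is either
        a scalar or per-axis triple, in voxels.
    brain_radii: radii of the normal-tissue ellipsoid (defaults to 45%%
        of the volume extent per axis).
    center_jitter: max |displacement| of the tumor center per axis.
    modality_profiles: mean intensity per (modality, tissue class).
    noise_sd: additive Gaussian sd in intensity units.
    kspace_noise_sd: Gaussian sd applied in the frequency domain.
    seed, n_cases: reproducibility and dataset size.
    """

    volume_shape: tuple[int, int, int] = (32, 32, 32)
    region_radii: tuple = (10.0, 6.0, 3.0)
    brain_radii: tuple | None = None
    center_jitter: float = 2.0
    modality_profiles: dict = field(default_factory=lambda: DEFAULT_PROFILES)
    noise_sd: float = 5.0
    kspace_noise_sd: float = 0.0
    seed: int = 0
    n_cases: int = 1

    def __post_init__(self):
        radii = [np.broadcast_to(np.asarray(r, dtype=float), (3,)).copy()
                 for r in self.region_radii]
        if len(radii) != 3:
            raise ValueError("region_radii must list three nested regions")
        for outer, inner in zip(radii, radii[1:]):
            if not np.all(outer > inner):
                raise ValueError(f"region radii must strictly decrease: {radii}")
        self.region_radii = tuple(tuple(r) for r in radii)
        if self.brain_radii is None:
            self.brain_radii = tuple(0.45 * n for n in self.volume_shape)
        else:
            self.brain_radii = tuple(
                np.broadcast_to(np.asarray(self.brain_radii, float), (3,))
            )
        shape = np.asarray(self.volume_shape, dtype=float)
        outer = np.asarray(self.region_radii[0])
        if np.any(outer + self.center_jitter > shape / 2.0):
            raise ValueError(
                "outermost region radii plus jitter exceed the volume bounds"
            )
        if self.noise_sd < 0 or self.kspace_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def to_json(self, path) -> None:
        d = dict(self.__dict__)
        d["brain_radii"] = list(d["brain_radii"])
        d["region_radii"] = [list(r) for r in d["region_radii"]]
        d["volume_shape"] = list(d["volume_shape"])
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "PhantomConfig":
        d = json.loads(Path(path).read_text())
        d["volume_shape"] = tuple(d["volume_shape"])
        d["region_radii"] = tuple(tuple(r) for r in d["region_radii"])
        d["brain_radii"] = tuple(d["brain_radii"]) if d.get("brain_radii") else None
        return cls(**d)


@dataclass
class PhantomCase:
    """One generated case: image (D, H, W, 4), labels (D, H, W), id."""

    image: np.ndarray
    labels: np.ndarray
    case_id: str

    def __post_init__(self):
        if self.image.shape[:3] != self.labels.shape:
            raise ValueError("image and labels must share spatial shape")
        bad = set(np.unique(self.labels)) - {0, 1, 2, 4}
        if bad:
            raise ValueError(f"illegal label values {sorted(bad)}")


def ellipsoid_mask(shape: tuple[int, int, int], center, radii) -> np.ndarray:
    """Boolean mask of the discrete ellipsoid (x/rx)^2+(y/ry)^2+(z/rz)^2 <= 1."""
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii, dtype=float)
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def generate_case(config: PhantomConfig, index: int) -> PhantomCase:
    """Generate case ``index`` deterministically from (seed, index)."""
    if not 0 <= index < config.n_cases:
        raise IndexError(f"index {index} outside 0..{config.n_cases - 1}")
    rng = np.random.default_rng([config.seed, index])
    shape = tuple(config.volume_shape)
    vol_center = (np.asarray(shape, float) - 1.0) / 2.0
    jitter = rng.uniform(-config.center_jitter, config.center_jitter, size=3)
    center = vol_center + jitter

    labels = np.zeros(shape, dtype=np.int16)
    tissue = np.zeros(shape, dtype=np.int8)  # index into TISSUE_CLASSES
    tissue[ellipsoid_mask(shape, vol_center, config.brain_radii)] = 1
    for cls_name, radii in zip(("edema", "necrotic", "enhancing"),
                               config.region_radii):
        mask = ellipsoid_mask(shape, center, radii)
        labels[mask] = LABEL_OF_CLASS[cls_name]
        tissue[mask] = TISSUE_CLASSES.index(cls_name)

    image = np.zeros(shape + (len(MODALITIES),), dtype=np.float32)
    for m, mod in enumerate(MODALITIES):
        profile = config.modality_profiles[mod]
        means = np.array([profile[c] for c in TISSUE_CLASSES], dtype=np.float32)
        chan = means[tissue]
        if config.noise_sd > 0:
            chan = chan + rng.normal(0.0, config.noise_sd, size=shape)
        image[..., m] = chan
    if config.kspace_noise_sd > 0:
        image = add_kspace_noise(
            image, config.kspace_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return PhantomCase(image=image.astype(np.float32), labels=labels,
                       case_id=f"phantom_{index:03d}")


def add_kspace_noise(image: np.ndarray, sd: float, seed: int) -> np.ndarray:
    """Add complex Gaussian noise in the frequency domain.

    Per modality channel: forward 3D FFT, add ``N(0, sd)`` independently
    to real and imaginary parts everywhere in the spectrum, inverse FFT,
    keep the real part. ``sd == 0`` returns the input unchanged.
    """
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    image = np.asarray(image)
    if sd == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    out = np.empty_like(image, dtype=np.float64)
    chans = image.shape[-1] if image.ndim == 4 else 1
    img4 = image if image.ndim == 4 else image[..., None]
    for m in range(chans):
        spec = np.fft.fftn(img4[..., m])
        noise = rng.normal(0.0, sd, spec.shape) + 1j * rng.normal(0.0, sd, spec.shape)
        chan = np.fft.ifftn(spec + noise).real
        if image.ndim == 4:
            out[..., m] = chan
        else:
            out = chan
    return out.astype(image.dtype) if np.issubdtype(image.dtype, np.floating) else out


def spectrum_rms(image: np.ndarray) -> float:
    """Root-mean-square magnitude of the image's 3D spectrum, averaged
    over channels. Used to express k-space noise sd as a fraction of the
    signal spectrum magnitude."""
    image = np.asarray(image, dtype=float)
    img4 = image if image.ndim == 4 else image[..., None]
    vals = [
        float(np.sqrt(np.mean(np.abs(np.fft.fftn(img4[..., m])) ** 2)))
        for m in range(img4.shape[-1])
    ]
    return float(np.mean(vals))
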