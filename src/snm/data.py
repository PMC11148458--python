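"""Synthetic labelled datasets emulating the shapes of common benchmarks.

Three generators are provided, all fully deterministic under a seed and all
producing values in [0, 1]:

* ``gen_image_dataset`` -- 28x28 grayscale "digit" images, up to 10 classes.
  Each class prototype is a seven-segment rendering of the class id, so
  prototypes are a deterministic function of the class and pairwise distinct;
  samples are the prototype plus clipped Gaussian pixel noise.
* ``gen_timeseries_dataset`` -- multichannel sinusoid signatures emulating
  accelerometer/gyroscope activity windows; each class has a distinct
  frequency/phase signature per channel.
* ``gen_separable_dataset`` -- a minimal control task: each class activates a
  disjoint block of input channels. Any failure to learn or unlearn this task
  is attributable to the network, not the data.

Also provides stratified train/validation/test splitting and forget-set
construction for the unlearning experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError
from .unlearning import ForgetSpec


@dataclass
class LabeledDataset:
    """Aligned samples and integer class labels plus generator provenance."""

    samples: np.ndarray
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.samples) != len(self.labels):
            raise DataError("samples and labels must be aligned")
        if self.samples.size and (self.samples.min() < -1e-9 or self.samples.max() > 1 + 1e-9):
            raise DataError("sample values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return int(self.provenance.get("n_classes", self.labels.max() + 1 if len(self) else 0))

    @property
    def n_features(self) -> int:
        return int(np.prod(self.samples.shape[1:]))

    def features(self) -> np.ndarray:
        """Samples flattened to (n, n_features), values in [0, 1]."""
        return self.samples.reshape(len(self), -1)

    def subset(self, indices: np.ndarray, note: str = "subset") -> "LabeledDataset":
        prov = dict(self.provenance)
        prov["note"] = note
        return LabeledDataset(self.samples[indices], self.labels[indices], prov)


# ---------------------------------------------------------------------------
# Image generator (seven-segment digit prototypes)
# ---------------------------------------------------------------------------

_SEGMENTS = {  # seven-segment display encoding of digits 0-9
    0: "abcdef",
    1: "bc",
    2: "abged",
    3: "abgcd",
    4: "fgbc",
    5: "afgcd",
    6: "afgedc",
    7: "abc",
    8: "abcdefg",
    9: "abcfgd",
}


def _digit_prototype(digit: int, size: int = 28) -> np.ndarray:
    """Deterministic 28x28 stroke prototype of a digit (seven-segment style)."""
    img = np.zeros((size, size))
    x0, x1 = 7, 21  # left/right stroke columns
    y0, ym, y1 = 4, 14, 24  # top/middle/bottom stroke rows
    t = 2  # stroke thickness
    segs = _SEGMENTS[digit]
    if "a" in segs:
        img[y0 : y0 + t, x0:x1] = 1.0
    if "g" in segs:
        img[ym : ym + t, x0:x1] = 1.0
    if "d" in segs:
        img[y1 - t : y1, x0:x1] = 1.0
    if "f" in segs:
        img[y0:ym, x0 : x0 + t] = 1.0
    if "b" in segs:
        img[y0:ym, x1 - t : x1] = 1.0
    if "e" in segs:
        img[ym:y1, x0 : x0 + t] = 1.0
    if "c" in segs:
        img[ym:y1, x1 - t : x1] = 1.0
    return img


def class_prototypes(n_classes: int, kind: str = "image") -> np.ndarray:
    """Noise-free class prototypes used by the generators (and oracle tests)."""
    if kind == "image":
        return np.stack([_digit_prototype(c) for c in range(n_classes)])
    raise ValueError(f"unknown prototype kind {kind!r}")


def _balanced_labels(n_samples: int, n_classes: int) -> np.ndarray:
    per = n_samples // n_classes
    rem = n_samples - per * n_classes
    counts = [per + (1 if c < rem else 0) for c in range(n_classes)]
    return np.repeat(np.arange(n_classes), counts)


def gen_image_dataset(
    n_samples: int, n_classes: int = 10, noise_sd: float = 0.05, rng_seed=None
) -> LabeledDataset:
    """Balanced 28x28 image dataset: class prototype + clipped Gaussian noise."""
    if not 1 <= n_classes <= 10:
        raise ConfigurationError("image generator supports 1..10 classes")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    labels = _balanced_labels(n_samples, n_classes)
    protos = class_prototypes(n_classes)
    samples = protos[labels] + rng.normal(0.0, noise_sd, size=(n_samples, 28, 28))
    samples = np.clip(samples, 0.0, 1.0)
    prov = {
        "generator": "gen_image_dataset",
        "n_classes": n_classes,
        "noise_sd": noise_sd,
        "seed": rng_seed if isinstance(rng_seed, int) else None,
    }
    return LabeledDataset(samples, labels, prov)


# ---------------------------------------------------------------------------
# Time-series generator (sinusoid signatures)
# ---------------------------------------------------------------------------


def timeseries_signature(
    c: int, n_channels: int, n_timesteps: int
) -> np.ndarray:
    """Noise-free per-channel sinusoid signature of class c, in [0.05, 0.95]."""
    t = np.arange(n_timesteps) / n_timesteps
    sig = np.empty((n_channels, n_timesteps))
    for ch in range(n_channels):
        freq = (c + 1) + ch * 0.5 * (c + 1)  # channel 0 carries c+1 cycles
        phase = 2.0 * np.pi * ((c * n_channels + ch) * 0.61803 % 1.0)
        sig[ch] = 0.5 + 0.45 * np.sin(2.0 * np.pi * freq * t + phase)
    return sig


def gen_timeseries_dataset(
    n_samples: int,
    n_classes: int = 6,
    n_channels: int = 6,
    n_timesteps: int = 64,
    noise_sd: float = 0.05,
    rng_seed=None,
) -> LabeledDataset:
    """Balanced multichannel time-series dataset with sinusoid class signatures."""
    if n_channels < 1:
        raise ConfigurationError("n_channels must be >= 1")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    labels = _balanced_labels(n_samples, n_classes)
    sigs = np.stack(
        [timeseries_signature(c, n_channels, n_timesteps) for c in range(n_classes)]
    )
    samples = sigs[labels] + rng.normal(0.0, noise_sd, size=(n_samples, n_channels, n_timesteps))
    samples = np.clip(samples, 0.0, 1.0)
    prov = {
        "generator": "gen_timeseries_dataset",
        "n_classes": n_classes,
        "n_channels": n_channels,
        "n_timesteps": n_timesteps,
        "noise_sd": noise_sd,
        "seed": rng_seed if isinstance(rng_seed, int) else None,
    }
    return LabeledDataset(samples, labels, prov)


# ---------------------------------------------------------------------------
# Separable control task (disjoint active channel blocks per class)
# ---------------------------------------------------------------------------


def gen_separable_dataset(
    n_samples: int,
    n_classes: int = 2,
    n_channels: int = 20,
    active_level: float = 0.9,
    inactive_level: float = 0.02,
    noise_sd: float = 0.05,
    rng_seed=None,
) -> LabeledDataset:
    """Linearly separable feature vectors: class c activates channel block c."""
    if n_channels % n_classes:
        raise ConfigurationError("n_channels must be divisible by n_classes")
    rng = np.random.default_rng(rng_seed)
    labels = _balanced_labels(n_samples, n_classes)
    block = n_channels // n_classes
    samples = np.clip(
        rng.normal(inactive_level, noise_sd, size=(n_samples, n_channels)), 0.0, 1.0
    )
    for i, c in enumerate(labels):
        lo = c * block
        samples[i, lo : lo + block] = np.clip(
            rng.normal(active_level, noise_sd, size=block), 0.0, 1.0
        )
    prov = {
        "generator": "gen_separable_dataset",
        "n_classes": n_classes,
        "n_channels": n_channels,
        "noise_sd": noise_sd,
        "seed": rng_seed if isinstance(rng_seed, int) else None,
    }
    return LabeledDataset(samples, labels, prov)


# ---------------------------------------------------------------------------
# Splitting and forget-set construction
# ---------------------------------------------------------------------------


def split_dataset(
    dataset: LabeledDataset, fractions=(0.7, 0.15, 0.15), rng_seed=None
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive, label-stratified random (train, val, test) split."""
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ConfigurationError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("fractions must sum to 1")
    rng = np.random.default_rng(rng_seed)
    parts: list[list[int]] = [[], [], []]
    for c in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == c)
        idx = rng.permutation(idx)
        # largest-remainder allocation so counts are exact per class
        raw = np.array(fractions) * len(idx)
        counts = np.floor(raw).astype(int)
        rem = len(idx) - counts.sum()
        order = np.argsort(-(raw - counts))
        for k in order[:rem]:
            counts[k] += 1
        off = 0
        for part, cnt in zip(parts, counts):
            part.extend(idx[off : off + cnt])
            off += cnt
    out = []
    for name, part in zip(("train", "validation", "test"), parts):
        sel = rng.permutation(np.array(sorted(part), dtype=int))
        out.append(dataset.subset(sel, note=name))
    return tuple(out)


def make_forget_spec(
    dataset: LabeledDataset, mode: str, target_or_fraction, rng_seed=None
) -> ForgetSpec:
    """Declare what to unlearn: a whole class or a uniform sample fraction.

    Class-wise mode selects every index of the target class; sample-wise mode
    draws a uniformly random, distinct index subset of the given fraction of
    the dataset. The target-data drive d(t) is filled in later by the
    unlearning pipeline from the encoded forget samples.
    """
    rng = np.random.default_rng(rng_seed)
    if mode in ("class", "class-wise"):
        target = int(target_or_fraction)
        indices = np.flatnonzero(dataset.labels == target)
        if indices.size == 0:
            raise DataError(f"class {target} not present in dataset")
        return ForgetSpec(mode="class", indices=indices, target=target)
    if mode in ("sample", "sample-wise"):
        fraction = float(target_or_fraction)
        if not 0 < fraction <= 1:
            raise DataError("fraction must lie in (0, 1]")
        n = max(1, int(round(fraction * len(dataset))))
        indices = np.sort(rng.choice(len(dataset), size=n, replace=False))
        return ForgetSpec(mode="sample", indices=indices, fraction=fraction)
    raise DataError(f"unknown forget mode {mode!r}")
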