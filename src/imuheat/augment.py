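"""Label-preserving image augmentation of heatmap samples.

Training sets are enlarged by flipping and rotating whole heatmap tensors.
Rotations are restricted to multiples of 90 degrees so that count grids are
permuted exactly, with no interpolation; the same spatial transform is applied
to every sub-window and channel so the temporal/channel structure of a sample
stays intact. Augmentation operates purely in image space and is only ever
applied to training folds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .heatmap import HeatmapSample

__all__ = ["AUGMENT_OPS", "AugmentPolicy", "transform", "augment_dataset"]

AUGMENT_OPS = ("flip_h", "flip_v", "rot90", "rot180", "rot270")


@dataclass(frozen=True)
class AugmentPolicy:
    ops: tuple[str, ...] = AUGMENT_OPS
    copies_per_sample: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ops", tuple(self.ops))
        if self.copies_per_sample < 0:
            raise ValueError("copies_per_sample must be >= 0")
        if self.copies_per_sample > 0 and not self.ops:
            raise ValueError("ops must be non-empty when copies are requested")
        unknown = set(self.ops) - set(AUGMENT_OPS)
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")


def transform(sample: HeatmapSample, op: str) -> HeatmapSample:
    """Apply one spatial transform to every sub-window and channel; the label
    is unchanged and the result is marked as augmented."""
    if op not in AUGMENT_OPS:
        raise ValueError(f"unknown op {op!r}")
    t = sample.tensor
    if op in ("rot90", "rot270") and t.shape[2] != t.shape[3]:
        raise ValueError("90-degree rotations require a square raster")
    if op == "flip_h":
        out = t[:, :, :, ::-1]
    elif op == "flip_v":
        out = t[:, :, ::-1, :]
    else:
        k = {"rot90": 1, "rot180": 2, "rot270": 3}[op]
        out = np.rot90(t, k=k, axes=(2, 3))
    return replace(sample, tensor=np.ascontiguousarray(out), augmented=True)


def augment_dataset(train_samples: list[HeatmapSample], policy: AugmentPolicy) -> list[HeatmapSample]:
    """Return originals plus ``copies_per_sample`` transformed copies of each,
    with ops drawn from a generator seeded by the policy."""
    out = list(train_samples)
    if policy.copies_per_sample == 0:
        return out
    rng = np.random.default_rng(policy.seed)
    for sample in train_samples:
        for _ in range(policy.copies_per_sample):
            op = policy.ops[rng.integers(len(policy.ops))]
            out.append(transform(sample, op))
    return out
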