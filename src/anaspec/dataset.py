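"""Spectrogram-image dataset assembly: augmentation and train/test split.

The split is stratified by default: with 8-12 recordings per class, a plain
random 30% draw can leave a class without any test item, so each class is
split separately with round-half-up on the train count and at least one
held-out item.  Horizontal-flip augmentation (the only augmentation used)
doubles the training set and is never applied to test items.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .respsynth import VOCABULARY
from .spectral import SpectrogramImage


def horizontal_flip(image: SpectrogramImage) -> SpectrogramImage:
    """Reverse pixel columns (time axis) and toggle the flipped flag."""
    return replace(image, pixels=image.pixels[:, ::-1].copy(),
                   flipped=not image.flipped)


@dataclass
class LabeledImageSet:
    """Sequence of (image, label, source_id) triples over a fixed vocabulary."""

    items: list[tuple[SpectrogramImage, str, str]]
    class_vocabulary: tuple[str, ...] = VOCABULARY

    def __post_init__(self) -> None:
        seen = set()
        for _, label, source_id in self.items:
            if label not in self.class_vocabulary:
                raise ValueError(f"label {label!r} not in vocabulary")
            if source_id in seen:
                raise ValueError(f"duplicate source_id {source_id!r}")
            seen.add(source_id)

    def __len__(self) -> int:
        return len(self.items)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_vocabulary}
        for _, label, _ in self.items:
            counts[label] += 1
        return counts


@dataclass
class DatasetSplit:
    train: LabeledImageSet
    test: LabeledImageSet
    train_fraction: float = 0.70
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        train_ids = {sid for _, _, sid in self.train.items}
        test_ids = {sid for _, _, sid in self.test.items}
        if train_ids & test_ids:
            raise ValueError("train and test share source_ids")


def augment_set(image_set: LabeledImageSet, seed: int = 0,
                flip_probability: float = 1.0) -> LabeledImageSet:
    """Add one horizontally flipped copy per item (cardinality doubled).

    ``flip_probability < 1`` switches to probabilistic augmentation where
    each item gains a flipped twin with that probability (non-default).
    """
    if len(image_set) == 0:
        raise ValueError("cannot augment an empty set")
    rng = np.random.default_rng(seed)
    items = list(image_set.items)
    for image, label, source_id in image_set.items:
        if flip_probability >= 1.0 or rng.random() < flip_probability:
            items.append((horizontal_flip(image), label, f"{source_id}#flip"))
    return LabeledImageSet(items, image_set.class_vocabulary)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_indices(labels: list[str], vocabulary: tuple[str, ...] = VOCABULARY,
                  train_fraction: float = 0.70, seed: int = 0,
                  stratified: bool = True) -> tuple[list[int], list[int]]:
    """Seeded random train/test index partition over a label sequence.

    Stratified (default): per class, round-half-up(count x fraction) items
    go to train and the rest to test, with at least one test item per class;
    classes with fewer than 2 items are rejected.  Unstratified: one global
    shuffle with round-half-up on the total.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    if stratified:
        for label in vocabulary:
            members = [i for i, lab in enumerate(labels) if lab == label]
            if not members:
                continue
            if len(members) < 2:
                raise ValueError(
                    f"class {label!r} has {len(members)} item(s); "
                    "stratified splitting needs at least 2"
                )
            order = rng.permutation(len(members))
            n_train = _round_half_up(len(members) * train_fraction)
            n_train = min(n_train, len(members) - 1)  # keep >= 1 test item
            for rank, idx in enumerate(order):
                (train if rank < n_train else test).append(members[idx])
    else:
        order = rng.permutation(len(labels))
        n_train = _round_half_up(len(labels) * train_fraction)
        train = [int(i) for i in order[:n_train]]
        test = [int(i) for i in order[n_train:]]
    return train, test


def split_dataset(image_set: LabeledImageSet, train_fraction: float = 0.70,
                  seed: int = 0, stratified: bool = True) -> DatasetSplit:
    """Seeded random train/test partition of a labeled image set
    (see :func:`split_indices` for the selection rule)."""
    labels = [label for _, label, _ in image_set.items]
    train_idx, test_idx = split_indices(labels, image_set.class_vocabulary,
                                        train_fraction, seed, stratified)
    return DatasetSplit(
        LabeledImageSet([image_set.items[i] for i in train_idx],
                        image_set.class_vocabulary),
        LabeledImageSet([image_set.items[i] for i in test_idx],
                        image_set.class_vocabulary),
        train_fraction=train_fraction, seed=seed, stratified=stratified,
    )
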