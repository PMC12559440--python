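"""Synthetic leaf imagery and synthetic member-classifier outputs.

Everything downstream — segmentation, symptom detection, severity scoring,
ensemble fusion and the fusion-weight search — is testable against ground
truth generated here, with no image downloads.

Two generators are provided:

* elliptical "leaves" on a dark background carrying chlorotic (yellow)
  disc-shaped patches covering a controllable fraction of the leaf area,
  together with the exact leaf and symptom masks used to render them;
* per-model class-probability tables in which each member classifier's
  top-1 accuracy is controlled exactly, emulating the softmax outputs of
  trained CNN members.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .data_pipeline import LabeledDataset

__all__ = [
    "MemberOutputTable",
    "SyntheticLeafSample",
    "SyntheticLeafSpec",
    "gen_dataset",
    "gen_leaf",
    "gen_member_probs",
    "write_image_dataset",
]


@dataclass(frozen=True)
class SyntheticLeafSpec:
    """Parameters of one synthetic leaf rendering.

    Default colours are chosen so the HSV yellow band used by symptom
    detection has a clean separation from both the green lamina and the
    dark background.
    """

    canvas_side: int = 224
    leaf_axes: tuple[int, int] = (90, 60)  # ellipse semi-axes, pixels
    base_leaf_color: tuple[int, int, int] = (40, 120, 40)
    background_color: tuple[int, int, int] = (10, 10, 10)
    symptom_fraction: float = 0.0
    symptom_color: tuple[int, int, int] = (180, 170, 40)
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.symptom_fraction <= 1.0:
            raise ValueError("symptom_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        a, b = self.leaf_axes
        if 2 * a >= self.canvas_side or 2 * b >= self.canvas_side:
            raise ValueError("leaf does not fit the canvas")


@dataclass
class SyntheticLeafSample:
    """A rendered leaf plus the masks it was rendered from."""

    image: np.ndarray  # H x W x 3 uint8
    leaf_mask: np.ndarray  # H x W bool
    symptom_mask: np.ndarray  # H x W bool
    spec: SyntheticLeafSpec

    def symptom_area_fraction(self) -> float:
        leaf_area = int(self.leaf_mask.sum())
        return float(self.symptom_mask.sum()) / leaf_area if leaf_area else 0.0


#: how close the rendered symptom area must come to the requested fraction
AREA_TOLERANCE = 0.02


def gen_leaf(spec: SyntheticLeafSpec) -> SyntheticLeafSample:
    """Render one elliptical leaf with chlorotic patches.

    Symptom discs of random radius are placed (centres restricted to the
    leaf interior) until the yellow area covers ``symptom_fraction`` of the
    leaf within ±0.02.  The last disc is shaved pixel-wise if it overshoots
    the tolerance.  Fully deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.canvas_side
    yy, xx = np.mgrid[0:side, 0:side]
    cy = cx = side / 2.0
    a, b = spec.leaf_axes
    leaf_mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    leaf_area = int(leaf_mask.sum())

    symptom_mask = np.zeros_like(leaf_mask)
    target = spec.symptom_fraction * leaf_area
    if spec.symptom_fraction > 0:
        interior_y, interior_x = np.nonzero(leaf_mask)
        max_r = max(3, int(0.25 * min(a, b)))
        # rejection placement: keep adding discs while short of target
        while symptom_mask.sum() < target - AREA_TOLERANCE * leaf_area:
            i = rng.integers(len(interior_y))
            py, px = interior_y[i], interior_x[i]
            r = int(rng.integers(3, max_r + 1))
            disc = (xx - px) ** 2 + (yy - py) ** 2 <= r * r
            candidate = symptom_mask | (disc & leaf_mask)
            overshoot = candidate.sum() - target
            if overshoot > AREA_TOLERANCE * leaf_area:
                # shave the new disc's excess pixels deterministically
                new_px = np.flatnonzero(candidate & ~symptom_mask)
                keep = len(new_px) - int(overshoot)
                if keep <= 0:
                    continue
                chosen = rng.permutation(new_px)[:keep]
                candidate = symptom_mask.copy()
                candidate.flat[chosen] = True
            symptom_mask = candidate

    img = np.empty((side, side, 3), dtype=float)
    img[:] = spec.background_color
    img[leaf_mask] = spec.base_leaf_color
    img[symptom_mask] = spec.symptom_color
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticLeafSample(
        image=image, leaf_mask=leaf_mask, symptom_mask=symptom_mask, spec=spec
    )


def gen_dataset(
    class_specs: Mapping[str, SyntheticLeafSpec],
    n_per_class: int,
    seed: int,
    return_samples: bool = False,
) -> LabeledDataset | tuple[LabeledDataset, list[SyntheticLeafSample]]:
    """Generate a balanced labelled dataset of synthetic leaves.

    Per-sample seeds are derived from the master ``seed`` so each image is
    independently reproducible.  Class order follows the mapping's key
    order.
    """
    if not class_specs:
        raise ValueError("class_specs must not be empty")
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    class_names = list(class_specs)
    samples: list[tuple[np.ndarray, int]] = []
    leaf_samples: list[SyntheticLeafSample] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(class_names) * n_per_class) >> 1
    i = 0
    for label, name in enumerate(class_names):
        spec = class_specs[name]
        for _ in range(n_per_class):
            sample = gen_leaf(replace(spec, seed=int(child_seeds[i])))
            samples.append((sample.image, label))
            leaf_samples.append(sample)
            i += 1
    ds = LabeledDataset(samples=samples, class_names=class_names)
    if return_samples:
        return ds, leaf_samples
    return ds


def write_image_dataset(ds: LabeledDataset, root: str | Path) -> None:
    """Write a dataset to disk in the dir-per-class layout."""
    root = Path(root)
    counters = {name: 0 for name in ds.class_names}
    for img, label in ds.samples:
        name = ds.class_names[label]
        cdir = root / name
        cdir.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img).save(cdir / f"{name}_{counters[name]:04d}.png")
        counters[name] += 1


@dataclass
class MemberOutputTable:
    """Per-sample class-probability outputs of N member classifiers.

    ``probs`` has shape (n, N, K); every (sample, model) row lies on the
    K-simplex.  Serializes to CSV with columns ``true_class, m<i>_p<k>``.
    """

    true_class: np.ndarray  # (n,) int
    probs: np.ndarray  # (n, N, K) float

    def __post_init__(self) -> None:
        self.true_class = np.asarray(self.true_class, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        n, n_models, k = self.probs.shape
        if len(self.true_class) != n:
            raise ValueError("label/probability row count mismatch")
        if np.any(self.true_class < 0) or np.any(self.true_class >= k):
            raise ValueError("true_class outside [0, K)")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative probabilities")
        if not np.allclose(self.probs.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("probability rows must sum to 1")

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    @property
    def n_models(self) -> int:
        return self.probs.shape[1]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]

    def member_accuracy(self, i: int) -> float:
        """Empirical top-1 accuracy of member ``i`` (lowest index wins ties)."""
        pred = self.probs[:, i, :].argmax(axis=1)
        return float((pred == self.true_class).mean())

    def subset(self, idx: np.ndarray) -> "MemberOutputTable":
        return MemberOutputTable(self.true_class[idx], self.probs[idx])

    def to_frame(self) -> pd.DataFrame:
        n, n_models, k = self.probs.shape
        data = {"true_class": self.true_class}
        for i in range(n_models):
            for c in range(k):
                data[f"m{i}_p{c}"] = self.probs[:, i, c]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MemberOutputTable":
        df = pd.read_csv(path)
        prob_cols = [c for c in df.columns if c.startswith("m")]
        n_models = 1 + max(int(c.split("_")[0][1:]) for c in prob_cols)
        k = 1 + max(int(c.split("_p")[1]) for c in prob_cols)
        probs = np.empty((len(df), n_models, k))
        for i in range(n_models):
            for c in range(k):
                probs[:, i, c] = df[f"m{i}_p{c}"].to_numpy()
        return cls(df["true_class"].to_numpy(dtype=int), probs)


def gen_member_probs(
    true_labels: Sequence[int],
    per_model_accuracy: Sequence[float],
    K: int,
    concentration: float = 20.0,
    seed: int = 0,
) -> MemberOutputTable:
    """Simulate member-classifier probability outputs with known accuracy.

    For each sample and member, the predicted (argmax) class is the true
    class with probability equal to that member's target accuracy and a
    uniformly drawn wrong class otherwise.  The full probability row is a
    Dirichlet draw peaked at the predicted class (peakedness set by
    ``concentration``); if the draw's argmax lands elsewhere the two
    coordinates are swapped, so the argmax class is controlled exactly and
    member accuracy is Binomial(n, accuracy) by construction.
    """
    true_labels = np.asarray(true_labels, dtype=int)
    if K < 2:
        raise ValueError("K must be at least 2")
    accs = np.asarray(per_model_accuracy, dtype=float)
    if np.any(accs <= 0) or np.any(accs > 1):
        raise ValueError("accuracies must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(true_labels)
    n_models = len(accs)
    probs = np.empty((n, n_models, K))
    for i, acc in enumerate(accs):
        correct = rng.random(n) < acc
        wrong_offset = rng.integers(1, K, size=n)
        pred = np.where(correct, true_labels, (true_labels + wrong_offset) % K)
        alpha = np.ones((n, K))
        alpha[np.arange(n), pred] += concentration
        draws = rng.gamma(alpha)  # normalized gamma = Dirichlet
        draws /= draws.sum(axis=1, keepdims=True)
        # enforce argmax at the intended class by swapping coordinates
        arg = draws.argmax(axis=1)
        fix = arg != pred
        rows = np.nonzero(fix)[0]
        tmp = draws[rows, arg[rows]].copy()
        draws[rows, arg[rows]] = draws[rows, pred[rows]]
        draws[rows, pred[rows]] = tmp
        probs[:, i, :] = draws
    return MemberOutputTable(true_class=true_labels, probs=probs)
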