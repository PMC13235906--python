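"""Image quality control and dataset splitting.

The QC pipeline mirrors a curation workflow for mixed lab/web imagery:
perceptual-hash duplicate removal, Laplacian-variance blur screening and
minimum-resolution screening (both *flag* images for manual review rather
than deleting them), a minimum-images-per-species filter, and a
species-stratified 70/15/15 train/validation/test split.

Conventions (fixed so results are bit-reproducible): grayscale conversion
uses ITU-R BT.601 luma weights (0.299, 0.587, 0.114); the perceptual hash is
an 8x8 average hash; images are float arrays in [0, 1] (uint8 input is
rescaled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .taxonomy import TaxonomyTree, build_taxonomy

logger = logging.getLogger(__name__)

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])
LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)

SUBSETS = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


def to_gray(image: np.ndarray) -> np.ndarray:
    """BT.601 luma of an RGB (or already-gray) image as float64 in [0, 1]."""
    image = np.asarray(image)
    if image.dtype == np.uint8:
        image = image.astype(np.float64) / 255.0
    else:
        image = image.astype(np.float64)
    if image.ndim == 3:
        image = image[..., :3] @ LUMA_WEIGHTS
    return image


@dataclass(frozen=True)
class HashSignature:
    """64-bit average-hash signature; deterministic for identical pixels."""

    bits: int

    def __post_init__(self):
        if not 0 <= self.bits < 2 ** 64:
            raise ValueError("hash must fit in 64 bits")

    def hamming(self, other: "HashSignature") -> int:
        return int(self.bits ^ other.bits).bit_count()

    def bit_array(self) -> np.ndarray:
        return np.array([(self.bits >> i) & 1 for i in range(63, -1, -1)],
                        dtype=np.uint8)


def _area_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) row-stochastic matrix performing exact area averaging."""
    m = np.zeros((n_out, n_in))
    edges = np.linspace(0.0, n_in, n_out + 1)
    for i in range(n_out):
        lo, hi = edges[i], edges[i + 1]
        for j in range(int(np.floor(lo)), int(np.ceil(hi))):
            m[i, j] = min(hi, j + 1) - max(lo, j)
    return m / (n_in / n_out)


def perceptual_hash(image: np.ndarray) -> HashSignature:
    """8x8 average hash: grayscale, area-average to 8x8, set bit i iff
    cell i strictly exceeds the mean of the 64 cells.

    Bit order is row-major with the top-left cell in the most significant
    bit.  A constant image therefore hashes to all-zero bits.
    """
    gray = to_gray(image)
    if gray.ndim != 2 or gray.shape[0] < 8 or gray.shape[1] < 8:
        raise ValueError(f"perceptual hash requires an image of at least "
                         f"8x8 pixels, got shape {gray.shape}")
    cells = _area_weights(gray.shape[0], 8) @ gray @ _area_weights(gray.shape[1], 8).T
    mask = (cells > cells.mean()).ravel()
    bits = 0
    for b in mask:
        bits = (bits << 1) | int(b)
    return HashSignature(bits)


@dataclass
class QcReport:
    """Outcome of the QC screen.  ``kept``, ``removed_duplicates`` (ids) and
    the union of flagged ids partition the input; an image may carry both a
    blur and a resolution flag."""

    kept: list = field(default_factory=list)
    removed_duplicates: list = field(default_factory=list)  # (id, matched_id, dist)
    flagged_blur: list = field(default_factory=list)        # (id, score)
    flagged_resolution: list = field(default_factory=list)  # (id, w, h)

    def to_dict(self) -> dict:
        return {
            "kept": list(self.kept),
            "removed_duplicates": [list(t) for t in self.removed_duplicates],
            "flagged_blur": [list(t) for t in self.flagged_blur],
            "flagged_resolution": [list(t) for t in self.flagged_resolution],
        }


def dedupe(entries, max_hamming: int = 0) -> QcReport:
    """Greedy duplicate scan in id order: an entry is removed iff its hash is
    within ``max_hamming`` of any previously *kept* entry (first occurrence
    kept).  ``entries`` is an iterable of (id, image)."""
    if not 0 <= max_hamming <= 64:
        raise ValueError(f"max_hamming must be in [0, 64], got {max_hamming}")
    report = QcReport()
    kept_sigs: list[tuple[object, HashSignature]] = []
    for entry_id, image in sorted(entries, key=lambda e: str(e[0])):
        sig = perceptual_hash(image)
        match = next(((kid, sig.hamming(ksig)) for kid, ksig in kept_sigs
                      if sig.hamming(ksig) <= max_hamming), None)
        if match is None:
            kept_sigs.append((entry_id, sig))
            report.kept.append(entry_id)
        else:
            report.removed_duplicates.append((entry_id, match[0], match[1]))
    return report


def blur_score(image: np.ndarray) -> float:
    """Variance of the 3x3 Laplacian of the grayscale image (low = blurry)."""
    gray = to_gray(image)
    if gray.ndim != 2 or min(gray.shape) < 3:
        raise ValueError(f"blur score requires an image of at least 3x3 "
                         f"pixels, got shape {gray.shape}")
    lap = ndimage.convolve(gray, LAPLACIAN_KERNEL, mode="mirror")
    return float(lap.var())


def qc_screen(entries, min_blur: float = 0.0, min_side: int = 0,
              near_dup_hamming: int | None = None) -> QcReport:
    """Full QC screen.  Optionally dedupes first (``near_dup_hamming``),
    then flags surviving images whose blur score falls below ``min_blur`` or
    whose shorter side is below ``min_side``.  Flagged images are routed to
    manual review, never silently deleted."""
    if min_blur < 0 or min_side < 0:
        raise ValueError("thresholds must be >= 0")
    entries = list(entries)
    if near_dup_hamming is not None:
        report = dedupe(entries, near_dup_hamming)
        removed = {rid for rid, _, _ in report.removed_duplicates}
        survivors = [(i, im) for i, im in entries if i not in removed]
    else:
        report = QcReport()
        survivors = entries
    report.kept = []
    for entry_id, image in survivors:
        ok = True
        h, w = np.asarray(image).shape[:2]
        if min(h, w) < min_side:
            report.flagged_resolution.append((entry_id, w, h))
            ok = False
        score = blur_score(image)
        if score < min_blur:
            report.flagged_blur.append((entry_id, score))
            ok = False
        if ok:
            report.kept.append(entry_id)
    return report


class EmptyDatasetError(ValueError):
    pass


def filter_min_images(manifest: pd.DataFrame, tree: TaxonomyTree,
                      min_count: int = 30
                      ) -> tuple[pd.DataFrame, TaxonomyTree]:
    """Drop species with fewer than ``min_count`` images ("at least
    min_count" survive); the taxonomy is rebuilt from the survivors so
    emptied genera/families are pruned."""
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    counts = manifest["species"].value_counts()
    surviving = set(counts[counts >= min_count].index)
    out = manifest[manifest["species"].isin(surviving)].reset_index(drop=True)
    if out.empty:
        raise EmptyDatasetError(
            f"no species has at least {min_count} images")
    new_tree = build_taxonomy(
        out[["family", "genus", "species"]].drop_duplicates()
        .itertuples(index=False, name=None))
    return out, new_tree


@dataclass
class SplitAssignment:
    """Exhaustive, disjoint image-id -> subset map."""

    assignment: dict

    def subset_ids(self, subset: str) -> list:
        return [k for k, v in self.assignment.items() if v == subset]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": list(self.assignment),
                             "subset": list(self.assignment.values())})


def _largest_remainder(n: int, fractions) -> np.ndarray:
    """Allocate n items to len(fractions) bins by largest-remainder rounding,
    then enforce a floor of one item per bin (taking from the largest)."""
    ideal = np.asarray(fractions, dtype=np.float64) * n
    base = np.floor(ideal).astype(int)
    remainder = ideal - base
    for k in np.argsort(-remainder, kind="stable")[: n - base.sum()]:
        base[k] += 1
    for i in range(len(base)):
        while base[i] == 0:
            base[int(np.argmax(base))] -= 1
            base[i] += 1
    return base


def stratified_split(manifest: pd.DataFrame,
                     fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
                     seed: int = 0, id_column: str = "path"
                     ) -> SplitAssignment:
    """Species-stratified train/val/test split.

    Per species, image ids are sorted, shuffled with a seeded RNG, and
    allocated by largest-remainder rounding of ``fractions`` with at least
    one image per subset — so every species appears in all three subsets.
    Deterministic for a fixed seed and independent of input row order.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    assignment: dict = {}
    for spe_idx, (species, group) in enumerate(
            sorted(manifest.groupby("species"), key=lambda kv: str(kv[0]))):
        ids = sorted(group[id_column].tolist())
        if len(ids) < 3:
            raise ValueError(
                f"species {species!r} has only {len(ids)} images; every "
                f"species needs >= 3 to appear in all subsets — apply "
                f"filter_min_images first")
        rng = np.random.default_rng([seed, spe_idx])
        ids = [ids[i] for i in rng.permutation(len(ids))]
        counts = _largest_remainder(len(ids), fractions)
        start = 0
        for subset, c in zip(SUBSETS, counts):
            for image_id in ids[start:start + c]:
                assignment[image_id] = subset
            start += c
    return SplitAssignment(assignment)


def center_square_crop(image: np.ndarray) -> np.ndarray:
    """Largest centered square crop (stand-in for a manual crop step)."""
    h, w = image.shape[:2]
    side = min(h, w)
    top, left = (h - side) // 2, (w - side) // 2
    return image[top:top + side, left:left + side]
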