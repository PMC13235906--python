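"""Synthetic hierarchically-structured specimen images.

The generator emulates the nested visual structure of real specimen
photographs so every pipeline stage has signal to exploit: the *family*
controls the coarse body silhouette (ellipse eccentricity and tail size),
the *genus* controls the base hue, and the *species* controls a localized
marking pattern (stripes or spots) drawn inside the body.  Two regimes
mirror typical image provenance:

``lab``
    uniform light background, centered specimen, sharp edges, small
    position/scale/brightness jitter;
``web``
    textured background clutter, off-center placement and scale variation,
    lighting jitter, and Gaussian blur — so web renders score strictly lower
    on Laplacian-variance sharpness than their lab counterparts.

Bodies are rasterized analytically (no interpolation), so markings follow
the body under jitter and masks are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from .taxonomy import TaxonomyTree, build_taxonomy

GOLDEN = 0.618033988749895
_SPECIES_SALT = 104729  # fixed stream offset for species-determined patterns


@dataclass
class SyntheticSpec:
    """Study-design knobs for a generated dataset."""

    n_families: int = 3
    n_genera: int = 6
    n_species: int = 12
    images_per_species: int = 60
    image_size: int = 32
    mode_mix: float = 0.0        # fraction of web-regime images per species
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.n_families <= self.n_genera <= self.n_species:
            raise ValueError("rank sizes must satisfy "
                             "n_families <= n_genera <= n_species")
        if self.images_per_species < 3:
            raise ValueError("images_per_species must be >= 3")
        if not 0.0 <= self.mode_mix <= 1.0:
            raise ValueError("mode_mix must lie in [0, 1]")


def make_taxonomy(spec: SyntheticSpec) -> TaxonomyTree:
    """Seeded taxonomy with every parent guaranteed at least one child and
    varying genus richness (to exercise richness analyses)."""
    rng = np.random.default_rng(spec.seed)
    gen_parent = np.concatenate([
        np.arange(spec.n_families),
        rng.integers(0, spec.n_families, spec.n_genera - spec.n_families)])
    weights = rng.dirichlet(np.ones(spec.n_genera))
    spe_parent = np.concatenate([
        np.arange(spec.n_genera),
        rng.choice(spec.n_genera, spec.n_species - spec.n_genera, p=weights)])
    triples = []
    for s in range(spec.n_species):
        g = int(spe_parent[s])
        f = int(gen_parent[g])
        triples.append((f"Fam{f + 1:02d}", f"Gen{g + 1:03d}",
                        f"Gen{g + 1:03d} sp{s + 1:03d}"))
    return build_taxonomy(triples)


def _family_shape(f: int, n_families: int) -> tuple[float, float, float]:
    """Semi-axis ratio and tail-size parameters for family ``f``."""
    t = f / max(1, n_families - 1) if n_families > 1 else 0.0
    semi_b = 0.28 + 0.22 * t        # body half-height (fraction of half-size)
    tail = 0.15 + 0.25 * (1.0 - t)  # tail ellipse size
    return 0.62, semi_b, tail


def _genus_hue(g: int) -> float:
    return (0.11 + g * GOLDEN) % 1.0


def _species_pattern(s: int) -> dict:
    """Deterministic marking-pattern parameters for species ``s``."""
    srng = np.random.default_rng(_SPECIES_SALT + s)
    kind = "stripes" if srng.random() < 0.5 else "spots"
    params = {
        "kind": kind,
        "dark": bool(srng.random() < 0.5),
        "n": int(srng.integers(2, 5)),
        "phase": float(srng.uniform(0, 2 * np.pi)),
        "vertical": bool(srng.random() < 0.5),
        "centers": srng.uniform(-0.75, 0.75, size=(4, 2)),
        "radius": float(srng.uniform(0.14, 0.24)),
    }
    return params


def render_specimen(tree: TaxonomyTree, species_index: int, regime: str = "lab",
                    rng: np.random.Generator | None = None, size: int = 32,
                    return_masks: bool = False):
    """Render one specimen image (HxWx3 float in [0, 1]).

    Deterministic given (species, rng state).  With ``return_masks=True``
    also returns ``{"body": ..., "marking": ...}`` boolean masks.
    """
    if regime not in ("lab", "web"):
        raise ValueError(f"regime must be 'lab' or 'web', got {regime!r}")
    rng = rng or np.random.default_rng(0)
    if not 0 <= species_index < tree.n_species:
        raise IndexError(f"species index {species_index} out of range")
    g = tree.genus_of_species(species_index)
    f = tree.family_of_genus(g)
    semi_a, semi_b, tail = _family_shape(f, tree.n_families)
    hue = _genus_hue(g)
    pattern = _species_pattern(species_index)

    # placement jitter (consumed identically for every species at a given
    # rng state, so same-genus renders share body geometry exactly)
    if regime == "lab":
        cx = 0.5 + rng.uniform(-0.04, 0.04)
        cy = 0.5 + rng.uniform(-0.04, 0.04)
        scale = rng.uniform(0.92, 1.05)
        light = rng.uniform(0.95, 1.05)
        # faint linear shading gradient (photo-tank lighting falloff); also
        # makes distinct renders perceptually distinct for hash-based QC
        amp = rng.uniform(0.03, 0.08)
        theta = rng.uniform(0.0, 2 * np.pi)
        gy, gx = np.mgrid[0:size, 0:size] / (size - 1)
        shade = amp * ((gx - 0.5) * np.cos(theta) + (gy - 0.5) * np.sin(theta))
        background = 0.86 + shade[..., None] * np.ones(3)
    else:
        cx = 0.5 + rng.uniform(-0.18, 0.18)
        cy = 0.5 + rng.uniform(-0.18, 0.18)
        scale = rng.uniform(0.55, 0.95)
        light = rng.uniform(0.60, 1.10)
        background = _textured_background(size, rng)

    yy, xx = np.mgrid[0:size, 0:size]
    # body-local coordinates in [-1, 1] along each semi-axis
    u = (xx / (size - 1) - cx) / (semi_a * scale / 2)
    v = (yy / (size - 1) - cy) / (semi_b * scale / 2)
    body = u ** 2 + v ** 2 <= 1.0
    tail_u = (xx / (size - 1) - (cx + semi_a * scale / 2)) / (tail * scale / 2)
    tail_v = (yy / (size - 1) - cy) / (tail * scale * 0.8 / 2)
    body |= tail_u ** 2 + tail_v ** 2 <= 1.0

    marking = np.zeros((size, size), dtype=bool)
    inside = u ** 2 + v ** 2 <= 1.0
    if pattern["kind"] == "stripes":
        coord = u if pattern["vertical"] else v
        wave = np.sin(pattern["n"] * np.pi * coord + pattern["phase"])
        marking = inside & (wave > 0.45)
    else:
        for k in range(pattern["n"]):
            du, dv = pattern["centers"][k]
            marking |= inside & ((u - du) ** 2 + (v - dv) ** 2
                                 <= pattern["radius"] ** 2)

    body_rgb = hsv_to_rgb([hue, 0.85, 0.72])
    mark_rgb = (np.array([0.06, 0.06, 0.06]) if pattern["dark"]
                else np.array([0.97, 0.97, 0.92]))
    image = background.copy()
    image[body] = body_rgb
    image[marking] = mark_rgb
    image = np.clip(image * light, 0.0, 1.0)
    if regime == "web":
        image = ndimage.gaussian_filter(image, sigma=(rng.uniform(0.9, 1.6),) * 2
                                        + (0.0,))
        image = np.clip(image, 0.0, 1.0)
    if return_masks:
        return image, {"body": body, "marking": marking}
    return image


def _textured_background(size: int, rng: np.random.Generator) -> np.ndarray:
    coarse = rng.uniform(0.15, 0.85, size=(size // 4 + 1, size // 4 + 1, 3))
    zoomed = ndimage.zoom(coarse, (size / coarse.shape[0],
                                   size / coarse.shape[1], 1), order=1)
    return np.clip(zoomed[:size, :size], 0.0, 1.0)


@dataclass
class SyntheticDataset:
    images: np.ndarray                 # (N, H, W, 3) float in [0, 1]
    manifest: pd.DataFrame             # path, family, genus, species, ...
    tree: TaxonomyTree
    spec: SyntheticSpec

    @property
    def labels(self) -> np.ndarray:
        """(N, 3) integer label array (family, genus, species)."""
        return self.manifest[["family_index", "genus_index",
                              "species_index"]].to_numpy()


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path | None = None
                     ) -> SyntheticDataset:
    """Generate ``images_per_species`` renders per species with the
    requested lab/web mix; optionally write a Family/Genus/Species folder
    hierarchy plus ``manifest.csv``.

    ``spec.duplicate_fraction`` injects exact pixel duplicates of earlier
    same-species images (recorded in the ``duplicate_of`` column) so
    duplicate-removal stages can be tested against a known ground truth;
    when active, base renders are re-jittered until their perceptual hashes
    are pairwise distinct.
    """
    tree = make_taxonomy(spec)
    rng = np.random.default_rng(spec.seed + 1)
    check_hashes = spec.duplicate_fraction > 0
    seen_hashes: set[int] = set()
    if check_hashes:
        from .dataqc import perceptual_hash

    images, rows = [], []
    all_triples = tree.triples()
    for s in range(tree.n_species):
        fam, gen, spe = all_triples[s]
        n = spec.images_per_species
        n_web = round(spec.mode_mix * n)
        regimes = ["web"] * n_web + ["lab"] * (n - n_web)
        for i, regime in enumerate(regimes):
            image = render_specimen(tree, s, regime, rng, spec.image_size)
            if check_hashes:
                # base images must be pairwise hash-distinct so that
                # hamming-0 dedupe removes the injected duplicates exactly;
                # on a collision, overlay a faint smooth lighting field
                for attempt in range(1, 101):
                    h = perceptual_hash(image).bits
                    if h not in seen_hashes:
                        break
                    field = _textured_background(spec.image_size, rng) - 0.5
                    amp = min(0.06 * attempt, 0.5)
                    image = np.clip(image + amp * field, 0.0, 1.0)
                else:
                    raise RuntimeError("could not generate hash-distinct "
                                       "images; increase image_size")
                seen_hashes.add(h)
            path = f"{fam}/{gen}/{spe}/{spe.replace(' ', '_')}_{i:03d}.png"
            images.append(image)
            rows.append({"path": path, "family": fam, "genus": gen,
                         "species": spe, "family_index": tree.families.index(fam),
                         "genus_index": tree.genera.index(gen),
                         "species_index": s, "regime": regime,
                         "duplicate_of": ""})

    # inject exact duplicates of earlier images of the same species
    n_dup = round(spec.duplicate_fraction * len(images))
    if n_dup:
        manifest = pd.DataFrame(rows)
        candidates = rng.permutation(len(images))
        injected = 0
        for idx in candidates:
            if injected >= n_dup:
                break
            same = manifest.index[
                (manifest["species_index"] == rows[idx]["species_index"])
                & (manifest.index < idx)
                & (manifest["duplicate_of"] == "")].tolist()
            same = [j for j in same if rows[j]["duplicate_of"] == ""]
            if not same:
                continue
            src = int(same[0])
            images[idx] = images[src].copy()
            rows[idx]["duplicate_of"] = rows[src]["path"]
            injected += 1

    manifest = pd.DataFrame(rows)
    stack = np.stack(images)
    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        for image, row in zip(stack, rows):
            target = out / row["path"]
            target.parent.mkdir(parents=True, exist_ok=True)
            iio.imwrite(target, (image * 255).round().astype(np.uint8))
        manifest.to_csv(out / "manifest.csv", index=False)
    return SyntheticDataset(stack, manifest, tree, spec)
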