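"""Three-rank biological taxonomy: families, genera, species.

The hierarchy is a forest of depth exactly two below family.  Every genus
belongs to exactly one family and every species to exactly one genus, so a
species index determines its full (family, genus, species) chain.  Names are
encoded as dense 0-based integer indices in case-insensitive lexicographic
order, which makes encodings reproducible regardless of input order or
platform.

Genus names are required to be unique across families and species names
unique across genera (biological genus names are unique; a duplicate would
make the parent maps ambiguous).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: file suffixes treated as images when scanning a folder hierarchy
IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png", ".bmp", ".tif", ".tiff"}


class HierarchyViolationError(ValueError):
    """A taxon is assigned to more than one parent, or a label triple
    contradicts the tree's parent maps."""


def _sort_key(name: str) -> tuple[str, str]:
    # case-insensitive primary key; exact string as tie-break for determinism
    return (name.casefold(), name)


@dataclass(frozen=True)
class TaxonomyTree:
    """Immutable family/genus/species hierarchy with dense integer encodings.

    Attributes
    ----------
    families, genera, species
        Rank name lists, sorted case-insensitively; list position is the
        taxon's integer index.
    parent_of_genus
        ``parent_of_genus[g]`` is the family index of genus ``g``.
    parent_of_species
        ``parent_of_species[s]`` is the genus index of species ``s``.
    """

    families: tuple[str, ...]
    genera: tuple[str, ...]
    species: tuple[str, ...]
    parent_of_genus: np.ndarray = field(repr=False)
    parent_of_species: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pg = np.asarray(self.parent_of_genus, dtype=np.int64)
        ps = np.asarray(self.parent_of_species, dtype=np.int64)
        object.__setattr__(self, "parent_of_genus", pg)
        object.__setattr__(self, "parent_of_species", ps)
        if pg.shape != (len(self.genera),) or ps.shape != (len(self.species),):
            raise ValueError("parent map lengths do not match rank sizes")
        if len(pg) and (pg.min() < 0 or pg.max() >= len(self.families)):
            raise HierarchyViolationError("genus parent index out of range")
        if len(ps) and (ps.min() < 0 or ps.max() >= len(self.genera)):
            raise HierarchyViolationError("species parent index out of range")

    # -- sizes ----------------------------------------------------------
    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_genera(self) -> int:
        return len(self.genera)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def rank_sizes(self) -> tuple[int, int, int]:
        return (self.n_families, self.n_genera, self.n_species)

    # -- lookups --------------------------------------------------------
    def family_of_genus(self, g: int) -> int:
        return int(self.parent_of_genus[g])

    def genus_of_species(self, s: int) -> int:
        return int(self.parent_of_species[s])

    def family_of_species(self, s: int) -> int:
        return int(self.parent_of_genus[self.parent_of_species[s]])

    def label_triple_for_species(self, s: int) -> "LabelTriple":
        g = self.genus_of_species(s)
        return LabelTriple(int(self.parent_of_genus[g]), g, int(s))

    def species_per_genus(self) -> np.ndarray:
        """Genus richness: number of species under each genus."""
        return np.bincount(self.parent_of_species, minlength=self.n_genera)

    def index_of(self, rank: str, name: str) -> int:
        names = {"family": self.families, "genus": self.genera,
                 "species": self.species}[rank]
        return names.index(name)

    def triples(self) -> list[tuple[str, str, str]]:
        """All (family, genus, species) name triples encoded by the tree."""
        out = []
        for s, name in enumerate(self.species):
            g = self.genus_of_species(s)
            f = self.family_of_genus(g)
            out.append((self.families[f], self.genera[g], name))
        return out


@dataclass(frozen=True)
class LabelTriple:
    """Ground-truth (family, genus, species) index triple."""

    family_index: int
    genus_index: int
    species_index: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.family_index, self.genus_index, self.species_index)

    def validate(self, tree: TaxonomyTree) -> None:
        f, g, s = self.as_tuple()
        if not (0 <= s < tree.n_species and 0 <= g < tree.n_genera
                and 0 <= f < tree.n_families):
            raise IndexError(f"label triple {self.as_tuple()} out of range "
                             f"for tree of sizes {tree.rank_sizes}")
        if tree.genus_of_species(s) != g or tree.family_of_genus(g) != f:
            raise HierarchyViolationError(
                f"label triple {self.as_tuple()} is inconsistent with the "
                f"taxonomy (expected chain "
                f"({tree.family_of_species(s)}, {tree.genus_of_species(s)}, {s}))")


def build_taxonomy(triples: Iterable[tuple[str, str, str]]) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from (family, genus, species) name triples.

    Ordering is deterministic (case-insensitive lexicographic) and independent
    of the order of ``triples``.  Raises :class:`HierarchyViolationError` if a
    genus appears under two families or a species under two genera.
    """
    triples = list(triples)
    if not triples:
        raise ValueError("cannot build a taxonomy from an empty triple list")

    genus_parent: dict[str, str] = {}
    species_parent: dict[str, str] = {}
    for fam, gen, spe in triples:
        if genus_parent.setdefault(gen, fam) != fam:
            raise HierarchyViolationError(
                f"genus {gen!r} appears under families "
                f"{genus_parent[gen]!r} and {fam!r}")
        if species_parent.setdefault(spe, gen) != gen:
            raise HierarchyViolationError(
                f"species {spe!r} appears under genera "
                f"{species_parent[spe]!r} and {gen!r}")

    families = tuple(sorted({f for f, _, _ in triples}, key=_sort_key))
    genera = tuple(sorted(genus_parent, key=_sort_key))
    species = tuple(sorted(species_parent, key=_sort_key))
    fam_idx = {n: i for i, n in enumerate(families)}
    gen_idx = {n: i for i, n in enumerate(genera)}

    parent_of_genus = np.array([fam_idx[genus_parent[g]] for g in genera],
                               dtype=np.int64)
    parent_of_species = np.array([gen_idx[species_parent[s]] for s in species],
                                 dtype=np.int64)
    return TaxonomyTree(families, genera, species,
                        parent_of_genus, parent_of_species)


def is_consistent(f: int, g: int, s: int, tree: TaxonomyTree) -> bool:
    """True iff genus ``g`` belongs to family ``f`` and species ``s`` to
    genus ``g`` (the validity condition for a predicted taxon chain)."""
    if not (0 <= f < tree.n_families):
        raise IndexError(f"family index {f} out of range")
    if not (0 <= g < tree.n_genera):
        raise IndexError(f"genus index {g} out of range")
    if not (0 <= s < tree.n_species):
        raise IndexError(f"species index {s} out of range")
    return (tree.family_of_genus(g) == f) and (tree.genus_of_species(s) == g)


def scan_folder_hierarchy(
    root_path: str | Path,
) -> tuple[list[tuple[Path, LabelTriple]], TaxonomyTree]:
    """Scan a ``root/Family/Genus/Species/*.png`` layout.

    Every image file at depth three receives the label triple of its
    enclosing directories.  Files at the wrong depth, and non-image files,
    are skipped with a logged warning.  Empty species directories still
    contribute their species to the tree.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")

    triples: list[tuple[str, str, str]] = []
    located: list[tuple[Path, tuple[str, str, str]]] = []
    for fam_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for gen_dir in sorted(p for p in fam_dir.iterdir() if p.is_dir()):
            for spe_dir in sorted(p for p in gen_dir.iterdir() if p.is_dir()):
                triple = (fam_dir.name, gen_dir.name, spe_dir.name)
                triples.append(triple)
                for f in sorted(spe_dir.iterdir()):
                    if f.is_dir():
                        logger.warning("unexpected directory below species "
                                       "level, skipped: %s", f)
                        continue
                    if f.suffix.lower() not in IMAGE_SUFFIXES:
                        logger.warning("non-image file skipped: %s", f)
                        continue
                    located.append((f, triple))

    for p in root.rglob("*"):
        if p.is_file() and len(p.relative_to(root).parts) != 4:
            logger.warning("file at wrong depth skipped: %s", p)

    if not triples:
        raise ValueError(f"no Family/Genus/Species directories under {root}")

    tree = build_taxonomy(triples)
    fam_idx = {n: i for i, n in enumerate(tree.families)}
    gen_idx = {n: i for i, n in enumerate(tree.genera)}
    spe_idx = {n: i for i, n in enumerate(tree.species)}
    entries = [
        (path, LabelTriple(fam_idx[f], gen_idx[g], spe_idx[s]))
        for path, (f, g, s) in located
    ]
    return entries, tree


def read_taxonomy_csv(path: str | Path) -> TaxonomyTree:
    """Read a UTF-8 CSV with header ``family,genus,species``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = ["family", "genus", "species"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"taxonomy CSV must start with columns {required}, "
                         f"got {list(df.columns)}")
    return build_taxonomy(df[required].itertuples(index=False, name=None))


def labels_to_array(labels: Sequence[LabelTriple]) -> np.ndarray:
    """Stack label triples into an (N, 3) int array [family, genus, species]."""
    return np.array([t.as_tuple() for t in labels], dtype=np.int64)
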