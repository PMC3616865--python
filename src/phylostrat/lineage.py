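"""Phylostratum systems: ordered age classes anchored to a species tree.

A phylostratum map is the coordinate system of the whole analysis: an
ordered series of age classes ps1..psP, each defined by the set of taxa
whose lineage diverged from the focal species at the corresponding node of
the rooted species tree. ps1 is the oldest class (root of cellular life),
psP the youngest (the focal species' terminal lineage).

Strata are defined by curated taxon *sets*, not computed clades: the tree
is a validation and derivation aid, but at runtime a taxon's age class is
whatever the stratum specification says. This mirrors how published
phylostratigraphies use consensus phylogenetic groups rather than strict
tree topology.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "Stratum",
    "PhylostratumMap",
    "LineageError",
    "load_lineage",
    "derive_strata_from_tree",
    "stratum_of",
    "read_stratum_spec",
    "mouse_lineage",
    "fish_lineage",
]


class LineageError(ValueError):
    """Invalid tree, stratum specification, or taxon lookup."""


def normalize_taxon(label: str) -> str:
    """Canonical form for taxon labels: trimmed and case-folded.

    Hit tables and trees typically come from different sources, so matching
    is deliberately forgiving about case and surrounding whitespace (but
    nothing else).
    """
    return label.strip().casefold()


@dataclass(frozen=True)
class Stratum:
    index: int
    name: str
    taxa: frozenset[str]  # normalized labels


@dataclass(frozen=True)
class PhylostratumMap:
    """Ordered phylostrata with their defining taxon sets.

    ``strata`` runs from the oldest class (index 1) to the youngest
    (index P, containing the focal taxon).
    """

    strata: tuple[Stratum, ...]
    focal_taxon: str
    _lookup: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.strata:
            raise LineageError("a phylostratum map needs at least one stratum")
        indices = [s.index for s in self.strata]
        if indices != list(range(1, len(self.strata) + 1)):
            raise LineageError(
                f"stratum indices must be consecutive 1..P, got {indices}"
            )
        lookup: dict[str, int] = {}
        for s in self.strata:
            for taxon in s.taxa:
                if taxon in lookup:
                    raise LineageError(
                        f"taxon {taxon!r} assigned to strata {lookup[taxon]} and {s.index}"
                    )
                lookup[taxon] = s.index
        focal = normalize_taxon(self.focal_taxon)
        if focal not in lookup:
            raise LineageError(f"focal taxon {self.focal_taxon!r} missing from strata")
        if lookup[focal] != len(self.strata):
            raise LineageError(
                f"focal taxon {self.focal_taxon!r} must belong to the youngest "
                f"stratum {len(self.strata)}, found in {lookup[focal]}"
            )
        object.__setattr__(self, "_lookup", lookup)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self._lookup)

    def stratum_of(self, taxon: str) -> int:
        """Stratum index of ``taxon``; raises on unknown taxa.

        Never defaults silently: an unmapped taxon in a hit table is a data
        error, not a young gene.
        """
        key = normalize_taxon(taxon)
        try:
            return self._lookup[key]
        except KeyError:
            raise LineageError(
                f"taxon {taxon!r} is not mapped to any phylostratum"
            ) from None

    def __contains__(self, taxon: str) -> bool:
        return normalize_taxon(taxon) in self._lookup

    def name_of(self, index: int) -> str:
        return self.strata[index - 1].name

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stratum": s.index, "name": s.name, "taxa": ",".join(sorted(s.taxa))}
            for s in self.strata
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def stratum_of(taxon: str, pmap: PhylostratumMap) -> int:
    """Functional form of :meth:`PhylostratumMap.stratum_of`."""
    return pmap.stratum_of(taxon)


def _parse_tree(newick: str | Path) -> dendropy.Tree:
    if isinstance(newick, Path) or (
        isinstance(newick, str) and "\n" not in newick and Path(newick).exists()
    ):
        text = Path(newick).read_text()
    else:
        text = str(newick)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise LineageError(f"could not parse Newick tree: {exc}") from exc
    if len(tree.leaf_nodes()) < 2:
        raise LineageError("tree must contain at least two leaves")
    return tree


def read_stratum_spec(source: str | Path | io.IOBase) -> pd.DataFrame:
    """Read a taxon-to-stratum table (TSV: taxon, stratum[, stratum_name])."""
    df = pd.read_csv(source, sep="\t", dtype={"taxon": str})
    required = {"taxon", "stratum"}
    if not required.issubset(df.columns):
        raise LineageError(
            f"stratum spec needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if "stratum_name" not in df.columns:
        df["stratum_name"] = "ps" + df["stratum"].astype(str)
    return df


def load_lineage(
    newick: str | Path,
    stratum_spec: pd.DataFrame | str | Path,
    focal_taxon: str | None = None,
) -> PhylostratumMap:
    """Build a validated phylostratum map from a rooted tree and a spec table.

    Parameters
    ----------
    newick:
        Newick text or a path to a Newick file. Every leaf must be covered
        by the spec and every spec taxon must be a leaf.
    stratum_spec:
        DataFrame (or TSV path) with columns ``taxon``, ``stratum`` and
        optionally ``stratum_name``.
    focal_taxon:
        The focal species. May be omitted when the youngest stratum holds a
        single taxon.
    """
    if not isinstance(stratum_spec, pd.DataFrame):
        stratum_spec = read_stratum_spec(stratum_spec)
    tree = _parse_tree(newick)
    leaves = {normalize_taxon(lf.taxon.label) for lf in tree.leaf_nodes()}

    spec = stratum_spec.copy()
    if "stratum_name" not in spec.columns:
        spec["stratum_name"] = "ps" + spec["stratum"].astype(str)
    spec["taxon_norm"] = spec["taxon"].map(normalize_taxon)

    unknown = sorted(set(spec["taxon_norm"]) - leaves)
    if unknown:
        raise LineageError(f"spec taxa absent from the tree: {unknown}")
    uncovered = sorted(leaves - set(spec["taxon_norm"]))
    if uncovered:
        raise LineageError(f"tree leaves not covered by the spec: {uncovered}")

    strata: list[Stratum] = []
    for idx, group in spec.groupby("stratum", sort=True):
        names = group["stratum_name"].unique()
        if len(names) > 1:
            raise LineageError(
                f"stratum {idx} has conflicting names: {sorted(names)}"
            )
        strata.append(
            Stratum(
                index=int(idx),
                name=str(names[0]),
                taxa=frozenset(group["taxon_norm"]),
            )
        )

    if focal_taxon is None:
        youngest = strata[-1]
        if len(youngest.taxa) != 1:
            raise LineageError(
                "focal_taxon must be given explicitly: youngest stratum "
                f"{youngest.index} contains {len(youngest.taxa)} taxa"
            )
        (focal_taxon,) = youngest.taxa
    if normalize_taxon(focal_taxon) not in leaves:
        raise LineageError(f"focal taxon {focal_taxon!r} is not a leaf of the tree")

    return PhylostratumMap(strata=tuple(strata), focal_taxon=focal_taxon)


def derive_strata_from_tree(newick: str | Path, focal: str) -> pd.DataFrame:
    """Derive a stratum spec from tree topology alone.

    Each internal node on the root-to-focal path becomes one stratum, oldest
    (root) first; leaves map to the node where their lineage diverges from
    that path. The focal taxon gets its own youngest stratum P equal to the
    number of path nodes plus one, representing the terminal branch.
    """
    tree = _parse_tree(newick)
    focal_norm = normalize_taxon(focal)
    focal_leaf = None
    for lf in tree.leaf_nodes():
        if normalize_taxon(lf.taxon.label) == focal_norm:
            focal_leaf = lf
            break
    if focal_leaf is None:
        raise LineageError(f"focal taxon {focal!r} is not a leaf of the tree")

    path = []  # root..parent-of-focal
    node = focal_leaf.parent_node
    while node is not None:
        path.append(node)
        node = node.parent_node
    path.reverse()
    if not path:
        raise LineageError("degenerate tree: focal leaf has no parent")

    rows: list[dict] = []
    on_path = set(id(n) for n in path) | {id(focal_leaf)}
    for index, node in enumerate(path, start=1):
        for child in node.child_nodes():
            if id(child) in on_path:
                continue
            for lf in child.leaf_iter():
                rows.append(
                    {
                        "taxon": lf.taxon.label,
                        "stratum": index,
                        "stratum_name": f"ps{index}",
                    }
                )
    p = len(path) + 1
    rows.append({"taxon": focal_leaf.taxon.label, "stratum": p, "stratum_name": f"ps{p}"})
    return pd.DataFrame(rows)


def _load_packaged(tree_name: str, spec_name: str, focal: str) -> PhylostratumMap:
    data = resources.files("phylostrat.data")
    newick = (data / tree_name).read_text()
    spec = read_stratum_spec(io.StringIO((data / spec_name).read_text()))
    return load_lineage(newick, spec, focal_taxon=focal)


def mouse_lineage() -> PhylostratumMap:
    """The packaged 20-stratum mouse phylostratigraphy.

    ps1 is the base of cellular life; ps20 is the lineage leading to mouse
    since the split from rat. Taxon sets are representative consensus
    groups (e.g. ps17 Boreoeutheria, ps18 Euarchontoglires).
    """
    return _load_packaged("mouse20.nwk", "mouse20_strata.tsv", "Mus_musculus")


def fish_lineage() -> PhylostratumMap:
    """The packaged 14-stratum zebrafish phylostratigraphy (ps1-12 shared
    with the mouse map)."""
    return _load_packaged("fish14.nwk", "fish14_strata.tsv", "Danio_rerio")
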