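"""Seven-rank prokaryotic lineages and the selectable taxonomic tree.

Lineages are normalized to a constant depth of 7
(superkingdom, phylum, class, order, family, genus, species) so that every
leaf of the selection tree sits at the same level.  Incomplete lineages are
handled in two tiers:

* superkingdom known, internal ranks incomplete — the organism is filed
  under ``<Superkingdom>/unclassified``, with its phylum (when known) kept
  one level below and the remaining internal slots filled with
  ``unclassified``;
* superkingdom unknown — the organism is filed under
  ``Prokaryote/unclassified``.

The genus/species leaf is always named, falling back to the first two
whitespace tokens of the organism name (with a leading "Candidatus"
stripped) when explicit genus/species ranks are missing.

The tree is a plain prefix-merge of the 7-tuples.  Selecting a node selects
all leaf genomes below it, recursively; parents are never implicitly
selected.  Input normally arrives as a flat tab-separated lineage table
(accession, organism, ``rank=value;rank=value;...``), the offline stand-in
for a live taxonomy feed.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "unclassified"
_INTERNAL = RANKS[1:5]  # phylum, class, order, family


@dataclass(frozen=True)
class Lineage:
    """A normalized 7-rank lineage."""

    ranks: tuple[str, str, str, str, str, str, str]
    source_organism: str

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise ValueError(f"lineage must have exactly 7 ranks, got {len(self.ranks)}")
        if any(not r for r in self.ranks):
            raise ValueError("lineage ranks must be non-empty strings")
        if self.ranks[0] not in ("Bacteria", "Archaea", "Prokaryote"):
            raise ValueError(
                f"superkingdom must be Bacteria, Archaea or Prokaryote, got {self.ranks[0]!r}"
            )

    @property
    def species(self) -> str:
        return self.ranks[6]


def _genus_species(organism: str) -> tuple[str, str]:
    tokens = organism.split()
    if tokens and tokens[0].lower() == "candidatus":
        tokens = tokens[1:]
    if len(tokens) >= 2:
        return tokens[0], tokens[1]
    if len(tokens) == 1:
        return tokens[0], "sp."
    raise ValueError("empty organism string: species leaf cannot be named")


def normalize_lineage(
    raw: Union[Mapping[str, str], Iterable[tuple[str, str]]], organism: str
) -> Lineage:
    """Normalize a possibly incomplete (rank, value) collection to depth 7."""
    if not organism or not organism.strip():
        raise ValueError("empty organism string: species leaf cannot be named")
    if isinstance(raw, Mapping):
        items = raw.items()
    else:
        items = raw
    d = {str(k).strip().lower(): str(v).strip() for k, v in items if v and str(v).strip()}
    fb_genus, fb_species = _genus_species(organism)
    genus = d.get("genus", fb_genus)
    species = d.get("species", fb_species)

    sk = d.get("superkingdom")
    if sk is not None and sk not in ("Bacteria", "Archaea", "Prokaryote"):
        raise ValueError(f"unsupported superkingdom {sk!r} (prokaryotes only)")
    if sk and all(r in d for r in _INTERNAL):
        ranks = (sk, d["phylum"], d["class"], d["order"], d["family"], genus, species)
    elif sk:
        # incomplete internal ranks: file under <superkingdom>/unclassified,
        # keeping the phylum one level down when it is known
        ranks = (
            sk,
            UNCLASSIFIED,
            d.get("phylum", UNCLASSIFIED),
            UNCLASSIFIED,
            UNCLASSIFIED,
            genus,
            species,
        )
    else:
        ranks = ("Prokaryote", UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED, genus, species)
    return Lineage(ranks=ranks, source_organism=organism)


@dataclass
class TaxonNode:
    """One node of the selection tree; leaves (level 6) carry accessions."""

    level: int
    name: str
    children: dict[str, "TaxonNode"] = field(default_factory=dict)
    accessions: list[str] = field(default_factory=list)
    lineage: Lineage | None = None

    def is_leaf(self) -> bool:
        return self.level == 6


@dataclass
class TaxonTree:
    """Prefix-merged hierarchy of normalized lineages."""

    root: TaxonNode = field(default_factory=lambda: TaxonNode(level=-1, name="root"))

    def leaves(self) -> list[TaxonNode]:
        out: list[TaxonNode] = []

        def walk(node: TaxonNode) -> None:
            if node.is_leaf():
                out.append(node)
                return
            for name in sorted(node.children):
                walk(node.children[name])

        walk(self.root)
        return out


def build_tree(entries: Iterable[tuple[Lineage, str]]) -> TaxonTree:
    """Prefix-merge normalized lineages into a tree.

    ``entries`` pairs each lineage with a genome accession; identical
    7-tuples merge into one species leaf holding all accessions.  The
    result is independent of input order.
    """
    tree = TaxonTree()
    for lineage, accession in entries:
        node = tree.root
        for level, name in enumerate(lineage.ranks):
            node = node.children.setdefault(name, TaxonNode(level=level, name=name))
        if node.lineage is None:
            node.lineage = lineage
        if accession not in node.accessions:
            node.accessions.append(accession)
            node.accessions.sort()
    return tree


def _resolve(tree: TaxonTree, path: Sequence[str]) -> TaxonNode:
    node = tree.root
    for i, name in enumerate(path):
        if name not in node.children:
            near = ", ".join(sorted(node.children)) or "(none)"
            prefix = "/".join(path[:i]) or "root"
            raise KeyError(
                f"no taxon {name!r} under {prefix!r}; available children: {near}"
            )
        node = node.children[name]
    return node


def select_node(tree: TaxonTree, path: Sequence[str]) -> list[str]:
    """Recursively select all leaf genome accessions under a node path.

    An empty path selects the whole tree.  Returns sorted accessions.
    """
    node = _resolve(tree, path)
    out: set[str] = set()

    def walk(n: TaxonNode) -> None:
        out.update(n.accessions)
        for child in n.children.values():
            walk(child)

    walk(node)
    return sorted(out)


def search_taxa(tree: TaxonTree, term: str) -> list[Lineage]:
    """Case-insensitive substring search across every rank of every lineage.

    Each matching species returns its full 7-rank lineage; results are
    sorted lexicographically by the 7-tuple.
    """
    if not term:
        raise ValueError("search term must be non-empty")
    needle = term.lower()
    hits = [
        leaf.lineage
        for leaf in tree.leaves()
        if leaf.lineage is not None
        and any(needle in rank.lower() for rank in leaf.lineage.ranks)
    ]
    return sorted(set(hits), key=lambda lin: lin.ranks)


def tree_to_json(tree: TaxonTree) -> str:
    def node_dict(n: TaxonNode) -> dict:
        d: dict = {"name": n.name, "level": n.level}
        if n.accessions:
            d["accessions"] = list(n.accessions)
        if n.children:
            d["children"] = [node_dict(n.children[k]) for k in sorted(n.children)]
        return d

    return json.dumps(node_dict(tree.root), indent=2)


# ---------------------------------------------------------------------------
# flat lineage table (TSV: accession <TAB> organism <TAB> rank=value;rank=value;...)

def parse_rank_string(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed rank entry {part!r}; expected rank=value")
        k, v = part.split("=", 1)
        out[k.strip().lower()] = v.strip()
    return out


def read_lineage_table(source: Union[str, Path, TextIO]) -> list[tuple[str, Lineage]]:
    """Read the tab-separated lineage table; '#' lines are comments."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    out = []
    for row in csv.reader(
        (ln for ln in lines if ln.strip() and not ln.startswith("#")), delimiter="\t"
    ):
        if len(row) < 2:
            raise ValueError(f"lineage table row needs >=2 fields: {row!r}")
        accession, organism = row[0].strip(), row[1].strip()
        ranks = parse_rank_string(row[2]) if len(row) > 2 else {}
        out.append((accession, normalize_lineage(ranks, organism)))
    return out


def write_lineage_table(entries: Iterable[tuple[str, Lineage]]) -> str:
    lines = []
    for accession, lin in entries:
        rank_str = ";".join(f"{r}={v}" for r, v in zip(RANKS, lin.ranks))
        lines.append(f"{accession}\t{lin.source_organism}\t{rank_str}")
    return "\n".join(lines) + "\n"
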