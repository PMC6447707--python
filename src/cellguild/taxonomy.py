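"""Ranked bacterial taxonomy shared by the simulator and the 16S classifier.

The tree is a plain rooted hierarchy over the standard rank ladder
domain -> phylum -> class -> order -> family -> genus.  Genus-level
bootstrap confidences are aggregated upward along this tree, and the
rank-escalation rule walks it from genus toward phylum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy configurations."""


@dataclass(frozen=True)
class TaxonomyNode:
    id: str
    name: str
    rank: str
    parent: str | None  # node id; None only for the root


@dataclass
class TaxonomyTree:
    """Rooted rank hierarchy with unique names within each rank."""

    nodes: dict[str, TaxonomyNode] = field(default_factory=dict)
    root: str = "root"

    def children(self, node_id: str) -> list[TaxonomyNode]:
        return [n for n in self.nodes.values() if n.parent == node_id]

    def lineage(self, genus: str) -> dict[str, str]:
        """Map rank -> taxon name along the path from a genus to the root."""
        node = self._by_name("genus", genus)
        out: dict[str, str] = {}
        while node is not None:
            out[node.rank] = node.name
            node = self.nodes.get(node.parent) if node.parent else None
        return out

    def genera(self) -> list[str]:
        return sorted(n.name for n in self.nodes.values() if n.rank == "genus")

    def ancestor_at(self, genus: str, rank: str) -> str:
        """Name of the ancestor of ``genus`` at ``rank``."""
        return self.lineage(genus)[rank]

    def _by_name(self, rank: str, name: str) -> TaxonomyNode:
        for n in self.nodes.values():
            if n.rank == rank and n.name == name:
                return n
        raise TaxonomyError(f"no {rank} named {name!r} in taxonomy")

    def validate(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for n in self.nodes.values():
            key = (n.rank, n.name)
            if key in seen:
                raise TaxonomyError(f"duplicate {n.rank} name {n.name!r}")
            seen[key] = n.id
            if n.parent is None:
                continue
            parent = self.nodes.get(n.parent)
            if parent is None:
                raise TaxonomyError(f"node {n.id} has unknown parent {n.parent}")
            if RANK_INDEX[n.rank] != RANK_INDEX[parent.rank] + 1:
                raise TaxonomyError(
                    f"rank of {n.id} ({n.rank}) does not directly refine {parent.rank}"
                )


def build_taxonomy(config: dict) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from a nested rank/name listing.

    ``config`` maps a single domain name to phyla, each phylum to
    ``{class: {order: {family: [genus, ...]}}}``.  A shorthand listing
    ``{phylum: [genus, ...]}`` is also accepted; intermediate ranks are
    then auto-named ``<Phylum>_cls`` / ``_ord`` / ``_fam`` per genus so
    the escalation path stays well defined.  Deterministic for identical
    configs; duplicate names within a rank raise :class:`TaxonomyError`.
    """
    tree = TaxonomyTree()
    domain = config.get("domain", "Bacteria")
    phyla = config["phyla"]
    if len(phyla) < 1:
        raise TaxonomyError("config must list at least one phylum")
    root = TaxonomyNode("root", domain, "domain", None)
    tree.nodes[root.id] = root
    counter = 0

    def add(name: str, rank: str, parent: str) -> str:
        nonlocal counter
        counter += 1
        nid = f"n{counter}"
        tree.nodes[nid] = TaxonomyNode(nid, name, rank, parent)
        return nid

    for phylum in sorted(phyla):
        spec = phyla[phylum]
        pid = add(phylum, "phylum", "root")
        if isinstance(spec, (list, tuple)):
            # shorthand: one auto-named class/order/family chain per phylum
            cid = add(f"{phylum}_cls", "class", pid)
            oid = add(f"{phylum}_ord", "order", cid)
            for genus in spec:
                fid = add(f"{genus}aceae", "family", oid)
                add(genus, "genus", fid)
        else:
            for cls in sorted(spec):
                cid = add(cls, "class", pid)
                for order in sorted(spec[cls]):
                    oid = add(order, "order", cid)
                    for family in sorted(spec[cls][order]):
                        fid = add(family, "family", oid)
                        for genus in spec[cls][order][family]:
                            add(genus, "genus", fid)
    tree.validate()
    if not tree.genera():
        raise TaxonomyError("config produced no genera")
    return tree


#: Lineages of the six genera dominating a cellulose-rich alkaline
#: paper-pulp community: two Bacteroidetes, three Firmicutes, one
#: Proteobacteria.
DEFAULT_TAXONOMY_CONFIG: dict = {
    "domain": "Bacteria",
    "phyla": {
        "Bacteroidetes": {
            "Flavobacteriia": {
                "Flavobacteriales": {"Weeksellaceae": ["Cloacibacterium"]}
            },
            "Bacteroidia": {
                "Bacteroidales": {"Porphyromonadaceae": ["Paludibacter"]}
            },
        },
        "Firmicutes": {
            "Bacilli": {"Bacillales": {"Bacillaceae": ["Exiguobacterium"]}},
            "Clostridia": {
                "Clostridiales": {
                    "Clostridiaceae": ["Clostridium"],
                    "Ruminococcaceae": ["Acetivibrio"],
                }
            },
        },
        "Proteobacteria": {
            "Gammaproteobacteria": {
                "Aeromonadales": {"Aeromonadaceae": ["Tolumonas"]}
            },
        },
    },
}


def default_taxonomy() -> TaxonomyTree:
    return build_taxonomy(DEFAULT_TAXONOMY_CONFIG)
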