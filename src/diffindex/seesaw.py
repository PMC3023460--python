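"""Seesaw-module search on a protein-interaction network.

A *seesaw module* couples significantly down-regulated and up-regulated
genes through "linker" genes whose expression does not change
significantly: on a protein-protein interaction graph, every unchanged
gene directly connected to at least one up- and one down-regulated gene
is a linker, and linkers sharing any up or down partner are merged into
one module.  Only direct (distance-1) interactions qualify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "SeesawModule",
    "read_interactions",
    "find_seesaw_modules",
]


@dataclass(frozen=True)
class SeesawModule:
    """One merged motif: unchanged linkers with their up/down partners."""

    linkers: frozenset[str]
    up_partners: frozenset[str]
    down_partners: frozenset[str]

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "linkers": sorted(self.linkers),
            "up_partners": sorted(self.up_partners),
            "down_partners": sorted(self.down_partners),
        }


def read_interactions(path, dialect: str = "two-column") -> nx.Graph:
    """Load an undirected interaction network from a tab-delimited file.

    ``dialect="two-column"``: two gene symbols per line (extra columns
    ignored); lines starting with '#' skipped.  ``dialect="biogrid-tab2"``:
    the BioGRID tab2 layout, using the Official Symbol columns (8 and 9,
    1-based).  Symbols are upper-cased; self-loops are dropped with a
    warning and duplicate edges collapse.
    """
    if dialect not in ("two-column", "biogrid-tab2"):
        raise ValueError(f"unknown dialect {dialect!r}")
    net = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if dialect == "two-column":
                if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                    raise ValueError(f"{path}:{lineno}: expected two symbols")
                a, b = parts[0], parts[1]
            else:
                if lineno == 1 and parts[0].lower().startswith(
                        ("#", "biogrid interaction id")):
                    continue
                if len(parts) < 9:
                    raise ValueError(
                        f"{path}:{lineno}: biogrid-tab2 needs >= 9 columns"
                    )
                a, b = parts[7], parts[8]
            a, b = a.strip().upper(), b.strip().upper()
            if a == b:
                n_self += 1
                net.add_node(a)
                continue
            net.add_edge(a, b)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop(s) from {path}",
                      stacklevel=2)
    return net


def find_seesaw_modules(net: nx.Graph, states: dict[str, str],
                        merge: bool = True) -> list[SeesawModule]:
    """Find seesaw modules given per-gene states 'up'/'down'/'unchanged'.

    Genes absent from ``states`` are ignored.  With ``merge`` (default),
    linkers sharing any up or down partner join one module; otherwise each
    linker yields its own raw triplet.  Output is sorted by each module's
    smallest linker symbol.
    """
    bad = {s for s in states.values()} - {"up", "down", "unchanged"}
    if bad:
        raise ValueError(f"unknown states: {sorted(bad)}")
    linkers: dict[str, tuple[set[str], set[str]]] = {}
    for gene, state in states.items():
        if state != "unchanged" or gene not in net:
            continue
        ups = {nb for nb in net[gene] if states.get(nb) == "up"}
        downs = {nb for nb in net[gene] if states.get(nb) == "down"}
        if ups and downs:
            linkers[gene] = (ups, downs)

    if not merge:
        modules = [
            SeesawModule(frozenset([g]), frozenset(u), frozenset(d))
            for g, (u, d) in linkers.items()
        ]
        return sorted(modules, key=lambda m: min(m.linkers))

    # union-find over linkers that share any partner
    parent = {g: g for g in linkers}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    partner_owner: dict[str, str] = {}
    for gene, (ups, downs) in linkers.items():
        for partner in ups | downs:
            if partner in partner_owner:
                union(partner_owner[partner], gene)
            else:
                partner_owner[partner] = gene

    groups: dict[str, list[str]] = {}
    for gene in linkers:
        groups.setdefault(find(gene), []).append(gene)

    modules = []
    for members in groups.values():
        ups: set[str] = set()
        downs: set[str] = set()
        for g in members:
            ups |= linkers[g][0]
            downs |= linkers[g][1]
        modules.append(SeesawModule(frozenset(members), frozenset(ups),
                                    frozenset(downs)))
    return sorted(modules, key=lambda m: min(m.linkers))
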