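"""Combinatorial enumeration of hetero-oligomeric assemblies.

Components are typed building blocks -- monovalent terminal caps,
bivalent and trivalent connectors, and cyclic homo-oligomeric hubs --
each carrying named binding sites.  A site is one side (A or B) of a
named heterodimer interface and binds exactly its cognate (same
interface, opposite side): interfaces are treated as perfectly
orthogonal.  Assemblies are connected multigraphs of component instances
whose edges pair cognate free sites; distinctness is connectivity
isomorphism over (component name, interface) labels, with geometry
deliberately ignored at this layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

KINDS = ("cap", "bivalent", "trivalent", "hub")
_SITE_COUNT = {"cap": 1, "bivalent": 2, "trivalent": 3}


@dataclass(frozen=True)
class BindingSite:
    interface: str
    side: str       # 'A' or 'B'; 'S' marks a self-complementary homodimer site

    def __post_init__(self):
        if self.side not in ("A", "B", "S"):
            raise ValueError(f"site side must be A, B or S, got {self.side!r}")

    @property
    def cognate(self) -> "BindingSite":
        if self.side == "S":
            return self
        return BindingSite(self.interface, "B" if self.side == "A" else "A")

    def __str__(self):
        return f"{self.interface}.{self.side}"


@dataclass(frozen=True)
class Component:
    name: str
    kind: str
    sites: tuple[BindingSite, ...]

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.kind == "hub":
            if len(self.sites) < 3 or len(set(self.sites)) != 1:
                raise ValueError("a hub carries >= 3 identical sites")
        elif len(self.sites) != _SITE_COUNT[self.kind]:
            raise ValueError(
                f"{self.kind} must carry {_SITE_COUNT[self.kind]} site(s), "
                f"got {len(self.sites)}"
            )


def parse_site(token: str) -> BindingSite:
    parts = token.strip().split(".")
    if len(parts) != 2 or not parts[0] or parts[1] not in ("A", "B", "S"):
        raise ValueError(
            f"malformed site token {token!r} (expected IFACE.A, IFACE.B or IFACE.S)"
        )
    return BindingSite(parts[0], parts[1])


def load_inventory(path) -> list[Component]:
    """Read a component inventory from a TSV with columns name, kind, sites.

    `sites` is a semicolon-joined list of interface.side tokens; hubs list
    their site once with a `xN` multiplicity suffix (e.g. HD2.B x4) or
    repeated tokens.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"name", "kind", "sites"}
    if not required.issubset(df.columns):
        raise ValueError(f"inventory must have columns {sorted(required)}")
    components = []
    seen = set()
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        name, kind = row.name.strip(), row.kind.strip()
        if name in seen:
            raise ValueError(f"line {line_no}: duplicate component name {name!r}")
        seen.add(name)
        sites: list[BindingSite] = []
        try:
            for token in str(row.sites).split(";"):
                token = token.strip()
                if " x" in token:
                    site_part, mult = token.rsplit(" x", 1)
                    sites.extend([parse_site(site_part)] * int(mult))
                else:
                    sites.append(parse_site(token))
            components.append(Component(name, kind, tuple(sites)))
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from exc
    return components


# -- pairwise complexes ------------------------------------------------------


def enumerate_heterodimer_complexes(
    inventory: list[Component],
) -> list[tuple[str, str, str]]:
    """All distinct two-component complexes (x, y, interface-set).

    A pair binds if some interface has its A side on one component and
    its B side on the other.  Distinctness is by unordered component-name
    pair; the output is sorted and deterministic.  A component that
    carries both sides of one interface can pair with itself.
    """
    found = {}
    items = list(inventory)
    for x, y in combinations(items, 2):
        ifaces = _pair_interfaces(x, y)
        if ifaces:
            key = tuple(sorted((x.name, y.name)))
            found[key] = ",".join(sorted(ifaces))
    for x in items:
        ifaces = _pair_interfaces(x, x)
        if ifaces:
            found[(x.name, x.name)] = ",".join(sorted(ifaces))
    return [(a, b, i) for (a, b), i in sorted(found.items())]


def _pair_interfaces(x: Component, y: Component) -> set[str]:
    out = set()
    for s in x.sites:
        if s.cognate in y.sites:
            out.add(s.interface)
    return out


# -- full assembly enumeration ----------------------------------------------


class Assembly:
    """A connected arrangement of component instances with cognate edges."""

    def __init__(self, graph: nx.MultiGraph, inventory_by_name: dict):
        self.graph = graph
        self._by_name = inventory_by_name

    @property
    def size(self) -> int:
        return self.graph.number_of_nodes()

    def component_names(self) -> list[str]:
        return sorted(self.graph.nodes[n]["component"] for n in self.graph.nodes)

    def free_sites(self) -> list[tuple[int, BindingSite]]:
        used: dict[int, list[BindingSite]] = {n: [] for n in self.graph.nodes}
        for _, _, d in self.graph.edges(data=True):
            for node, site in d["sites"]:
                used[node].append(site)
        out = []
        for node in self.graph.nodes:
            comp = self._by_name[self.graph.nodes[node]["component"]]
            remaining = list(comp.sites)
            for s in used[node]:
                remaining.remove(s)
            out.extend((node, s) for s in remaining)
        return out

    @property
    def saturated(self) -> bool:
        return not self.free_sites()

    @property
    def topology(self) -> str:
        g = nx.Graph(self.graph)
        if self.graph.number_of_edges() >= self.graph.number_of_nodes():
            return "cyclic"
        if any(self.graph.degree(n) >= 3 for n in self.graph.nodes):
            return "branched"
        return "linear"

    def validate(self) -> bool:
        """Cognate-edge + single-binding + connectivity invariants."""
        if not nx.is_connected(nx.Graph(self.graph)):
            return False
        per_node_used: dict = {n: [] for n in self.graph.nodes}
        for u, v, d in self.graph.edges(data=True):
            (nu, su), (nv, sv) = d["sites"]
            if su.cognate != sv:
                return False
            per_node_used[nu].append(su)
            per_node_used[nv].append(sv)
        for n, used in per_node_used.items():
            avail = list(self._by_name[self.graph.nodes[n]["component"]].sites)
            for s in used:
                if s not in avail:
                    return False
                avail.remove(s)
        return True


def _canonical_key(graph: nx.MultiGraph):
    """A cheap invariant for grouping candidate isomorphs."""
    names = sorted(d["component"] for _, d in graph.nodes(data=True))
    edges = sorted(d["interface"] for _, _, d in graph.edges(data=True))
    degs = sorted(deg for _, deg in graph.degree())
    return (tuple(names), tuple(edges), tuple(degs))


def _isomorphic(g1: nx.MultiGraph, g2: nx.MultiGraph) -> bool:
    nm = nx.algorithms.isomorphism.categorical_node_match("component", None)
    em = nx.algorithms.isomorphism.categorical_multiedge_match("interface", None)
    return nx.is_isomorphic(g1, g2, node_match=nm, edge_match=em)


def enumerate_assemblies(
    inventory: list[Component],
    max_components: int,
    allow_cyclic: bool = False,
    saturated_only: bool = False,
) -> list[Assembly]:
    """Exhaustive connected assemblies up to `max_components` instances.

    Components may appear multiple times.  Hubs participate as single
    nodes of their full valency.  Duplicates are removed by labelled
    graph isomorphism.  With `allow_cyclic`, ring-closing edges between
    two free cognate sites of an existing assembly are also explored.
    """
    if max_components > 8:
        raise ValueError("max_components > 8 is intractable by design")
    by_name = {c.name: c for c in inventory}
    seen: dict = {}
    results: list[Assembly] = []

    def register(graph: nx.MultiGraph) -> bool:
        key = _canonical_key(graph)
        bucket = seen.setdefault(key, [])
        for g in bucket:
            if _isomorphic(g, graph):
                return False
        bucket.append(graph.copy())
        results.append(Assembly(graph.copy(), by_name))
        return True

    def expand(assembly: Assembly):
        graph = assembly.graph
        free = assembly.free_sites()
        # attach a new instance
        if graph.number_of_nodes() < max_components:
            for node, site in free:
                for comp in inventory:
                    if site.cognate in comp.sites:
                        new = graph.copy()
                        new_id = max(graph.nodes) + 1
                        new.add_node(new_id, component=comp.name)
                        new.add_edge(
                            node, new_id,
                            interface=site.interface,
                            sites=((node, site), (new_id, site.cognate)),
                        )
                        cand = Assembly(new, by_name)
                        if register(new):
                            expand(cand)
        # close a cycle between existing free sites
        if allow_cyclic:
            for (n1, s1), (n2, s2) in combinations(free, 2):
                if s1.cognate != s2:
                    continue
                new = graph.copy()
                new.add_edge(
                    n1, n2, interface=s1.interface, sites=((n1, s1), (n2, s2))
                )
                cand = Assembly(new, by_name)
                if register(new):
                    expand(cand)

    for comp in inventory:
        g = nx.MultiGraph()
        g.add_node(0, component=comp.name)
        a = Assembly(g, by_name)
        if register(g):
            expand(a)

    if saturated_only:
        results = [a for a in results if a.saturated]
    results.sort(key=lambda a: (a.size, a.component_names(), stoichiometry_of(a)))
    return results


def stoichiometry_of(assembly: Assembly) -> str:
    """Canonical stoichiometry label.

    Unique component names are lettered A, B, ... in traversal order from
    a deterministic root (the lexicographically smallest terminal
    component, or smallest of all for cycles).  Linear assemblies are
    written as the letter sequence along the path (e.g. ABC, ABBA);
    branched, cyclic and hub-containing assemblies as letter+count
    multiplicities (e.g. A4B4).
    """
    graph = assembly.graph
    nodes = list(graph.nodes)
    if len(nodes) == 1:
        return "A"
    terminals = [n for n in nodes if graph.degree(n) == 1]
    pool = terminals or nodes
    root = min(pool, key=lambda n: (graph.nodes[n]["component"], n))
    order = list(nx.bfs_tree(graph, root))
    letters: dict[str, str] = {}
    for n in order:
        name = graph.nodes[n]["component"]
        if name not in letters:
            letters[name] = chr(ord("A") + len(letters))
    is_path = (
        assembly.topology == "linear"
        and all(graph.degree(n) <= 2 for n in nodes)
    )
    if is_path:
        # walk the path from the root terminal
        seq = []
        prev, cur = None, root
        while cur is not None:
            seq.append(letters[graph.nodes[cur]["component"]])
            nxt = [m for m in graph.neighbors(cur) if m != prev]
            prev, cur = cur, (nxt[0] if nxt else None)
        return "".join(seq)
    counts: dict[str, int] = {}
    for n in nodes:
        comp = assembly._by_name[graph.nodes[n]["component"]]
        letter = letters[comp.name]
        # a Ck hub is a homo-oligomer of k protomer chains
        mult = len(comp.sites) if comp.kind == "hub" else 1
        counts[letter] = counts.get(letter, 0) + mult
    return "".join(
        f"{letter}{count if count > 1 else ''}" for letter, count in sorted(counts.items())
    )
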