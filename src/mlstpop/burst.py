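"""Clonal-complex inference and minimum spanning trees on allelic profiles.

The population model follows the eBURST view of clonal expansion: a
founder ST diversifies by accumulating single-locus variants (SLVs).
STs are grouped by connected components of the SLV graph (profiles
sharing L-1 of L loci); components with >= 3 member STs are clonal
complexes (named after their predicted founder, e.g. CC9), components of
2 are doublets, and unlinked STs are singletons.  The founder of a
complex is the member with the most SLVs, with documented deterministic
tie-breaks (DLV count, isolate count, lower ST number).

The minimum spanning tree over all STs uses Prim's algorithm on the
complete graph weighted by profile mismatch counts, with a deterministic
tie-break (heavier in-tree endpoint by isolate count, then lower ST on
the new endpoint).  MST total weight is tie-invariant; the tree itself
can legitimately differ between equally valid tie rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .scheme import IsolateRecord

__all__ = [
    "profile_distance",
    "variant_class",
    "ProfileMatrix",
    "BurstGroup",
    "BurstPartition",
    "MSTEdge",
    "slv_graph",
    "burst_groups",
    "predict_founder",
    "minimum_spanning_tree",
    "mst_to_graph",
]


def profile_distance(p: Sequence[int], q: Sequence[int]) -> int:
    """Number of loci at which two allelic profiles differ."""
    if len(p) != len(q):
        raise ValueError(f"profile lengths differ: {len(p)} vs {len(q)}")
    return sum(a != b for a, b in zip(p, q))


def variant_class(d: int) -> str:
    """eBURST nomenclature for a profile distance: SLV/DLV/TLV/unrelated."""
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    return {1: "SLV", 2: "DLV", 3: "TLV"}.get(d, "identical" if d == 0 else "unrelated")


@dataclass
class ProfileMatrix:
    """Distinct STs with their profiles and isolate counts."""

    sts: list[int]
    profiles: dict[int, tuple[int, ...]]
    counts: dict[int, int]
    source_counts: dict[int, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sts)) != len(self.sts):
            raise ValueError("duplicate STs in profile matrix")
        for st in self.sts:
            if self.counts.get(st, 0) < 1:
                raise ValueError(f"ST{st} has isolate count < 1")

    @classmethod
    def from_records(cls, records: Iterable[IsolateRecord]) -> "ProfileMatrix":
        sts: list[int] = []
        profiles: dict[int, tuple[int, ...]] = {}
        counts: dict[int, int] = {}
        sources: dict[int, dict[str, int]] = {}
        for rec in records:
            if rec.st is None or rec.profile is None:
                continue
            if rec.st not in profiles:
                sts.append(rec.st)
                profiles[rec.st] = rec.profile
                counts[rec.st] = 0
                sources[rec.st] = {}
            elif profiles[rec.st] != rec.profile:
                raise ValueError(f"ST{rec.st} carries two different profiles")
            counts[rec.st] += 1
            if rec.source_type:
                sources[rec.st][rec.source_type] = sources[rec.st].get(rec.source_type, 0) + 1
        return cls(sts=sts, profiles=profiles, counts=counts, source_counts=sources)

    @classmethod
    def from_profiles(cls, profiles: dict[int, Sequence[int]],
                      counts: Optional[dict[int, int]] = None) -> "ProfileMatrix":
        sts = list(profiles)
        return cls(
            sts=sts,
            profiles={st: tuple(p) for st, p in profiles.items()},
            counts=dict(counts) if counts else {st: 1 for st in sts},
        )

    def distance(self, a: int, b: int) -> int:
        return profile_distance(self.profiles[a], self.profiles[b])


@dataclass(frozen=True)
class BurstGroup:
    members: tuple[int, ...]  # sorted ST numbers
    founder: Optional[int]
    category: str  # "CC" | "doublet" | "singleton"

    @property
    def name(self) -> str:
        if self.category == "CC":
            return f"CC{self.founder}"
        return f"{self.category}:{'-'.join(map(str, self.members))}"


@dataclass(frozen=True)
class BurstPartition:
    groups: tuple[BurstGroup, ...]

    @property
    def clonal_complexes(self) -> tuple[BurstGroup, ...]:
        return tuple(g for g in self.groups if g.category == "CC")

    @property
    def doublets(self) -> tuple[BurstGroup, ...]:
        return tuple(g for g in self.groups if g.category == "doublet")

    @property
    def singletons(self) -> tuple[BurstGroup, ...]:
        return tuple(g for g in self.groups if g.category == "singleton")


def slv_graph(m: ProfileMatrix, group_def: int = 1) -> nx.Graph:
    """Graph on STs with edges between profiles differing at <= group_def loci."""
    g = nx.Graph()
    g.add_nodes_from(m.sts)
    for i, a in enumerate(m.sts):
        for b in m.sts[i + 1:]:
            if m.distance(a, b) <= group_def:
                g.add_edge(a, b)
    return g


def _variant_counts(st: int, members: Sequence[int], m: ProfileMatrix) -> tuple[int, int]:
    slv = sum(1 for o in members if o != st and m.distance(st, o) == 1)
    dlv = sum(1 for o in members if o != st and m.distance(st, o) == 2)
    return slv, dlv


def predict_founder(members: Sequence[int], m: ProfileMatrix) -> Optional[int]:
    """The member ST with the most SLVs within the group.

    Ties break by more DLVs, then more isolates, then lower ST number.
    Two-member groups get no founder.
    """
    members = sorted(members)
    if len(members) < 2:
        raise ValueError("founder prediction needs a group of >= 2 STs")
    if len(members) == 2:
        return None

    def key(st: int):
        slv, dlv = _variant_counts(st, members, m)
        return (-slv, -dlv, -m.counts.get(st, 1), st)

    return min(members, key=key)


def burst_groups(m: ProfileMatrix, group_def: int = 1) -> BurstPartition:
    """Partition STs into clonal complexes / doublets / singletons.

    Groups are the connected components of the SLV graph; the default
    ``group_def=1`` is the eBURST convention of sharing L-1 of L loci.
    """
    if not m.sts:
        raise ValueError("empty profile matrix")
    components = nx.connected_components(slv_graph(m, group_def))
    groups = []
    for comp in components:
        members = tuple(sorted(comp))
        if len(members) >= 3:
            groups.append(BurstGroup(members, predict_founder(members, m), "CC"))
        elif len(members) == 2:
            groups.append(BurstGroup(members, None, "doublet"))
        else:
            groups.append(BurstGroup(members, None, "singleton"))
    groups.sort(key=lambda g: (-len(g.members), g.members[0]))
    return BurstPartition(tuple(groups))


@dataclass(frozen=True)
class MSTEdge:
    st_a: int
    st_b: int
    weight: int


def minimum_spanning_tree(m: ProfileMatrix) -> list[MSTEdge]:
    """Prim's algorithm on the complete profile-distance graph.

    Deterministic and seed-free: growth starts at the ST with the most
    isolates (lowest ST on ties); among equal-weight frontier edges the
    one whose in-tree endpoint has more isolates wins, then the lower ST
    number on the new endpoint, then the lower in-tree ST.
    """
    if len(m.sts) < 2:
        raise ValueError("MST needs at least 2 STs")
    start = min(m.sts, key=lambda s: (-m.counts.get(s, 1), s))
    in_tree = [start]
    out = set(m.sts) - {start}
    edges: list[MSTEdge] = []
    while out:
        best = None
        for u in in_tree:
            for v in out:
                cand = (m.distance(u, v), -m.counts.get(u, 1), v, u)
                if best is None or cand < best:
                    best = cand
                    best_edge = (u, v)
        u, v = best_edge
        edges.append(MSTEdge(u, v, best[0]))
        in_tree.append(v)
        out.remove(v)
    return edges


def mst_to_graph(edges: Sequence[MSTEdge], m: ProfileMatrix) -> nx.Graph:
    """MST as a networkx graph with rendering attributes (for DOT/GraphML)."""
    g = nx.Graph()
    for st in m.sts:
        sources = m.source_counts.get(st, {})
        majority = max(sources, key=sources.get) if sources else ""
        g.add_node(st, isolates=m.counts.get(st, 1), source_majority=majority)
    for e in edges:
        g.add_edge(e.st_a, e.st_b, weight=e.weight)
    return g
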