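"""Macrocyst compatibility: replicate aggregation, group tables, mating types.

Macrocyst formation between a pair of clones is the assay for sexual
compatibility.  Replicated pairwise mixes are aggregated by strict
majority (ties flagged ambiguous and excluded), successful pairings form
the edges of a compatibility graph, and mating types are inferred by
2-colouring: a bipartite component is consistent with exactly two mating
types, while an odd cycle — e.g. a triad of mutually compatible clones —
indicates more than two types or bisexual clones.  Self-pairings are kept
as selfing records, never as graph edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import pandas as pd

Outcome = Literal["macrocysts", "none"]


@dataclass(frozen=True)
class MatingObservation:
    """One replicate of one (unordered) pairwise mix."""

    clone_a: str
    clone_b: str
    replicate: int
    outcome: Outcome

    def __post_init__(self) -> None:
        if self.outcome not in ("macrocysts", "none"):
            raise ValueError(f"unknown outcome: {self.outcome!r}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.clone_a, self.clone_b))

    @property
    def is_self(self) -> bool:
        return self.clone_a == self.clone_b


@dataclass
class MatingGraph:
    """Aggregated compatibility graph.

    ``edges`` holds majority-positive non-self pairs; ``ambiguous_pairs``
    are exact replicate ties (excluded from edges); ``selfings`` maps a
    clone to its aggregated self-pairing outcome; ``tested_pairs`` is every
    non-self pair with at least one observation.
    """

    nodes: set[str]
    edges: set[frozenset[str]]
    ambiguous_pairs: list[frozenset[str]]
    selfings: dict[str, str]
    tested_pairs: set[frozenset[str]] = field(default_factory=set)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g


@dataclass
class GroupTable:
    """Group-by-group counts of successful vs. tested mixes (upper triangle)."""

    successes: pd.DataFrame
    totals: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        """Cells as 'successes/tested' strings, lower triangle blank."""
        out = self.totals.astype(object).copy()
        for i, g in enumerate(out.index):
            for j, h in enumerate(out.columns):
                if j < i:
                    out.loc[g, h] = ""
                else:
                    out.loc[g, h] = (
                        f"{int(self.successes.loc[g, h])}/{int(self.totals.loc[g, h])}"
                    )
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.formatted().to_csv(path, sep="\t")


@dataclass
class MatingTypeReport:
    bipartite: bool
    parts: tuple[list[str], list[str]] | None
    odd_cycles: list[list[str]]
    unassigned: list[str]
    completeness: float | None  # fraction of tested cross-part pairs that mated

    def to_json(self, path: str | Path) -> None:
        payload = {
            "bipartite": self.bipartite,
            "parts": [sorted(p) for p in self.parts] if self.parts else None,
            "odd_cycles": self.odd_cycles,
            "unassigned": sorted(self.unassigned),
            "completeness": self.completeness,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def read_observations(path: str | Path) -> list[MatingObservation]:
    """Read a TSV with columns clone_a, clone_b, replicate, outcome."""
    df = pd.read_csv(path, sep="\t", dtype={"clone_a": str, "clone_b": str})
    return [
        MatingObservation(
            clone_a=row.clone_a, clone_b=row.clone_b,
            replicate=int(row.replicate), outcome=row.outcome,
        )
        for row in df.itertuples()
    ]


def aggregate_replicates(observations: Iterable[MatingObservation]) -> MatingGraph:
    """Aggregate replicated observations per unordered pair by strict majority.

    A pair is an edge iff macrocyst-positive replicates strictly outnumber
    negatives; exact ties are reported as ambiguous and excluded.
    Self-pairings are aggregated the same way but stored as selfing records
    (positive/negative/ambiguous), never as edges.
    """
    votes: dict[frozenset[str], list[int]] = {}
    nodes: set[str] = set()
    tested: set[frozenset[str]] = set()
    self_votes: dict[str, list[int]] = {}
    for obs in observations:
        nodes.update((obs.clone_a, obs.clone_b))
        positive = 1 if obs.outcome == "macrocysts" else 0
        if obs.is_self:
            self_votes.setdefault(obs.clone_a, []).append(positive)
        else:
            tested.add(obs.pair)
            votes.setdefault(obs.pair, []).append(positive)
    edges: set[frozenset[str]] = set()
    ambiguous: list[frozenset[str]] = []
    for pair, v in votes.items():
        pos = sum(v)
        neg = len(v) - pos
        if pos > neg:
            edges.add(pair)
        elif pos == neg:
            ambiguous.append(pair)
    selfings = {}
    for clone, v in self_votes.items():
        pos = sum(v)
        neg = len(v) - pos
        selfings[clone] = (
            "macrocysts" if pos > neg else "none" if neg > pos else "ambiguous"
        )
    return MatingGraph(
        nodes=nodes,
        edges=edges,
        ambiguous_pairs=sorted(ambiguous, key=sorted),
        selfings=selfings,
        tested_pairs=tested,
    )


def group_table(
    graph: MatingGraph,
    groups: dict[str, str],
    tested_pairs: Iterable[frozenset[str]] | None = None,
    include_self: bool = True,
) -> GroupTable:
    """Successful/tested mix counts per unordered group pair.

    Cell (G, H) counts tested non-self pairs with one member in G and the
    other in H; the diagonal additionally counts self-pairings when
    ``include_self`` is set.  Successes are pairs that aggregated positive.
    """
    tested = set(tested_pairs) if tested_pairs is not None else set(graph.tested_pairs)
    clones = set().union(*tested) if tested else set()
    clones |= set(graph.selfings) if include_self else set()
    unlabeled = sorted(c for c in clones if c not in groups)
    if unlabeled:
        raise ValueError(f"clones without group label: {unlabeled}")
    labels = sorted(set(groups[c] for c in clones) | set(groups.values()))
    successes = pd.DataFrame(0, index=labels, columns=labels)
    totals = pd.DataFrame(0, index=labels, columns=labels)
    for pair in tested:
        a, b = sorted(pair)
        ga, gb = sorted((groups[a], groups[b]))
        totals.loc[ga, gb] += 1
        if pair in graph.edges:
            successes.loc[ga, gb] += 1
    if include_self:
        for clone, outcome in graph.selfings.items():
            g = groups[clone]
            totals.loc[g, g] += 1
            if outcome == "macrocysts":
                successes.loc[g, g] += 1
    return GroupTable(successes=successes, totals=totals)


def _shortest_odd_cycle(g: nx.Graph) -> list[str]:
    """Shortest odd cycle in a connected non-bipartite graph.

    BFS from every node; an edge joining two nodes at the same BFS level
    closes an odd walk of length 2*level + 1, and the minimum over sources
    is a shortest odd cycle.
    """
    best: list[str] | None = None
    for source in g.nodes:
        levels = nx.single_source_shortest_path(g, source)
        for u, v in g.edges:
            if u in levels and v in levels:
                pu, pv = levels[u], levels[v]
                if len(pu) == len(pv):
                    # paths may share a prefix; keep only the cycle through
                    # their last common ancestor
                    k = 0
                    while k < len(pu) and pu[k] == pv[k]:
                        k += 1
                    cycle = pu[k - 1:] + list(reversed(pv[k:]))
                    if best is None or len(cycle) < len(best):
                        best = cycle
    assert best is not None
    return best


def infer_mating_types(
    graph: MatingGraph,
    tested_pairs: Iterable[frozenset[str]] | None = None,
) -> MatingTypeReport:
    """Attempt a two-mating-type assignment by 2-colouring the graph.

    Each connected component is 2-coloured; if every component is
    consistent the graph is bipartite and the two colour classes are the
    candidate mating types (isolated clones reported unassigned).
    Otherwise a shortest odd cycle — the paper-level signature being a
    triad — is reported per violating component.  Completeness is the
    fraction of tested cross-part pairs that actually mated.
    """
    g = graph.graph()
    tested = set(tested_pairs) if tested_pairs is not None else set(graph.tested_pairs)
    part_a: list[str] = []
    part_b: list[str] = []
    odd_cycles: list[list[str]] = []
    unassigned = sorted(n for n in g.nodes if g.degree(n) == 0)
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            continue
        sub = g.subgraph(comp)
        if nx.is_bipartite(sub):
            colors = nx.algorithms.bipartite.color(sub)
            zero = sorted(n for n, c in colors.items() if c == 0)
            one = sorted(n for n, c in colors.items() if c == 1)
            # deterministic orientation: the part containing the smallest id first
            part_a.extend(zero)
            part_b.extend(one)
        else:
            odd_cycles.append(_shortest_odd_cycle(sub))
    bipartite = not odd_cycles
    completeness: float | None = None
    parts: tuple[list[str], list[str]] | None = None
    if bipartite:
        parts = (sorted(part_a), sorted(part_b))
        in_a, in_b = set(part_a), set(part_b)
        cross = [
            p for p in tested
            if len(p & in_a) == 1 and len(p & in_b) == 1
        ]
        if cross:
            completeness = sum(1 for p in cross if p in graph.edges) / len(cross)
    return MatingTypeReport(
        bipartite=bipartite,
        parts=parts,
        odd_cycles=odd_cycles,
        unassigned=unassigned,
        completeness=completeness,
    )
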