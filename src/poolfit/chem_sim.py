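"""Compound structural similarity: Tanimoto coefficients between
extended-connectivity fingerprint bit-sets, threshold similarity networks,
and per-cluster selection of the most potent representatives.

Fingerprints are consumed as sets of set-bit indices generated externally;
the module is agnostic to radius and bit length.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass
class SimilarityNetwork:
    """Undirected compound similarity graph at a Tanimoto threshold.

    ``components`` maps each compound to its component label — the
    lexicographically smallest member id, so labels are stable across node
    orderings.
    """

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted((min(a, b), max(a, b), d["tanimoto"]) for a, b, d in self.graph.edges(data=True))

    @property
    def components(self) -> dict[str, str]:
        return {
            node: min(comp)
            for comp in nx.connected_components(self.graph)
            for node in comp
        }

    def to_edge_list(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["compound_a", "compound_b", "tanimoto"])


def tanimoto(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """|A n B| / |A u B| on [0, 1]."""
    if not a or not b:
        raise ValueError("fingerprints must be non-empty")
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


def build_network(fingerprints: dict[str, frozenset[int]], threshold: float) -> SimilarityNetwork:
    """All-pairs Tanimoto network with edges at coefficient >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    g = nx.Graph()
    ids = sorted(fingerprints)
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            t = tanimoto(fingerprints[a], fingerprints[b])
            if t >= threshold:
                g.add_edge(a, b, tanimoto=t)
    return SimilarityNetwork(graph=g, threshold=threshold)


def select_representatives(
    network: SimilarityNetwork,
    activity: dict[str, float],
    per_component: int = 1,
    lower_is_more_potent: bool = True,
) -> list[str]:
    """Most potent member(s) of every component, up to ``per_component``.

    ``activity`` is a potency value per compound (an inhibitory
    concentration by default, so lower = more potent). Ties go to the
    lexicographically first compound id. Returns a sorted compound list.
    """
    missing = set(network.nodes) - set(activity)
    if missing:
        raise ValueError(f"missing activity for {sorted(missing)[:3]}...")
    sign = 1 if lower_is_more_potent else -1
    chosen: list[str] = []
    by_comp: dict[str, list[str]] = {}
    for node, label in network.components.items():
        by_comp.setdefault(label, []).append(node)
    for label in sorted(by_comp):
        members = sorted(by_comp[label], key=lambda c: (sign * activity[c], c))
        chosen.extend(members[:per_component])
    return sorted(chosen)
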