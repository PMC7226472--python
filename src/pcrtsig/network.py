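"""Interaction-frequency pathway analysis over a protein-protein network.

Given a signature gene set, a user-supplied undirected PPI network and
pathway gene sets (GMT), this module finds the network neighborhood of the
signature, computes each neighbor's *interaction frequency* — the percentage
of signature genes it interacts with (within a hop limit) — and ranks
pathways by how strongly the neighborhood maps onto them.  A frequency of
100% means a gene interacts with every signature gene present in the
network; genes at or above the high-frequency threshold (default 75%) are
annotated per pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "load_network",
    "load_gene_sets",
    "find_interactors",
    "interaction_frequency",
    "rank_pathways",
    "PathwayReport",
]

HIGH_FREQUENCY_THRESHOLD = 75.0  # percent


def load_network(path: str | Path) -> nx.Graph:
    """Read a 2-column TSV edge list into an undirected graph.

    Gene symbols are uppercased; duplicate edges collapse and self-loops are
    dropped.  A third column, if present, is stored as edge weight.
    """
    g = nx.Graph()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{line_no}: expected at least 2 columns")
        a, b = parts[0].upper(), parts[1].upper()
        if a == b:
            continue
        if len(parts) > 2:
            g.add_edge(a, b, weight=float(parts[2]))
        else:
            g.add_edge(a, b)
    return g


def load_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read GMT pathway gene sets: name, description, member genes per line."""
    sets: dict[str, set[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{line_no}: GMT lines need name, description, >=1 gene")
        genes = {g.upper() for g in parts[2:] if g.strip()}
        if not genes:
            raise ValueError(f"{path}:{line_no}: empty gene set {parts[0]!r}")
        sets[parts[0]] = genes
    return sets


def _present_signature(network: nx.Graph, signature: list[str]) -> list[str]:
    sig = [g.upper() for g in signature]
    present = [g for g in sig if g in network]
    missing = sorted(set(sig) - set(present))
    if missing:
        warnings.warn(f"signature genes absent from network: {missing}", stacklevel=3)
    return present


def find_interactors(
    network: nx.Graph, signature: list[str], max_distance: int = 1
) -> dict[str, int]:
    """Genes within ``max_distance`` hops of any signature gene.

    Returns neighbor -> distance to the nearest signature gene; the
    signature genes themselves are excluded.  ``max_distance=0`` or an empty
    network yields an empty set (with a warning for the latter).
    """
    if network.number_of_nodes() == 0:
        warnings.warn("empty network; no interactors", stacklevel=2)
        return {}
    present = _present_signature(network, signature)
    if not present or max_distance <= 0:
        return {}
    dist = nx.multi_source_dijkstra_path_length(
        network, present, cutoff=max_distance, weight=None
    )
    return {g: int(d) for g, d in dist.items() if g not in set(present)}


def interaction_frequency(
    network: nx.Graph,
    signature: list[str],
    candidate: str,
    max_distance: int = 1,
) -> float | None:
    """Percentage of in-network signature genes the candidate interacts with.

    100 x (signature genes within ``max_distance`` of the candidate) /
    (signature genes present in the network).  None when no signature gene
    is in the network (undefined).
    """
    candidate = candidate.upper()
    if candidate not in network:
        raise KeyError(f"candidate gene {candidate!r} not in network")
    present = _present_signature(network, signature)
    if not present:
        return None
    dist = nx.single_source_shortest_path_length(network, candidate, cutoff=max_distance)
    hits = sum(1 for g in present if g in dist and dist[g] > 0)
    # a candidate that is itself a signature gene still interacts with itself
    # only through an actual path, so distance 0 never counts
    return 100.0 * hits / len(present)


@dataclass
class PathwayReport:
    """Ranked pathway table plus the per-gene frequency map behind it."""

    table: pd.DataFrame          # one row per pathway, ranked
    frequencies: dict[str, float]  # interactor -> frequency (%)
    high_frequency_genes: list[str]
    threshold: float


def rank_pathways(
    network: nx.Graph,
    signature: list[str],
    gene_sets: dict[str, set[str]],
    *,
    top_k: int = 10,
    max_distance: int = 1,
    threshold: float = HIGH_FREQUENCY_THRESHOLD,
) -> PathwayReport:
    """Rank pathways by signature interaction burden.

    Per pathway: *interacting genes* are the pathway members in the
    signature's neighborhood; the *interaction count* sums, over those
    genes, how many signature genes each one touches within
    ``max_distance``.  Pathways sort by (interaction count, interacting-gene
    count) descending with lexicographic name tie-break; the top ``top_k``
    are returned, annotated with their high-interaction-frequency members.
    """
    present = _present_signature(network, signature)
    interactors = find_interactors(network, signature, max_distance=max_distance)
    freqs: dict[str, float] = {}
    links: dict[str, int] = {}
    for g in interactors:
        dist = nx.single_source_shortest_path_length(network, g, cutoff=max_distance)
        hits = sum(1 for s in present if s in dist and dist[s] > 0)
        links[g] = hits
        freqs[g] = 100.0 * hits / len(present) if present else 0.0

    high = sorted(g for g, f in freqs.items() if f >= threshold)

    rows = []
    for name, members in gene_sets.items():
        inter = sorted(set(interactors) & members)
        rows.append(
            {
                "pathway": name,
                "interaction_count": int(sum(links[g] for g in inter)),
                "interacting_genes_count": len(inter),
                "interacting_genes": "|".join(inter),
                "high_frequency_genes": "|".join(g for g in inter if freqs[g] >= threshold),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(
            by=["interaction_count", "interacting_genes_count", "pathway"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        .head(top_k)
        .reset_index(drop=True)
    )
    table.index = pd.RangeIndex(1, len(table) + 1, name="rank")
    return PathwayReport(table, freqs, high, threshold)
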