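"""Guilt-by-association candidate ranking.

Genes not on the known disease list (the seeds) are scored by the number
of their distinct direct neighbors that *are* seeds in the full interaction
network. Candidates are ranked by that connection count descending, ties
broken by gene id ascending, so output order is fully deterministic. A
strict minimum-connection cut ("more than m connections") can then be
applied; by default all candidates are reported and the cut is a flag,
because any particular realized cutoff is specific to one network snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .network import Network

__all__ = ["CandidateScore", "score_candidates", "select_candidates", "write_candidates_tsv"]


@dataclass(frozen=True)
class CandidateScore:
    gene_id: int
    connections: int
    rank: int


def score_candidates(full_network: Network, seeds: Iterable[int]) -> list[CandidateScore]:
    """Score every non-seed node by its number of seed neighbors.

    Zero-connection nodes are retained with score 0 so the candidate
    universe is the full non-seed node set. Raises if no seed maps into the
    network.
    """
    seed_set = set(seeds) & set(full_network.graph.nodes)
    if not seed_set:
        raise ValueError("no seed gene maps to the network")
    graph = full_network.graph
    scored = [
        (node, sum(1 for nb in graph.neighbors(node) if nb in seed_set))
        for node in graph.nodes
        if node not in seed_set
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return [
        CandidateScore(gene_id=node, connections=count, rank=i + 1)
        for i, (node, count) in enumerate(scored)
    ]


def select_candidates(
    scores: Iterable[CandidateScore], min_connections: int
) -> list[CandidateScore]:
    """Keep candidates with strictly more than ``min_connections`` links."""
    if min_connections < 0:
        raise ValueError("min_connections must be >= 0")
    return [s for s in scores if s.connections > min_connections]


def write_candidates_tsv(
    scores: Iterable[CandidateScore], path: str, symbols: Mapping[int, str] | None = None
) -> None:
    symbols = symbols or {}
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene_id\tsymbol\tconnections\trank\n")
        for s in scores:
            handle.write(f"{s.gene_id}\t{symbols.get(s.gene_id, '')}\t{s.connections}\t{s.rank}\n")
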