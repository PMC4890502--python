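"""PPI network construction, degree statistics, and hub-gene detection.

Interactions from merged interaction databases arrive as PSI-MITAB 2.5 or
plain two-column edge lists. The network is simple and undirected: edges
are deduplicated across orientations, self-loops removed, and a node's
degree is its number of distinct neighbors. Hubs are the nodes whose degree
strictly exceeds the mean degree plus ``sd_multiplier`` (default 2) sample
standard deviations — the classical mean + 2 SD rule. The degree histogram
is summarized by a least-squares power-law fit on log-log axes, the usual
scale-free diagnostic for such networks.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionEdge",
    "Network",
    "DegreeDistribution",
    "PowerLawFit",
    "HubCall",
    "load_interactions",
    "build_network",
    "induced_subgraph",
    "degree_distribution",
    "fit_power_law",
    "detect_hubs",
    "write_sif",
    "write_graphml",
    "write_degree_histogram_tsv",
    "write_hubs_tsv",
]


@dataclass(frozen=True)
class InteractionEdge:
    """One binary interaction, canonically ordered (gene_a <= gene_b)."""

    gene_a: int
    gene_b: int
    source_db: str = ""
    species_pair: tuple[int, int] = (0, 0)

    @classmethod
    def make(
        cls,
        a: int,
        b: int,
        source_db: str = "",
        species_pair: tuple[int, int] = (0, 0),
    ) -> "InteractionEdge":
        lo, hi = (a, b) if a <= b else (b, a)
        return cls(lo, hi, source_db, species_pair)


@dataclass
class Network:
    """Simple undirected gene graph with degree lookup.

    Backed by a :class:`networkx.Graph`; ``isolated_mapped`` records genes
    that were requested for an induced subgraph but kept no edge in it.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    isolated_mapped: frozenset[int] = frozenset()

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    @property
    def node_degrees(self) -> dict[int, int]:
        return dict(self.graph.degree)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene_id: int) -> int:
        return self.graph.degree(gene_id)

    def check_handshake(self) -> None:
        """Assert the handshake lemma (sum of degrees = 2|E|)."""
        total = sum(d for _, d in self.graph.degree)
        if total != 2 * self.n_edges:
            raise AssertionError("handshake lemma violated")


@dataclass(frozen=True)
class DegreeDistribution:
    histogram: dict[int, int]
    mean: float
    sd: float  # sample SD, n-1 denominator

    @property
    def n_nodes(self) -> int:
        return sum(self.histogram.values())


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of log c(k) = log C - gamma * log k."""

    exponent: float
    intercept: float
    r_squared: float
    fit_range: tuple[int, int]


@dataclass(frozen=True)
class HubCall:
    mean_degree: float
    sd_degree: float
    threshold: float
    hubs: frozenset[int]
    sub_network: "Network | None" = None


# ---------------------------------------------------------------------------
# Interaction loading
# ---------------------------------------------------------------------------

_TAXID = re.compile(r"taxid:(-?\d+)")
_MITAB_MIN_COLUMNS = 15


def _mitab_identifier(column: str) -> str:
    # "uniprotkb:P12345" / "entrez gene/locuslink:348" -> final token
    primary = column.split("|")[0]
    return primary.split(":")[-1].strip()


def load_interactions(
    source: IO[str] | str,
    allowed_taxa: Iterable[int] | None = None,
    id_map: Mapping[str, int] | None = None,
    strict: bool = False,
) -> list[InteractionEdge]:
    """Read interactions from PSI-MITAB 2.5 or a 2-column edge-list TSV.

    The format is sniffed per file: rows with >= 15 tab-separated columns
    are treated as MITAB (identifiers in columns 1-2, taxa in columns
    10-11), otherwise as ``gene_a<TAB>gene_b``. Identifiers are mapped to
    integer gene ids via ``id_map`` when given, else parsed as integers;
    unmappable rows and rows outside ``allowed_taxa`` are dropped (counted
    and logged). ``strict=True`` turns malformed rows into errors.
    """
    taxa = set(allowed_taxa) if allowed_taxa is not None else None
    close = False
    if isinstance(source, str):
        handle: IO[str] = open(source, encoding="utf-8")
        close = True
    else:
        handle = source

    edges: list[InteractionEdge] = []
    n_unmapped = n_filtered = n_malformed = 0
    try:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= _MITAB_MIN_COLUMNS:
                raw_a = _mitab_identifier(parts[0])
                raw_b = _mitab_identifier(parts[1])
                tax_a = _TAXID.search(parts[9])
                tax_b = _TAXID.search(parts[10])
                species = (
                    int(tax_a.group(1)) if tax_a else 0,
                    int(tax_b.group(1)) if tax_b else 0,
                )
                source_db = parts[12].split(":")[-1].strip('"()') if len(parts) > 12 else ""
            elif len(parts) >= 2:
                raw_a, raw_b = parts[0].strip(), parts[1].strip()
                species = (0, 0)
                source_db = ""
            else:
                n_malformed += 1
                if strict:
                    raise ValueError(f"malformed interaction line: {line!r}")
                logger.warning("skipping malformed interaction line: %r", line)
                continue

            if taxa is not None and species != (0, 0) and (
                species[0] not in taxa or species[1] not in taxa
            ):
                n_filtered += 1
                continue

            ids: list[int] = []
            for raw in (raw_a, raw_b):
                if id_map is not None and raw in id_map:
                    ids.append(id_map[raw])
                elif id_map is None and raw.lstrip("-").isdigit():
                    ids.append(int(raw))
                else:
                    break
            if len(ids) != 2:
                n_unmapped += 1
                continue
            edges.append(InteractionEdge.make(ids[0], ids[1], source_db, species))
    finally:
        if close:
            handle.close()

    if n_unmapped or n_filtered or n_malformed:
        logger.info(
            "interaction loading: %d edges kept, %d unmappable, %d outside taxa, %d malformed",
            len(edges), n_unmapped, n_filtered, n_malformed,
        )
    return edges


# ---------------------------------------------------------------------------
# Network construction and topology
# ---------------------------------------------------------------------------

def build_network(edges: Iterable[InteractionEdge]) -> Network:
    """Simple undirected graph: orientations merged, self-loops dropped."""
    graph = nx.Graph()
    for edge in edges:
        if edge.gene_a == edge.gene_b:
            continue
        graph.add_edge(edge.gene_a, edge.gene_b)
    net = Network(graph)
    net.check_handshake()
    return net


def induced_subgraph(network: Network, genes: Iterable[int]) -> Network:
    """Subgraph on ``genes``, keeping only nodes that retain an edge.

    Mapped genes that end up isolated (present in the network but with no
    neighbor inside ``genes``, or absent from the network entirely) are
    reported through ``isolated_mapped`` rather than kept as degree-0
    nodes, so node counts reflect the connected mapped set.
    """
    genes = set(genes)
    sub = network.graph.subgraph(genes & set(network.graph.nodes)).copy()
    isolated = {n for n in sub.nodes if sub.degree(n) == 0} | (genes - set(sub.nodes))
    sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree(n) == 0])
    net = Network(sub, isolated_mapped=frozenset(isolated))
    net.check_handshake()
    return net


def degree_distribution(network: Network) -> DegreeDistribution:
    """Degree histogram with mean and sample standard deviation (n-1)."""
    degrees = [d for _, d in network.graph.degree]
    if len(degrees) < 2:
        raise ValueError("degree distribution needs at least 2 nodes")
    histogram: dict[int, int] = {}
    for d in degrees:
        histogram[d] = histogram.get(d, 0) + 1
    arr = np.asarray(degrees, dtype=float)
    return DegreeDistribution(
        histogram=dict(sorted(histogram.items())),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
    )


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """Least-squares line on (log k, log c(k)) over nonzero bins.

    The fitted exponent is the negated slope: c(k) ~ C * k^-gamma. Degree
    zero bins are excluded (log undefined); at least three distinct
    positive degrees are required.
    """
    points = [(k, c) for k, c in dist.histogram.items() if k > 0 and c > 0]
    if len(points) < 3:
        raise ValueError("power-law fit needs >=3 distinct nonzero degrees")
    log_k = np.log([k for k, _ in points])
    log_c = np.log([c for _, c in points])
    slope, intercept = np.polyfit(log_k, log_c, 1)
    predicted = slope * log_k + intercept
    ss_res = float(np.sum((log_c - predicted) ** 2))
    ss_tot = float(np.sum((log_c - log_c.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return PowerLawFit(
        exponent=float(-slope),
        intercept=float(intercept),
        r_squared=min(1.0, r_squared),
        fit_range=(min(k for k, _ in points), max(k for k, _ in points)),
    )


def detect_hubs(network: Network, sd_multiplier: float = 2.0) -> HubCall:
    """Call hub genes: degree strictly greater than mean + m * sample SD.

    No rounding is applied to the threshold; the realized cutoff is
    reported so downstream consumers can log it. The hub sub-network is the
    induced subgraph on the called hubs.
    """
    dist = degree_distribution(network)
    if math.isnan(dist.sd):
        raise ValueError("standard deviation undefined for this network")
    threshold = dist.mean + sd_multiplier * dist.sd
    hubs = frozenset(
        node for node, deg in network.graph.degree if deg > threshold
    )
    sub = induced_subgraph(network, hubs) if hubs else Network(nx.Graph())
    return HubCall(
        mean_degree=dist.mean,
        sd_degree=dist.sd,
        threshold=threshold,
        hubs=hubs,
        sub_network=sub,
    )


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_sif(network: Network, path: str, relation: str = "pp") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for a, b in sorted(network.edges):
            handle.write(f"{a}\t{relation}\t{b}\n")


def write_graphml(network: Network, path: str) -> None:
    nx.write_graphml(network.graph, path)


def write_degree_histogram_tsv(dist: DegreeDistribution, path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("degree\tn_nodes\n")
        for k in sorted(dist.histogram):
            handle.write(f"{k}\t{dist.histogram[k]}\n")


def write_hubs_tsv(
    call: HubCall, network: Network, path: str, symbols: Mapping[int, str] | None = None
) -> None:
    symbols = symbols or {}
    degrees = network.node_degrees
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene_id\tsymbol\tdegree\n")
        for gene in sorted(call.hubs, key=lambda g: (-degrees[g], g)):
            handle.write(f"{gene}\t{symbols.get(gene, '')}\t{degrees[gene]}\n")
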