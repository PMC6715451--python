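"""lncRNA-RBP-mRNA triple network and shared-RBP co-regulation edges.

A lncRNA and an mRNA are linked when the number of RNA-binding proteins
they share is larger than chance.  With ``m`` RBPs in total, ``t`` bound by
the mRNA, ``n`` bound by the lncRNA and ``r`` shared, the evidence is the
hypergeometric upper tail

    P(X >= r) = sum_{i=r}^{min(t,n)} C(t, i) C(m - t, n - i) / C(m, n),

i.e. the probability that ``n`` draws without replacement from ``m`` RBPs of
which ``t`` are "successes" contain at least ``r`` successes.  The tail is
computed with exact integer binomials, so it is correct to the last float
digit for any realistic ``m``.  Edges with P below the significance
threshold (raw p, no multiplicity correction) form the insulin-resistance
lncRNA-mRNA network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from pathlib import Path

import networkx as nx
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import LNCRNA, MRNA

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TripleNetwork:
    """Bipartite binding maps and the RBP universe they span."""

    lnc_to_rbp: dict[str, frozenset[str]]
    mrna_to_rbp: dict[str, frozenset[str]]
    rbp_universe: frozenset[str]

    @property
    def m(self) -> int:
        return len(self.rbp_universe)


@dataclass
class CoRegulationEdge:
    lncrna: str
    mrna: str
    t: int                      # RBPs bound by the mRNA
    n: int                      # RBPs bound by the lncRNA
    r: int                      # shared RBPs
    p: float
    shared_rbps: frozenset[str]


@dataclass
class Irlmn:
    """Extracted co-regulation network: significant lncRNA-mRNA pairs."""

    edges: list[CoRegulationEdge]
    threshold: float
    lnc_nodes: set[str] = field(init=False)
    mrna_nodes: set[str] = field(init=False)
    degree: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.lnc_nodes = {e.lncrna for e in self.edges}
        self.mrna_nodes = {e.mrna for e in self.edges}
        deg: dict[str, int] = {}
        for e in self.edges:
            deg[e.lncrna] = deg.get(e.lncrna, 0) + 1
            deg[e.mrna] = deg.get(e.mrna, 0) + 1
        self.degree = deg

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lncrna": e.lncrna, "mrna": e.mrna, "t": e.t, "n": e.n,
                    "r": e.r, "p": e.p,
                    "shared_rbps": ",".join(sorted(e.shared_rbps)),
                }
                for e in self.edges
            ],
            columns=["lncrna", "mrna", "t", "n", "r", "p", "shared_rbps"],
        )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_global_network(
    lnc_rbp_table: pd.DataFrame, mrna_rbp_table: pd.DataFrame
) -> TripleNetwork:
    """Assemble the triple network from (feature_id, rbp_id) pair tables.

    Duplicate pairs collapse; malformed rows (missing ids) are skipped with
    a logged count.  The RBP universe is the union of RBPs in either table.
    """

    def to_map(tab: pd.DataFrame) -> dict[str, frozenset[str]]:
        if tab.empty:
            return {}
        if not {"feature_id", "rbp_id"} <= set(tab.columns):
            raise ValueError("interaction table needs feature_id and rbp_id columns")
        ok = tab.dropna(subset=["feature_id", "rbp_id"])
        skipped = len(tab) - len(ok)
        if skipped:
            log.warning("skipped %d malformed interaction rows", skipped)
        grouped = ok.groupby("feature_id")["rbp_id"].agg(frozenset)
        return dict(grouped)

    lnc = to_map(lnc_rbp_table)
    mrna = to_map(mrna_rbp_table)
    universe = frozenset().union(*lnc.values(), *mrna.values()) if (lnc or mrna) else frozenset()
    log.info(
        "global triple network: %d lncRNAs, %d mRNAs, %d RBPs",
        len(lnc), len(mrna), len(universe),
    )
    return TripleNetwork(lnc_to_rbp=lnc, mrna_to_rbp=mrna, rbp_universe=universe)


def starbase_export_to_pairs(
    table: pd.DataFrame, gene_col: str = "geneName", rbp_col: str = "RBP"
) -> pd.DataFrame:
    """Adapter for starBase-style exports: keep the gene and RBP columns."""
    if gene_col not in table.columns or rbp_col not in table.columns:
        raise ValueError(f"expected columns {gene_col!r} and {rbp_col!r}")
    return pd.DataFrame(
        {"feature_id": table[gene_col], "rbp_id": table[rbp_col]}
    ).drop_duplicates()


def map_degs(
    net: TripleNetwork, de_lncrnas, de_mrnas
) -> tuple[list[str], list[str]]:
    """Intersect DE feature lists with the network's feature ids."""
    lnc = sorted(set(de_lncrnas) & set(net.lnc_to_rbp))
    mrna = sorted(set(de_mrnas) & set(net.mrna_to_rbp))
    log.info("mapped %d/%d lncRNAs and %d/%d mRNAs onto the network",
             len(lnc), len(set(de_lncrnas)), len(mrna), len(set(de_mrnas)))
    return lnc, mrna


# ---------------------------------------------------------------------------
# the hypergeometric tail
# ---------------------------------------------------------------------------

def hypergeometric_tail(m: int, t: int, n: int, r: int) -> float:
    """Exact P(X >= r) for X ~ Hypergeometric(m, t, n).

    ``m`` total RBPs, ``t`` bound by the mRNA, ``n`` bound by the lncRNA,
    ``r`` shared.  Symmetric in (t, n).  Preconditions are enforced, never
    clamped.
    """
    for name, v in (("m", m), ("t", t), ("n", n), ("r", r)):
        if v != int(v) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    m, t, n, r = int(m), int(t), int(n), int(r)
    if t > m or n > m:
        raise ValueError(f"t={t} and n={n} must not exceed m={m}")
    if r > min(t, n):
        raise ValueError(f"r={r} exceeds min(t, n)={min(t, n)}")
    if r == 0:
        return 1.0
    num = sum(comb(t, i) * comb(m - t, n - i) for i in range(r, min(t, n) + 1))
    return float(Fraction(num, comb(m, n)))


# ---------------------------------------------------------------------------
# network extraction and enrichment
# ---------------------------------------------------------------------------

def extract_irlmn(
    net: TripleNetwork,
    mapped_lncrnas,
    mapped_mrnas,
    threshold: float = 0.01,
) -> Irlmn:
    """Keep (lncRNA, mRNA) pairs whose shared-RBP count is significant.

    Only pairs sharing at least one RBP are tested: a pair with r = 0 has
    P = 1 and cannot pass any threshold, so skipping it changes nothing.
    Raw p-values are thresholded directly (no multiplicity correction).
    """
    m = net.m
    edges: list[CoRegulationEdge] = []
    for lnc in mapped_lncrnas:
        lnc_set = net.lnc_to_rbp.get(lnc, frozenset())
        if not lnc_set:
            continue
        for mr in mapped_mrnas:
            mr_set = net.mrna_to_rbp.get(mr, frozenset())
            shared = lnc_set & mr_set
            if not shared:
                continue
            p = hypergeometric_tail(m, len(mr_set), len(lnc_set), len(shared))
            if p < threshold:
                edges.append(CoRegulationEdge(
                    lncrna=lnc, mrna=mr, t=len(mr_set), n=len(lnc_set),
                    r=len(shared), p=p, shared_rbps=frozenset(shared),
                ))
    log.info("IRLMN: %d lncRNA nodes, %d mRNA nodes, %d edges at p < %g",
             len({e.lncrna for e in edges}), len({e.mrna for e in edges}),
             len(edges), threshold)
    return Irlmn(edges=edges, threshold=threshold)


def ora_hypergeometric(
    query_genes, gene_sets: dict[str, set[str]], universe
) -> pd.DataFrame:
    """Generic over-representation test of a query list against gene sets.

    For each set: m = |universe|, t = |set within universe|, n = |query|,
    r = |query in set|; the tail is the same exact hypergeometric as for
    network edges.  A Benjamini-Hochberg column is included.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        t = len(set(members) & universe)
        r = len(query & set(members) & universe)
        p = hypergeometric_tail(len(universe), t, len(query), r)
        rows.append({"gene_set": name, "set_size": t, "overlap": r, "p": p})
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    if len(out):
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_bh"] = []
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_network(irlmn: Irlmn, path: str | Path, format: str = "tsv") -> Path:
    """Write the network as a TSV edge list or GraphML with node attributes."""
    path = Path(path)
    if format == "tsv":
        irlmn.edge_table().to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "graphml":
        g = nx.Graph()
        for node in sorted(irlmn.lnc_nodes):
            g.add_node(node, type=LNCRNA, degree=irlmn.degree[node])
        for node in sorted(irlmn.mrna_nodes):
            g.add_node(node, type=MRNA, degree=irlmn.degree[node])
        for e in irlmn.edges:
            g.add_edge(e.lncrna, e.mrna, r=e.r, p=e.p,
                       shared_rbps=",".join(sorted(e.shared_rbps)))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format: {format!r}")
    return path


def import_network_tsv(path: str | Path, threshold: float = 0.01) -> Irlmn:
    """Read a TSV edge list written by :func:`export_network`."""
    tab = pd.read_csv(path, sep="\t")
    edges = [
        CoRegulationEdge(
            lncrna=row.lncrna, mrna=row.mrna, t=int(row.t), n=int(row.n),
            r=int(row.r), p=float(row.p),
            shared_rbps=frozenset(
                str(row.shared_rbps).split(",") if pd.notna(row.shared_rbps) and str(row.shared_rbps) else []
            ),
        )
        for row in tab.itertuples()
    ]
    return Irlmn(edges=edges, threshold=threshold)
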