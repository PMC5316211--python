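"""Metabolite-gene enrichment, miRNA overlay, network assembly, pathway impact.

The central integration step: a metabolite's *metabolic genes* are the genes
operating in any metabolic pathway the metabolite participates in. Two
complementary tests ask whether a metabolite's metabolic genes are unusually
tied to the differential expression signal:

1. a hypergeometric test for over-representation of metabolic genes among
   the DEGs whose expression correlates with the metabolite's abundance
   (|r| > 0.5 and unadjusted p < 0.05 across the paired samples);
2. its generalization — a one-sided Wilcoxon rank-sum test of whether the
   metabolic genes have smaller differential-expression p-values than the
   rest of the transcriptome (correlation-free, for metabolites with few
   metabolic genes).

BH correction is applied per test family across metabolites and a metabolite
is *enriched* when either test passes FDR < 0.1. Significant DE miRNAs whose
validated targets fall among the metabolic genes are overlaid, and the whole
structure is assembled into a typed regulatory network. Pathway impact
scores follow the topology convention: the sum of relative centralities
(betweenness by default, out-degree by flag) of the matched metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, PathwayDB, TargetDB
from .de import DEResults, bh_adjust

__all__ = [
    "metabolic_genes_for", "correlate_metabolite_degs",
    "hypergeometric_enrichment", "wilcoxon_enrichment",
    "MetaboliteEnrichment", "enrich_metabolites", "select_enriched_metabolites",
    "mirna_overlay", "RegulatoryNetwork", "assemble_network", "pathway_impact",
]


def metabolic_genes_for(metabolite: str, db: PathwayDB) -> set[str]:
    """Union of gene sets over all pathways containing the metabolite.

    Unknown metabolites yield an empty set with a warning (only metabolites
    with at least one pathway carrying a coding gene proceed).
    """
    pids = db.metabolite_index.get(metabolite)
    if not pids:
        warnings.warn(f"metabolite {metabolite!r} not in pathway database", stacklevel=2)
        return set()
    out: set[str] = set()
    for pid in pids:
        out |= db.pathways[pid].genes
    return out


def correlate_metabolite_degs(metab_abund: pd.Series, expr: ExpressionMatrix,
                              r_thresh: float = 0.5,
                              p_thresh: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of a metabolite's abundance with each DEG.

    Computed across all paired samples pooled over T0 and T1. A gene is
    retained iff |r| strictly exceeds ``r_thresh`` AND the unadjusted
    two-sided p is strictly below ``p_thresh``. Zero-variance vectors are
    skipped with a warning.
    """
    common = expr.values.index.intersection(metab_abund.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned samples for correlations")
    v = metab_abund.loc[common].to_numpy(dtype=float)
    E = expr.values.loc[common].to_numpy(dtype=float)
    n = len(common)
    sv = v.std()
    if sv == 0:
        warnings.warn("metabolite vector has zero variance; no correlations", stacklevel=2)
        return pd.DataFrame(columns=["r", "p", "retained"])
    vz = (v - v.mean()) / sv
    sd = E.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance gene(s) skipped", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        Ez = (E - E.mean(axis=0)) / sd
        r = (Ez * vz[:, None]).mean(axis=0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    out = pd.DataFrame({"r": r, "p": p}, index=expr.values.columns)
    out = out[~zero]
    out["retained"] = (out["r"].abs() > r_thresh) & (out["p"] < p_thresh)
    return out


def hypergeometric_enrichment(correlated: set, metabolic: set, universe: set) -> float:
    """Upper-tail hypergeometric p: P(X >= k) for the overlap of the
    correlated-DEG draw with the metabolic gene set inside the universe."""
    if not universe:
        raise ValueError("empty universe")
    if not metabolic <= universe:
        raise ValueError("metabolic genes must be a subset of the universe")
    if not correlated <= universe:
        raise ValueError("correlated genes must be a subset of the universe")
    N, K, n = len(universe), len(metabolic), len(correlated)
    k = len(correlated & metabolic)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def wilcoxon_enrichment(metabolic_p, other_p) -> float:
    """One-sided rank-sum p that the metabolic genes' DE p-values are
    stochastically smaller than the other genes'.

    Exact null distribution when the combined sample is small (n <= 25)
    without ties; normal approximation with tie correction otherwise.
    """
    a = np.asarray(metabolic_p, dtype=float)
    b = np.asarray(other_p, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    exact = len(combined) <= 25 and len(np.unique(combined)) == len(combined)
    res = stats.mannwhitneyu(a, b, alternative="less",
                             method="exact" if exact else "asymptotic")
    return float(res.pvalue)


@dataclass
class MetaboliteEnrichment:
    """Both enrichment tests for one metabolite."""

    metabolite_id: str
    metabolic_genes: set[str]
    correlated_degs: set[str]
    overlap: set[str] = field(init=False)
    p_hyper: float = np.nan
    p_wilcoxon: float = np.nan
    q_hyper: float = np.nan
    q_wilcoxon: float = np.nan
    enriched: bool = False

    def __post_init__(self) -> None:
        self.overlap = self.metabolic_genes & self.correlated_degs


def enrich_metabolites(abundances: pd.DataFrame, db: PathwayDB,
                       de_genes: DEResults, expr: ExpressionMatrix,
                       universe: set[str] | None = None,
                       r_thresh: float = 0.5, p_thresh: float = 0.05,
                       fdr: float = 0.1) -> list[MetaboliteEnrichment]:
    """Run both enrichment tests for every candidate metabolite.

    ``abundances``: samples x metabolites table of per-sample abundances
    (one column per assigned metabolite). The universe defaults to every
    gene on the expression platform. Candidates without a single metabolic
    gene are skipped, mirroring the requirement of at least one pathway
    with one coding gene.
    """
    universe = set(expr.values.columns) if universe is None else set(universe)
    deg_ids = sorted(de_genes.significant & universe)
    deg_expr = ExpressionMatrix(values=expr.values[deg_ids], feature_kind=expr.feature_kind)
    p_by_gene = de_genes.table["p"]

    candidates: list[MetaboliteEnrichment] = []
    for m in abundances.columns:
        metabolic = metabolic_genes_for(m, db) & universe
        if not metabolic:
            continue
        corr = correlate_metabolite_degs(abundances[m], deg_expr,
                                         r_thresh=r_thresh, p_thresh=p_thresh)
        correlated = set(corr.index[corr["retained"]])
        other = sorted(universe - metabolic)
        cand = MetaboliteEnrichment(
            metabolite_id=m, metabolic_genes=metabolic, correlated_degs=correlated)
        cand.p_hyper = hypergeometric_enrichment(correlated, metabolic, universe)
        cand.p_wilcoxon = wilcoxon_enrichment(
            p_by_gene.loc[sorted(metabolic)].to_numpy(),
            p_by_gene.loc[other].to_numpy())
        candidates.append(cand)
    return select_enriched_metabolites(candidates, fdr=fdr)


def select_enriched_metabolites(candidates: list[MetaboliteEnrichment],
                                fdr: float = 0.1) -> list[MetaboliteEnrichment]:
    """BH-correct each test family across metabolites; a metabolite is
    enriched when either q falls below the FDR threshold (default 0.1)."""
    if not candidates:
        return candidates
    q_h = bh_adjust([c.p_hyper for c in candidates])
    q_w = bh_adjust([c.p_wilcoxon for c in candidates])
    for c, qh, qw in zip(candidates, q_h, q_w):
        c.q_hyper = float(qh)
        c.q_wilcoxon = float(qw)
        c.enriched = (c.q_hyper < fdr) or (c.q_wilcoxon < fdr)
    return candidates


def enrichment_table(candidates: list[MetaboliteEnrichment]) -> pd.DataFrame:
    rows = [{
        "metabolite": c.metabolite_id,
        "n_metabolic": len(c.metabolic_genes),
        "n_correlated": len(c.correlated_degs),
        "overlap": len(c.overlap),
        "p_hyper": c.p_hyper, "q_hyper": c.q_hyper,
        "p_wilcoxon": c.p_wilcoxon, "q_wilcoxon": c.q_wilcoxon,
        "enriched": c.enriched,
    } for c in candidates]
    cols = ["metabolite", "n_metabolic", "n_correlated", "overlap", "p_hyper",
            "q_hyper", "p_wilcoxon", "q_wilcoxon", "enriched"]
    return pd.DataFrame(rows, columns=cols).set_index("metabolite")


def mirna_overlay(metabolic_genes: set[str], targets: TargetDB,
                  demirnas: DEResults, support: str | None = "validated",
                  alpha: float = 0.05) -> pd.DataFrame:
    """miRNA -> metabolic-gene edges for significant DE miRNAs.

    The DE gate applies first (q < alpha); a miRNA is retained only with at
    least one validated target inside the metabolic gene set.
    Returns an edge table (mirna_id, gene_id).
    """
    sig = {f for f in demirnas.table.index
           if demirnas.table.loc[f, "q"] < alpha}
    t = targets.table
    if support is not None:
        t = t[t["support"] == support]
    hits = t[t["mirna_id"].isin(sig) & t["gene_id"].isin(metabolic_genes)]
    return hits[["mirna_id", "gene_id"]].drop_duplicates().reset_index(drop=True)


# --------------------------------------------------------------------------
# network assembly

EVIDENCE_KINDS = ("pathway_membership", "correlation", "mirna_target", "tf_target")
NODE_KINDS = ("metabolite", "gene", "tf", "mirna")


@dataclass
class RegulatoryNetwork:
    """Typed multi-omic regulatory network over a networkx DiGraph.

    Nodes carry ``kind`` (metabolite/gene/tf/mirna) and ``direction``
    (up/down at T1); every edge carries an ``evidence`` tag.
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if d.get("evidence") not in EVIDENCE_KINDS:
                raise ValueError(f"edge ({u}, {v}) missing valid evidence tag")

    def nodes_of_kind(self, kind: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind}

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def read_graphml(cls, path) -> "RegulatoryNetwork":
        return cls(nx.DiGraph(nx.read_graphml(path)))

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{d['evidence']}\t{v}\n")


def assemble_network(enriched: list[MetaboliteEnrichment],
                     mirna_edges: pd.DataFrame,
                     tf_list: set[str],
                     de_genes: DEResults,
                     de_mirnas: DEResults,
                     metabolite_directions: dict[str, str] | None = None,
                     min_targets: int = 1) -> RegulatoryNetwork:
    """Assemble the typed regulatory network.

    Metabolite -> gene edges come from each enriched metabolite's overlap
    (correlated metabolic DEGs, evidence ``correlation``); miRNA -> gene
    edges from the overlay (evidence ``mirna_target``), keeping only miRNAs
    with at least ``min_targets`` in-network target genes. Genes found in
    the TF catalogue are typed ``tf``. Node directions come from the DE
    log-fold-change sign (genes, miRNAs) or the supplied metabolite loading
    signs.
    """
    g = nx.DiGraph()
    metabolite_directions = metabolite_directions or {}

    def gene_kind(gid: str) -> str:
        return "tf" if gid in tf_list else "gene"

    def de_direction(res: DEResults, fid: str) -> str:
        if fid in res.table.index:
            return "up" if res.table.loc[fid, "log_fc"] > 0 else "down"
        return "unknown"

    in_network_genes: set[str] = set()
    for c in enriched:
        if not c.enriched:
            continue
        g.add_node(c.metabolite_id, kind="metabolite",
                   direction=metabolite_directions.get(c.metabolite_id, "unknown"))
        for gid in sorted(c.overlap):
            if gid in g.nodes and g.nodes[gid].get("kind") not in ("gene", "tf"):
                raise ValueError(f"id collision across node kinds: {gid}")
            g.add_node(gid, kind=gene_kind(gid), direction=de_direction(de_genes, gid))
            g.add_edge(c.metabolite_id, gid, evidence="correlation")
            in_network_genes.add(gid)

    if len(mirna_edges):
        edges = mirna_edges[mirna_edges["gene_id"].isin(in_network_genes)]
        degree = edges.groupby("mirna_id")["gene_id"].nunique()
        keep = set(degree.index[degree >= min_targets])
        for _, row in edges.iterrows():
            m = row["mirna_id"]
            if m not in keep:
                continue
            if m in g.nodes and g.nodes[m].get("kind") != "mirna":
                raise ValueError(f"id collision across node kinds: {m}")
            g.add_node(m, kind="mirna", direction=de_direction(de_mirnas, m))
            g.add_edge(m, row["gene_id"], evidence="mirna_target")
    return RegulatoryNetwork(g)


# --------------------------------------------------------------------------
# pathway impact

def pathway_impact(db: PathwayDB, pathway_id: str, matched_metabolites: set[str],
                   centrality: str = "betweenness") -> float:
    """Topological pathway impact in [0, 1].

    Per-metabolite importance is its centrality (relative betweenness by
    default, out-degree by flag) normalized to sum 1 within the pathway's
    directed metabolite graph; the impact is the summed importance of the
    matched metabolites. When every centrality is zero (e.g. a single-node
    or edgeless graph) importance falls back to uniform, with a warning.
    """
    pw = db.pathways[pathway_id]
    graph = pw.graph
    if graph.number_of_nodes() == 0:
        raise ValueError(f"pathway {pathway_id} has an empty metabolite graph")
    if centrality == "betweenness":
        c = nx.betweenness_centrality(graph, normalized=True)
    elif centrality == "out_degree":
        c = dict(graph.out_degree())
    else:
        raise ValueError(f"unknown centrality {centrality!r}")
    total = float(sum(c.values()))
    if total == 0:
        warnings.warn(f"pathway {pathway_id}: all-zero centralities, "
                      "using uniform importance", stacklevel=2)
        importance = {n: 1.0 / graph.number_of_nodes() for n in graph.nodes}
    else:
        importance = {n: v / total for n, v in c.items()}
    return float(sum(importance.get(m, 0.0) for m in matched_metabolites))
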