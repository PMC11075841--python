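"""Region-level GO term enrichment.

Annotations are read from an OBO ontology and a GAF 2.x association file,
filtered by qualifier (positive relations only) and evidence code
(experimental, TAS, IC by default), propagated up the ontology graph along
is_a and part_of edges, and joined to regions: every annotation of a gene
attaches to every region derived from that gene.  Enrichment of a region
set against a reference uses the exact upper-tail hypergeometric
probability with regions as the sampling unit; p-values within a cluster
are Benjamini-Hochberg corrected (the disorder-score analysis is left
uncorrected by design, mirroring the two entry points' fixed behaviors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from Bio.UniProt.GOA import gafiterator

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "ALLOWED_QUALIFIERS",
    "ALLOWED_EVIDENCE",
    "load_annotations",
    "hypergeom_enrichment",
    "bh_adjust",
    "select_upper_decile",
]

ALLOWED_QUALIFIERS = frozenset(
    {"enables", "contributes_to", "involved_in", "located_in", "part_of", "is_active_in"}
)
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI", "HEP"})
ALLOWED_EVIDENCE = EXPERIMENTAL_EVIDENCE | {"TAS", "IC"}
PROPAGATE_RELATIONS = ("is_a", "part_of")


@dataclass
class AnnotationSet:
    graph: nx.MultiDiGraph  # obonet graph: edges child -> parent
    gene_terms: dict  # gene -> set of term ids (propagated)
    region_terms: dict = field(default_factory=dict)  # region id -> set of terms
    n_dropped: dict = field(default_factory=dict)

    def term_name(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("name", "") if term_id in self.graph else ""

    def join_regions(self, region_to_gene: dict) -> None:
        """Attach every gene annotation to the regions derived from it."""
        self.region_terms = {
            rid: set(self.gene_terms.get(gene, ())) for rid, gene in region_to_gene.items()
        }


@dataclass
class EnrichmentResult:
    cluster_id: str
    term_id: str
    term_name: str
    k: int  # regions in cluster with term
    n: int  # cluster size
    K: int  # regions with term in reference
    N: int  # reference size
    p: float
    p_adj: float = float("nan")


def _ancestors(graph: nx.MultiDiGraph, term: str, cache: dict) -> set:
    if term in cache:
        return cache[term]
    out = {term}
    for _, parent, rel in graph.out_edges(term, keys=True):
        if rel in PROPAGATE_RELATIONS:
            out |= _ancestors(graph, parent, cache)
    cache[term] = out
    return out


def load_annotations(
    obo_path,
    gaf_path,
    allowed_qualifiers=ALLOWED_QUALIFIERS,
    allowed_evidence=ALLOWED_EVIDENCE,
) -> AnnotationSet:
    """Parse ontology + associations, filter, and propagate to ancestors.

    Drops annotations with a NOT or disallowed qualifier, disallowed
    evidence codes, and terms absent from the ontology (obsolete); counts
    of dropped annotations are kept per filter.  Raises on a cyclic
    ontology.
    """
    graph = obonet.read_obo(obo_path)
    if not nx.is_directed_acyclic_graph(nx.DiGraph(graph.edges())):
        raise ValueError("cyclic ontology graph")
    dropped = {"qualifier": 0, "evidence": 0, "obsolete": 0, "kept": 0}
    gene_terms: dict[str, set] = {}
    cache: dict = {}
    with open(gaf_path) as fh:
        for rec in gafiterator(fh):
            quals = rec.get("Qualifier") or []
            if any(q.upper() == "NOT" for q in quals) or not any(
                q in allowed_qualifiers for q in quals
            ):
                dropped["qualifier"] += 1
                continue
            if rec.get("Evidence") not in allowed_evidence:
                dropped["evidence"] += 1
                continue
            term = rec.get("GO_ID")
            if term not in graph:
                dropped["obsolete"] += 1
                continue
            gene = rec.get("DB_Object_Symbol") or rec.get("DB_Object_ID")
            gene_terms.setdefault(gene, set()).update(_ancestors(graph, term, cache))
            dropped["kept"] += 1
    return AnnotationSet(graph, gene_terms, n_dropped=dropped)


def hypergeom_enrichment(
    cluster_regions,
    reference_regions,
    annotations: AnnotationSet,
    min_regions_per_term: int = 2,
    cluster_id: str = "",
    adjust: bool = True,
) -> list[EnrichmentResult]:
    """Exact upper-tail hypergeometric enrichment, regions as sampling unit.

    p = P(X >= k) with N reference regions, K carrying the term, cluster
    size n, and k term-carrying regions in the cluster; terms with fewer
    than ``min_regions_per_term`` regions in the cluster are skipped.
    ``adjust`` applies Benjamini-Hochberg within the cluster.
    """
    cluster = list(cluster_regions)
    reference = list(reference_regions)
    if not cluster:
        raise ValueError("empty cluster")
    if not set(cluster) <= set(reference):
        raise ValueError("cluster must be a subset of the reference")
    terms = annotations.region_terms
    N = len(reference)
    n = len(cluster)
    term_K: dict[str, int] = {}
    for rid in reference:
        for t in terms.get(rid, ()):
            term_K[t] = term_K.get(t, 0) + 1
    term_k: dict[str, int] = {}
    for rid in cluster:
        for t in terms.get(rid, ()):
            term_k[t] = term_k.get(t, 0) + 1
    results = []
    for t, k in sorted(term_k.items()):
        if k < min_regions_per_term:
            continue
        K = term_K[t]
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(cluster_id, t, annotations.term_name(t), k, n, K, N, min(p, 1.0))
        )
    if adjust and results:
        adj = bh_adjust([r.p for r in results])
        for r, a in zip(results, adj):
            r.p_adj = a
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_upper_decile(region_rates: dict) -> list:
    """Regions at or above the empirical 90th percentile of the rate
    distribution (ties at the threshold included)."""
    if len(region_rates) < 10:
        raise ValueError("need at least 10 regions")
    ids = list(region_rates)
    rates = np.array([region_rates[r] for r in ids], dtype=float)
    threshold = np.quantile(rates, 0.9)
    return [r for r, v in zip(ids, rates) if v >= threshold]
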