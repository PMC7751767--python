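"""Guilt-by-association gene-function prediction and benchmarking.

Annotations are propagated to ontology ancestors (true-path rule), each
gene's network neighborhood is tested for term enrichment with exact
hypergeometric tails, and prediction sets are scored against a gold
standard at gene and category level over a grid of FDR thresholds.  A focal
network's curve can be classified against an ensemble of comparison
networks (very good ... very poor).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .spatial_stats import bh_adjust

__all__ = [
    "AnnotationSet",
    "PerformanceCurve",
    "RelativePerformanceClass",
    "parse_obo",
    "read_annotations",
    "propagate_annotations",
    "neighborhood_enrichment",
    "gene_level_recall_precision",
    "category_recall_precision",
    "performance_curve",
    "classify_relative_performance",
    "cluster_go_enrichment",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = tuple(10.0 ** -k for k in range(2, 12))  # 1e-2 ... 1e-11


@dataclass
class AnnotationSet:
    """Gene -> term sets, closed under ancestor propagation, plus the DAG."""

    gene_terms: dict[str, set[str]]
    ontology: nx.DiGraph  # edges child -> parent

    def genes_with(self, term: str) -> set[str]:
        return {g for g, terms in self.gene_terms.items() if term in terms}


@dataclass
class PerformanceCurve:
    thresholds: list[float]
    recall: list[float]
    precision: list[float]
    f_measure: list[float]
    predicted_positives: list[int]


@dataclass
class RelativePerformanceClass:
    label: str  # very good | good | average | poor | very poor | insufficient information
    rmsd_to_p25: float = np.nan
    rmsd_to_p50: float = np.nan
    rmsd_to_p75: float = np.nan
    subrange: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ontology / annotation I/O
# ---------------------------------------------------------------------------

_OBO_REL = re.compile(r"^relationship:\s+part_of\s+(\S+)")


def parse_obo(path_or_text: str) -> nx.DiGraph:
    """Minimal OBO parser: [Term] stanzas with is_a and part_of edges.

    Returns a DiGraph with child -> parent edges; obsolete terms skipped.
    """
    try:
        text = open(path_or_text).read()
    except (OSError, ValueError):
        text = path_or_text
    graph = nx.DiGraph()
    stanzas = text.split("\n[")
    for block in stanzas:
        lines = [l.strip() for l in block.strip().splitlines()]
        if not lines or not (lines[0] in ("Term]", "[Term]")):
            continue
        term_id = None
        parents = []
        obsolete = False
        for line in lines[1:]:
            if line.startswith("id:"):
                term_id = line.split("id:", 1)[1].strip()
            elif line.startswith("is_obsolete: true"):
                obsolete = True
            elif line.startswith("is_a:"):
                parents.append(line.split("is_a:", 1)[1].split("!")[0].strip())
            else:
                m = _OBO_REL.match(line)
                if m:
                    parents.append(m.group(1))
        if term_id is None or obsolete:
            continue
        graph.add_node(term_id)
        graph.add_edges_from((term_id, p) for p in parents)
    return graph


def read_annotations(path: str) -> pd.DataFrame:
    """Gene->term pairs from a two-column TSV or a GAF 2.x file (cols 2, 5)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("!") or len(first.rstrip("\n").split("\t")) >= 15:
        df = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str)
        return df[[1, 4]].rename(columns={1: "gene", 4: "term"}).drop_duplicates()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene", "term"]:
        df.columns = ["gene", "term"][: len(df.columns)]
    return df[["gene", "term"]].drop_duplicates()


def propagate_annotations(
    raw: pd.DataFrame | dict[str, set[str]],
    ontology: nx.DiGraph,
) -> AnnotationSet:
    """Close each gene's term set under is_a/part_of ancestors (true-path rule)."""
    if not nx.is_directed_acyclic_graph(ontology):
        raise ValueError("ontology graph contains a cycle")
    ancestors = {t: nx.descendants(ontology, t) for t in ontology.nodes}
    if isinstance(raw, pd.DataFrame):
        direct: dict[str, set[str]] = {}
        for gene, term in raw[["gene", "term"]].itertuples(index=False):
            direct.setdefault(gene, set()).add(term)
    else:
        direct = {g: set(t) for g, t in raw.items()}
    closed = {}
    for gene, terms in direct.items():
        full = set(terms)
        for t in terms:
            full |= ancestors.get(t, set())
        closed[gene] = full
    return AnnotationSet(closed, ontology)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def neighborhood_enrichment(
    network: nx.Graph,
    annotations: AnnotationSet,
    background: set[str] | None = None,
    exclude_root: bool = True,
) -> pd.DataFrame:
    """Hypergeometric term enrichment in each gene's direct neighborhood.

    Background defaults to the annotated genes present in the network.  For
    gene g and term T: X ~ Hypergeom(N=|background|, K=#background genes
    with T, n=#annotated neighbors of g), p = P[X >= observed].  The focal
    gene never counts toward its own neighborhood.  q-values are BH-adjusted
    over all tests of the network.
    """
    annotated = {g for g, t in annotations.gene_terms.items() if t}
    if background is None:
        background = {g for g in network.nodes if g in annotated}
    background = set(background)
    N = len(background)
    roots = {t for t in annotations.ontology.nodes
             if annotations.ontology.out_degree(t) == 0} if exclude_root else set()
    term_counts: dict[str, int] = {}
    for g in background:
        for t in annotations.gene_terms.get(g, ()):
            term_counts[t] = term_counts.get(t, 0) + 1
    records = []
    for gene in network.nodes:
        neigh = [v for v in network.neighbors(gene) if v in background and v != gene]
        n_draw = len(neigh)
        if n_draw == 0:
            continue
        counts: dict[str, int] = {}
        for v in neigh:
            for t in annotations.gene_terms.get(v, ()):
                counts[t] = counts.get(t, 0) + 1
        for term, k in counts.items():
            if term in roots:
                continue
            K = term_counts.get(term, 0)
            p = float(stats.hypergeom.sf(k - 1, N, K, n_draw))
            records.append({"gene": gene, "term": term, "k": k, "K": K,
                            "n_neighbors": n_draw, "p": p})
    preds = pd.DataFrame.from_records(records)
    if len(preds):
        preds["q"] = bh_adjust(preds["p"].to_numpy())
        preds["novel"] = [
            t not in annotations.gene_terms.get(g, set())
            for g, t in preds[["gene", "term"]].itertuples(index=False)
        ]
    return preds


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _predicted_at(predictions: pd.DataFrame, threshold_q: float) -> dict[str, set[str]]:
    if not len(predictions):
        return {}
    sel = predictions[predictions["q"] <= threshold_q]
    out: dict[str, set[str]] = {}
    for g, t in sel[["gene", "term"]].itertuples(index=False):
        out.setdefault(g, set()).add(t)
    return out


def gene_level_recall_precision(
    predictions: pd.DataFrame,
    gold: AnnotationSet,
    threshold_q: float,
    genes: set[str] | None = None,
) -> tuple[float, float, float]:
    """Mean per-gene recall/precision/F over genes with non-empty gold sets.

    Genes with no predictions at the threshold contribute recall, precision
    and F of 0.
    """
    gold_genes = {g for g, t in gold.gene_terms.items() if t}
    if genes is not None:
        gold_genes &= set(genes)
    if not gold_genes:
        raise ValueError("empty gold standard")
    pred = _predicted_at(predictions, threshold_q)
    recalls, precisions, fs = [], [], []
    for g in gold_genes:
        known = gold.gene_terms[g]
        predicted = pred.get(g, set())
        tp = len(known & predicted)
        r = tp / len(known)
        p = tp / len(predicted) if predicted else 0.0
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        recalls.append(r)
        precisions.append(p)
        fs.append(f)
    return float(np.mean(recalls)), float(np.mean(precisions)), float(np.mean(fs))


def category_recall_precision(
    predictions: pd.DataFrame,
    gold: AnnotationSet,
    term: str,
    threshold_q: float,
    genes: set[str] | None = None,
) -> tuple[float, float, float]:
    """Traditional R = tp/(tp+fn), P = tp/(tp+fp) for one term."""
    pred = _predicted_at(predictions, threshold_q)
    gold_genes = gold.genes_with(term)
    if genes is not None:
        gold_genes &= set(genes)
    predicted_genes = {g for g, terms in pred.items() if term in terms}
    tp = len(predicted_genes & gold_genes)
    fn = len(gold_genes - predicted_genes)
    fp = len(predicted_genes - gold_genes)
    r = tp / (tp + fn) if (tp + fn) else 0.0
    p = tp / (tp + fp) if (tp + fp) else 0.0
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return r, p, f


def performance_curve(
    predictions: pd.DataFrame,
    gold: AnnotationSet,
    thresholds=DEFAULT_THRESHOLDS,
    term: str | None = None,
    genes: set[str] | None = None,
) -> PerformanceCurve:
    """Recall/precision/F and predicted-positive counts per FDR threshold.

    ``term=None`` gives the gene-averaged overall curve; otherwise the
    traditional per-category metrics for that term.
    """
    thresholds = list(thresholds)
    if any(a < b for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be descending")
    recs, precs, fs, counts = [], [], [], []
    for q in thresholds:
        if term is None:
            r, p, f = gene_level_recall_precision(predictions, gold, q, genes=genes)
        else:
            r, p, f = category_recall_precision(predictions, gold, term, q, genes=genes)
        n_pred = int((predictions["q"] <= q).sum()) if len(predictions) else 0
        recs.append(r)
        precs.append(p)
        fs.append(f)
        counts.append(n_pred)
    return PerformanceCurve(thresholds, recs, precs, fs, counts)


def classify_relative_performance(
    focal: PerformanceCurve,
    sampled: list[PerformanceCurve],
) -> RelativePerformanceClass:
    """Classify a focal F-curve against an ensemble of comparison curves.

    Evaluated over the threshold subrange where the focal network or at
    least half of the sampled networks have non-zero F.  RMSD of the focal
    F to the 25th/50th/75th percentile curves decides the label.
    """
    if len(sampled) < 2:
        raise ValueError("need >= 2 sampled curves")
    thresholds = focal.thresholds
    F = np.array([c.f_measure for c in sampled])  # ensemble x threshold
    focal_f = np.array(focal.f_measure)
    half_nonzero = (F > 0).sum(axis=0) >= len(sampled) / 2
    in_range = (focal_f > 0) | half_nonzero
    if not in_range.any():
        return RelativePerformanceClass("insufficient information")
    p25, p50, p75 = (np.percentile(F, q, axis=0) for q in (25, 50, 75))
    sub = in_range
    rmsd25 = float(np.sqrt(np.mean((focal_f[sub] - p25[sub]) ** 2)))
    rmsd50 = float(np.sqrt(np.mean((focal_f[sub] - p50[sub]) ** 2)))
    rmsd75 = float(np.sqrt(np.mean((focal_f[sub] - p75[sub]) ** 2)))
    n_sub = int(sub.sum())
    above75 = (focal_f[sub] >= p75[sub]).sum() / n_sub
    above50 = (focal_f[sub] > p50[sub]).sum() / n_sub
    below25 = (focal_f[sub] <= p25[sub]).sum() / n_sub
    below50 = (focal_f[sub] < p50[sub]).sum() / n_sub
    if above75 > 0.5 and rmsd75 < rmsd50:
        label = "very good"
    elif below25 > 0.5 and rmsd25 < rmsd50:
        label = "very poor"
    elif above50 > 0.5 and rmsd50 <= rmsd75:
        label = "good"
    elif below50 > 0.5 and rmsd50 <= rmsd25:
        label = "poor"
    else:
        label = "average"
    return RelativePerformanceClass(label, rmsd25, rmsd50, rmsd75,
                                    [t for t, s in zip(thresholds, sub) if s])


def cluster_go_enrichment(
    gene_sets: dict[str, list[str]] | dict[str, set[str]],
    annotations: AnnotationSet,
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation per (cluster, term).

    BH correction is applied within each cluster separately.
    """
    background = set(background)
    N = len(background)
    term_counts: dict[str, int] = {}
    for g in background:
        for t in annotations.gene_terms.get(g, ()):
            term_counts[t] = term_counts.get(t, 0) + 1
    records = []
    for cluster, genes in gene_sets.items():
        genes = set(genes) & background
        if not genes:
            continue
        n_draw = len(genes)
        counts: dict[str, int] = {}
        for g in genes:
            for t in annotations.gene_terms.get(g, ()):
                counts[t] = counts.get(t, 0) + 1
        rows = []
        for term, k in counts.items():
            K = term_counts.get(term, 0)
            p = float(stats.hypergeom.sf(k - 1, N, K, n_draw))
            rows.append({"cluster": cluster, "term": term, "k": k, "K": K,
                         "n": n_draw, "p": p})
        if rows:
            qs = bh_adjust([r["p"] for r in rows])
            for r, q in zip(rows, qs):
                r["q"] = float(q)
            records.extend(rows)
    return pd.DataFrame.from_records(records)
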