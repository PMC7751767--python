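import networkx as nx
import numpy as np
import pandas as pd
import pytest
from math import comb

from fieldomics.go_prediction import (
    AnnotationSet,
    PerformanceCurve,
    category_recall_precision,
    classify_relative_performance,
    cluster_go_enrichment,
    gene_level_recall_precision,
    neighborhood_enrichment,
    parse_obo,
    performance_curve,
    propagate_annotations,
    read_annotations,
)


@pytest.fixture()
def diamond_ontology():
    # L -> (M1, M2) -> root: diamond closure counts root once
    g = nx.DiGraph()
    g.add_edges_from([("L", "M1"), ("L", "M2"), ("M1", "root"), ("M2", "root")])
    return g


class TestParseObo:
    def test_roundtrip_with_synthetic_writer(self, tmp_path):
        from fieldomics.synthetic_field import _obo_text
        edges = [("GO:L0000", "GO:B0000"), ("GO:B0000", "GO:ROOT")]
        path = tmp_path / "o.obo"
        path.write_text(_obo_text(edges))
        g = parse_obo(str(path))
        assert set(g.edges) == set(edges)

    def test_part_of_and_obsolete(self):
        text = (
            "[Term]\nid: A\nis_a: B ! b\n\n"
            "[Term]\nid: B\nrelationship: part_of C\n\n"
            "[Term]\nid: D\nis_obsolete: true\nis_a: B\n\n"
            "[Term]\nid: C\n"
        )
        g = parse_obo(text)
        assert ("A", "B") in g.edges and ("B", "C") in g.edges
        assert "D" not in g.nodes


class TestPropagateAnnotations:
    def test_chain_closure(self):
        g = nx.DiGraph([("L", "M"), ("M", "root")])
        ann = propagate_annotations(pd.DataFrame({"gene": ["g"], "term": ["L"]}), g)
        assert ann.gene_terms["g"] == {"L", "M", "root"}

    def test_idempotent(self, diamond_ontology):
        first = propagate_annotations(
            pd.DataFrame({"gene": ["g"], "term": ["L"]}), diamond_ontology)
        again = propagate_annotations(
            {g: set(t) for g, t in first.gene_terms.items()}, diamond_ontology)
        assert again.gene_terms == first.gene_terms

    def test_diamond_counted_once(self, diamond_ontology):
        ann = propagate_annotations(
            pd.DataFrame({"gene": ["g"], "term": ["L"]}), diamond_ontology)
        assert ann.gene_terms["g"] == {"L", "M1", "M2", "root"}

    def test_cycle_raises(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(ValueError, match="cycle"):
            propagate_annotations(pd.DataFrame({"gene": ["g"], "term": ["A"]}), g)


def hypergeom_tail_oracle(k, N, K, n):
    """Exact upper-tail hypergeometric by direct summation."""
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / comb(N, n)


def _flat_annset(gene_terms):
    g = nx.DiGraph()
    for terms in gene_terms.values():
        g.add_nodes_from(terms)
    return AnnotationSet({k: set(v) for k, v in gene_terms.items()}, g)


class TestNeighborhoodEnrichment:
    def test_exact_hypergeometric_example(self):
        # focal gene with 5 annotated neighbors, 4 carrying T;
        # background of 50 genes, 5 with T
        net = nx.Graph()
        background = [f"b{i}" for i in range(50)]
        gene_terms = {b: {"other"} for b in background}
        for b in background[:5]:
            gene_terms[b] = {"T", "other"}
        neighbors = background[1:5] + [background[10]]  # 4 with T, 1 without
        net.add_edges_from([("focal", v) for v in neighbors])
        net.add_nodes_from(background)
        ann = _flat_annset(gene_terms)
        preds = neighborhood_enrichment(net, ann, background=set(background),
                                        exclude_root=False)
        row = preds[(preds["gene"] == "focal") & (preds["term"] == "T")].iloc[0]
        assert row["p"] == pytest.approx(hypergeom_tail_oracle(4, 50, 5, 5), rel=1e-12)

    def test_enumeration_oracle_small_background(self, rng):
        net = nx.Graph()
        background = [f"b{i}" for i in range(12)]
        gene_terms = {b: ({"T"} if i < 4 else {"U"}) for i, b in enumerate(background)}
        neigh = list(rng.choice(background, 5, replace=False))
        net.add_edges_from([("focal", v) for v in neigh])
        net.add_nodes_from(background)
        ann = _flat_annset(gene_terms)
        preds = neighborhood_enrichment(net, ann, background=set(background),
                                        exclude_root=False)
        for rec in preds[preds["gene"] == "focal"].itertuples(index=False):
            K = sum(1 for b in background if rec.term in gene_terms[b])
            assert rec.p == pytest.approx(
                hypergeom_tail_oracle(rec.k, 12, K, len(neigh)), rel=1e-12)

    def test_unrepresented_term_not_tested(self):
        net = nx.Graph([("focal", "b0"), ("focal", "b1")])
        ann = _flat_annset({"b0": {"A"}, "b1": {"A"}, "b2": {"T"}})
        preds = neighborhood_enrichment(net, ann, exclude_root=False)
        assert "T" not in set(preds[preds["gene"] == "focal"]["term"])

    def test_isolated_gene_no_tests(self):
        net = nx.Graph()
        net.add_node("loner")
        net.add_edge("a", "b")
        ann = _flat_annset({"a": {"T"}, "b": {"T"}, "loner": {"T"}})
        preds = neighborhood_enrichment(net, ann, exclude_root=False)
        assert "loner" not in set(preds["gene"])


class TestGeneLevelScores:
    def _preds(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "term", "q"])
        df["p"] = df["q"]
        return df

    def test_perfect_predictions(self):
        gold = _flat_annset({"g1": {"A"}, "g2": {"B"}})
        preds = self._preds([("g1", "A", 1e-5), ("g2", "B", 1e-5)])
        r, p, f = gene_level_recall_precision(preds, gold, 0.01)
        assert (r, p, f) == (1.0, 1.0, 1.0)

    def test_half_overlap(self):
        gold = _flat_annset({"g": {"A", "B"}})
        preds = self._preds([("g", "A", 1e-5), ("g", "C", 1e-5)])
        r, p, f = gene_level_recall_precision(preds, gold, 0.01)
        assert r == 0.5 and p == 0.5 and f == 0.5

    def test_no_predictions_zero(self):
        gold = _flat_annset({"g": {"A"}})
        preds = self._preds([])
        r, p, f = gene_level_recall_precision(preds, gold, 0.01)
        assert (r, p, f) == (0.0, 0.0, 0.0)

    def test_empty_gold_raises(self):
        gold = _flat_annset({})
        with pytest.raises(ValueError):
            gene_level_recall_precision(self._preds([]), gold, 0.01)


class TestCategoryScores:
    def test_hand_counts(self):
        gold = _flat_annset({f"g{i}": {"T"} for i in range(4)})
        preds = pd.DataFrame({
            "gene": ["g0", "g1", "g2", "x"], "term": "T",
            "q": [1e-5] * 4, "p": [1e-5] * 4,
        })
        r, p, f = category_recall_precision(preds, gold, "T", 0.01)
        assert (r, p, f) == (0.75, 0.75, 0.75)

    def test_zero_tp(self):
        gold = _flat_annset({"g": {"T"}})
        preds = pd.DataFrame({"gene": ["x"], "term": ["T"], "q": [1e-5], "p": [1e-5]})
        r, p, f = category_recall_precision(preds, gold, "T", 0.01)
        assert (r, f) == (0.0, 0.0)

    def test_f_equals_p_when_p_equals_r(self):
        gold = _flat_annset({f"g{i}": {"T"} for i in range(4)})
        preds = pd.DataFrame({
            "gene": ["g0", "g1", "g2", "x"], "term": "T",
            "q": [1e-5] * 4, "p": [1e-5] * 4,
        })
        r, p, f = category_recall_precision(preds, gold, "T", 0.01)
        assert p == r == f


class TestPerformanceCurve:
    def _setup(self):
        gold = _flat_annset({"g1": {"A"}, "g2": {"B"}, "g3": {"C"}})
        preds = pd.DataFrame({
            "gene": ["g1", "g2", "g3"], "term": ["A", "B", "C"],
            "p": [1e-6, 1e-4, 1e-3], "q": [1e-6, 1e-4, 1e-3],
        })
        return preds, gold

    def test_monotone_predicted_positives(self):
        preds, gold = self._setup()
        curve = performance_curve(preds, gold)
        assert all(a >= b for a, b in zip(curve.predicted_positives,
                                          curve.predicted_positives[1:]))

    def test_loose_threshold_full_recall(self):
        preds, gold = self._setup()
        curve = performance_curve(preds, gold, thresholds=[1.0])
        assert curve.recall[0] == pytest.approx(1.0)

    def test_brute_force_recomputation(self):
        preds, gold = self._setup()
        curve = performance_curve(preds, gold)
        for t, r in zip(curve.thresholds, curve.recall):
            recalls = []
            for g, known in gold.gene_terms.items():
                hit = set(preds[(preds["gene"] == g) & (preds["q"] <= t)]["term"])
                recalls.append(len(hit & known) / len(known))
            assert r == pytest.approx(np.mean(recalls))

    def test_ascending_thresholds_raise(self):
        preds, gold = self._setup()
        with pytest.raises(ValueError):
            performance_curve(preds, gold, thresholds=[1e-4, 1e-2])


class TestClassifyRelativePerformance:
    def _curves(self, focal_values, sample_matrix):
        thresholds = [10.0 ** -k for k in range(2, 2 + len(focal_values))]
        mk = lambda f: PerformanceCurve(thresholds, list(f), list(f), list(f),
                                        [1] * len(f))
        return mk(focal_values), [mk(row) for row in sample_matrix]

    def test_strictly_above_everything(self, rng):
        samples = rng.uniform(0.1, 0.5, (20, 5))
        focal, sampled = self._curves([0.9] * 5, samples)
        assert classify_relative_performance(focal, sampled).label == "very good"

    def test_equal_to_median(self, rng):
        samples = np.tile(np.linspace(0.2, 0.6, 5), (21, 1))
        samples += rng.normal(0, 0.01, samples.shape)
        median = np.median(samples, axis=0)
        focal, sampled = self._curves(median, samples)
        assert classify_relative_performance(focal, sampled).label == "average"

    def test_strictly_below_everything(self, rng):
        samples = rng.uniform(0.5, 0.9, (20, 5))
        focal, sampled = self._curves([0.05] * 5, samples)
        assert classify_relative_performance(focal, sampled).label == "very poor"

    def test_empty_subrange_insufficient(self):
        focal, sampled = self._curves([0.0] * 5, np.zeros((10, 5)))
        res = classify_relative_performance(focal, sampled)
        assert res.label == "insufficient information"

    def test_needs_two_samples(self):
        focal, sampled = self._curves([0.5] * 5, np.zeros((1, 5)))
        with pytest.raises(ValueError):
            classify_relative_performance(focal, sampled[:1])


class TestClusterGoEnrichment:
    def test_rare_term_cluster_minimal_p(self):
        background = {f"g{i}" for i in range(100)}
        gene_terms = {g: {"common"} for g in background}
        for g in list(sorted(background))[:5]:
            gene_terms[g] = {"rare", "common"}
        ann = _flat_annset(gene_terms)
        cluster = {"c1": [g for g in sorted(background)[:5]]}
        table = cluster_go_enrichment(cluster, ann, background)
        row = table[table["term"] == "rare"].iloc[0]
        assert row["p"] == pytest.approx(hypergeom_tail_oracle(5, 100, 5, 5), rel=1e-9)

    def test_whole_background_term_p_one(self):
        background = {f"g{i}" for i in range(20)}
        ann = _flat_annset({g: {"T"} for g in background})
        table = cluster_go_enrichment({"c": list(background)[:6]}, ann, background)
        assert table.iloc[0]["p"] == pytest.approx(1.0)

    def test_null_calibration(self, rng):
        background = [f"g{i}" for i in range(80)]
        gene_terms = {}
        for g in background:
            gene_terms[g] = {f"T{t}" for t in rng.choice(8, 2, replace=False)}
        ann = _flat_annset(gene_terms)
        hits, total = 0, 0
        for _ in range(100):
            cluster = {"c": list(rng.choice(background, 10, replace=False))}
            table = cluster_go_enrichment(cluster, ann, set(background))
            hits += int((table["q"] <= 0.05).sum())
            total += len(table)
        assert hits / total <= 0.06

    def test_bh_within_cluster(self):
        background = {f"g{i}" for i in range(30)}
        gene_terms = {g: {"A", "B"} for g in background}
        ann = _flat_annset(gene_terms)
        table = cluster_go_enrichment({"c1": sorted(background)[:5],
                                       "c2": sorted(background)[5:10]}, ann, background)
        for _, group in table.groupby("cluster"):
            from fieldomics.spatial_stats import bh_adjust
            assert np.allclose(group["q"], bh_adjust(group["p"].to_numpy()))


class TestReadAnnotations:
    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("gene\tterm\ng1\tGO:1\ng2\tGO:2\n")
        df = read_annotations(str(p))
        assert list(df.columns) == ["gene", "term"]
        assert len(df) == 2

    def test_gaf_columns(self, tmp_path):
        p = tmp_path / "ann.gaf"
        fields = ["DB", "g1", "sym", "", "GO:0001", "ref", "IEA", "", "P",
                  "", "", "protein", "taxon:1", "20200101", "DB"]
        p.write_text("!gaf-version: 2.1\n" + "\t".join(fields) + "\n")
        df = read_annotations(str(p))
        assert df.iloc[0]["gene"] == "g1"
        assert df.iloc[0]["term"] == "GO:0001"
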