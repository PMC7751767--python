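"""End-to-end orchestration and the ``fieldomics`` command-line interface.

Stages communicate through TSV matrices (features in rows, plants in
columns, header row of plant ids) inside a run directory; a JSON manifest
records config, seeds and input hashes so that re-runs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import (
    coexpr_network,
    go_prediction,
    phenotype_pred,
    preprocess,
    spatial_lme,
    spatial_stats,
    synthetic_field,
    variability,
)

__all__ = ["PipelineConfig", "run_pipeline", "read_matrix", "write_matrix", "cli"]


@dataclass
class PipelineConfig:
    """Thresholds and paths for one pipeline run."""

    data_dir: str = "."
    out_dir: str = "run"
    moran_q: float = 0.01
    edge_alpha: float = 0.01
    trend_exclusion: float = 0.05
    hv_fraction: float = 0.10
    prediction_q: list[float] = field(default_factory=lambda: list(go_prediction.DEFAULT_THRESHOLDS))
    effects: list[str] = field(default_factory=lambda: ["batch", "doh", "snp"])
    phenotype_effects: list[str] = field(default_factory=lambda: ["doh", "snp"])
    n_clusters: int | None = None
    learner: str = "elastic_net"
    n_permutations: int = 0
    seed: int = 0

    def __post_init__(self):
        for name, value, lo, hi in [
            ("moran_q", self.moran_q, 0, 1), ("edge_alpha", self.edge_alpha, 0, 1),
            ("trend_exclusion", self.trend_exclusion, 0, 1),
            ("hv_fraction", self.hv_fraction, 0, 0.5),
        ]:
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.map(lambda v: isinstance(v, str)).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric cell in {path} at row {df.index[i]!r}, column {df.columns[j]!r}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_layout(path: str | Path) -> pd.DataFrame:
    layout = pd.read_csv(path, sep="\t")
    layout = layout.rename(columns={"x_cm": "x", "y_cm": "y"})
    required = {"plant_id", "x", "y", "batch", "doh", "snp_group"}
    missing = required - set(layout.columns)
    if missing:
        raise ValueError(f"layout {path} missing columns: {sorted(missing)}")
    return layout


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run preprocess -> correct -> screens -> network -> predictions.

    Expects ``counts.tsv``, ``metabolites.tsv``, ``phenotypes.tsv``,
    ``layout.tsv``, ``annotations.tsv`` and ``ontology.obo`` in
    ``config.data_dir``; writes every stage output plus ``manifest.json``
    into ``config.out_dir``.
    """
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {name: data / f"{name}.tsv" for name in
              ("counts", "metabolites", "phenotypes", "layout", "annotations")}
    inputs["ontology"] = data / "ontology.obo"
    for name, path in inputs.items():
        if not path.exists():
            raise FileNotFoundError(f"missing input {name}: {path}")
    manifest = {
        "config": asdict(config),
        "inputs": {k: _hash_file(v) for k, v in inputs.items()},
        "stages": {},
    }
    layout = read_layout(inputs["layout"])

    # preprocess
    counts = read_matrix(inputs["counts"])
    expr = preprocess.preprocess_counts(counts)
    write_matrix(expr.values, out / "expression_log2.tsv", "gene")
    mets = preprocess.preprocess_metabolites(read_matrix(inputs["metabolites"]))
    write_matrix(mets.values, out / "metabolites_log2.tsv", "metabolite")
    manifest["stages"]["preprocess"] = {
        "expression": expr.provenance, "metabolites": mets.provenance,
        "n_genes": len(expr.values), "n_metabolites": len(mets.values),
        "delta": expr.pseudocount_delta,
    }

    # spatial correction
    expr_resid, expr_stats = spatial_lme.residualize_matrix(expr.values, layout, config.effects)
    write_matrix(expr_resid, out / "expression_resid.tsv", "gene")
    expr_stats.to_csv(out / "expression_lme_stats.tsv", sep="\t")
    phen = read_matrix(inputs["phenotypes"])
    phen = phen.loc[phen.std(axis=1) > 0]
    phen_resid, phen_stats = spatial_lme.residualize_matrix(
        phen, layout, config.phenotype_effects)
    write_matrix(phen_resid, out / "phenotypes_resid.tsv", "trait")
    manifest["stages"]["correct"] = {
        "effects": config.effects,
        "ols_fallback_fraction": float((expr_stats.get("fitted_by") == "OLS-fallback").mean()),
    }

    # autocorrelation screen + clusters
    moran = spatial_stats.moran_table(expr_resid, layout)
    moran.to_csv(out / "moran.tsv", sep="\t")
    clusters = spatial_stats.cluster_autocorrelated_features(
        expr_resid, moran, config.moran_q, k=config.n_clusters)
    pd.DataFrame([
        {"feature": f, "cluster": c.cluster_id} for c in clusters for f in c.member_features
    ]).to_csv(out / "clusters.tsv", sep="\t", index=False)
    if clusters:
        assoc = spatial_stats.cluster_phenotype_correlation(clusters, phen_resid)
        assoc.to_csv(out / "cluster_phenotype.tsv", sep="\t", index=False)
    manifest["stages"]["autocorr"] = {
        "n_significant": int((moran["q"] <= config.moran_q).sum()),
        "n_clusters": len(clusters),
    }

    # variability
    linear = preprocess.back_transform(expr_resid, expr.pseudocount_delta)
    linear = linear.clip(lower=0)
    normcv, trend = variability.norm_cv_table(
        linear, excluded_fraction=config.trend_exclusion, flag_fraction=config.hv_fraction)
    normcv.to_csv(out / "norm_cv.tsv", sep="\t")
    manifest["stages"]["varscore"] = {
        "trend": {"a": trend.a, "b": trend.b, "model": trend.model},
        "n_highly_variable": int(normcv["highly_variable"].sum()),
    }

    # network + function prediction
    net = coexpr_network.build_network(expr_resid, layout, alpha=config.edge_alpha)
    edges = pd.DataFrame(
        [{"gene_a": a, "gene_b": b, **d} for a, b, d in net.edges(data=True)])
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    manifest["stages"]["network"] = net.graph["stats"]

    ontology = go_prediction.parse_obo(str(inputs["ontology"]))
    raw_ann = go_prediction.read_annotations(str(inputs["annotations"]))
    annset = go_prediction.propagate_annotations(raw_ann, ontology)
    predictions = go_prediction.neighborhood_enrichment(net, annset)
    predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    curve = go_prediction.performance_curve(predictions, annset, config.prediction_q)
    pd.DataFrame({
        "threshold": curve.thresholds, "recall": curve.recall,
        "precision": curve.precision, "f_measure": curve.f_measure,
        "predicted_positives": curve.predicted_positives,
    }).to_csv(out / "prediction_performance.tsv", sep="\t", index=False)
    manifest["stages"]["predict_function"] = {"n_predictions": int(len(predictions))}

    # phenotype prediction
    pheno_perf = {}
    for trait, row in phen_resid.iterrows():
        perf = phenotype_pred.nested_cv_fit(
            expr_resid, row.to_numpy(dtype=float), config.learner,
            seed=config.seed, n_permutations=config.n_permutations,
            permutation_grid=phenotype_pred.REDUCED_ENET_GRID
            if config.learner == "elastic_net" else None,
        )
        pheno_perf[str(trait)] = {
            "pooled_r2": perf.pooled_r2, "median_r2": perf.median_r2,
            "pcc": perf.pcc, "empirical_p": perf.empirical_p,
        }
    (out / "phenotype_performance.json").write_text(json.dumps(pheno_perf, indent=1))
    manifest["stages"]["predict_phenotype"] = pheno_perf

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def cli():
    """Spatially aware single-plant field-omics pipeline."""


@cli.command()
@click.option("--out", default="synthetic", show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--rows", default=10, show_default=True)
@click.option("--cols", default=56, show_default=True)
@click.option("--genes", default=200, show_default=True)
def simulate(out, seed, rows, cols, genes):
    """Generate a synthetic field dataset with ground truth."""
    config = synthetic_field.SimulationConfig(n_rows=rows, n_cols=cols,
                                              n_genes=genes, seed=seed)
    synthetic_field.write_dataset(synthetic_field.simulate_dataset(config), out)
    click.echo(f"wrote synthetic dataset to {out}")


@cli.command("run")
@click.option("--config", "config_path", default=None, help="YAML config file")
@click.option("--data-dir", default=".", show_default=True)
@click.option("--out-dir", default="run", show_default=True)
@click.option("--seed", default=0, show_default=True)
def run_cmd(config_path, data_dir, out_dir, seed):
    """Run the full pipeline on a data directory."""
    if config_path:
        config = PipelineConfig.from_yaml(config_path)
    else:
        config = PipelineConfig(data_dir=data_dir, out_dir=out_dir, seed=seed)
    path = run_pipeline(config)
    click.echo(f"pipeline complete: {path}")


@cli.command()
@click.argument("matrix_path")
@click.argument("layout_path")
@click.option("--effects", default="batch,doh,snp", show_default=True)
@click.option("--out", default="residuals.tsv", show_default=True)
def correct(matrix_path, layout_path, effects, out):
    """Remove batch/DOH/SNP effects with the spatial LME."""
    matrix = read_matrix(matrix_path)
    layout = read_layout(layout_path)
    resid, stats = spatial_lme.residualize_matrix(matrix, layout, effects.split(","))
    write_matrix(resid, out)
    stats.to_csv(Path(out).with_suffix(".stats.tsv"), sep="\t")
    click.echo(f"wrote {out}")


@cli.command()
@click.argument("matrix_path")
@click.argument("layout_path")
@click.option("--out", default="moran.tsv", show_default=True)
def autocorr(matrix_path, layout_path, out):
    """Per-feature Moran's I with BH q-values."""
    table = spatial_stats.moran_table(read_matrix(matrix_path), read_layout(layout_path))
    table.to_csv(out, sep="\t")
    click.echo(f"wrote {out}")


@cli.command()
@click.argument("matrix_path")
@click.option("--out", default="norm_cv.tsv", show_default=True)
@click.option("--model", default="gamma-identity", show_default=True)
def varscore(matrix_path, out, model):
    """normCV variability scores (input must be linear-scale)."""
    table, _ = variability.norm_cv_table(read_matrix(matrix_path), model=model)
    table.to_csv(out, sep="\t")
    click.echo(f"wrote {out}")


@cli.command()
@click.argument("matrix_path")
@click.argument("layout_path")
@click.option("--alpha", default=0.01, show_default=True)
@click.option("--fixed-edges", default=None, type=int)
@click.option("--out", default="edges.tsv", show_default=True)
def network(matrix_path, layout_path, alpha, fixed_edges, out):
    """Spatially adjusted co-expression network."""
    matrix = read_matrix(matrix_path)
    layout = read_layout(layout_path)
    if fixed_edges:
        table = coexpr_network.pair_table(matrix, layout)
        graph = coexpr_network.threshold_to_edge_count(table, fixed_edges, nodes=matrix.index)
    else:
        graph = coexpr_network.build_network(matrix, layout, alpha=alpha)
    pd.DataFrame([{"gene_a": a, "gene_b": b, **d} for a, b, d in graph.edges(data=True)]
                 ).to_csv(out, sep="\t", index=False)
    click.echo(json.dumps(coexpr_network.network_stats(graph)))
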