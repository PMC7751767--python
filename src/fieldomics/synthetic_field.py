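"""Synthetic field-grown single-plant datasets with known ground truth.

Generates a rectangular field layout, spatially autocorrelated latent
factors (spherical covariance plus nugget), count-type expression data,
metabolite intensities with missingness, phenotypes coupled to the latent
factors, and a small ontology with planted gene modules — everything the
downstream stages consume, with the generating truth retained for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .spatial_lme import SphericalCovariance, _layout_distances

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "make_field_layout",
    "sample_spatial_gp",
    "simulate_expression",
    "simulate_metabolites",
    "simulate_phenotypes",
    "simulate_go_annotations",
    "simulate_dataset",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic field generator.  All randomness flows from ``seed``."""

    n_rows: int = 10
    n_cols: int = 56
    within_row_spacing: float = 10.0  # cm, between plants along a row
    between_row_spacing: float = 75.0  # cm, between rows
    n_latent_factors: int = 2
    kernel_params: list[SphericalCovariance] = field(default_factory=list)
    n_genes: int = 200
    n_metabolites: int = 40
    n_traits: int = 4
    effect_sizes: tuple[float, float, float] = (0.5, 0.5, 0.5)  # batch, doh, snp
    effect_fraction: float = 0.3  # fraction of features carrying each effect
    count_model: str = "poisson-lognormal"  # or "lognormal"
    base_log2_mean: float = 6.0
    noise_sd: float = 0.3  # i.i.d. log2-scale noise
    missing_rate: float = 0.05
    group_scheme: str = "blocks"  # or "random"
    module_size: int = 10
    n_modules: int = 6
    withheld_fraction: float = 0.2
    trait_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.count_model not in ("poisson-lognormal", "lognormal"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if self.noise_sd < 0 or self.trait_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.kernel_params:
            self.kernel_params = [
                SphericalCovariance(1.0, 0.2, 150.0 + 100.0 * k)
                for k in range(self.n_latent_factors)
            ]
        for kp in self.kernel_params:
            if not 0.0 <= kp.nugget <= 1.0 or kp.range_ < 0:
                raise ValueError("invalid kernel parameters")


@dataclass
class SyntheticTruth:
    """Ground truth retained from a simulation run."""

    latent_factor_fields: np.ndarray  # factor x plant
    gene_loadings: np.ndarray  # gene x factor
    phenotype_coefficients: np.ndarray  # trait x factor
    planted_go_modules: dict[str, list[str]]
    true_fixed_effects: dict[str, tuple[float, float, float]]
    metabolite_loadings: np.ndarray | None = None
    withheld_annotations: set[tuple[str, str]] = field(default_factory=set)


def _majority_zero(labels: np.ndarray) -> np.ndarray:
    """Recode a 0/1 vector so that 0 marks the larger group."""
    if labels.sum() > len(labels) / 2:
        return 1 - labels
    return labels


def make_field_layout(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Lay out ``n_rows x n_cols`` plants on a regular grid.

    ``x = col * within_row_spacing`` and ``y = row * between_row_spacing``;
    batch and day-of-harvest labels follow field blocks (split along columns
    and rows respectively) and the SNP subgroup is random, unless
    ``group_scheme='random'`` randomizes all three.  Code 0 always marks the
    larger group.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows, cols = np.meshgrid(np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    n = len(rows)
    if config.group_scheme == "random":
        batch = rng.integers(0, 2, n)
        doh = rng.integers(0, 2, n)
    elif config.group_scheme == "blocks":
        # batch: right-of-center columns; doh: later rows — both minorities
        batch = (cols >= np.ceil(config.n_cols * 0.55)).astype(int)
        doh = (rows >= np.ceil(config.n_rows * 0.55)).astype(int)
    else:
        raise ValueError(f"unknown group_scheme {config.group_scheme!r}")
    snp = (rng.random(n) < 0.4).astype(int)
    layout = pd.DataFrame({
        "plant_id": [f"P{r:02d}_{c:02d}" for r, c in zip(rows, cols)],
        "row": rows,
        "col": cols,
        "x": cols * config.within_row_spacing,
        "y": rows * config.between_row_spacing,
        "batch": _majority_zero(batch),
        "doh": _majority_zero(doh),
        "snp_group": _majority_zero(snp),
    })
    return layout


def sample_spatial_gp(
    layout: pd.DataFrame,
    kernel: SphericalCovariance,
    rng: np.random.Generator | int | None = None,
    size: int = 1,
) -> np.ndarray:
    """Draw from a zero-mean Gaussian process over the plant positions.

    Covariance is ``sigma^2 [n I + (1-n) C(r)]``.  A small jitter is added
    if the Cholesky factorization fails; a persistent failure raises with a
    diagnostic.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dist = _layout_distances(layout)
    Sigma = kernel.covariance_matrix(dist)
    n = Sigma.shape[0]
    jitter = 0.0
    for attempt in range(6):
        try:
            L = np.linalg.cholesky(Sigma + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * max(kernel.sigma**2, 1.0))
    else:
        raise np.linalg.LinAlgError(
            f"covariance not PSD even after jitter {jitter:g} "
            f"(sigma={kernel.sigma}, nugget={kernel.nugget}, range={kernel.range_})"
        )
    z = rng.standard_normal((n, size))
    draws = (L @ z).T
    return draws[0] if size == 1 else draws


def _latent_factors(layout, config, rng) -> np.ndarray:
    return np.vstack([
        sample_spatial_gp(layout, kp, rng) for kp in config.kernel_params
    ]) if config.n_latent_factors else np.zeros((0, len(layout)))


def _effect_design(layout) -> np.ndarray:
    return layout[["batch", "doh", "snp_group"]].to_numpy(dtype=float)


def simulate_expression(
    layout: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Counts (genes x plants) from a log2-scale linear signal.

    signal = intercept + loadings @ factors + batch/doh/snp shifts + noise;
    counts are Poisson with mean 2^signal (poisson-lognormal) or the
    continuous 2^signal itself (lognormal mode, fast tests).
    """
    n_plants = len(layout)
    G = truth.gene_loadings.shape[0]
    design = _effect_design(layout)
    betas = np.array([truth.true_fixed_effects[f"G{g}"] for g in range(G)])
    signal = (
        config.base_log2_mean
        + truth.gene_loadings @ truth.latent_factor_fields
        + betas @ design.T
        + rng.normal(0.0, config.noise_sd, (G, n_plants))
    )
    mean_linear = np.exp2(signal)
    if config.count_model == "poisson-lognormal":
        values = rng.poisson(mean_linear).astype(float)
    else:
        values = mean_linear
    return pd.DataFrame(values, index=[f"G{g}" for g in range(G)], columns=layout["plant_id"])


def simulate_metabolites(
    layout: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Linear-scale metabolite intensities with MCAR missingness."""
    n_plants = len(layout)
    M = config.n_metabolites
    loadings = truth.metabolite_loadings
    design = _effect_design(layout)
    betas = np.array([truth.true_fixed_effects[f"M{m}"] for m in range(M)])
    signal = (
        config.base_log2_mean
        + loadings @ truth.latent_factor_fields
        + betas @ design.T
        + rng.normal(0.0, config.noise_sd, (M, n_plants))
    )
    values = np.exp2(signal)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)
    return pd.DataFrame(values, index=[f"M{m}" for m in range(M)], columns=layout["plant_id"])


def simulate_phenotypes(
    layout: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Traits (traits x plants) = phenotype_coefficients @ factors + noise."""
    n_plants = len(layout)
    T = truth.phenotype_coefficients.shape[0]
    values = (
        truth.phenotype_coefficients @ truth.latent_factor_fields
        + rng.normal(0.0, config.trait_noise_sd, (T, n_plants))
    )
    df = pd.DataFrame(values, index=[f"trait{t}" for t in range(T)], columns=layout["plant_id"])
    degenerate = df.std(axis=1) == 0
    if degenerate.any():
        df.attrs["degenerate_traits"] = list(df.index[degenerate])
    return df


def simulate_go_annotations(
    gene_ids: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    modules: dict[str, list[str]] | None = None,
):
    """Small is_a DAG (root -> branches -> leaves) plus a gene->term table.

    Planted modules share leaf terms.  A ``withheld_fraction`` of the direct
    annotations is removed from the emitted table and returned separately as
    the recall oracle.  Returns (annotations_df, ontology_edges, modules,
    withheld_set).  ``ontology_edges`` is a list of (child, parent) is_a pairs.
    """
    n_mod = config.n_modules if modules is None else len(modules)
    if modules is None:
        modules = {}
        pool = list(gene_ids)
        rng.shuffle(pool)
        size = max(config.module_size, 5)
        for m in range(n_mod):
            members = pool[m * size:(m + 1) * size]
            if len(members) < 5:
                break
            modules[f"GO:L{m:04d}"] = members
    # 3-level DAG: leaves -> branch terms -> root
    edges = []
    leaf_terms = list(modules)
    n_branches = max(2, (len(leaf_terms) + 1) // 2)
    for b in range(n_branches):
        edges.append((f"GO:B{b:04d}", "GO:ROOT"))
    for i, leaf in enumerate(leaf_terms):
        edges.append((leaf, f"GO:B{i % n_branches:04d}"))
    records = [(g, term) for term, members in modules.items() for g in members]
    rng.shuffle(records)
    n_withheld = int(round(config.withheld_fraction * len(records)))
    withheld = set(records[:n_withheld])
    kept = records[n_withheld:]
    ann = pd.DataFrame(sorted(kept), columns=["gene", "term"])
    return ann, edges, modules, withheld


def simulate_dataset(config: SimulationConfig) -> dict:
    """Run the full generator; returns layout, matrices, truth and annotations."""
    rng = np.random.default_rng(config.seed)
    layout = make_field_layout(config, rng)
    factors = _latent_factors(layout, config, rng)
    K = factors.shape[0]
    G, M, T = config.n_genes, config.n_metabolites, config.n_traits

    # module genes co-load on a shared factor; other loadings sparse/weak
    gene_loadings = np.zeros((G, K))
    modules: dict[str, list[str]] = {}
    gidx = rng.permutation(G)
    cursor = 0
    for m in range(config.n_modules):
        members = gidx[cursor:cursor + config.module_size]
        if len(members) < 5 or K == 0:
            break
        cursor += config.module_size
        k = m % K
        gene_loadings[members, k] = 1.0 + 0.2 * rng.standard_normal(len(members))
        modules[f"GO:L{m:04d}"] = [f"G{g}" for g in sorted(members)]

    met_loadings = 0.3 * rng.standard_normal((M, K)) if K else np.zeros((M, K))
    pheno_coeffs = rng.standard_normal((T, K)) if K else np.zeros((T, K))

    eb, ed, es = config.effect_sizes
    effects = {}
    for name, count in (("G", G), ("M", M)):
        for i in range(count):
            carries = rng.random(3) < config.effect_fraction
            effects[f"{name}{i}"] = (
                eb * carries[0] * rng.choice([-1, 1]),
                ed * carries[1] * rng.choice([-1, 1]),
                es * carries[2] * rng.choice([-1, 1]),
            )

    truth = SyntheticTruth(
        latent_factor_fields=factors,
        gene_loadings=gene_loadings,
        phenotype_coefficients=pheno_coeffs,
        planted_go_modules=modules,
        true_fixed_effects=effects,
        metabolite_loadings=met_loadings,
    )
    counts = simulate_expression(layout, truth, config, rng)
    metabolites = simulate_metabolites(layout, truth, config, rng)
    phenotypes = simulate_phenotypes(layout, truth, config, rng)
    annotations, ontology_edges, modules, withheld = simulate_go_annotations(
        list(counts.index), config, rng, modules=modules or None
    )
    truth.withheld_annotations = withheld
    return {
        "layout": layout,
        "counts": counts,
        "metabolites": metabolites,
        "phenotypes": phenotypes,
        "annotations": annotations,
        "ontology_edges": ontology_edges,
        "truth": truth,
        "config": config,
    }


def _obo_text(edges: list[tuple[str, str]]) -> str:
    terms = sorted({t for e in edges for t in e})
    parents = {}
    for child, parent in edges:
        parents.setdefault(child, []).append(parent)
    blocks = ["format-version: 1.2\nontology: synthetic"]
    for t in terms:
        lines = [f"[Term]", f"id: {t}", f"name: synthetic term {t}"]
        for p in sorted(parents.get(t, [])):
            lines.append(f"is_a: {p} ! synthetic term {p}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def write_dataset(data: dict, outdir: str | Path) -> None:
    """Write all generated tables as TSV/OBO/JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = data["layout"].rename(columns={"x": "x_cm", "y": "y_cm"})
    layout.to_csv(outdir / "layout.tsv", sep="\t", index=False)
    data["counts"].to_csv(outdir / "counts.tsv", sep="\t", index_label="gene")
    data["metabolites"].to_csv(outdir / "metabolites.tsv", sep="\t", index_label="metabolite")
    data["phenotypes"].to_csv(outdir / "phenotypes.tsv", sep="\t", index_label="trait")
    data["annotations"].to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    (outdir / "ontology.obo").write_text(_obo_text(data["ontology_edges"]))
    truth = data["truth"]
    payload = {
        "latent_factor_fields": truth.latent_factor_fields.tolist(),
        "gene_loadings": truth.gene_loadings.tolist(),
        "phenotype_coefficients": truth.phenotype_coefficients.tolist(),
        "planted_go_modules": truth.planted_go_modules,
        "true_fixed_effects": {k: list(v) for k, v in truth.true_fixed_effects.items()},
        "withheld_annotations": sorted(list(truth.withheld_annotations)),
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1))
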