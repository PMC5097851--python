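"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator states a small world and sticks to it: gene TSSs uniform per
chromosome with random strands; per gene and feature a Poisson number of
reads (mean = the gene's target score) at offsets uniform in [-d*, d*]
around the TSS, plus a uniform Poisson background along each chromosome;
expression generated as Y = X beta_true + N(0, sigma^2) from the
*processed* score matrix (transformed, quantile-normalised, bias column),
so the linear model is exactly the generative truth.

Uniform read offsets make the expected raw histone score exactly the
Poisson mean plus the in-window background expectation, giving closed-form
oracles; a triangular-peak offset option exists for realism.  Everything
is deterministic under the config seed (byte-identical files).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as gio
from .engine import EngineConfig
from .io import ExpressionVector, GeneAnnotation, ScoreMatrix, SignalRecord
from .scoring import (
    ScoringConfig,
    TssIndex,
    assemble_score_matrix,
    mr_epigenetic_scores,
    quantile_normalise,
    transform_scores,
)

__all__ = [
    "SimulationConfig",
    "make_fixture_suite",
    "sigma_for_target_r2",
    "simulate_annotation",
    "simulate_chipseq",
    "simulate_expression",
    "simulate_score_matrix",
]


@dataclass
class SimulationConfig:
    """The stated world for synthetic fixture generation.

    Defaults: 1000 genes over 2 chromosomes, 6 features (the six
    promoter-localised histone marks of the reference design), mean 50
    reads per gene and feature, a background of 1e-6 reads/bp, and
    Gaussian expression noise sigma = 1.  Chromosome length defaults to
    10 * d_star * genes-per-chromosome so uniform TSS placement is sparse
    but still yields occasional multi-gene windows.
    """

    n_genes: int = 1000
    n_features: int = 6
    n_chroms: int = 2
    chrom_length: int | None = None
    reads_per_gene: float = 50.0
    background_read_rate: float = 1e-6
    beta_true: np.ndarray | None = None
    noise_sigma: float = 1.0
    seed: int = 0
    d_star: int = 2000
    d0: float = 5000.0
    kind: str = "histone"
    peak_shape: str = "uniform"
    target_shape: float = 2.0  # gamma shape of per-gene target scores

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_features", "n_chroms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.chrom_length is None:
            per_chrom = -(-self.n_genes // self.n_chroms)
            self.chrom_length = 10 * self.d_star * per_chrom
        if self.beta_true is None:
            rng = np.random.default_rng([self.seed, 17])
            self.beta_true = np.round(rng.uniform(-2.0, 2.0, self.n_features), 3)
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.peak_shape not in ("uniform", "triangular"):
            raise ValueError(f"unknown peak_shape {self.peak_shape!r}")

    def scoring_config(self) -> ScoringConfig:
        return ScoringConfig(d_star=self.d_star, d0=self.d0, kind=self.kind)


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def simulate_annotation(config: SimulationConfig) -> list[GeneAnnotation]:
    """M genes with TSSs uniform per chromosome and Bernoulli(1/2) strands."""
    per_chrom = -(-config.n_genes // config.n_chroms)
    min_len = 10 * config.d_star * per_chrom
    if config.chrom_length < min_len:
        raise ValueError(
            f"chrom_length {config.chrom_length} too short for {per_chrom} genes "
            f"per chromosome (need >= {min_len} to avoid pathological crowding)"
        )
    rng = _rng(config, 1)
    genes: list[GeneAnnotation] = []
    width = len(str(config.n_genes - 1))
    gid = 0
    for c in range(config.n_chroms):
        n_here = min(per_chrom, config.n_genes - gid)
        lo, hi = config.d_star + 1, config.chrom_length - config.d_star
        tss = np.sort(rng.integers(lo, hi, size=n_here))
        strands = rng.random(n_here) < 0.5
        for t, plus in zip(tss, strands):
            genes.append(
                GeneAnnotation(
                    f"g{gid:0{width}d}", f"chr{c + 1}", int(t), "+" if plus else "-"
                )
            )
            gid += 1
    return genes


def _peak_offsets(rng: np.random.Generator, n: int, d_star: int, shape: str) -> np.ndarray:
    if shape == "uniform":
        return rng.integers(-d_star, d_star + 1, size=n)
    # triangular: denser near the TSS, zero density at +/- d_star
    return np.round(rng.triangular(-d_star, 0, d_star, size=n)).astype(np.int64)


def simulate_chipseq(
    annotation: list[GeneAnnotation],
    target_scores: np.ndarray,
    config: SimulationConfig,
    stream: int = 2,
) -> list[SignalRecord]:
    """Poisson(target) reads per gene around its TSS plus uniform background.

    Reads landing at the same base are aggregated into one integral-weight
    record, keeping histone scores exact integers.
    """
    target_scores = np.asarray(target_scores, dtype=float)
    if np.any(target_scores < 0):
        raise ValueError("target_scores must be non-negative")
    if len(target_scores) != len(annotation):
        raise ValueError("target_scores length must match annotation")
    rng = _rng(config, stream)
    counts: dict[tuple[str, int], int] = {}
    for gene, target in zip(annotation, target_scores):
        n_reads = rng.poisson(target)
        if n_reads == 0:
            continue
        offsets = _peak_offsets(rng, n_reads, config.d_star, config.peak_shape)
        for off in offsets:
            pos = max(1, gene.tss + int(off))
            key = (gene.chrom, pos)
            counts[key] = counts.get(key, 0) + 1
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_bg = rng.poisson(config.background_read_rate * config.chrom_length)
        positions = rng.integers(1, config.chrom_length + 1, size=n_bg)
        for pos in positions:
            key = (chrom, int(pos))
            counts[key] = counts.get(key, 0) + 1
    return [
        SignalRecord(chrom, pos, float(w))
        for (chrom, pos), w in sorted(counts.items())
    ]


def simulate_score_matrix(
    config: SimulationConfig, add_bias: bool = True, stream: int = 3
) -> ScoreMatrix:
    """Raw score matrix drawn directly as Poisson(target) counts per feature.

    Statistically equivalent (for zero background) to scoring the simulated
    reads, but skips read placement; used where only the regression stage
    is under study.
    """
    rng = _rng(config, stream)
    width = len(str(config.n_genes - 1))
    gene_ids = [f"g{i:0{width}d}" for i in range(config.n_genes)]
    targets = rng.gamma(
        config.target_shape,
        config.reads_per_gene / config.target_shape,
        size=(config.n_genes, config.n_features),
    )
    raw = rng.poisson(targets).astype(float)
    names = [f"feat{j + 1}" for j in range(config.n_features)]
    if add_bias:
        raw = np.column_stack([raw, np.ones(config.n_genes)])
        names = names + ["bias"]
    return ScoreMatrix(gene_ids, names, raw, has_bias=add_bias)


def simulate_expression(
    X: ScoreMatrix,
    beta_true: np.ndarray,
    noise_sigma: float,
    seed: int,
) -> ExpressionVector:
    """Y = X beta_true + N(0, sigma^2) i.i.d.; sigma=0 gives exact linearity."""
    beta_true = np.asarray(beta_true, dtype=float)
    if X.values.shape[1] != len(beta_true):
        raise ValueError(
            f"X has {X.values.shape[1]} columns but beta_true has {len(beta_true)}"
        )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sigma, size=X.values.shape[0]) if noise_sigma else 0.0
    return ExpressionVector(list(X.gene_ids), X.values @ beta_true + noise)


def sigma_for_target_r2(X: ScoreMatrix, beta_true: np.ndarray, r2: float) -> float:
    """Noise sigma making the population R^2 = Var(X beta)/(Var(X beta)+sigma^2) equal r2."""
    if not 0 < r2 < 1:
        raise ValueError("target r2 must be in (0, 1)")
    signal_var = float(np.var(X.values @ np.asarray(beta_true, dtype=float)))
    return float(np.sqrt(signal_var * (1.0 - r2) / r2))


@dataclass
class FixtureSuite:
    """Paths and ground truth of a generated fixture directory."""

    out_dir: Path
    bed_path: Path
    wig_paths: dict[str, dict[str, Path]]  # cell-line -> feature -> path
    expression_paths: dict[str, Path]
    score_paths: dict[str, Path]
    truth: dict = field(default_factory=dict)


def make_fixture_suite(
    config: SimulationConfig,
    out_dir: str | Path,
    n_cell_lines: int = 1,
    shared_beta: bool = True,
    latent_residual_groups: list[list[int]] | None = None,
    latent_sd: float = 0.0,
    target_r2: float | None = None,
    engine: EngineConfig | None = None,
) -> FixtureSuite:
    """Write a self-contained BED + WIG + expression fixture directory.

    Per cell-line, per feature: target scores ~ Gamma, reads simulated and
    written as WIG; the written WIGs are then scored through the real
    pipeline (log transform, quantile normalisation, bias column) and
    expression simulated from the processed matrix, so every file is
    consumed by the corresponding reader and the regression model is the
    generative truth.

    ``shared_beta=False`` draws an independent beta per cell-line (to probe
    cross-cell-line divergence).  ``latent_residual_groups`` adds a shared
    gene-level noise component (SD ``latent_sd``) to the named cell-line
    groups, inducing correlated residuals for clustering tests.
    ``target_r2`` overrides ``noise_sigma`` with the sigma achieving that
    population R^2 per cell-line.  truth.json records everything.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    bed_path = out_dir / "genes.bed"
    gio.write_gene_annotation(annotation, bed_path)
    index = TssIndex.build(annotation)
    scfg = config.scoring_config()

    latent_of_cell: dict[int, int] = {}
    if latent_residual_groups:
        for gi, group in enumerate(latent_residual_groups):
            for cell in group:
                latent_of_cell[cell] = gi
    latent_rng = _rng(config, 40)
    latent_vectors = {
        gi: latent_rng.normal(0.0, 1.0, config.n_genes)
        for gi in sorted({v for v in latent_of_cell.values()})
    }

    wig_paths: dict[str, dict[str, Path]] = {}
    expression_paths: dict[str, Path] = {}
    score_paths: dict[str, Path] = {}
    truth_cells = {}
    for c in range(n_cell_lines):
        cell = f"cell{c + 1}"
        target_rng = _rng(config, 10, c)
        wig_paths[cell] = {}
        columns = []
        for f in range(config.n_features):
            feature = f"feat{f + 1}"
            targets = target_rng.gamma(
                config.target_shape,
                config.reads_per_gene / config.target_shape,
                size=config.n_genes,
            )
            reads = simulate_chipseq(annotation, targets, config, stream=100 + 10 * c + f)
            path = out_dir / f"{cell}_{feature}.wig"
            gio.write_wig(reads, path)
            wig_paths[cell][feature] = path
            col = mr_epigenetic_scores(
                gio.read_wig(path), index, scfg, engine, feature_name=feature
            )
            columns.append(col)
        X = assemble_score_matrix(columns, add_bias=True)
        X = transform_scores(X, "log")
        X = quantile_normalise(X)
        score_path = out_dir / f"{cell}_scores.tsv"
        gio.write_score_matrix(X, score_path)
        score_paths[cell] = score_path

        if shared_beta:
            beta = np.append(config.beta_true, 1.0)  # bias coefficient
        else:
            beta_rng = _rng(config, 20, c)
            beta = np.append(
                np.round(beta_rng.uniform(-2.0, 2.0, config.n_features), 3), 1.0
            )
        sigma = (
            sigma_for_target_r2(X, beta, target_r2)
            if target_r2 is not None
            else config.noise_sigma
        )
        expr = simulate_expression(X, beta, sigma, seed=int(config.seed * 1009 + c) % (2**31))
        values = expr.values
        if c in latent_of_cell:
            values = values + latent_sd * latent_vectors[latent_of_cell[c]]
        expr = ExpressionVector(expr.gene_ids, values)
        expr_path = out_dir / f"{cell}_expression.tsv"
        gio.write_expression(expr, expr_path)
        expression_paths[cell] = expr_path
        truth_cells[cell] = {
            "beta_true": [float(b) for b in beta],
            "noise_sigma": float(sigma),
            "latent_group": latent_of_cell.get(c),
        }

    truth = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "n_features": config.n_features,
        "d_star": config.d_star,
        "kind": config.kind,
        "shared_beta": shared_beta,
        "latent_sd": latent_sd,
        "cell_lines": truth_cells,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return FixtureSuite(out_dir, bed_path, wig_paths, expression_paths, score_paths, truth)
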