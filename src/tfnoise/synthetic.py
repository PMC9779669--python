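"""Synthetic data generators with known ground truth.

Every generator is a pure function of its spec and seed, and each one
emulates the statistical structure of the corresponding real input of the
analysis pipeline:

* `gen_expression_matrix` — a genes × cells count matrix whose per-gene CV
  follows a polynomial trend in log mean plus a planted gene-specific excess
  (negative-binomial counts; the dispersion is solved from the target CV).
* `gen_promoters` — promoter sequences (−1000..+10 relative to the start
  codon by convention, 1010 bp) with planted, possibly overlapping, motif
  instances carrying a controlled number of mismatches.
* `gen_feature_table` — a gene × feature matrix with a sparse linear effect
  on a noise response, with known population R².
* `gen_coexpression_panel` — a conditions × genes expression panel with
  planted gene–TF slopes and TF–TF correlation blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TREND",
    "SyntheticNoiseSpec",
    "SyntheticPromoterSpec",
    "SyntheticFeatureSpec",
    "gen_expression_matrix",
    "gen_promoters",
    "gen_feature_table",
    "gen_coexpression_panel",
]

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _default_trend_coefficients() -> np.ndarray:
    """Degree-5 CV-vs-log-mean trend (ascending powers of ln mean).

    Shaped like the scRNA-seq mean–CV relationship: high CV at low
    expression, decaying with mean, with genuine quintic curvature so the
    trend order is identifiable. Defined on ln(mean) in [ln 5, ln 1000] and
    everywhere above the Poisson CV floor 1/sqrt(mean) there.
    """
    lo, hi = np.log(5.0), np.log(1000.0)
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    # Legendre series in u = (x - mid)/half so every order up to 5 carries
    # substantial orthogonal variance (identifiable trend order)
    in_u = np.polynomial.Legendre([1.2, -0.40, 0.15, 0.20, -0.25, 0.30]).convert(
        kind=np.polynomial.Polynomial
    )
    return in_u(np.polynomial.Polynomial([-mid / half, 1.0 / half])).coef


DEFAULT_TREND = _default_trend_coefficients()


@dataclass
class SyntheticNoiseSpec:
    """Generative model of a single-cell expression matrix."""

    n_genes: int = 2000
    n_cells: int = 200
    trend_coefficients: np.ndarray = field(default_factory=lambda: DEFAULT_TREND.copy())
    excess_noise: np.ndarray | None = None  # per gene; None -> all zero
    excess_noise_sd: float = 0.0  # used to draw excess_noise when it is None
    mean_range: tuple[float, float] = (5.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be positive")
        if not 0 < self.mean_range[0] < self.mean_range[1]:
            raise ValueError("mean_range must be an increasing positive interval")
        self.trend_coefficients = np.asarray(self.trend_coefficients, dtype=float)
        if self.excess_noise is not None:
            self.excess_noise = np.asarray(self.excess_noise, dtype=float)
            if self.excess_noise.shape != (self.n_genes,):
                raise ValueError("excess_noise must have one entry per gene")
            if not np.all(np.isfinite(self.excess_noise)):
                raise ValueError("excess_noise must be finite")
        x = np.log(np.linspace(*self.mean_range, 256))
        if np.polynomial.polynomial.polyval(x, self.trend_coefficients).min() <= 0:
            raise ValueError("trend gives non-positive baseline CV over mean_range")

    def baseline_cv(self, log_mean: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(log_mean, self.trend_coefficients)


def gen_expression_matrix(spec: SyntheticNoiseSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes × cells negative-binomial count matrix plus ground truth.

    Per gene, the mean is log-uniform over ``mean_range`` and the target CV
    is ``trend(ln mean) + excess_noise``. The NB dispersion r solves
    CV² = 1/mean + 1/r; genes whose target CV falls below the Poisson floor
    are clipped to (near-)Poisson and flagged in the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    mu = np.exp(rng.uniform(*np.log(spec.mean_range), size=spec.n_genes))
    if spec.excess_noise is not None:
        excess = spec.excess_noise
    elif spec.excess_noise_sd > 0:
        excess = rng.normal(0.0, spec.excess_noise_sd, size=spec.n_genes)
    else:
        excess = np.zeros(spec.n_genes)
    target_cv = spec.baseline_cv(np.log(mu)) + excess
    inv_r = target_cv**2 - 1.0 / mu
    clipped = inv_r <= 0
    if clipped.any():
        warnings.warn(
            f"{clipped.sum()} gene(s) below the Poisson CV floor; clipped to Poisson",
            stacklevel=2,
        )
    inv_r = np.where(clipped, 1e-12, inv_r)
    r = 1.0 / inv_r
    p = r / (r + mu)
    counts = rng.negative_binomial(r[:, None], p[:, None], size=(spec.n_genes, spec.n_cells))
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    expr = pd.DataFrame(
        counts, index=genes, columns=[f"cell{j:04d}" for j in range(spec.n_cells)]
    )
    truth = pd.DataFrame(
        {
            "true_mean": mu,
            "true_cv": np.where(clipped, np.sqrt(1.0 / mu), target_cv),
            "excess_noise": excess,
            "dispersion": r,
            "poisson_clipped": clipped,
        },
        index=genes,
    )
    return expr, truth


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


@dataclass
class SyntheticPromoterSpec:
    """Promoters with planted (possibly overlapping) motif instances.

    `motif_library` maps motif ids to consensus strings over ACGT;
    `planted_sites[p]` lists (motif_id, start, strand, n_mismatches) tuples
    for promoter index p, with `start` 0-based on the forward strand (local
    coordinate 0 = position −1000 relative to the start codon).
    """

    n_promoters: int = 50
    promoter_length: int = 1010
    motif_library: dict[str, str] = field(default_factory=dict)
    planted_sites: dict[int, list[tuple[str, int, str, int]]] = field(default_factory=dict)
    background_gc: float = 0.38  # yeast-like intergenic GC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters < 1 or self.promoter_length < 1:
            raise ValueError("n_promoters and promoter_length must be positive")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must be in [0, 1]")
        for motif_id, cons in self.motif_library.items():
            if set(cons) - set("ACGT"):
                raise ValueError(f"motif {motif_id} has non-ACGT characters")
        for p, sites in self.planted_sites.items():
            for motif_id, start, strand, n_mm in sites:
                length = len(self.motif_library[motif_id])
                if not 0 <= start <= self.promoter_length - length:
                    raise ValueError(f"planted site {motif_id}@{start} outside promoter {p}")
                if strand not in "+-":
                    raise ValueError("strand must be '+' or '-'")
                if not 0 <= n_mm <= length:
                    raise ValueError("n_mismatches must be in [0, motif length]")


def _mutate(rng: np.random.Generator, seq: str, n: int) -> str:
    """Introduce exactly n substitutions at distinct random positions."""
    if n == 0:
        return seq
    arr = list(seq)
    for pos in rng.choice(len(arr), size=n, replace=False):
        arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
    return "".join(arr)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gen_promoters(spec: SyntheticPromoterSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate promoter sequences and the planted-site ground truth.

    The background is i.i.d. with the requested GC fraction; planted
    instances overwrite it (minus-strand instances are inserted as the
    reverse complement of the mutated motif). Overlapping planted sites are
    allowed — later sites in the list take precedence over earlier ones in
    the shared bases, so overlapping instances are only guaranteed
    recoverable when their sequences agree on the overlap. The ground-truth table uses
    BED conventions (0-based, half-open) plus the biologist-style signed
    position relative to the start codon.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.background_gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    rows = []
    promoters: dict[str, str] = {}
    for p in range(spec.n_promoters):
        name = f"prom{p:04d}"
        seq = rng.choice(BASES, size=spec.promoter_length, p=probs)
        for motif_id, start, strand, n_mm in spec.planted_sites.get(p, []):
            inst = _mutate(rng, spec.motif_library[motif_id], n_mm)
            planted = inst if strand == "+" else reverse_complement(inst)
            seq[start : start + len(planted)] = list(planted)
            rows.append(
                {
                    "chrom": name,
                    "start": start,
                    "end": start + len(planted),
                    "name": motif_id,
                    "score": n_mm,
                    "strand": strand,
                    "signed_start": signed_position(start, spec.promoter_length),
                }
            )
        promoters[name] = "".join(seq)
    truth = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand", "signed_start"]
    )
    return promoters, truth


def signed_position(local: int, promoter_length: int = 1010) -> int:
    """Convert a 0-based promoter-local coordinate to the signed convention.

    Local 0 is −1000 (1000 bp upstream of the start codon); there is no
    position 0, and +1 is the first base of the ATG.
    """
    codon_start = promoter_length - 10
    return local - codon_start if local < codon_start else local - codon_start + 1


def random_planted_sites(
    n_promoters: int,
    motif_library: dict[str, str],
    sites_per_promoter: int = 3,
    max_planted_mismatch: int = 2,
    promoter_length: int = 1010,
    seed: int = 0,
) -> dict[int, list[tuple[str, int, str, int]]]:
    """Draw a random planted-site layout (sites may overlap by chance)."""
    rng = np.random.default_rng(seed)
    motif_ids = list(motif_library)
    layout: dict[int, list[tuple[str, int, str, int]]] = {}
    for p in range(n_promoters):
        sites = []
        for _ in range(sites_per_promoter):
            mid = motif_ids[rng.integers(len(motif_ids))]
            length = len(motif_library[mid])
            start = int(rng.integers(0, promoter_length - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            n_mm = int(rng.integers(0, max_planted_mismatch + 1))
            sites.append((mid, start, strand, n_mm))
        layout[p] = sites
    return layout


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


@dataclass
class SyntheticFeatureSpec:
    """Sparse linear generative model: response = X @ beta + noise."""

    n_genes: int = 2000
    n_features: int = 100
    true_coefficients: np.ndarray | None = None  # None -> 5 coefficients of 1.0
    noise_sd: float = 1.0
    feature_correlation: float = 0.0
    orthogonalize: bool = False  # QR-orthogonalise columns (exact orthogonal design)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_features < 1:
            raise ValueError("dimensions must be positive")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature_correlation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.true_coefficients is None:
            beta = np.zeros(self.n_features)
            beta[: min(5, self.n_features)] = 1.0
            self.true_coefficients = beta
        else:
            self.true_coefficients = np.asarray(self.true_coefficients, dtype=float)
            if self.true_coefficients.shape != (self.n_features,):
                raise ValueError("true_coefficients must have one entry per feature")

    def population_r2(self) -> float:
        """Implied R²: var(X beta) / (var(X beta) + noise_sd²)."""
        beta, rho = self.true_coefficients, self.feature_correlation
        signal = (1 - rho) * np.sum(beta**2) + rho * np.sum(beta) ** 2
        return float(signal / (signal + self.noise_sd**2))

    def noise_sd_for_r2(self, r2: float) -> float:
        """The noise_sd giving population R² = r2 for the current beta."""
        beta, rho = self.true_coefficients, self.feature_correlation
        signal = (1 - rho) * np.sum(beta**2) + rho * np.sum(beta) ** 2
        return float(np.sqrt(signal * (1 - r2) / r2))


def gen_feature_table(
    spec: SyntheticFeatureSpec,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Feature matrix, response vector and the true coefficient vector.

    Features are standard normal with equicorrelation
    ``feature_correlation``; with ``orthogonalize`` the realized columns are
    QR-orthogonalised (and rescaled to unit variance) so the design is
    exactly orthogonal.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.feature_correlation
    z = rng.standard_normal((spec.n_genes, spec.n_features))
    if rho > 0:
        common = rng.standard_normal((spec.n_genes, 1))
        x = np.sqrt(rho) * common + np.sqrt(1 - rho) * z
    else:
        x = z
    if spec.orthogonalize:
        q, _ = np.linalg.qr(x - x.mean(axis=0))
        x = q / q.std(axis=0, ddof=0)
    y = x @ spec.true_coefficients + rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    features = [f"f{j:03d}" for j in range(spec.n_features)]
    return (
        pd.DataFrame(x, index=genes, columns=features),
        pd.Series(y, index=genes, name="noise"),
        spec.true_coefficients.copy(),
    )


# ---------------------------------------------------------------------------
# co-expression panels
# ---------------------------------------------------------------------------


def gen_coexpression_panel(
    n_samples: int,
    tf_target_slopes: dict[str, float],
    tf_tf_correlation_blocks: Sequence[tuple[Sequence[str], float]] = (),
    residual_sd: float = 1.0,
    gene_id: str = "gene",
    seed: int = 0,
) -> pd.DataFrame:
    """Samples × genes expression panel with planted regulatory structure.

    TF expression is standard normal across conditions; TFs listed in a
    correlation block share a common factor giving pairwise correlation r.
    The target gene is the planted linear combination of its TFs plus
    Gaussian residual noise of sd `residual_sd`.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    tfs = list(tf_target_slopes)
    expr = pd.DataFrame(
        rng.standard_normal((n_samples, len(tfs))),
        columns=tfs,
        index=[f"s{i:03d}" for i in range(n_samples)],
    )
    for block, r in tf_tf_correlation_blocks:
        if not 0.0 <= r < 1.0:
            raise ValueError("block correlation must be in [0, 1)")
        factor = rng.standard_normal(n_samples)
        for tf in block:
            if tf not in expr.columns:
                expr[tf] = rng.standard_normal(n_samples)
            expr[tf] = np.sqrt(r) * factor + np.sqrt(1 - r) * rng.standard_normal(n_samples)
    gene = sum(
        slope * expr[tf] for tf, slope in tf_target_slopes.items()
    ) + rng.normal(0.0, residual_sd, size=n_samples)
    expr.insert(0, gene_id, gene)
    return expr
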