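"""Synthetic data generators and validation utilities.

Two regimes:

* Gaussian-mixture factor score vectors with known component overlap, used to
  benchmark the interpretability metrics;
* planted-covariate Poisson count matrices, where each covariate level drives
  a disjoint gene block, used to exercise the full pipeline end to end.

All randomness flows from a single root seed: every sub-generator is spawned
from ``numpy.random.default_rng(seed)`` in a fixed documented order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr, spearmanr

from .io_model import CountMatrix, CovariateTable

__all__ = [
    "GaussianMixtureSpec",
    "PlantedCountSpec",
    "default_mixture_specs",
    "simulate_factors",
    "overlap",
    "metric_overlap_benchmark",
    "simulate_counts",
    "sparsify",
]


@dataclass
class GaussianMixtureSpec:
    """Two-component 1-D Gaussian mixture for one simulated factor."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    pi: float = 0.5  # proportion of component 1

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigmas must be positive")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")

    def overlap(self) -> float:
        return overlap(self.mu1, self.mu2, self.sigma1, self.sigma2)


def default_mixture_specs(
    n_factors: int = 10,
    rng: np.random.Generator | None = None,
    mu_range: tuple[float, float] = (0.0, 4.0),
    sigma_range: tuple[float, float] = (0.5, 1.0),
    pi: float = 0.5,
) -> list[GaussianMixtureSpec]:
    """Draw mixture parameters from the default uniform priors."""
    rng = rng if rng is not None else np.random.default_rng()
    specs = []
    for _ in range(n_factors):
        mu1, mu2 = rng.uniform(*mu_range, size=2)
        s1, s2 = rng.uniform(*sigma_range, size=2)
        specs.append(GaussianMixtureSpec(mu1, mu2, s1, s2, pi))
    return specs


def simulate_factors(
    specs: list[GaussianMixtureSpec] | None = None,
    n: int = 10000,
    seed: int = 0,
    n_factors: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample factor score vectors from two-component Gaussian mixtures.

    Returns ``(scores, membership, overlaps)``: an n x f score matrix, the
    ground-truth component membership of every cell for every factor (the
    factor's binary covariate), and each factor's true density overlap.
    """
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = default_mixture_specs(n_factors, rng)
    f = len(specs)
    scores = np.empty((n, f))
    membership = np.empty((n, f), dtype=int)
    overlaps = np.empty(f)
    for j, sp in enumerate(specs):
        z = rng.random(n) < sp.pi  # True -> component 1
        mu = np.where(z, sp.mu1, sp.mu2)
        sd = np.where(z, sp.sigma1, sp.sigma2)
        scores[:, j] = rng.normal(mu, sd)
        membership[:, j] = np.where(z, 1, 2)
        overlaps[j] = sp.overlap()
    return scores, membership, overlaps


# ---------------------------------------------------------------------------
# Gaussian overlap
# ---------------------------------------------------------------------------

def _density_crossings(mu1, mu2, s1, s2) -> np.ndarray:
    """Real solutions of N(mu1, s1)(x) = N(mu2, s2)(x)."""
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (mu1 / s1**2 - mu2 / s2**2)
    c = mu2**2 / s2**2 - mu1**2 / s1**2 + 2.0 * np.log(s2 / s1)
    if abs(a) < 1e-14:  # equal sigmas: linear equation
        if abs(b) < 1e-14:
            return np.array([])  # identical densities
        return np.array([-c / b])
    disc = b**2 - 4 * a * c
    if disc < 0:
        return np.array([])
    r = np.sqrt(disc)
    return np.sort(np.array([(-b - r) / (2 * a), (-b + r) / (2 * a)]))


def overlap(mu1: float, mu2: float, sigma1: float, sigma2: float) -> float:
    """Overlap of two normal densities, the mass under min(f1, f2).

    Computed analytically from the density crossing points: on each segment
    the smaller density's CDF increment is accumulated.  Reduces to
    ``1 - (1/2)[erf((c-mu1)/(sqrt(2) s1)) - erf((c-mu2)/(sqrt(2) s2))]`` with
    ``c`` the between-means crossing when the sigmas are equal, and to 1 for
    identical densities.
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigmas must be positive")
    if mu1 == mu2 and sigma1 == sigma2:
        return 1.0
    roots = _density_crossings(mu1, mu2, sigma1, sigma2)
    edges = np.concatenate([[-np.inf], roots, [np.inf]])
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        if np.isinf(lo) and np.isinf(hi):  # no crossings at all
            mid = 0.5 * (mu1 + mu2)
        else:
            mid_lo = hi - 1.0 if np.isinf(lo) else lo
            mid_hi = lo + 1.0 if np.isinf(hi) else hi
            mid = 0.5 * (mid_lo + mid_hi)
        # log densities: tail pdfs underflow to 0 and would tie incorrectly
        f1 = norm.logpdf(mid, mu1, sigma1)
        f2 = norm.logpdf(mid, mu2, sigma2)
        mu, sd = (mu1, sigma1) if f1 <= f2 else (mu2, sigma2)
        total += norm.cdf(hi, mu, sd) - norm.cdf(lo, mu, sd)
    return float(np.clip(total, 0.0, 1.0))


# ---------------------------------------------------------------------------
# metric-vs-overlap benchmark
# ---------------------------------------------------------------------------

BENCHMARK_METRICS = (
    "silhouette",
    "bimodality_index",
    "dip",
    "vrs",
    "wvrs",
    "davies_bouldin_inv",
    "simpson",
    "shannon_inv",
    "homogeneity_arithmetic",
    "homogeneity_geometric",
)


def _benchmark_fca(scores: np.ndarray, membership: np.ndarray, seed: int) -> np.ndarray:
    """One FCA row per simulated factor's binary ground-truth covariate.

    For a two-level covariate the one-vs-rest labels of the two levels are
    complements and yield identical ensemble importances, so a single row per
    covariate suffices.  Classifier importances are standardized over the
    whole table (not per row) so that weakly-associated covariates produce
    genuinely flat rows; per-row scaling would saturate every row's peak and
    erase the magnitude signal the specificity metrics rely on.
    """
    from .fca import DEFAULT_CLASSIFIERS, compute_importances, ensemble_score, scale_importances

    raws = []
    for j in range(membership.shape[1]):
        labels = membership[:, j] == 1
        raws.append(compute_importances(scores, labels, DEFAULT_CLASSIFIERS, seed=seed).to_numpy())
    k = scores.shape[1]
    stacked = np.concatenate(raws, axis=1)  # classifier x (covariate*factor)
    scaled = scale_importances(stacked, "standardize")
    return np.asarray([
        ensemble_score(scaled[:, i * k:(i + 1) * k], "arithmetic")
        for i in range(len(raws))
    ])


def metric_overlap_benchmark(
    rounds: int = 100,
    n: int = 10000,
    n_factors: int = 10,
    seed: int = 0,
    metrics: tuple[str, ...] = BENCHMARK_METRICS,
    correlation: str = "pearson",
    n_fca: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Correlate each interpretability metric with the true mixture overlap.

    Per round, ``n_factors`` mixture factors are simulated, every metric is
    evaluated per factor, and its correlation with the factors' true overlaps
    recorded.  Homogeneity metrics pool the scaled variances over the levels
    of *all* ground-truth covariates (the full per-factor column of the
    scaled-variance table).  ``n_fca`` optionally fits the FCA ensemble on a
    seeded cell subsample to bound classifier cost; all other metrics always
    use every cell.  Returns per-round correlations and a mean/sd summary.
    """
    from . import fis

    corr_fn = pearsonr if correlation == "pearson" else spearmanr
    root = np.random.default_rng(seed)
    per_round = {m: [] for m in metrics}
    for _ in range(rounds):
        rseed = int(root.integers(2**31 - 1))
        scores, membership, overlaps = simulate_factors(n=n, seed=rseed, n_factors=n_factors)
        values: dict[str, np.ndarray] = {m: np.full(n_factors, np.nan) for m in metrics}
        need_fca = "simpson" in metrics or "shannon_inv" in metrics
        if need_fca:
            if n_fca is not None and n_fca < n:
                sub = np.random.default_rng(rseed).choice(n, size=n_fca, replace=False)
                fca_rows = _benchmark_fca(scores[sub], membership[sub], seed=rseed)
            else:
                fca_rows = _benchmark_fca(scores, membership, seed=rseed)
        for j in range(n_factors):
            x = scores[:, j]
            labels = fis.cluster_k2(x, seed=rseed)
            if "silhouette" in values:
                values["silhouette"][j] = fis.silhouette(x, labels)
            if "vrs" in values:
                values["vrs"][j] = fis.vrs(x, labels)
            if "wvrs" in values:
                values["wvrs"][j] = fis.wvrs(x, labels)
            if "davies_bouldin_inv" in values:
                values["davies_bouldin_inv"][j] = fis.davies_bouldin_inv(x, labels)
            if "bimodality_index" in values:
                values["bimodality_index"][j] = fis.bimodality_index(x, seed=rseed)
            if "dip" in values:
                values["dip"][j] = fis.dip(x)
            if need_fca:
                p = fis.fca_column_to_probabilities(fca_rows[:, j])
                if "simpson" in values:
                    values["simpson"][j] = fis.simpson(p)
                if "shannon_inv" in values:
                    values["shannon_inv"][j] = (
                        np.log(p.size) - fis.shannon(p)
                    ) / np.log(p.size)
            if "homogeneity_arithmetic" in values or "homogeneity_geometric" in values:
                svs = []
                for i in range(n_factors):
                    per_level, _ = fis.homogeneity(x, membership[:, i], "arithmetic")
                    svs.extend(per_level.values())
                svs = np.asarray(svs)
                if "homogeneity_arithmetic" in values:
                    values["homogeneity_arithmetic"][j] = svs.mean()
                if "homogeneity_geometric" in values:
                    values["homogeneity_geometric"][j] = float(
                        np.exp(np.log(np.maximum(svs, np.finfo(float).tiny)).mean())
                    )
        for m in metrics:
            v = values[m]
            ok = np.isfinite(v)
            if ok.sum() < 2 or np.std(v[ok]) == 0 or np.std(overlaps[ok]) == 0:
                per_round[m].append(np.nan)  # zero-variance round, skipped
            else:
                per_round[m].append(float(corr_fn(v[ok], overlaps[ok])[0]))
    table = pd.DataFrame(per_round)
    summary = pd.DataFrame(
        {
            "mean": table.mean(),
            "sd": table.std(),
            "n_skipped": table.isna().sum(),
        }
    )
    return {"per_round": table, "summary": summary}


# ---------------------------------------------------------------------------
# planted-covariate count matrices
# ---------------------------------------------------------------------------

@dataclass
class PlantedCountSpec:
    """Poisson count matrix where each covariate level drives a gene block."""

    n_cells: int = 3000
    n_genes: int = 1000
    levels: tuple[str, ...] = ("L1", "L2", "L3", "L4", "L5")
    covariate_name: str = "group"
    block_size: int = 80
    effect: float = 2.5  # log-fold effect of a level on its gene block
    effect_sd: float = 1.0  # per-cell spread of the planted program intensity
    baseline_log_mean: tuple[float, float] = (-1.2, 0.7)
    libsize_cv: float = 0.5
    seed: int = 0
    extra_levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.block_size * len(self.levels) > self.n_genes:
            raise ValueError("gene blocks exceed the number of genes")


def simulate_counts(
    spec: PlantedCountSpec,
) -> tuple[CountMatrix, CovariateTable, dict[str, list[int]]]:
    """Generate counts with log-mean = baseline + library offset + planted effects.

    Returns the counts, a covariate table holding the planted annotation
    covariate, and the ground-truth map from covariate level to the gene
    indices (0-based) of the block it drives.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_cells, spec.n_genes
    levels = list(spec.levels)
    assignment = rng.integers(len(levels), size=n)
    base = rng.uniform(*spec.baseline_log_mean, size=g)
    sigma = np.sqrt(np.log(1.0 + spec.libsize_cv**2))
    lib_offset = rng.normal(0.0, sigma, size=n)  # log-normal library factor

    log_mu = base[None, :] + lib_offset[:, None]
    truth: dict[str, list[int]] = {}
    for li, level in enumerate(levels):
        block = list(range(li * spec.block_size, (li + 1) * spec.block_size))
        truth[level] = block
        mask = assignment == li
        # cells express their level's program with variable intensity, so each
        # block contributes its own cell-space direction
        intensity = np.maximum(
            rng.normal(spec.effect, spec.effect_sd, size=int(mask.sum())), 0.0
        )
        log_mu[np.ix_(mask, block)] += intensity[:, None]
    log_mu = np.minimum(log_mu, 20.0)  # overflow guard
    values = rng.poisson(np.exp(log_mu))

    cell_ids = [f"cell{i + 1}" for i in range(n)]
    gene_ids = [f"gene{j + 1}" for j in range(g)]
    counts = CountMatrix(values, cell_ids, gene_ids)
    data = pd.DataFrame(
        {spec.covariate_name: [levels[a] for a in assignment]},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    roles = {spec.covariate_name: "annotation"}
    for name, level_values in spec.extra_levels.items():
        data[name] = list(level_values)
        roles[name] = "annotation"
    return counts, CovariateTable(data, roles), truth


def sparsify(counts: CountMatrix, fraction: float, seed: int = 0) -> CountMatrix:
    """Set exactly ``floor(fraction * n_entries)`` random entries to zero.

    Entries are drawn uniformly over *all* matrix positions (zeros included).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    values = counts.values.copy()
    total = values.size
    n_zero = int(np.floor(fraction * total))
    if n_zero:
        flat = rng.choice(total, size=n_zero, replace=False)
        values.ravel()[flat] = 0
    return CountMatrix(values, list(counts.cell_ids), list(counts.gene_ids))
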