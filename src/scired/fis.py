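"""Factor interpretability scores (FIS): separability, effect size,
specificity and homogeneity metrics per factor."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score
from sklearn.mixture import GaussianMixture

from ._dip import dip_statistic
from .factorize import FactorModel
from .fca import FCATable
from .io_model import CovariateTable

__all__ = [
    "FISTable",
    "MixtureFit",
    "SEPARABILITY_CAP",
    "cluster_k2",
    "vrs",
    "wvrs",
    "silhouette",
    "davies_bouldin_inv",
    "bimodality_index",
    "fit_gmm2",
    "dip",
    "effect_size",
    "simpson",
    "shannon",
    "fca_column_to_probabilities",
    "homogeneity",
    "build_fis",
]

#: cap used when a separability denominator collapses to zero
SEPARABILITY_CAP = 1e6


@dataclass
class MixtureFit:
    """Equal-variance two-component Gaussian mixture summary."""

    mu1: float
    mu2: float
    sigma: float
    pi: float

    @property
    def delta(self) -> float:
        return abs(self.mu1 - self.mu2) / self.sigma


@dataclass
class FISTable:
    values: pd.DataFrame  # metrics x factors; NaN where undefined

    def scaled(self) -> pd.DataFrame:
        """Row-standardized display copy (NaN entries excluded per row)."""
        out = self.values.copy()
        for name, row in out.iterrows():
            sd = row.std(ddof=0)
            out.loc[name] = (row - row.mean()) / sd if sd > 0 else 0.0
        return out


# ---------------------------------------------------------------------------
# cluster-based separability
# ---------------------------------------------------------------------------

def cluster_k2(factor_scores: np.ndarray, seed: int = 0) -> np.ndarray:
    """Two-cluster 1-D k-means labels with deterministic seeded init."""
    x = np.asarray(factor_scores, dtype=float).reshape(-1, 1)
    if np.unique(x).size < 2:
        raise ValueError("constant factor scores cannot be clustered")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    return km.fit_predict(x)


def _cluster_stats(scores: np.ndarray, labels: np.ndarray):
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = [x[labels == u] for u in np.unique(labels)]
    if len(groups) != 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need exactly two non-empty clusters")
    n = x.size
    tss = ((x - x.mean()) ** 2).sum()
    wss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    bss = tss - wss
    return groups, n, tss, wss, bss


def vrs(scores: np.ndarray, labels: np.ndarray) -> float:
    """Variance ratio (Calinski-Harabasz): (BSS/(k-1)) / (WSS/(n-k)), k = 2."""
    _, n, _, wss, bss = _cluster_stats(scores, labels)
    if wss == 0:
        warnings.warn("zero within-cluster scatter; VRS capped")
        return SEPARABILITY_CAP
    return float(bss / (wss / (n - 2)))


def wvrs(scores: np.ndarray, labels: np.ndarray) -> float:
    """Size-independent variance ratio.

    Like ``vrs`` but the denominator is the unweighted mean of per-cluster
    sample variances, so unbalanced cluster sizes do not dominate; on
    balanced clusters it coincides with ``vrs``.
    """
    groups, n, _, wss, bss = _cluster_stats(scores, labels)
    variances = [g.var(ddof=1) if len(g) > 1 else 0.0 for g in groups]
    denom = float(np.mean(variances))
    if denom == 0:
        warnings.warn("zero within-cluster variance; WVRS capped")
        return SEPARABILITY_CAP
    return float(bss / denom)


def silhouette(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette, (NCD - ICD)/max(ICD, NCD) per point, 1-D Euclidean."""
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    if x.size < 3:
        raise ValueError("need at least 3 points for a silhouette")
    return float(silhouette_score(x, np.asarray(labels)))


def davies_bouldin_inv(scores: np.ndarray, labels: np.ndarray) -> float:
    """Inverse Davies-Bouldin index so that larger = more separable.

    DB of zero (zero within-cluster scatter, distinct centroids) maps to the
    cap; coincident centroids give 0.
    """
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    groups, *_ = _cluster_stats(scores, labels)
    if abs(groups[0].mean() - groups[1].mean()) < 1e-15:
        return 0.0
    db = float(davies_bouldin_score(x, np.asarray(labels)))
    if db == 0:
        return SEPARABILITY_CAP
    return min(1.0 / db, SEPARABILITY_CAP)


# ---------------------------------------------------------------------------
# model-based separability
# ---------------------------------------------------------------------------

def fit_gmm2(factor_scores: np.ndarray, seed: int = 0) -> MixtureFit:
    """Equal-variance two-component GMM fitted by EM with seeded restarts."""
    x = np.asarray(factor_scores, dtype=float).reshape(-1, 1)
    if x.size < 10:
        raise ValueError("need at least 10 observations for the mixture fit")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="tied",  # shared variance in 1-D
        n_init=10,
        tol=1e-6,
        random_state=seed,
    )
    gm.fit(x)
    var = float(gm.covariances_.ravel()[0])
    floor = 1e-6 * float(np.var(x))
    var = max(var, floor, np.finfo(float).tiny)
    return MixtureFit(
        mu1=float(gm.means_[0, 0]),
        mu2=float(gm.means_[1, 0]),
        sigma=float(np.sqrt(var)),
        pi=float(gm.weights_[0]),
    )


def bimodality_index(factor_scores: np.ndarray, seed: int = 0) -> float:
    """BI = sqrt(pi * (1 - pi)) * |mu1 - mu2| / sigma from the 2-GMM fit."""
    fit = fit_gmm2(factor_scores, seed=seed)
    return float(np.sqrt(fit.pi * (1.0 - fit.pi)) * fit.delta)


def dip(factor_scores: np.ndarray) -> float:
    """Hartigan's dip statistic of the factor score distribution."""
    x = np.asarray(factor_scores, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations for the dip")
    return dip_statistic(x)


# ---------------------------------------------------------------------------
# effect size / specificity / homogeneity
# ---------------------------------------------------------------------------

def effect_size(factor_scores: np.ndarray) -> float:
    """Sample variance of the factor scores."""
    x = np.asarray(factor_scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return float(np.var(x, ddof=1))


def fca_column_to_probabilities(column: np.ndarray) -> np.ndarray:
    """Shift an FCA column to be nonnegative and normalize it to sum 1."""
    p = np.asarray(column, dtype=float)
    if p.min() < 0:
        p = p - p.min()
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero FCA column; specificity undefined")
    return p / total


def simpson(p: np.ndarray) -> float:
    """Simpson diversity D = sum(p_i^2); 1 = maximal specificity."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("p must be a probability vector")
    return float((p**2).sum())


def shannon(p: np.ndarray) -> float:
    """Shannon entropy H = -sum(p_i log p_i) (natural log, 0 log 0 = 0)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("p must be a probability vector")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def homogeneity(
    factor_scores: np.ndarray,
    covariate: np.ndarray,
    mean_type: str = "arithmetic",
    min_cells: int = 2,
) -> tuple[dict, float]:
    """Scaled variance SV = Var(x_level)/Var(x) per level, plus a pooled mean.

    Levels with fewer than ``min_cells`` cells are excluded with a warning.
    Pooling is arithmetic by default (geometric available).
    """
    x = np.asarray(factor_scores, dtype=float)
    cov = np.asarray(covariate).astype(str)
    total_var = np.var(x, ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance; homogeneity undefined")
    per_level: dict = {}
    for level in sorted(np.unique(cov)):
        sel = x[cov == level]
        if sel.size < min_cells:
            warnings.warn(f"level {level!r} has fewer than {min_cells} cells; skipped")
            continue
        per_level[level] = float(np.var(sel, ddof=1) / total_var)
    if not per_level:
        raise ValueError("no covariate level large enough for homogeneity")
    values = np.asarray(list(per_level.values()))
    if mean_type == "arithmetic":
        pooled = float(values.mean())
    elif mean_type == "geometric":
        pooled = float(np.exp(np.log(np.maximum(values, np.finfo(float).tiny)).mean()))
    else:
        raise ValueError(f"unknown mean type {mean_type!r}")
    return per_level, pooled


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_fis(
    model: FactorModel,
    cov: CovariateTable | None = None,
    fca: FCATable | None = None,
    seed: int = 0,
    metrics: list[str] | None = None,
    homogeneity_mean: str = "arithmetic",
) -> FISTable:
    """Assemble the metrics x factors FIS table.

    Separability metrics operate on k-means (k=2) clusters of each factor's
    scores; specificity metrics on the factor's FCA column; homogeneity on
    each annotation covariate.  Undefined values are left missing (NaN).
    """
    S = model.scores
    k = S.shape[1]
    names = model.factor_names
    rows: dict[str, list[float]] = {}

    def metric_wanted(m: str) -> bool:
        return metrics is None or m in metrics

    sep_metrics = ["silhouette", "vrs", "wvrs", "davies_bouldin_inv"]
    for m in sep_metrics + ["bimodality_index", "dip", "variance"]:
        if metric_wanted(m):
            rows[m] = [np.nan] * k
    if fca is not None:
        for m in ("simpson", "shannon_inv"):
            if metric_wanted(m):
                rows[m] = [np.nan] * k
    hom_rows: dict[str, list[float]] = {}
    ann_cols = cov.columns_with_role("annotation") if cov is not None else []
    for col in ann_cols:
        name = f"homogeneity_{col}"
        if metric_wanted(name):
            hom_rows[name] = [np.nan] * k

    for j in range(k):
        x = S[:, j]
        constant = np.unique(x).size < 2
        if not constant:
            labels = cluster_k2(x, seed=seed)
            for m in sep_metrics:
                if m not in rows:
                    continue
                try:
                    fn = {"silhouette": silhouette, "vrs": vrs,
                          "wvrs": wvrs, "davies_bouldin_inv": davies_bouldin_inv}[m]
                    rows[m][j] = fn(x, labels)
                except ValueError:
                    pass
            if "bimodality_index" in rows and x.size >= 10:
                rows["bimodality_index"][j] = bimodality_index(x, seed=seed)
            if "dip" in rows and x.size >= 4:
                rows["dip"][j] = dip(x)
        if "variance" in rows:
            rows["variance"][j] = 0.0 if constant else effect_size(x)
        if fca is not None:
            col = fca.scores.iloc[:, j].to_numpy()
            try:
                p = fca_column_to_probabilities(col)
                n_levels = p.size
                if "simpson" in rows:
                    rows["simpson"][j] = simpson(p)
                if "shannon_inv" in rows and n_levels > 1:
                    # inverted & normalized so that high = specific
                    rows["shannon_inv"][j] = (np.log(n_levels) - shannon(p)) / np.log(n_levels)
            except ValueError:
                pass
        for col_name in ann_cols:
            key = f"homogeneity_{col_name}"
            if key not in hom_rows or constant:
                continue
            try:
                _, pooled = homogeneity(
                    x, cov.data[col_name].to_numpy(), mean_type=homogeneity_mean
                )
                hom_rows[key][j] = pooled
            except ValueError:
                pass

    rows.update(hom_rows)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    _check_bounds(table)
    return FISTable(values=table)


def _check_bounds(table: pd.DataFrame) -> None:
    def _row(name):
        return table.loc[name].dropna() if name in table.index else pd.Series(dtype=float)

    s = _row("silhouette")
    if len(s) and ((s < -1 - 1e-9) | (s > 1 + 1e-9)).any():
        raise AssertionError("silhouette out of [-1, 1]")
    sim = _row("simpson")
    if len(sim) and ((sim <= 0) | (sim > 1 + 1e-9)).any():
        raise AssertionError("simpson out of (0, 1]")
    for name in ("dip", "variance", "vrs", "wvrs", "davies_bouldin_inv"):
        r = _row(name)
        if len(r) and (r < 0).any():
            raise AssertionError(f"{name} negative")
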