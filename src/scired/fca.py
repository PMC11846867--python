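"""Factor-covariate association (FCA): ensemble importances, binarization,
permutation significance and sparsity diagnostics.

For every level of every annotation covariate a one-vs-rest label vector is
formed and each classifier in the ensemble produces one importance per
factor.  Importances are scaled per classifier (standardization by default),
averaged (arithmetic by default) into one FCA row, and the pooled FCA table
is binarized with Otsu thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .factorize import FactorModel
from .io_model import CovariateTable

__all__ = [
    "DEFAULT_CLASSIFIERS",
    "ImportanceProfile",
    "FCATable",
    "AssociationDiagnostics",
    "importance_logistic",
    "importance_auc",
    "importance_trees",
    "importance_knn_permutation",
    "scale_importances",
    "ensemble_score",
    "build_fca",
    "otsu_threshold",
    "permutation_test",
    "gini",
    "global_gini",
    "benchmark_matching",
]

#: default ensemble; KNN and random forest are deliberately excluded.
DEFAULT_CLASSIFIERS = (
    "logistic",
    "auc_linear",
    "decision_tree",
    "gradient_boosted_trees",
)

N_TREES = 100


@dataclass
class ImportanceProfile:
    """Raw classifier x factor importances for one covariate level."""

    level: str
    raw: pd.DataFrame  # index: classifier names, columns: factor names


@dataclass
class FCATable:
    scores: pd.DataFrame  # levels x factors
    scaling: str = "standardize"
    mean_type: str = "arithmetic"
    threshold: float | None = None
    binarized: pd.DataFrame | None = None
    profiles: list[ImportanceProfile] = field(default_factory=list)

    @property
    def levels(self) -> list[str]:
        return list(self.scores.index)

    @property
    def factors(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class AssociationDiagnostics:
    empirical_p: pd.DataFrame  # levels x factors
    n_significant_per_level: pd.Series
    gini_per_level: pd.Series
    global_gini: float
    n_perm: int


# ---------------------------------------------------------------------------
# per-classifier importances
# ---------------------------------------------------------------------------

def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    return labels


def importance_logistic(scores: np.ndarray, labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """|coefficient| from an L2-penalized logistic regression on all factors."""
    labels = _check_labels(labels)
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit(np.asarray(scores, dtype=float), labels.astype(int))
    return np.abs(clf.coef_[0])


def importance_auc(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-factor AUC via the Mann-Whitney U statistic, U / (n0 * n1).

    Midranks handle ties; the result is folded as max(AUC, 1 - AUC) so a
    factor "low" in the target group scores as high as one that is "high"
    (factor sign is arbitrary after rotation).  A constant factor gives 0.5.
    """
    labels = _check_labels(labels)
    X = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = X.shape[0] - n1
    ranks = np.apply_along_axis(rankdata, 0, X)
    u = ranks[labels].sum(axis=0) - n1 * (n1 + 1) / 2.0
    auc = u / (n0 * n1)
    return np.maximum(auc, 1.0 - auc)


def importance_trees(
    scores: np.ndarray, labels: np.ndarray, model: str = "decision_tree", seed: int = 0
) -> np.ndarray:
    """Impurity-decrease importances, nonnegative and summing to 1."""
    labels = _check_labels(labels)
    X = np.asarray(scores, dtype=float)
    if model == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif model == "random_forest":
        clf = RandomForestClassifier(n_estimators=N_TREES, random_state=seed)
    elif model == "gradient_boosted_trees":
        clf = GradientBoostingClassifier(n_estimators=N_TREES, random_state=seed)
    else:
        raise ValueError(f"unknown tree model {model!r}")
    clf.fit(X, labels.astype(int))
    imp = np.asarray(clf.feature_importances_, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else np.full(X.shape[1], 1.0 / X.shape[1])


def importance_knn_permutation(
    scores: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 5,
    n_repeats: int = 5,
) -> np.ndarray:
    """Mean accuracy drop over permutations of each factor (KNN classifier).

    Provided for completeness; excluded from the default ensemble.
    """
    labels = _check_labels(labels)
    X = np.asarray(scores, dtype=float)
    if X.shape[0] < n_neighbors:
        raise ValueError("fewer samples than KNN neighbors")
    clf = KNeighborsClassifier(n_neighbors=n_neighbors)
    clf.fit(X, labels.astype(int))
    res = permutation_importance(
        clf, X, labels.astype(int), n_repeats=n_repeats, random_state=seed
    )
    return np.asarray(res.importances_mean, dtype=float)


def compute_importances(
    scores: np.ndarray,
    labels: np.ndarray,
    classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw classifier x factor importance matrix for one level's labels."""
    rows = {}
    for name in classifiers:
        if name == "logistic":
            rows[name] = importance_logistic(scores, labels, seed=seed)
        elif name == "auc_linear":
            rows[name] = importance_auc(scores, labels)
        elif name in ("decision_tree", "random_forest", "gradient_boosted_trees"):
            rows[name] = importance_trees(scores, labels, model=name, seed=seed)
        elif name == "knn_permutation":
            rows[name] = importance_knn_permutation(scores, labels, seed=seed)
        else:
            raise ValueError(f"unknown classifier {name!r}")
    k = np.asarray(scores).shape[1]
    cols = [f"F{i + 1}" for i in range(k)]
    return pd.DataFrame(rows, index=cols).T


# ---------------------------------------------------------------------------
# scaling / ensembling
# ---------------------------------------------------------------------------

def scale_importances(raw: pd.DataFrame | np.ndarray, method: str = "standardize"):
    """Scale each classifier row independently.

    ``standardize``: (x - mean)/std; ``minmax``: (x - min)/(max - min);
    ``rank``: ascending ranks divided by the number of factors.
    """
    X = np.asarray(raw, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] < 2:
        raise ValueError("need at least two factors to scale importances")
    out = np.empty_like(X)
    for i, row in enumerate(X):
        if method == "standardize":
            sd = row.std()
            if sd == 0:
                warnings.warn("zero std in importance row; scaled to zeros")
                out[i] = 0.0
            else:
                out[i] = (row - row.mean()) / sd
        elif method == "minmax":
            rng = row.max() - row.min()
            if rng == 0:
                warnings.warn("zero range in importance row; scaled to 0.5")
                out[i] = 0.5
            else:
                out[i] = (row - row.min()) / rng
        elif method == "rank":
            out[i] = rankdata(row) / row.size
        else:
            raise ValueError(f"unknown scaling {method!r}")
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out if np.asarray(raw).ndim > 1 else out[0]


def ensemble_score(scaled: pd.DataFrame | np.ndarray, mean_type: str = "arithmetic") -> np.ndarray:
    """Combine scaled per-classifier importances into one FCA row."""
    X = np.asarray(scaled, dtype=float)
    if mean_type == "arithmetic":
        return X.mean(axis=0)
    if mean_type == "geometric":
        if np.any(X < 0):
            raise ValueError(
                "geometric mean needs nonnegative importances; "
                "use minmax or rank scaling"
            )
        return np.exp(np.log(np.where(X > 0, X, np.finfo(float).tiny)).mean(axis=0))
    raise ValueError(f"unknown mean type {mean_type!r}")


# ---------------------------------------------------------------------------
# FCA table
# ---------------------------------------------------------------------------

def _iter_levels(cov: CovariateTable, columns: list[str] | None = None):
    cols = columns if columns is not None else cov.columns_with_role("annotation")
    for col in cols:
        values = cov.data[col].astype(str).to_numpy()
        for level in sorted(pd.unique(values)):
            yield f"{col}:{level}", values == level


def build_fca(
    model: FactorModel | np.ndarray,
    cov: CovariateTable,
    classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS,
    scaling: str = "standardize",
    mean_type: str = "arithmetic",
    seed: int = 0,
    columns: list[str] | None = None,
    keep_profiles: bool = False,
    binarize: bool = True,
    scale_over: str = "row",
) -> FCATable:
    """Build the levels x factors FCA table (and binarize it by default).

    ``scale_over="row"`` (default) scales each classifier's importances within
    one level's row; ``"table"`` scales each classifier across all levels
    jointly, preserving magnitude differences between strong and weak levels.
    """
    scores = model.scores if isinstance(model, FactorModel) else np.asarray(model)
    raw_by_level = {}
    profiles = []
    for name, labels in _iter_levels(cov, columns):
        if labels.sum() < 10:
            warnings.warn(f"covariate level {name} has fewer than 10 cells")
        raw = compute_importances(scores, labels, classifiers, seed=seed)
        raw_by_level[name] = raw
        if keep_profiles:
            profiles.append(ImportanceProfile(level=name, raw=raw))
    if not raw_by_level:
        raise ValueError("no annotation covariate levels found")
    if scale_over == "row":
        rows = {
            name: ensemble_score(scale_importances(raw, scaling), mean_type)
            for name, raw in raw_by_level.items()
        }
    elif scale_over == "table":
        # scale each classifier over the stacked (levels x factors) block
        names = list(raw_by_level)
        stacked = np.concatenate([raw_by_level[n].to_numpy() for n in names], axis=1)
        scaled = scale_importances(stacked, scaling)
        k = scores.shape[1]
        rows = {
            n: ensemble_score(scaled[:, i * k:(i + 1) * k], mean_type)
            for i, n in enumerate(names)
        }
    else:
        raise ValueError(f"unknown scale_over {scale_over!r}")
    k = scores.shape[1]
    table = FCATable(
        scores=pd.DataFrame.from_dict(
            rows, orient="index", columns=[f"F{i + 1}" for i in range(k)]
        ),
        scaling=scaling,
        mean_type=mean_type,
        profiles=profiles,
    )
    if binarize:
        otsu_threshold(table)
    return table


def _otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance-maximizing threshold of a 1-D sample.

    Histogram-based Otsu over ``nbins`` bins.  The objective is flat across
    empty histogram regions; ties are broken at the middle of the maximal
    plateau so the threshold lands centrally in the separating gap instead of
    hugging one class.
    """
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)[:-1].astype(float)
    w1 = counts.sum() - w0
    csum = np.cumsum(counts * centers)[:-1]
    total = (counts * centers).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = csum / w0
        m1 = (total - csum) / w1
        sigma_b = w0 * w1 * (m0 - m1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf)
    best = sigma_b.max()
    tied = np.flatnonzero(sigma_b >= best * (1 - 1e-12))
    # middle of the contiguous plateau containing the first argmax
    start = tied[0]
    end = start
    while end + 1 in tied:
        end += 1
    return float((centers[start] + centers[end]) / 2.0)


def otsu_threshold(fca: FCATable, nbins: int = 256) -> tuple[float, pd.DataFrame]:
    """Binarize the FCA table at the Otsu threshold of its pooled scores.

    The threshold maximizes between-class variance over a 256-bin histogram
    of all FCA entries; matches are strictly greater than the threshold.
    """
    values = fca.scores.to_numpy().ravel()
    if np.unique(values).size < 2:
        warnings.warn("constant FCA scores; no matches")
        thr = float(values.max()) if values.size else 0.0
    else:
        thr = _otsu(values, nbins=nbins)
    fca.threshold = thr
    fca.binarized = fca.scores > thr
    return thr, fca.binarized


def gini(fca_row: np.ndarray) -> float:
    """Pairwise-difference Gini index of one FCA row.

    Scores are shifted to be nonnegative (min-subtracted) when negative
    values are present, since the formula presumes nonnegative values.
    An all-equal row gives 0.
    """
    x = np.asarray(fca_row, dtype=float)
    if x.min() < 0:
        x = x - x.min()
    xbar = x.mean()
    if xbar == 0:
        return 0.0
    n = x.size
    diff = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff / (2.0 * n * n * xbar))


def global_gini(fca: FCATable | pd.DataFrame) -> float:
    """Mean per-level Gini across the FCA table."""
    scores = fca.scores if isinstance(fca, FCATable) else fca
    return float(np.mean([gini(r) for r in scores.to_numpy()]))


def permutation_test(
    model: FactorModel | np.ndarray,
    cov: CovariateTable,
    n_perm: int = 500,
    seed: int = 0,
    classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS,
    scaling: str = "standardize",
    mean_type: str = "arithmetic",
    columns: list[str] | None = None,
    observed: FCATable | None = None,
) -> AssociationDiagnostics:
    """Empirical significance of FCA scores under label shuffling.

    Covariate labels are shuffled ``n_perm`` times; the empirical p-value of
    each (level, factor) is the fraction of permuted scores at least as
    extreme as the observed score (0 is reported as 0, no pseudo-count).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = model.scores if isinstance(model, FactorModel) else np.asarray(model)
    if observed is None:
        observed = build_fca(
            model, cov, classifiers, scaling, mean_type, seed=seed,
            columns=columns, binarize=False,
        )
    obs = observed.scores
    rng = np.random.default_rng(seed)
    n = scores.shape[0]
    exceed = pd.DataFrame(0.0, index=obs.index, columns=obs.columns)
    for _ in range(n_perm):
        # one shared cell shuffle per round, applied to every level's labels
        perm = rng.permutation(n)
        for name, labels in _iter_levels(cov, columns):
            raw = compute_importances(scores, labels[perm], classifiers, seed=seed)
            row = ensemble_score(scale_importances(raw, scaling), mean_type)
            exceed.loc[name] += row >= obs.loc[name].to_numpy()
    pvals = exceed / n_perm
    gini_per_level = pd.Series({name: gini(obs.loc[name].to_numpy()) for name in obs.index})
    return AssociationDiagnostics(
        empirical_p=pvals,
        n_significant_per_level=(pvals < 0.05).sum(axis=1),
        gini_per_level=gini_per_level,
        global_gini=float(gini_per_level.mean()),
        n_perm=n_perm,
    )


def benchmark_matching(fca: FCATable) -> dict[str, int]:
    """Sparsity diagnostics of the binarized FCA.

    ``entangled_covariates``: levels matched to more than one factor;
    ``split_factors``: factors matched to more than one level;
    ``unmatched_levels``: levels with no match.
    """
    if fca.binarized is None:
        raise ValueError("binarize the FCA table first (otsu_threshold)")
    B = fca.binarized.to_numpy()
    return {
        "entangled_covariates": int((B.sum(axis=1) > 1).sum()),
        "split_factors": int((B.sum(axis=0) > 1).sum()),
        "unmatched_levels": int((B.sum(axis=1) == 0).sum()),
    }
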