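"""SVD factorization of the residual matrix and varimax / promax rotation.

The varimax optimizer is the SVD-based simultaneous update used by base R's
``varimax`` (Kaiser row-normalization on by default); promax builds the
powered pattern matrix from the row-column normalized varimax loadings and
solves the least-squares fit, normalizing rotation columns to unit sum of
squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .residualize import ResidualMatrix

__all__ = [
    "FactorModel",
    "RotationDiagnostics",
    "svd_factorize",
    "varimax",
    "promax",
    "apply_rotation",
    "factorize",
    "kaiser_criterion",
]

DEFAULT_K = 30


@dataclass
class RotationDiagnostics:
    kaiser_criterion: float
    communalities: np.ndarray
    n_iter: int
    criterion_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class FactorModel:
    """Rotated (or unrotated) score/loading pair.

    ``scores @ loadings.T`` reconstructs the centered residual matrix for any
    rotation; ``rotation`` maps the unrotated loadings onto the current ones.
    """

    scores: np.ndarray  # n x k
    loadings: np.ndarray  # g x k
    rotation: np.ndarray  # k x k
    variance_explained: np.ndarray  # length k
    rotation_type: str
    k: int
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    diagnostics: RotationDiagnostics | None = None

    @property
    def factor_names(self) -> list[str]:
        return [f"F{i + 1}" for i in range(self.k)]

    def reconstruction(self) -> np.ndarray:
        return self.scores @ self.loadings.T


def kaiser_criterion(loadings: np.ndarray) -> float:
    """Raw varimax criterion: sum(L^4) - (1/g) * sum_j (sum_i L_ij^2)^2."""
    L = np.asarray(loadings, dtype=float)
    g = L.shape[0]
    return float((L**4).sum() - ((L**2).sum(axis=0) ** 2).sum() / g)


def svd_factorize(residuals: ResidualMatrix | np.ndarray, k: int) -> FactorModel:
    """Top-k SVD of the column-centered residual matrix.

    Scores are left singular vectors scaled by singular values; loadings are
    the right singular vectors; ``variance_explained`` holds the per-factor
    score variances (squared singular values / (n - 1)).
    """
    X = residuals.values if isinstance(residuals, ResidualMatrix) else np.asarray(residuals)
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("residual matrix contains non-finite values")
    n, g = X.shape
    if k < 1:
        raise ValueError("k must be positive")
    if k > min(n, g):
        raise ValueError(f"k={k} exceeds min(n, g)={min(n, g)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    if min(n, g) > 400 and k <= min(n, g) // 10:
        # tall problems with small k: seeded randomized SVD (deterministic)
        from sklearn.utils.extmath import randomized_svd

        U, s, Vt = randomized_svd(
            Xc, n_components=k, n_oversamples=20, n_iter=7, random_state=0
        )
    else:
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * max(n, g) * np.finfo(float).eps).sum()) if s.size else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds matrix rank {rank}; truncating")
        k = max(rank, 1)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    model = FactorModel(
        scores=scores,
        loadings=loadings,
        rotation=np.eye(k),
        variance_explained=s[:k] ** 2 / max(n - 1, 1),
        rotation_type="none",
        k=k,
    )
    _fix_signs(model)
    return model


def _fix_signs(model: FactorModel) -> None:
    """Make each loading column's largest-magnitude entry positive (in place)."""
    idx = np.argmax(np.abs(model.loadings), axis=0)
    signs = np.sign(model.loadings[idx, np.arange(model.k)])
    signs[signs == 0] = 1.0
    model.loadings *= signs
    model.scores *= signs
    model.rotation *= signs


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, RotationDiagnostics]:
    """Varimax rotation maximizing the Kaiser criterion.

    Returns ``(rotated_loadings, rotation, diagnostics)`` with an orthogonal
    rotation matrix.  With ``normalize=True`` rows are scaled by their
    communalities before rotation and unscaled after.
    """
    L = np.asarray(loadings, dtype=float)
    g, k = L.shape
    communalities = (L**2).sum(axis=1)
    if k == 1:
        R = np.eye(1)
        diag = RotationDiagnostics(kaiser_criterion(L), communalities, 0)
        return L.copy(), R, diag
    sc = np.sqrt(communalities)
    if normalize:
        if np.any(sc == 0):
            raise ValueError("zero communality row; cannot Kaiser-normalize")
        x = L / sc[:, None]
    else:
        x = L.copy()
    R = np.eye(k)
    d = 0.0
    trace = [kaiser_criterion(x)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = x @ R
        B = x.T @ (z**3 - z @ np.diag((z**2).sum(axis=0)) / g)
        U, s, Vt = np.linalg.svd(B)
        R = U @ Vt
        trace.append(kaiser_criterion(x @ R))
        d_new = s.sum()
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    rotated = x @ R
    if normalize:
        rotated = rotated * sc[:, None]
    diag = RotationDiagnostics(
        kaiser_criterion=trace[-1],
        communalities=communalities,
        n_iter=n_iter,
        criterion_trace=np.asarray(trace),
    )
    return rotated, R, diag


def promax(
    loadings: np.ndarray, power: int = 3, normalize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation (varimax followed by a powered-pattern fit).

    The pattern matrix is ``|l^(power+1)| / l`` (0 where l is 0) of the
    row-column normalized varimax loadings; the returned rotation is the
    least-squares fit of the varimax loadings to that pattern, columns
    normalized to unit sum of squares, composed with the varimax rotation.
    """
    if power < 2:
        raise ValueError("promax power must be >= 2")
    L = np.asarray(loadings, dtype=float)
    if L.shape[1] == 1:
        return L.copy(), np.eye(1)
    L_rot, R_v, _ = varimax(L, normalize=normalize)
    # row-column normalization of the varimax loadings for the pattern target
    row = np.sqrt((L_rot**2).sum(axis=1))
    row[row == 0] = 1.0
    col = np.sqrt((L_rot**2).sum(axis=0))
    col[col == 0] = 1.0
    Lnorm = L_rot / row[:, None] / col[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(Lnorm != 0, np.abs(Lnorm ** (power + 1)) / Lnorm, 0.0)
    R_p = np.linalg.solve(L_rot.T @ L_rot, L_rot.T @ P)
    R_p = R_p / np.sqrt((R_p**2).sum(axis=0))[None, :]
    if abs(np.linalg.det(R_p)) < 1e-12:
        raise np.linalg.LinAlgError("singular promax rotation")
    return L_rot @ R_p, R_v @ R_p


def apply_rotation(model: FactorModel, rotation: np.ndarray, rotation_type: str | None = None,
                   diagnostics: RotationDiagnostics | None = None) -> FactorModel:
    """Rotate a factor model, preserving the reconstruction scores @ loadings.T.

    Loadings become ``L @ R`` and scores ``S @ inv(R).T`` (equal to ``S @ R``
    when R is orthogonal).  Factors are then sign-fixed (largest-magnitude
    loading positive) and reordered by descending score variance.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (model.k, model.k):
        raise ValueError(f"rotation must be {model.k}x{model.k}")
    if abs(np.linalg.det(R)) < 1e-12:
        raise np.linalg.LinAlgError("singular rotation matrix")
    loadings = model.loadings @ R
    scores = model.scores @ np.linalg.inv(R).T
    var = scores.var(axis=0, ddof=1)
    order = np.argsort(-var, kind="stable")
    new = FactorModel(
        scores=scores[:, order],
        loadings=loadings[:, order],
        rotation=(model.rotation @ R)[:, order],
        variance_explained=var[order],
        rotation_type=rotation_type or model.rotation_type,
        k=model.k,
        gene_ids=model.gene_ids,
        cell_ids=model.cell_ids,
        diagnostics=diagnostics,
    )
    _fix_signs(new)
    return new


def factorize(
    residuals: ResidualMatrix | np.ndarray,
    k: int = DEFAULT_K,
    rotation: str = "varimax",
    promax_power: int = 3,
) -> FactorModel:
    """SVD factorization followed by the requested rotation."""
    model = svd_factorize(residuals, k)
    if rotation == "none":
        return model
    if rotation == "varimax":
        _, R, diag = varimax(model.loadings)
        return apply_rotation(model, R, "varimax", diag)
    if rotation == "promax":
        _, R = promax(model.loadings, power=promax_power)
        return apply_rotation(model, R, "promax")
    raise ValueError(f"unknown rotation {rotation!r}")
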