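"""End-to-end orchestration: preprocess -> residualize -> factorize ->
FCA -> FIS -> exports, with a plain-text run config and per-stage logging."""

from __future__ import annotations

import dataclasses
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import factorize as _factorize
from . import fca as _fca
from . import fis as _fis
from . import io_model, residualize

__all__ = [
    "RunConfig",
    "run_pipeline",
    "export_ranked_genes",
    "unannotated_factor_report",
]

log = logging.getLogger("scired")


@dataclass
class RunConfig:
    counts: str = ""
    covariates: str = ""
    technical: list[str] = field(default_factory=lambda: ["library_size"])
    annotation: list[str] = field(default_factory=list)
    n_hvg: int = 2000
    residual_type: str = "pearson"
    k: int = 30
    rotation: str = "varimax"
    promax_power: int = 3
    scaling: str = "standardize"
    mean_type: str = "arithmetic"
    n_perm: int = 0
    seed: int = 0
    top_n_genes: int = 200
    out_dir: str = "scired_out"

    _LIST_FIELDS = ("technical", "annotation")
    _INT_FIELDS = ("n_hvg", "k", "promax_power", "n_perm", "seed", "top_n_genes")

    def save(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            if f.name.startswith("_"):
                continue
            v = getattr(self, f.name)
            if f.name in self._LIST_FIELDS:
                v = ",".join(v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in cls._LIST_FIELDS:
                kwargs[key] = [v for v in value.split(",") if v]
            elif key in cls._INT_FIELDS:
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def export_ranked_genes(
    model: _factorize.FactorModel, factor: int | str, top_n: int = 200
) -> pd.DataFrame:
    """Genes ranked by loading on one factor.

    ``rank_positive`` orders by descending loading (the factor's positive
    pole), ``rank_negative`` by ascending loading.  ``factor`` is a 0-based
    index or a name like ``"F3"``.
    """
    if isinstance(factor, str):
        j = model.factor_names.index(factor)
    else:
        j = int(factor)
    if not 0 <= j < model.k:
        raise IndexError(f"factor {factor!r} out of range")
    loadings = model.loadings[:, j]
    genes = model.gene_ids or [f"g{i + 1}" for i in range(loadings.size)]
    top_n = min(top_n, loadings.size)
    order_pos = np.argsort(-loadings, kind="stable")[:top_n]
    order_neg = np.argsort(loadings, kind="stable")[:top_n]
    return pd.DataFrame(
        {
            "rank": np.arange(1, top_n + 1),
            "gene_positive": [genes[i] for i in order_pos],
            "loading_positive": loadings[order_pos],
            "gene_negative": [genes[i] for i in order_neg],
            "loading_negative": loadings[order_neg],
        }
    )


def unannotated_factor_report(
    fca: _fca.FCATable,
    model: _factorize.FactorModel,
    extra_covariates: pd.DataFrame | None = None,
    threshold: float = 0.45,
) -> pd.DataFrame:
    """Factors with no binarized FCA match, correlated against numeric covariates.

    Correlations strictly above ``threshold`` in absolute value flag the
    factor as likely technical; untagged unmatched factors are candidate
    hidden signals.
    """
    if fca.binarized is None:
        raise ValueError("binarize the FCA table first")
    unmatched = [
        name
        for name, col in zip(fca.factors, fca.binarized.to_numpy().T)
        if not col.any()
    ]
    rows = []
    for name in unmatched:
        j = fca.factors.index(name)
        x = model.scores[:, j]
        row: dict = {"factor": name, "flagged_technical": False}
        if extra_covariates is not None:
            for cov_name in extra_covariates.columns:
                v = extra_covariates[cov_name].to_numpy(dtype=float)
                sd = v.std()
                r = 0.0 if sd == 0 or x.std() == 0 else float(np.corrcoef(x, v)[0, 1])
                row[f"r_{cov_name}"] = r
                if abs(r) > threshold:
                    row["flagged_technical"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all artifacts to ``config.out_dir``.

    Stages: preprocess, residualize, factorize (+rotation), FCA (+Otsu,
    optional permutation test), FIS, ranked-gene export.  Any stage failure
    raises with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.txt")
    artifacts: dict = {}
    stage = "read"
    t0 = time.time()
    try:
        counts = io_model.read_counts(config.counts)
        cov = (
            io_model.read_covariates(
                config.covariates,
                technical=[c for c in config.technical if c != "library_size"],
                annotation=config.annotation,
            )
            if config.covariates
            else None
        )

        stage = "preprocess"
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            counts, cov = io_model.preprocess(counts, config.n_hvg, cov)
        log.info(
            "preprocess: %d cells x %d genes (%.1fs, %d warnings)",
            counts.n_cells, counts.n_genes, time.time() - t0, len(wlist),
        )

        stage = "residualize"
        t = time.time()
        design, names = io_model.encode_design(cov, config.technical)
        fit = residualize.fit_poisson_glm(counts, design, design_cols=names)
        res = residualize.residuals(counts, fit, type=config.residual_type)
        _write(
            pd.DataFrame(res.values, index=counts.cell_ids, columns=counts.gene_ids),
            out / "residuals.tsv",
        )
        log.info("residualize: %s residuals, %d/%d genes converged (%.1fs)",
                 config.residual_type, int(fit.converged.sum()), counts.n_genes,
                 time.time() - t)

        stage = "factorize"
        t = time.time()
        model = _factorize.factorize(
            res, k=min(config.k, min(counts.n_cells, counts.n_genes)),
            rotation=config.rotation, promax_power=config.promax_power,
        )
        model.gene_ids = counts.gene_ids
        model.cell_ids = counts.cell_ids
        _write(pd.DataFrame(model.scores, index=counts.cell_ids,
                            columns=model.factor_names), out / "scores.tsv")
        _write(pd.DataFrame(model.loadings, index=counts.gene_ids,
                            columns=model.factor_names), out / "loadings.tsv")
        log.info("factorize: k=%d rotation=%s (%.1fs)", model.k, config.rotation,
                 time.time() - t)

        stage = "fca"
        t = time.time()
        fca = _fca.build_fca(
            model, cov, scaling=config.scaling, mean_type=config.mean_type,
            seed=config.seed,
        )
        _write(fca.scores, out / "fca.tsv")
        _write(fca.binarized.astype(int), out / "fca_binarized.tsv")
        diag = None
        if config.n_perm > 0:
            diag = _fca.permutation_test(
                model, cov, n_perm=config.n_perm, seed=config.seed,
                scaling=config.scaling, mean_type=config.mean_type, observed=fca,
            )
            _write(diag.empirical_p, out / "fca_pvalues.tsv")
        log.info("fca: %d levels, otsu=%.3f (%.1fs)", len(fca.levels),
                 fca.threshold, time.time() - t)

        stage = "fis"
        t = time.time()
        fis = _fis.build_fis(model, cov, fca, seed=config.seed)
        _write(fis.values, out / "fis.tsv")
        _write(fis.scaled(), out / "fis_scaled.tsv")
        log.info("fis: %d metrics (%.1fs)", fis.values.shape[0], time.time() - t)

        stage = "export"
        gene_dir = out / "ranked_genes"
        gene_dir.mkdir(exist_ok=True)
        for name in model.factor_names:
            _write(export_ranked_genes(model, name, config.top_n_genes),
                   gene_dir / f"{name}.tsv", index=False)
        numeric = cov.data[[c for c in cov.data.columns
                            if not cov.is_categorical(c)]].astype(float)
        report = unannotated_factor_report(fca, model, numeric)
        _write(report, out / "unannotated_factors.tsv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    artifacts.update(
        counts=counts, cov=cov, fit=fit, residuals=res, model=model,
        fca=fca, fis=fis, diagnostics=diag, report=report, out_dir=out,
    )
    return artifacts
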