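"""Linearization of the MLP predictor into per-gene cis-SNP elastic nets.

An in-silico reference expression matrix is built by running the predictor
on personalized feature vectors for every individual in a genotype panel;
each gene's reference row is then regressed on its cis-SNP dosages with an
elastic net (mixing parameter 0.5, penalty by internal 10-fold CV),
following the standard approach for SNP-based expression models. The same
machinery fitted to observed per-individual expression percentiles gives
the pseudobulk elastic-net (PEN) baseline.

A model "converges" when at least one SNP weight is nonzero at the
CV-selected penalty. Converged weights and reference-panel dosage
covariances are exported in the conventional SQLite + TSV layout consumed
by summary-statistics association tools.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
import warnings

from .ctpred import CtPredModel, predict
from .epifeatures import EpigenomeBackend, backend_feature_vector
from .simulate import GenotypePanel

__all__ = [
    "ElasticNetParams",
    "InSilicoReference",
    "LinearGeneModel",
    "NotConverged",
    "build_insilico_reference",
    "fit_elastic_net",
    "fit_pen",
    "cv_spearman",
    "compute_covariance",
    "export_weights",
    "load_weight_db",
    "load_covariances",
]

CIS_WINDOW = 1_000_000  # bp each side of the TSS


@dataclass
class ElasticNetParams:
    l1_ratio: float = 0.5
    maf_min: float = 0.01
    n_folds: int = 10
    n_alphas: int = 50
    max_iter: int = 5000
    # minimum cross-validated R^2 for a model to count as converged; with
    # small noisy cohorts the bare "any nonzero weight" rule admits many
    # spurious fits, so a PredictDB-style CV performance floor is applied
    min_cv_r2: float = 0.01
    seed: int = 0


@dataclass
class InSilicoReference:
    cell_type: str
    expr: pd.DataFrame  # genes x individuals
    provenance: dict = field(default_factory=dict)


@dataclass
class LinearGeneModel:
    gene_id: str
    cell_type: str
    variant_ids: list[str]
    ref_alleles: list[str]
    eff_alleles: list[str]  # weights count these (alt) alleles
    weights: np.ndarray
    intercept: float
    cv_spearman: float | None = None
    target: str = "insilico"  # or "observed"

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)

    def predict(self, dosages: np.ndarray) -> np.ndarray:
        return np.atleast_2d(dosages) @ self.weights + self.intercept


@dataclass
class NotConverged:
    gene_id: str
    cell_type: str
    reason: str
    target: str = "insilico"


def build_insilico_reference(model: CtPredModel, backend: EpigenomeBackend,
                             panel: GenotypePanel, gene_ids: Sequence[str],
                             ) -> InSilicoReference:
    """Predict expression for every (gene, individual) in the panel."""
    cols = {}
    for ind in panel.individuals:
        X = np.vstack([backend_feature_vector(g, ind, backend) for g in gene_ids])
        cols[ind] = predict(model, X)
    expr = pd.DataFrame(cols, index=list(gene_ids))
    return InSilicoReference(
        cell_type=model.cell_type, expr=expr,
        provenance={"backend": getattr(backend, "name", type(backend).__name__),
                    "n_individuals": panel.n_individuals},
    )


def _maf_filter(variants: pd.DataFrame, dosages: np.ndarray, maf_min: float,
                ) -> tuple[pd.DataFrame, np.ndarray]:
    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= maf_min
    return variants[keep], dosages[:, keep]


def fit_elastic_net(gene_id: str, expr_row: np.ndarray, variants: pd.DataFrame,
                    dosages: np.ndarray, params: ElasticNetParams | None = None,
                    cell_type: str = "", target: str = "insilico",
                    ) -> LinearGeneModel | NotConverged:
    """Elastic net of one gene's expression on its cis dosages.

    Returns :class:`NotConverged` (never raises) when expression is constant,
    fewer than two variants survive the MAF filter, or the CV-selected
    penalty zeroes every weight.
    """
    params = params or ElasticNetParams()
    y = np.asarray(expr_row, dtype=float)
    variants, X = _maf_filter(variants, np.asarray(dosages, dtype=float), params.maf_min)
    if X.shape[1] < 2:
        return NotConverged(gene_id, cell_type, "fewer than 2 cis variants after MAF filter",
                            target)
    if np.std(y) < 1e-12:
        return NotConverged(gene_id, cell_type, "constant expression", target)
    cv = KFold(n_splits=min(params.n_folds, len(y)), shuffle=True,
               random_state=params.seed)
    enet = ElasticNetCV(l1_ratio=params.l1_ratio, alphas=params.n_alphas,
                        cv=cv, max_iter=params.max_iter, n_jobs=None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        enet.fit(X, y)
    nz = np.flatnonzero(enet.coef_)
    if nz.size == 0:
        return NotConverged(gene_id, cell_type, "all weights zero at CV-selected penalty",
                            target)
    cv_r2 = 1.0 - float(enet.mse_path_.mean(axis=-1).min()) / float(np.var(y))
    if cv_r2 < params.min_cv_r2:
        return NotConverged(gene_id, cell_type,
                            f"cross-validated R^2 {cv_r2:.3f} below "
                            f"{params.min_cv_r2}", target)
    sub = variants.iloc[nz]
    return LinearGeneModel(
        gene_id=gene_id, cell_type=cell_type,
        variant_ids=sub["variant_id"].tolist(),
        ref_alleles=sub["ref"].tolist(),
        eff_alleles=sub["alt"].tolist(),
        weights=enet.coef_[nz].copy(),
        intercept=float(enet.intercept_),
        target=target,
    )


def fit_pen(gene_id: str, observed_percentiles_row: np.ndarray,
            variants: pd.DataFrame, dosages: np.ndarray,
            params: ElasticNetParams | None = None, cell_type: str = "",
            ) -> LinearGeneModel | NotConverged:
    """PEN baseline: identical machinery, observed pseudobulk target."""
    return fit_elastic_net(gene_id, observed_percentiles_row, variants, dosages,
                           params, cell_type, target="observed")


def cv_spearman(gene_id: str, expr_row: np.ndarray, variants: pd.DataFrame,
                dosages: np.ndarray, params: ElasticNetParams | None = None,
                folds: int = 10, seed: int = 0) -> float:
    """Spearman correlation between expression and out-of-fold elastic-net
    predictions assembled over ``folds`` folds."""
    params = params or ElasticNetParams()
    y = np.asarray(expr_row, dtype=float)
    if folds > len(y):
        raise ValueError(f"folds ({folds}) exceeds number of individuals ({len(y)})")
    variants, X = _maf_filter(variants, np.asarray(dosages, dtype=float), params.maf_min)
    oof = np.full(len(y), np.nan)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    inner = KFold(n_splits=min(params.n_folds, folds), shuffle=True, random_state=seed)
    for tr, te in kf.split(X):
        enet = ElasticNetCV(l1_ratio=params.l1_ratio, alphas=params.n_alphas,
                            cv=inner, max_iter=params.max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            enet.fit(X[tr], y[tr])
        oof[te] = enet.predict(X[te])
    rho = spearmanr(y, oof).statistic
    return float(rho)


def compute_covariance(panel: GenotypePanel, model: LinearGeneModel) -> np.ndarray:
    """Sample covariance (ddof=1) of the model's variant dosages over the
    reference individuals. Raises if a variant is absent from the panel."""
    col_of = {v: j for j, v in enumerate(panel.variants["variant_id"])}
    cols = []
    for v in model.variant_ids:
        if v not in col_of:
            raise KeyError(f"variant {v} not present in reference panel")
        cols.append(col_of[v])
    D = panel.dosages[:, cols].astype(float)
    return np.atleast_2d(np.cov(D, rowvar=False, ddof=1))


# --------------------------------------------------------------------------
# export / import (PredictDB-style SQLite + covariance TSV)
# --------------------------------------------------------------------------

def export_weights(models: Sequence[LinearGeneModel],
                   covariances: Mapping[str, np.ndarray],
                   db_path: str | Path, cov_path: str | Path) -> None:
    """Write weights to SQLite (tables ``weights`` and ``extra``) and the
    per-gene dosage covariances as a GENE RSID1 RSID2 VALUE TSV (upper
    triangle including the diagonal)."""
    seen = set()
    for m in models:
        for v in m.variant_ids:
            if (m.gene_id, v) in seen:
                raise ValueError(f"duplicate (gene, rsid): ({m.gene_id}, {v})")
            seen.add((m.gene_id, v))

    db_path = Path(db_path)
    if db_path.exists():
        db_path.unlink()
    con = sqlite3.connect(db_path)
    try:
        con.execute("CREATE TABLE weights (gene TEXT, rsid TEXT, varID TEXT, "
                    "ref_allele TEXT, eff_allele TEXT, weight REAL)")
        con.execute("CREATE TABLE extra (gene TEXT, cell_type TEXT, n_snps INTEGER, "
                    "cv_performance REAL, intercept REAL, target TEXT)")
        for m in models:
            for v, ref, alt, w in zip(m.variant_ids, m.ref_alleles, m.eff_alleles,
                                      m.weights):
                con.execute("INSERT INTO weights VALUES (?,?,?,?,?,?)",
                            (m.gene_id, v, v, ref, alt, float(w)))
            con.execute("INSERT INTO extra VALUES (?,?,?,?,?,?)",
                        (m.gene_id, m.cell_type, m.n_snps, m.cv_spearman,
                         m.intercept, m.target))
        con.commit()
    finally:
        con.close()

    with open(cov_path, "w") as fh:
        fh.write("GENE\tRSID1\tRSID2\tVALUE\n")
        for m in models:
            gamma = np.atleast_2d(covariances[m.gene_id])
            for i, vi in enumerate(m.variant_ids):
                for j in range(i, len(m.variant_ids)):
                    fh.write(f"{m.gene_id}\t{vi}\t{m.variant_ids[j]}\t"
                             f"{float(gamma[i, j])!r}\n")


def load_weight_db(db_path: str | Path) -> list[LinearGeneModel]:
    con = sqlite3.connect(db_path)
    try:
        extra = {row[0]: row[1:] for row in
                 con.execute("SELECT gene, cell_type, n_snps, cv_performance, "
                             "intercept, target FROM extra")}
        rows = con.execute("SELECT gene, rsid, ref_allele, eff_allele, weight "
                           "FROM weights").fetchall()
    finally:
        con.close()
    by_gene: dict[str, list] = {}
    for gene, rsid, ref, alt, w in rows:
        by_gene.setdefault(gene, []).append((rsid, ref, alt, w))
    models = []
    for gene, recs in by_gene.items():
        ct, _n, cvs, intercept, target = extra[gene]
        models.append(LinearGeneModel(
            gene_id=gene, cell_type=ct,
            variant_ids=[r[0] for r in recs],
            ref_alleles=[r[1] for r in recs],
            eff_alleles=[r[2] for r in recs],
            weights=np.array([r[3] for r in recs]),
            intercept=float(intercept) if intercept is not None else 0.0,
            cv_spearman=cvs, target=target,
        ))
    return models


def load_covariances(cov_path: str | Path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(cov_path, sep="\t", float_precision="round_trip")
    out: dict[str, pd.DataFrame] = {}
    for gene, sub in df.groupby("GENE", sort=False):
        ids = pd.unique(pd.concat([sub["RSID1"], sub["RSID2"]]))
        gamma = pd.DataFrame(0.0, index=ids, columns=ids)
        for r in sub.itertuples(index=False):
            gamma.loc[r.RSID1, r.RSID2] = r.VALUE
            gamma.loc[r.RSID2, r.RSID1] = r.VALUE
        out[gene] = gamma
    return out
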