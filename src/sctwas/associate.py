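"""Gene-trait association from GWAS summary statistics.

The gene-level Z score combines a gene model's SNP weights with the
per-SNP GWAS z-statistics, scaled by reference-panel dosage standard
deviations:

    Z_g = sum_l w_{g,l} * (sigma_l / sigma_g) * (beta_l / se_l)

with sigma_l = sqrt(Gamma_ll) and sigma_g = sqrt(w' Gamma w) computed over
the SNPs actually matched in the GWAS. The two-tailed p-value is the
standard-normal tail probability of |Z_g|.

GWAS records are harmonized to each model's effect alleles by
(chromosome, position) with allele comparison: swapped alleles flip the
beta sign, strand-ambiguous pairs (A/T, C/G) are dropped by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .linearize import LinearGeneModel, load_covariances, load_weight_db

__all__ = [
    "AssociationResult",
    "HarmonizationReport",
    "read_gwas",
    "harmonize",
    "spredixcan_z",
    "run_association",
]

GWAS_COLUMNS = ("variant_id", "chromosome", "position", "effect_allele",
                "non_effect_allele", "beta", "se")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass
class AssociationResult:
    gene_id: str
    cell_type: str
    zscore: float
    pvalue: float
    log10_pvalue: float  # -log10(p); robust below the float64 underflow limit
    sigma_g: float
    n_snps_used: int
    n_snps_in_model: int


@dataclass
class HarmonizationReport:
    n_model_snps: int
    n_matched: int
    n_flipped: int
    n_palindromic_dropped: int
    n_allele_mismatch: int
    n_unmatched: int


def read_gwas(path: str | Path, column_map: Mapping[str, str] | None = None,
              ) -> pd.DataFrame:
    """Read a summary-statistics TSV; raises on malformed rows with their
    1-based line number (header = line 1)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = set(GWAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"GWAS file missing columns: {sorted(missing)}")
    df = df[list(GWAS_COLUMNS)].copy()
    for col in ("position",):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ValueError(f"malformed {col} at line {int(bad.idxmax()) + 2}")
        df[col] = df[col].astype(int)
    for col in ("beta", "se"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise ValueError(f"malformed {col} at line {int(bad.idxmax()) + 2}")
        df[col] = vals
    bad_se = df.index[df["se"] <= 0]
    if len(bad_se):
        raise ValueError(f"non-positive se at line {int(bad_se[0]) + 2}")
    same = df.index[df["effect_allele"].str.upper() == df["non_effect_allele"].str.upper()]
    if len(same):
        raise ValueError(f"identical alleles at line {int(same[0]) + 2}")
    return df


def harmonize(gwas: pd.DataFrame, model: LinearGeneModel,
              variant_positions: Mapping[str, tuple[str, int]],
              drop_palindromic: bool = True,
              ) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Match GWAS records to one model's variants and orient betas onto the
    model's effect alleles.

    ``variant_positions`` maps model variant ids to (chromosome, position);
    matching is positional with an rsID fallback. Nothing raises: drops are
    counted in the report.
    """
    by_pos: dict[tuple[str, int], int] = {}
    by_id: dict[str, int] = {}
    for i, rec in enumerate(gwas.itertuples(index=False)):
        by_pos.setdefault((str(rec.chromosome), int(rec.position)), i)
        by_id.setdefault(str(rec.variant_id), i)

    rows = []
    n_flip = n_pal = n_mismatch = n_unmatched = 0
    for vid, ref, alt, w in zip(model.variant_ids, model.ref_alleles,
                                model.eff_alleles, model.weights):
        idx = None
        if vid in variant_positions:
            idx = by_pos.get((str(variant_positions[vid][0]), int(variant_positions[vid][1])))
        if idx is None:
            idx = by_id.get(vid)
        if idx is None:
            n_unmatched += 1
            continue
        rec = gwas.iloc[idx]
        ea, oa = str(rec["effect_allele"]).upper(), str(rec["non_effect_allele"]).upper()
        if drop_palindromic and _is_palindromic(ea, oa):
            n_pal += 1
            continue
        beta = float(rec["beta"])
        if (ea, oa) == (alt.upper(), ref.upper()):
            pass
        elif (ea, oa) == (ref.upper(), alt.upper()):
            beta = -beta
            n_flip += 1
        else:
            n_mismatch += 1
            continue
        rows.append((vid, w, beta, float(rec["se"])))
    matched = pd.DataFrame(rows, columns=["variant_id", "weight", "beta", "se"])
    report = HarmonizationReport(
        n_model_snps=model.n_snps, n_matched=len(matched), n_flipped=n_flip,
        n_palindromic_dropped=n_pal, n_allele_mismatch=n_mismatch,
        n_unmatched=n_unmatched,
    )
    return matched, report


def spredixcan_z(model: LinearGeneModel, matched: pd.DataFrame,
                 covariance: pd.DataFrame | np.ndarray,
                 ) -> AssociationResult | None:
    """Gene-level Z and two-tailed p from harmonized records and the
    reference covariance. ``covariance`` must be indexed by (or ordered as)
    the model's variant ids; sigma_g is recomputed on the matched subset.

    Returns None (flagged undefined) when sigma_g is zero.
    """
    if len(matched) == 0:
        return None
    if isinstance(covariance, pd.DataFrame):
        gamma_full = covariance.loc[model.variant_ids, model.variant_ids].to_numpy()
    else:
        gamma_full = np.atleast_2d(np.asarray(covariance, dtype=float))
    order = {v: i for i, v in enumerate(model.variant_ids)}
    sel = [order[v] for v in matched["variant_id"]]
    gamma = gamma_full[np.ix_(sel, sel)]
    w = matched["weight"].to_numpy(dtype=float)
    sigma_l = np.sqrt(np.clip(np.diag(gamma), 0.0, None))
    sigma_g2 = float(w @ gamma @ w)
    if sigma_g2 <= 0:
        return None
    sigma_g = float(np.sqrt(sigma_g2))
    snp_z = matched["beta"].to_numpy() / matched["se"].to_numpy()
    z = float(np.sum(w * sigma_l / sigma_g * snp_z))
    log10p = float((norm.logsf(abs(z)) + np.log(2.0)) / np.log(10.0))
    p = float(min(2.0 * norm.sf(abs(z)), 1.0))
    p = max(p, np.nextafter(0, 1))  # keep pvalue in (0, 1]
    return AssociationResult(
        gene_id=model.gene_id, cell_type=model.cell_type, zscore=z, pvalue=p,
        log10_pvalue=-log10p, sigma_g=sigma_g,
        n_snps_used=len(matched), n_snps_in_model=model.n_snps,
    )


def run_association(weight_db: str | Path, covariance_file: str | Path,
                    gwas_file: str | Path,
                    variant_positions: Mapping[str, tuple[str, int]] | None = None,
                    column_map: Mapping[str, str] | None = None,
                    drop_palindromic: bool = True,
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Full association pass: one result row per converged gene model,
    plus the list of genes whose Z was undefined or unmatched."""
    models = load_weight_db(weight_db)
    covariances = load_covariances(covariance_file)
    gwas = read_gwas(gwas_file, column_map)
    if variant_positions is None:
        variant_positions = {str(r.variant_id): (str(r.chromosome), int(r.position))
                             for r in gwas.itertuples(index=False)}
    rows = []
    undefined = []
    for model in models:
        matched, _report = harmonize(gwas, model, variant_positions,
                                     drop_palindromic=drop_palindromic)
        res = spredixcan_z(model, matched, covariances[model.gene_id])
        if res is None:
            undefined.append(model.gene_id)
            continue
        rows.append((res.gene_id, res.cell_type, res.zscore, res.pvalue,
                     res.log10_pvalue, res.sigma_g, res.n_snps_used,
                     res.n_snps_in_model))
    df = pd.DataFrame(rows, columns=["gene_id", "cell_type", "zscore", "pvalue",
                                     "neg_log10_pvalue", "sigma_g",
                                     "n_snps_used", "n_snps_in_model"])
    return df.sort_values("pvalue").reset_index(drop=True), undefined
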