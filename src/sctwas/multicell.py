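"""Cohort-level statistics across genes and cell types.

Cauchy (tangent) p-value combination, Bonferroni thresholds, the Storey
pi0/pi1 true-positive estimate with its m1 count, precision/recall against
a silver-standard gene list, LD-block accounting, and the shared /
enriched / specific cell-type classification of association hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TruePositiveEstimate",
    "SpecificityCall",
    "acat_combine",
    "bonferroni_threshold",
    "estimate_pi1",
    "precision_recall",
    "assign_ld_blocks",
    "classify_specificity",
]

NOMINAL_ALPHA = 0.05
_P_CEIL = 1.0 - 1e-16  # p == 1 floored below 1 to avoid tan(-pi/2)


def acat_combine(pvalues: Sequence[float], weights: Sequence[float] | None = None,
                 ) -> float:
    """Cauchy combination: T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i,
    combined p = 0.5 - arctan(T)/pi.

    The tangent is evaluated as cot(p*pi), which is numerically exact for
    small p (no explicit small-p branch needed), and the arctangent is
    inverted through its reciprocal for large T. A single p combines to
    itself; p = 0 raises (callers must floor); p = 1 is floored to 1-1e-16.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any():
        raise ValueError("p-values must be > 0 (floor tiny values upstream)")
    if (p > 1).any():
        raise ValueError("p-values must be <= 1")
    p = np.minimum(p, _P_CEIL)
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape:
            raise ValueError("weights and p-values differ in length")
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be >= 0 and not all zero")
    # tan((0.5 - p) * pi) == cot(p * pi) for p in (0, 1)
    t = 1.0 / np.tan(p * np.pi)
    T = float(np.sum(w * t) / np.sum(w))
    if T > 1.0:
        return float(np.arctan(1.0 / T) / np.pi)
    return float(0.5 - np.arctan(T) / np.pi)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class TruePositiveEstimate:
    pi0: float
    pi1: float
    m1: float
    n: int
    lambda_grid: tuple[float, ...]


def estimate_pi1(pvalues: Sequence[float],
                 lambda_grid: Sequence[float] | None = None,
                 ) -> TruePositiveEstimate:
    """Storey estimator pi0(lambda) = #{p > lambda} / ((1 - lambda) n);
    pi1 = 1 - pi0 clipped to [0, 1], m1 = pi1 * n.

    The default uses the classic fixed lambda = 0.5 (stable at the sample
    sizes this package targets); pass a grid to smooth instead as the
    median of pi0(lambda) over the grid. Spline extrapolation toward
    lambda = 1 was rejected: at n <= a few thousand its variance dwarfs the
    bias it removes.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if p.size < 50:
        warnings.warn(f"pi1 estimate unstable with only {p.size} p-values",
                      stacklevel=2)
    grid = np.asarray([0.5]) if lambda_grid is None \
        else np.asarray(lambda_grid, dtype=float)
    pi0_lambda = np.array([(p > lam).sum() / ((1.0 - lam) * p.size) for lam in grid])
    pi0 = float(np.clip(np.median(pi0_lambda), 0.0, 1.0))
    pi1 = 1.0 - pi0
    return TruePositiveEstimate(pi0=pi0, pi1=pi1, m1=pi1 * p.size, n=p.size,
                                lambda_grid=tuple(grid))


def precision_recall(nominated: Iterable[str], silver: Iterable[str],
                     ) -> tuple[float | None, float]:
    """Precision = |nominated & silver| / |nominated| (None when nothing is
    nominated), recall = |nominated & silver| / |silver|."""
    nominated, silver = set(nominated), set(silver)
    if not silver:
        raise ValueError("silver-standard set is empty")
    hits = len(nominated & silver)
    precision = hits / len(nominated) if nominated else None
    recall = hits / len(silver)
    return precision, recall


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chromosome", "start", "end", "name"][:4],
                     usecols=[0, 1, 2, 3], engine="python")
    return df


def assign_ld_blocks(genes: pd.DataFrame, blocks: pd.DataFrame,
                     significant: Iterable[str] | None = None,
                     ) -> tuple[pd.Series, int, int]:
    """Assign each gene's TSS to a 0-based half-open block interval.

    ``genes`` needs gene_id / chromosome / tss (1-based) columns; ``blocks``
    needs chromosome / start / end (+ optional name). Returns the
    gene -> block-id mapping (NaN when unassigned), the unassigned count,
    and - when ``significant`` is given - the number of distinct blocks
    holding at least one significant gene.
    """
    for chrom, sub in blocks.groupby("chromosome"):
        iv = sub.sort_values("start")
        if (iv["end"].to_numpy()[:-1] > iv["start"].to_numpy()[1:]).any():
            raise ValueError(f"overlapping LD blocks on {chrom}")
    if "name" not in blocks.columns or blocks["name"].isna().any():
        blocks = blocks.copy()
        blocks["name"] = [f"{r.chromosome}:{r.start}-{r.end}"
                          for r in blocks.itertuples(index=False)]
    assignment = {}
    n_unassigned = 0
    for rec in genes.itertuples(index=False):
        pos0 = int(rec.tss) - 1  # to 0-based; block interval is half-open
        sub = blocks[blocks["chromosome"] == rec.chromosome]
        hit = sub[(sub["start"] <= pos0) & (pos0 < sub["end"])]
        if len(hit):
            assignment[rec.gene_id] = hit.iloc[0]["name"]
        else:
            assignment[rec.gene_id] = None
            n_unassigned += 1
    mapping = pd.Series(assignment, name="ld_block")
    n_blocks_hit = 0
    if significant is not None:
        hit_blocks = {mapping[g] for g in significant
                      if g in mapping.index and mapping[g] is not None}
        n_blocks_hit = len(hit_blocks)
    return mapping, n_unassigned, n_blocks_hit


@dataclass
class SpecificityCall:
    gene_id: str
    focal_cell_type: str
    label: str  # "shared" | "cell_type_enriched" | "cell_type_specific"
    acat_p_other: float | None
    n_other_cell_types: int


def classify_specificity(results: Mapping[str, pd.DataFrame],
                         bonferroni: Mapping[str, float] | float,
                         nominal_alpha: float = NOMINAL_ALPHA,
                         ) -> list[SpecificityCall]:
    """Partition Bonferroni-significant genes into shared / enriched /
    specific classes.

    ``results`` maps cell type -> frame with gene_id and pvalue columns.
    A gene significant in >= 2 cell types is "shared". A gene significant
    in exactly one cell type has its p-values in the remaining cell types
    combined by ACAT: below ``nominal_alpha`` -> "cell_type_enriched",
    otherwise "cell_type_specific".
    """
    if len(results) < 2:
        raise ValueError("need >= 2 cell types")
    thresholds = {ct: (bonferroni if np.isscalar(bonferroni) else bonferroni[ct])
                  for ct in results}
    pmat: dict[str, dict[str, float]] = {}
    for ct, df in results.items():
        for rec in df.itertuples(index=False):
            pmat.setdefault(rec.gene_id, {})[ct] = float(rec.pvalue)

    calls: list[SpecificityCall] = []
    for gene, ps in pmat.items():
        sig_in = [ct for ct, p in ps.items() if p < thresholds[ct]]
        if not sig_in:
            continue
        if len(sig_in) >= 2:
            for ct in sig_in:
                calls.append(SpecificityCall(gene, ct, "shared", None,
                                             len(ps) - 1))
            continue
        focal = sig_in[0]
        others = [max(p, np.nextafter(0, 1)) for ct, p in ps.items() if ct != focal]
        if others:
            p_other = acat_combine(others)
            label = "cell_type_enriched" if p_other < nominal_alpha \
                else "cell_type_specific"
        else:
            p_other = None
            label = "cell_type_specific"
        calls.append(SpecificityCall(gene, focal, label, p_other, len(others)))
    return calls
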