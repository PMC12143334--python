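"""Synthetic genotype / epigenome / expression / GWAS generator with known truth.

Every downstream stage of the pipeline (pseudobulk targets, feature
extraction, MLP training, linearization, association testing) can be
exercised against data produced here, for which the genetic component of
expression is available in closed form.

Model sketch
------------
* Genotypes: per-gene blocks of biallelic SNPs. Haplotypes are drawn from a
  first-order autoregressive Gaussian copula (``ld_decay`` is the latent
  correlation between adjacent SNPs; 0 means linkage equilibrium) and
  thresholded at the allele frequency, so dosages are in {0, 1, 2}.
* Epigenome oracle: a deterministic per-gene baseline matrix
  (``n_tracks`` x 896) plus dosage-linear terms on a set of causal tracks,
  confined to the central four bins (1-based bins 447-450). A fraction of
  genes additionally carries a dosage-product interaction term.
* Expression: each cell type weights the aggregated feature vector with a
  fixed track-weight vector; the resulting score is the "true genetic
  expression". Pseudobulk counts are negative-binomial draws around
  ``exp(score)``.
* GWAS: a fresh cohort of ``gwas_n`` individuals; the phenotype is linear
  in the true genetic expression of the planted causal genes plus N(0,1)
  noise; marginal per-SNP OLS beta and SE are reported.

Cell-type specificity is planted through track usage: causal tracks are
split into a shared pool plus one private pool per cell type, and a gene
whose SNP effects act only on a private pool has genetic expression
variation in that cell type alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite
from scipy.stats import norm

N_BINS = 896
BIN_WIDTH = 128
CENTRAL_BINS = (447, 450)  # 1-based inclusive
FULL_N_TRACKS = 5313
SMALL_N_TRACKS = 53

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "GenotypePanel",
    "SimulatedDataset",
    "gen_genotypes",
    "epigenome_oracle",
    "oracle_feature_vector",
    "gen_pseudobulk_counts",
    "gen_gwas_sumstats",
    "simulate_dataset",
    "write_vcf",
]


@dataclass
class SimulationConfig:
    """Knobs for one synthetic dataset; all randomness flows from ``seed``."""

    n_individuals: int = 100
    n_genes: int = 50
    n_cell_types: int = 2
    snps_per_gene: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.3
    n_causal_tracks: int = 8
    nonlinear_fraction: float = 0.0
    nb_dispersion: float = 0.2
    gwas_n: int = 1000
    causal_genes: list[tuple[str, str | None, float]] = field(default_factory=list)
    seed: int = 0
    # plumbing knobs (not part of the statistical model)
    n_tracks: int = SMALL_N_TRACKS
    n_chromosomes: int | None = None
    causal_snps_per_gene: int = 3
    effect_scale: float = 0.6
    interaction_scale: float = 0.4
    cells_per_individual: int = 8
    count_log_mean: float = 1.5

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_genes", "n_cell_types", "snps_per_gene",
                     "n_causal_tracks", "gwas_n", "n_tracks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.nonlinear_fraction <= 1.0:
            raise ValueError("nonlinear_fraction must be in [0, 1]")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        if self.n_causal_tracks > self.n_tracks:
            raise ValueError("n_causal_tracks cannot exceed n_tracks")

    @property
    def cell_types(self) -> list[str]:
        return [f"CT{i}" for i in range(self.n_cell_types)]


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]

GENE_SPACING = 2_500_000  # keeps +/-1 Mb cis-windows of adjacent genes disjoint
SNP_SPACING = 1_000


@dataclass
class GenotypePanel:
    """Dosage matrix plus variant and sample metadata."""

    individuals: list[str]
    variants: pd.DataFrame  # variant_id, chromosome, position, ref, alt, maf, gene_id
    dosages: np.ndarray  # n_individuals x n_variants, values in {0,1,2}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def cis_indices(self, gene_id: str) -> np.ndarray:
        idx = np.flatnonzero((self.variants["gene_id"] == gene_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no variants for gene {gene_id}")
        return idx

    def cis_dosages(self, gene_id: str) -> tuple[pd.DataFrame, np.ndarray]:
        idx = self.cis_indices(gene_id)
        return self.variants.iloc[idx], self.dosages[:, idx].astype(float)


def _gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    n_chrom = config.n_chromosomes
    if n_chrom is None:
        n_chrom = int(min(22, max(3, config.n_genes // 8 + 3)))
    rows = []
    for g in range(config.n_genes):
        chrom = f"chr{g % n_chrom + 1}"
        rank_on_chrom = g // n_chrom
        tss = 1_500_000 + rank_on_chrom * GENE_SPACING
        rows.append((f"G{g:04d}", chrom, tss, "+" if g % 2 == 0 else "-"))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "tss", "strand"])


def _variant_frame(config: SimulationConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Variant metadata (incl. MAF) fixed by the config seed, shared by every
    cohort sampled from this simulation."""
    rng = np.random.default_rng([config.seed, 11])
    lo, hi = config.maf_range
    rows = []
    k = 0
    for _, gene in genes.iterrows():
        start = gene.tss - (config.snps_per_gene // 2) * SNP_SPACING
        for j in range(config.snps_per_gene):
            ref, alt = _ALLELE_PAIRS[k % len(_ALLELE_PAIRS)]
            pos = start + j * SNP_SPACING
            maf = float(rng.uniform(lo, hi))
            rows.append((f"rs{k:06d}", gene.chromosome, pos, ref, alt, maf, gene.gene_id))
            k += 1
    return pd.DataFrame(
        rows, columns=["variant_id", "chromosome", "position", "ref", "alt", "maf", "gene_id"]
    )


def _sample_dosages(variants: pd.DataFrame, genes: pd.DataFrame, n: int,
                    ld_decay: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1)-copula haplotypes, independently per gene block."""
    out = np.empty((n, len(variants)), dtype=np.int8)
    thresholds = norm.ppf(variants["maf"].to_numpy())
    for gene_id, block in variants.groupby("gene_id", sort=False):
        idx = block.index.to_numpy()
        m = idx.size
        dos = np.zeros((n, m), dtype=np.int8)
        for _hap in range(2):
            z = np.empty((n, m))
            z[:, 0] = rng.standard_normal(n)
            scale = np.sqrt(1.0 - ld_decay**2)
            for j in range(1, m):
                z[:, j] = ld_decay * z[:, j - 1] + scale * rng.standard_normal(n)
            dos += (z < thresholds[idx]).astype(np.int8)
        out[:, idx] = dos
    return out


def gen_genotypes(config: SimulationConfig, vcf_path: str | Path | None = None,
                  ) -> GenotypePanel:
    """Reference genotype panel (the cohort used for linearization).

    If ``vcf_path`` is given the panel is also written as VCF 4.2 with GT
    fields. Deterministic for a fixed config.
    """
    if config.n_individuals < 2:
        raise ValueError("n_individuals must be >= 2 (dosage variance undefined)")
    genes = _gene_annotation(config)
    variants = _variant_frame(config, genes)
    rng = np.random.default_rng([config.seed, 23])
    dosages = _sample_dosages(variants, genes, config.n_individuals, config.ld_decay, rng)
    panel = GenotypePanel(
        individuals=[f"IND{i:04d}" for i in range(config.n_individuals)],
        variants=variants,
        dosages=dosages,
    )
    if vcf_path is not None:
        write_vcf(panel, vcf_path)
    return panel


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT genotypes; dosage d maps to 0/0, 0/1 or 1/1."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    chroms = panel.variants["chromosome"].unique()
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += panel.individuals
    lines.append("\t".join(header))
    for j, v in enumerate(panel.variants.itertuples(index=False)):
        gts = "\t".join(gt_map[int(d)] for d in panel.dosages[:, j])
        lines.append(
            f"{v.chromosome}\t{v.position}\t{v.variant_id}\t{v.ref}\t{v.alt}"
            f"\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a GT-only VCF back into a panel (gene_id recovered by position later)."""
    individuals: list[str] = []
    rows = []
    dosage_rows = []
    gt_map = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                individuals = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            gts = [gt_map[g.split(":")[0]] for g in parts[9:]]
            dosage_rows.append(gts)
            rows.append((vid, chrom, pos, ref, alt))
    variants = pd.DataFrame(rows, columns=["variant_id", "chromosome", "position", "ref", "alt"])
    dosages = np.asarray(dosage_rows, dtype=np.int8).T
    maf = dosages.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(maf, 1 - maf)
    variants["gene_id"] = ""
    return GenotypePanel(individuals=individuals, variants=variants, dosages=dosages)


# --------------------------------------------------------------------------
# ground truth / epigenome oracle
# --------------------------------------------------------------------------


@dataclass
class EffectBlock:
    """One bundle of cis-SNP effects acting on a set of feature tracks.

    A gene carries one block on the shared track pool by default; genes
    planted as cell-type specific carry one block per cell type, each on
    that cell type's private tracks with its own (disjoint) SNP subset.
    """

    tracks: np.ndarray       # track indices carrying this block's effects
    track_mult: np.ndarray   # per-track multiplier, same length as tracks
    snps: np.ndarray         # local SNP indices within the gene's cis block
    effects: np.ndarray      # effect per causal SNP
    interaction: tuple[int, int, float] | None = None  # indices into snps

    def score(self, dosages: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(np.asarray(dosages, dtype=float))
        s = d[:, self.snps] @ self.effects
        if self.interaction is not None:
            i, j, coef = self.interaction
            s = s + coef * d[:, self.snps[i]] * d[:, self.snps[j]]
        return s


@dataclass
class GroundTruth:
    """Everything needed to evaluate each individual's genetic expression in
    closed form, and to generate oracle feature matrices."""

    config: SimulationConfig
    genes: pd.DataFrame
    cell_types: list[str]
    track_weights: dict[str, np.ndarray]          # cell type -> length n_tracks
    blocks: dict[str, list[EffectBlock]]          # gene -> effect blocks
    causal_genes: list[tuple[str, str | None, float]]
    _baseline_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    # -- baselines ---------------------------------------------------------
    def _gene_index(self, gene_id: str) -> int:
        return int(self.genes.index[self.genes["gene_id"] == gene_id][0])

    def baseline_matrix(self, gene_id: str) -> np.ndarray:
        """Deterministic per-gene baseline, regenerated from the seed."""
        rng = np.random.default_rng([self.config.seed, 101, self._gene_index(gene_id)])
        return rng.standard_normal((self.config.n_tracks, N_BINS))

    def baseline_feature(self, gene_id: str) -> np.ndarray:
        if gene_id not in self._baseline_cache:
            lo, hi = CENTRAL_BINS
            mat = self.baseline_matrix(gene_id)
            self._baseline_cache[gene_id] = mat[:, lo - 1:hi].mean(axis=1)
        return self._baseline_cache[gene_id]

    # -- closed forms ------------------------------------------------------
    def causal_snp_local(self, gene_id: str) -> np.ndarray:
        """Union of causal SNP indices over all of the gene's blocks."""
        return np.unique(np.concatenate([b.snps for b in self.blocks[gene_id]]))

    def genetic_expression(self, gene_id: str, cell_type: str,
                           dosages_cis: np.ndarray) -> np.ndarray:
        """True genetic expression = u_c . feature_vector(gene, dosages)."""
        u = self.track_weights[cell_type]
        base = float(u @ self.baseline_feature(gene_id))
        out = np.full(np.atleast_2d(dosages_cis).shape[0], base)
        for block in self.blocks[gene_id]:
            gain = float(u[block.tracks] @ block.track_mult)
            if gain != 0.0:
                out = out + gain * block.score(dosages_cis)
        return out

    def expression_varies(self, gene_id: str, cell_type: str) -> bool:
        u = self.track_weights[cell_type]
        return any(abs(float(u[b.tracks] @ b.track_mult)) > 1e-12
                   for b in self.blocks[gene_id])

    # -- (de)serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config).items()},
            "genes": self.genes.to_dict(orient="list"),
            "cell_types": self.cell_types,
            "track_weights": {k: v.tolist() for k, v in self.track_weights.items()},
            "blocks": {g: [{
                "tracks": b.tracks.tolist(),
                "track_mult": b.track_mult.tolist(),
                "snps": b.snps.tolist(),
                "effects": b.effects.tolist(),
                "interaction": list(b.interaction) if b.interaction else None,
            } for b in blist] for g, blist in self.blocks.items()},
            "causal_genes": [list(t) for t in self.causal_genes],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        cfg_raw = payload["config"]
        cfg_raw["maf_range"] = tuple(cfg_raw["maf_range"])
        cfg_raw["causal_genes"] = [tuple(t) for t in cfg_raw["causal_genes"]]
        config = SimulationConfig(**cfg_raw)
        blocks = {g: [EffectBlock(
            tracks=np.asarray(b["tracks"], dtype=int),
            track_mult=np.asarray(b["track_mult"]),
            snps=np.asarray(b["snps"], dtype=int),
            effects=np.asarray(b["effects"]),
            interaction=(int(b["interaction"][0]), int(b["interaction"][1]),
                         float(b["interaction"][2])) if b["interaction"] else None,
        ) for b in blist] for g, blist in payload["blocks"].items()}
        return cls(
            config=config,
            genes=pd.DataFrame(payload["genes"]),
            cell_types=payload["cell_types"],
            track_weights={k: np.asarray(v) for k, v in payload["track_weights"].items()},
            blocks=blocks,
            causal_genes=[tuple(t) for t in payload["causal_genes"]],
        )


def _make_truth(config: SimulationConfig, genes: pd.DataFrame) -> GroundTruth:
    rng = np.random.default_rng([config.seed, 37])
    cell_types = config.cell_types

    # causal tracks: a shared pool and one private pool per cell type
    n_ct = config.n_cell_types
    causal = np.arange(config.n_causal_tracks)
    n_shared = max(1, config.n_causal_tracks // 2) if n_ct > 1 else config.n_causal_tracks
    shared = causal[:n_shared]
    private: dict[str, np.ndarray] = {}
    rest = causal[n_shared:]
    for i, ct in enumerate(cell_types):
        private[ct] = rest[i::n_ct] if rest.size else np.empty(0, dtype=int)

    track_weights: dict[str, np.ndarray] = {}
    for ct in cell_types:
        u = np.zeros(config.n_tracks)
        active = np.concatenate([shared, private[ct]]).astype(int)
        u[active] = np.abs(rng.normal(1.0, 0.3, size=active.size))
        # scale so u . baseline_feature has sd ~1.2 across genes
        # (baseline features have per-track sd 0.5 = sd of a 4-bin mean of N(0,1))
        u *= 1.2 / (0.5 * np.linalg.norm(u))
        track_weights[ct] = u

    specific_of = {g: ct for g, ct, _ in config.causal_genes if ct is not None}

    n_nonlinear = int(round(config.nonlinear_fraction * config.n_genes))
    nonlinear_genes = set(
        rng.choice(genes["gene_id"].to_numpy(), size=n_nonlinear, replace=False).tolist()
    ) if n_nonlinear else set()

    def scaled_mult(tracks: np.ndarray, gain_cts: list[str]) -> np.ndarray:
        """Multipliers scaled so the largest per-cell-type expression gain
        is ~0.35, keeping the exp() count model in a sane range."""
        mult = rng.uniform(0.5, 1.5, size=tracks.size)
        denom = max(abs(float(track_weights[c][tracks] @ mult)) for c in gain_cts)
        if denom > 1e-12:
            mult *= 0.35 / denom
        return mult

    def draw_effects(k: int) -> np.ndarray:
        eff = rng.normal(0.0, config.effect_scale, size=k)
        # keep at least one sizeable effect so eQTL signal never vanishes
        i_max = int(np.argmax(np.abs(eff)))
        if abs(eff[i_max]) < config.effect_scale / 2:
            eff[i_max] = np.sign(eff[i_max] or 1.0) * config.effect_scale
        return eff

    blocks: dict[str, list[EffectBlock]] = {}
    k = min(config.causal_snps_per_gene, config.snps_per_gene)
    for gene_id in genes["gene_id"]:
        inter = None
        if gene_id in nonlinear_genes and k >= 2:
            i, j = rng.choice(k, size=2, replace=False)
            inter = (int(i), int(j), float(rng.normal(0.0, config.interaction_scale)))
        focal = specific_of.get(gene_id)
        if focal is not None and private[focal].size:
            # cell-type specific gene: a separate eQTL block per cell type,
            # each on that cell type's private tracks with disjoint SNPs
            k_ct = max(1, min(k, config.snps_per_gene // n_ct))
            loc_all = rng.choice(config.snps_per_gene, size=k_ct * n_ct,
                                 replace=False)
            gene_blocks = []
            for i, ct in enumerate(cell_types):
                loc = np.sort(loc_all[i * k_ct:(i + 1) * k_ct])
                gene_blocks.append(EffectBlock(
                    tracks=private[ct].astype(int),
                    track_mult=scaled_mult(private[ct], [ct]),
                    snps=loc,
                    effects=draw_effects(k_ct),
                    interaction=inter if (ct == focal and k_ct >= 2) else None,
                ))
            blocks[gene_id] = gene_blocks
        else:
            loc = np.sort(rng.choice(config.snps_per_gene, size=k, replace=False))
            blocks[gene_id] = [EffectBlock(
                tracks=shared.astype(int),
                track_mult=scaled_mult(shared, cell_types),
                snps=loc,
                effects=draw_effects(k),
                interaction=inter,
            )]

    return GroundTruth(
        config=config, genes=genes, cell_types=cell_types,
        track_weights=track_weights, blocks=blocks,
        causal_genes=list(config.causal_genes),
    )


def epigenome_oracle(dosages_cis: np.ndarray, gene_id: str, truth: GroundTruth,
                     ) -> np.ndarray:
    """Deterministic feature matrix (n_tracks x 896) for one individual.

    Equals the gene baseline plus dosage-driven terms on the gene's active
    tracks, confined to the central four bins.
    """
    d = np.asarray(dosages_cis, dtype=float)
    if d.ndim != 1:
        raise ValueError("dosages_cis must be a 1-D vector for one individual")
    mat = truth.baseline_matrix(gene_id).copy()
    lo, hi = CENTRAL_BINS
    for block in truth.blocks[gene_id]:
        s = float(block.score(d)[0])
        mat[block.tracks, lo - 1:hi] += (block.track_mult * s)[:, None]
    return mat


def oracle_feature_vector(dosages_cis: np.ndarray, gene_id: str, truth: GroundTruth,
                          ) -> np.ndarray:
    """Central-4-bin aggregation of :func:`epigenome_oracle`, computed in
    closed form without materializing the full matrix."""
    d = np.atleast_2d(np.asarray(dosages_cis, dtype=float))
    base = truth.baseline_feature(gene_id)
    out = np.tile(base, (d.shape[0], 1))
    for block in truth.blocks[gene_id]:
        s = block.score(d)
        out[:, block.tracks] += s[:, None] * block.track_mult[None, :]
    return out[0] if np.asarray(dosages_cis).ndim == 1 else out


def gen_pseudobulk_counts(truth: GroundTruth, panel: GenotypePanel,
                          config: SimulationConfig,
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Cell x gene negative-binomial counts plus cell metadata.

    Each (individual, cell type) contributes ``cells_per_individual`` cells;
    the per-cell mean is ``exp(count_log_mean + genetic expression)``.
    """
    rng = np.random.default_rng([config.seed, 53])
    gene_ids = truth.genes["gene_id"].tolist()
    n_ind = panel.n_individuals

    # per (gene, cell type): expression per individual
    expr = {}  # (gene, ct) -> (n_ind,)
    for gene_id in gene_ids:
        _, dos = panel.cis_dosages(gene_id)
        for ct in truth.cell_types:
            expr[(gene_id, ct)] = truth.genetic_expression(gene_id, ct, dos)

    meta_rows = []
    blocks = []
    cell_k = 0
    for ct in truth.cell_types:
        mu = np.empty((n_ind, len(gene_ids)))
        for gj, gene_id in enumerate(gene_ids):
            mu[:, gj] = np.exp(np.clip(config.count_log_mean + expr[(gene_id, ct)], None, 12.0))
        for i, ind in enumerate(panel.individuals):
            n_cells = config.cells_per_individual
            m = np.tile(mu[i], (n_cells, 1))
            if config.nb_dispersion > 1e-8:
                lam = rng.gamma(shape=1.0 / config.nb_dispersion,
                                scale=m * config.nb_dispersion)
            else:
                lam = m
            counts = rng.poisson(lam)
            blocks.append(counts)
            for _ in range(n_cells):
                meta_rows.append((f"CELL{cell_k:06d}", ind, ct))
                cell_k += 1
    counts = np.vstack(blocks)
    meta = pd.DataFrame(meta_rows, columns=["cell_id", "individual_id", "cell_type"])
    return counts, meta


def write_cells(counts: np.ndarray, meta: pd.DataFrame, gene_ids: Sequence[str],
                mtx_path: str | Path, meta_path: str | Path,
                genes_path: str | Path) -> None:
    mmwrite(str(mtx_path), sparse.csr_matrix(counts))
    meta.to_csv(meta_path, sep="\t", index=False)
    pd.Series(list(gene_ids), name="gene_id").to_csv(genes_path, sep="\t", index=False)


# --------------------------------------------------------------------------
# GWAS summary statistics
# --------------------------------------------------------------------------

def gen_gwas_sumstats(truth: GroundTruth, config: SimulationConfig,
                      path: str | Path | None = None) -> pd.DataFrame:
    """Marginal per-SNP OLS summary statistics from a simulated cohort.

    The cohort is freshly sampled (independent of the reference panel) and
    the phenotype is ``sum_causal effect * standardized(expression) + noise``.
    """
    if config.gwas_n < 10:
        raise ValueError("gwas_n must be >= 10")
    if not truth.causal_genes:
        raise ValueError("causal_genes is empty; nothing to plant in the phenotype")
    genes = truth.genes
    variants = _variant_frame(config, genes)
    rng = np.random.default_rng([config.seed, 71])
    dosages = _sample_dosages(variants, genes, config.gwas_n, config.ld_decay, rng).astype(float)

    y = rng.standard_normal(config.gwas_n)
    for gene_id, ct, effect in truth.causal_genes:
        if effect == 0.0:
            continue
        cts = [ct] if ct is not None else truth.cell_types
        idx = np.flatnonzero((variants["gene_id"] == gene_id).to_numpy())
        dos = dosages[:, idx]
        for c in cts:
            e = truth.genetic_expression(gene_id, c, dos)
            sd = e.std()
            if sd > 1e-12:
                y = y + effect * (e - e.mean()) / sd

    n = config.gwas_n
    xc = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    sxx = np.where(sxx < 1e-12, np.nan, sxx)
    beta = xc.T @ yc / sxx
    syy = float((yc**2).sum())
    resid_var = np.maximum(syy - beta**2 * sxx, 0.0) / (n - 2)
    se = np.sqrt(resid_var / sxx)

    out = variants[["variant_id", "chromosome", "position"]].copy()
    out["effect_allele"] = variants["alt"]
    out["non_effect_allele"] = variants["ref"]
    out["beta"] = beta
    out["se"] = se
    out = out.dropna(subset=["beta", "se"]).reset_index(drop=True)
    out = out[out["se"] > 0].reset_index(drop=True)
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out


# --------------------------------------------------------------------------
# bundle
# --------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    truth: GroundTruth
    panel: GenotypePanel
    counts: np.ndarray
    cell_meta: pd.DataFrame
    gwas: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return self.truth.genes["gene_id"].tolist()


def simulate_dataset(config: SimulationConfig, outdir: str | Path | None = None,
                     ) -> SimulatedDataset:
    """Run all generators; optionally persist every artifact under ``outdir``."""
    panel = gen_genotypes(config)
    truth = _make_truth(config, _gene_annotation(config))
    counts, meta = gen_pseudobulk_counts(truth, panel, config)
    if config.causal_genes:
        gwas = gen_gwas_sumstats(truth, config)
    else:
        gwas = pd.DataFrame()
    ds = SimulatedDataset(config=config, truth=truth, panel=panel,
                          counts=counts, cell_meta=meta, gwas=gwas)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(panel, outdir / "genotypes.vcf")
        write_cells(counts, meta, ds.gene_ids, outdir / "counts.mtx",
                    outdir / "cells.tsv", outdir / "genes.tsv")
        truth.genes.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        truth.to_json(outdir / "truth.json")
        if len(gwas):
            gwas.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
    return ds
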