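"""Three-step workflow orchestration.

Stages (simulate -> pseudobulk -> features -> train -> linearize -> assoc
-> stats) exchange artifacts through files in one working directory, so any
stage can be re-run standalone from persisted upstream outputs. A manifest
records seeds, package version, and SHA-256 hashes of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from . import __version__
from .associate import run_association
from .ctpred import (CtPredHyperparams, CtPredModel, evaluate_across_genes,
                     load_model, save_model, split_by_chromosome, train_ctpred)
from .epifeatures import OracleBackend, backend_feature_vector, read_gene_annotation
from .linearize import (ElasticNetParams, build_insilico_reference, compute_covariance,
                        cv_spearman, export_weights, fit_elastic_net, LinearGeneModel)
from .multicell import acat_combine, bonferroni_threshold, classify_specificity, estimate_pi1
from .pseudobulk import (CellQCParams, aggregate_pseudobulk, qc_filter,
                         rank_percentile, rank_percentile_per_individual)
from .simulate import (GroundTruth, SimulationConfig, gen_gwas_sumstats,
                       read_vcf, simulate_dataset)

ALL_STAGES = ("simulate", "pseudobulk", "features", "train", "linearize",
              "assoc", "stats")


@dataclass
class RunConfig:
    workdir: str
    seed: int = 0
    profile: str = "small"  # "small" (53 tracks) or "full" (5,313 tracks)
    stages: tuple[str, ...] = ALL_STAGES
    simulation: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    mlp: dict = field(default_factory=dict)
    elastic_net: dict = field(default_factory=dict)
    gwas_file: str | None = None  # defaults to the simulated sumstats

    def __post_init__(self) -> None:
        if not self.workdir:
            raise ValueError("config field 'workdir' is required")
        if self.profile not in {"small", "full"}:
            raise ValueError(f"config field 'profile' must be 'small' or 'full', "
                             f"got {self.profile!r}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"config field 'stages' contains unknown stages: "
                             f"{sorted(unknown)}")
        if "simulate" not in self.stages and self.gwas_file is None:
            gwas = Path(self.workdir) / "gwas.tsv"
            if not gwas.exists():
                raise ValueError("config field 'gwas_file' is required when the "
                                 "simulate stage is disabled")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid config: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the manifest dict (also written
    to ``workdir/manifest.json``)."""
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "profile": config.profile, "stages": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {p.name: _sha256(p) for p in paths if p.exists()}

    n_tracks = 5313 if config.profile == "full" else 53

    # ---- simulate -------------------------------------------------------
    if "simulate" in config.stages:
        sim_kwargs = dict(config.simulation)
        if "causal_genes" in sim_kwargs:
            sim_kwargs["causal_genes"] = [tuple(t) for t in sim_kwargs["causal_genes"]]
        if "maf_range" in sim_kwargs:
            sim_kwargs["maf_range"] = tuple(sim_kwargs["maf_range"])
        sim_cfg = SimulationConfig(seed=config.seed, n_tracks=n_tracks, **sim_kwargs)
        simulate_dataset(sim_cfg, outdir=wd)
        record("simulate", *(wd / f for f in
                             ("genotypes.vcf", "counts.mtx", "cells.tsv", "genes.tsv",
                              "annotation.tsv", "truth.json", "gwas.tsv")))

    truth = GroundTruth.from_json(wd / "truth.json")
    panel = _load_panel(wd, truth)
    genes = read_gene_annotation(wd / "annotation.tsv")
    gene_ids = [g.gene_id for g in genes]

    # ---- pseudobulk -----------------------------------------------------
    if "pseudobulk" in config.stages:
        counts = np.asarray(mmread(wd / "counts.mtx").todense())
        meta = pd.read_csv(wd / "cells.tsv", sep="\t")
        loaded_genes = pd.read_csv(wd / "genes.tsv", sep="\t")["gene_id"].tolist()
        qc = CellQCParams(**config.qc) if config.qc else CellQCParams(
            min_genes_per_cell=0, min_cells_per_gene=0)
        counts, meta, kept_genes, _report = qc_filter(counts, meta, loaded_genes, qc)
        pbs = aggregate_pseudobulk(counts, meta, kept_genes)
        outs = []
        for ct, pb in pbs.items():
            pb.counts.to_csv(wd / f"pseudobulk_{ct}.tsv", sep="\t")
            rank_percentile(pb).percentile.rename("percentile") \
                .to_csv(wd / f"percentiles_{ct}.tsv", sep="\t")
            rank_percentile_per_individual(pb).to_csv(
                wd / f"percentiles_ind_{ct}.tsv", sep="\t")
            outs += [wd / f"pseudobulk_{ct}.tsv", wd / f"percentiles_{ct}.tsv",
                     wd / f"percentiles_ind_{ct}.tsv"]
        record("pseudobulk", *outs)

    backend = OracleBackend(truth, panel)

    # ---- features -------------------------------------------------------
    if "features" in config.stages:
        ref = {g: backend_feature_vector(g, None, backend) for g in gene_ids}
        pd.DataFrame(ref).T.to_csv(wd / "features_ref.tsv", sep="\t", header=False)
        record("features", wd / "features_ref.tsv")

    # ---- train ----------------------------------------------------------
    cell_types = truth.cell_types
    if "train" in config.stages:
        features = _read_feature_tsv(wd / "features_ref.tsv")
        split = split_by_chromosome(genes, seed=config.seed)
        (wd / "split.json").write_text(json.dumps({
            "train": sorted(split.train), "validation": sorted(split.validation),
            "test": sorted(split.test), "seed": config.seed}))
        outs = [wd / "split.json"]
        for ct in cell_types:
            targets = pd.read_csv(wd / f"percentiles_{ct}.tsv", sep="\t",
                                  index_col=0)["percentile"].to_dict()
            usable = {g: features[g] for g in features if g in targets}
            hp = CtPredHyperparams(seed=config.seed, **config.mlp)
            model, log = train_ctpred(usable, targets, split, genes, hp, cell_type=ct)
            save_model(model, wd / f"ctpred_{ct}.npz")
            log.to_csv(wd / f"trainlog_{ct}.tsv", sep="\t", index=False)
            outs += [wd / f"ctpred_{ct}.npz", wd / f"trainlog_{ct}.tsv"]
        record("train", *outs)

    # ---- linearize ------------------------------------------------------
    if "linearize" in config.stages:
        enet = ElasticNetParams(seed=config.seed, **config.elastic_net)
        outs = []
        for ct in cell_types:
            model = load_model(wd / f"ctpred_{ct}.npz")
            ref = build_insilico_reference(model, backend, panel, gene_ids)
            ref.expr.to_csv(wd / f"insilico_{ct}.tsv", sep="\t")
            fitted: list[LinearGeneModel] = []
            for g in gene_ids:
                variants, dosages = panel.cis_dosages(g)
                res = fit_elastic_net(g, ref.expr.loc[g].to_numpy(), variants,
                                      dosages, enet, cell_type=ct)
                if isinstance(res, LinearGeneModel):
                    res.cv_spearman = cv_spearman(g, ref.expr.loc[g].to_numpy(),
                                                  variants, dosages, enet,
                                                  folds=min(enet.n_folds,
                                                            panel.n_individuals),
                                                  seed=config.seed)
                    fitted.append(res)
            cov = {m.gene_id: compute_covariance(panel, m) for m in fitted}
            export_weights(fitted, cov, wd / f"weights_{ct}.db", wd / f"cov_{ct}.tsv")
            outs += [wd / f"insilico_{ct}.tsv", wd / f"weights_{ct}.db",
                     wd / f"cov_{ct}.tsv"]
        record("linearize", *outs)

    # ---- assoc ----------------------------------------------------------
    if "assoc" in config.stages:
        gwas_file = Path(config.gwas_file) if config.gwas_file else wd / "gwas.tsv"
        outs = []
        for ct in cell_types:
            results, _undef = run_association(wd / f"weights_{ct}.db",
                                              wd / f"cov_{ct}.tsv", gwas_file)
            results.to_csv(wd / f"results_{ct}.tsv", sep="\t", index=False)
            outs.append(wd / f"results_{ct}.tsv")
        record("assoc", *outs)

    # ---- stats ----------------------------------------------------------
    if "stats" in config.stages:
        results = {ct: pd.read_csv(wd / f"results_{ct}.tsv", sep="\t")
                   for ct in cell_types}
        thresholds = {ct: bonferroni_threshold(len(df)) for ct, df in results.items()
                      if len(df)}
        summary: dict = {"bonferroni": thresholds}
        all_p = np.concatenate([df["pvalue"].to_numpy() for df in results.values()
                                if len(df)]) if results else np.array([])
        if all_p.size >= 1:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                est = estimate_pi1(all_p)
            summary["pi1"] = {"pi0": est.pi0, "pi1": est.pi1, "m1": est.m1,
                              "n": est.n}
        # ACAT across cell types per gene
        per_gene: dict[str, list[float]] = {}
        for df in results.values():
            for rec in df.itertuples(index=False):
                per_gene.setdefault(rec.gene_id, []).append(max(rec.pvalue, 1e-300))
        summary["acat_across_cell_types"] = {g: acat_combine(ps)
                                             for g, ps in per_gene.items()}
        if len(results) >= 2 and thresholds:
            calls = classify_specificity(results, thresholds)
            summary["specificity"] = [asdict(c) for c in calls]
        (wd / "summary.json").write_text(json.dumps(summary, indent=1))
        record("stats", wd / "summary.json")

    (wd / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _load_panel(wd: Path, truth: GroundTruth):
    panel = read_vcf(wd / "genotypes.vcf")
    # recover gene_id assignment from per-gene block layout
    cfg = truth.config
    n_per = cfg.snps_per_gene
    gene_ids = truth.genes["gene_id"].tolist()
    labels = []
    for i in range(len(panel.variants)):
        labels.append(gene_ids[i // n_per])
    panel.variants["gene_id"] = labels
    # true MAFs (variant metadata) are deterministic given the config
    return panel


def _read_feature_tsv(path: Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return {g: row.to_numpy(dtype=float) for g, row in df.iterrows()}
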