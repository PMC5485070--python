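"""End-to-end pipeline: data -> kinship -> structure -> responses -> h2 ->
animal models -> MTMM -> QTL report.

One YAML config drives every stage; defaults are the analysis settings used
throughout the package (Moran alpha 0.001, ten genetic groups, 75-day
life-cycle threshold, MCMC 150k/50/50k for the Gaussian models and ten-fold
longer for the threshold model, MAF 0.05, -log10 p threshold 4, 20-kb QTL
windows).  Every output carries a provenance header (package version,
config hash, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .animal import (McmcSettings, PosteriorSummary, default_prior_gaussian,
                     default_prior_threshold, fit_gaussian_animal_model,
                     fit_threshold_animal_model, trade_off_models,
                     trade_off_table)
from .bioassay import (RESPONSE_COLUMNS, classify_life_cycle,
                       derive_stress_responses, fit_experiment_lmm,
                       predicted_means)
from .genotypes import (GeoRecord, read_genotypes, read_geo_table,
                        geographic_subset, write_genotypes, write_geo_table)
from .heritability import h2_table
from .kinship import compute_kinship
from .mtmm import (build_trait_vectors, fit_mtmm_varcomp, gls_f_tests,
                   regions_to_bed, select_qtl_regions)
from .simulate import SimulationTruth, simulate_dataset, study_like_truth
from .structure import (build_spatial_weights, cluster_phenotype_anova,
                        pca_markers, select_informative_pcs, ward_cluster,
                        ward_tree_newick)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineStageError"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, last_artifact: str | None, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause} "
                         f"(last good artifact: {last_artifact})")
        self.stage = stage
        self.last_artifact = last_artifact


@dataclass
class McmcConfig:
    n_iter: int = 150_000
    thin: int = 50
    burn_in: int = 50_000

    def settings(self, seed: int) -> McmcSettings:
        return McmcSettings(n_iter=self.n_iter, thin=self.thin,
                            burn_in=self.burn_in, seed=seed)


@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "stresshap_out"
    # either a simulation block or explicit input paths
    simulate: dict | None = field(default_factory=lambda: {"preset": "study-like"})
    inputs: dict | None = None
    kinship_estimator: str = "standardized"
    structure_alpha: float = 0.001
    n_groups: int = 10
    weights_scheme: str = "knn"
    weights_k: int = 5
    n_components: int = 20
    life_cycle_threshold: float = 75.0
    mcmc_type1: McmcConfig = field(default_factory=McmcConfig)
    mcmc_type2: McmcConfig = field(
        default_factory=lambda: McmcConfig(1_500_000, 500, 500_000))
    mcmc_type3: McmcConfig = field(default_factory=McmcConfig)
    mtmm_maf: float = 0.05
    mtmm_threshold: float = 4.0
    mtmm_window_bp: int = 20_000
    mtmm_test: str = "specific"
    geographic_filter: dict | None = None   # lat_min/lon_min/lon_max/elev_max

    def __post_init__(self) -> None:
        for name in ("mcmc_type1", "mcmc_type2", "mcmc_type3"):
            cfg = getattr(self, name)
            if isinstance(cfg, dict):
                cfg = McmcConfig(**cfg)
                setattr(self, name, cfg)
            if cfg.burn_in >= cfg.n_iter:
                raise ValueError(f"{name}: burn_in must be < n_iter")
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a simulate block or inputs")
        if self.inputs is not None:
            for key, path in self.inputs.items():
                if key.endswith("format"):
                    continue
                if not Path(path).exists():
                    raise FileNotFoundError(f"inputs.{key}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_with_header(df: pd.DataFrame, path: Path, header: str,
                       sep: str = ",", index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep=sep, index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns artifacts and paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"# stresshap {__version__} config={config.config_hash()} "
              f"seed={config.seed}\n")
    artifacts: dict = {"output_dir": str(out)}
    last_artifact: str | None = None
    stage = "init"
    t_start = time.time()
    try:
        # ------------------------------------------------------------ data
        stage = "data"
        if config.simulate is not None:
            sim_opts = dict(config.simulate)
            preset = sim_opts.pop("preset", "study-like")
            if preset == "study-like":
                truth = study_like_truth(seed=config.seed, **sim_opts)
            else:
                truth = SimulationTruth(seed=config.seed, **sim_opts)
            sim = simulate_dataset(truth)
            geno, geo = sim.genotypes, sim.geo
            bioassays = sim.bioassays
            flowering = sim.life_cycle.drop(columns=["strategy"])
            write_genotypes(geno, out / "genotypes.tsv")
            write_geo_table(geo, out / "geo.csv")
            artifacts["simulation_truth"] = truth
            artifacts["sim"] = sim
        else:
            inp = config.inputs
            geno = read_genotypes(inp["genotypes"],
                                  format=inp.get("genotypes_format", "tsv"))
            geo = read_geo_table(inp["geo"])
            if config.geographic_filter:
                geno = geographic_subset(geno, geo, **config.geographic_filter)
                geo = [g for g in geo if g.accession_id in set(geno.accession_ids)]
            bioassays = {
                e: pd.read_csv(inp[f"bioassay_exp{e}"])
                for e in (1, 2, 3, 4) if f"bioassay_exp{e}" in inp
            }
            flowering = pd.read_csv(inp["flowering"])
        last_artifact = str(out / "genotypes.tsv")

        # --------------------------------------------------------- kinship
        stage = "kinship"
        kin = compute_kinship(geno, estimator=config.kinship_estimator)
        kin.to_file(out / "kinship.tsv")
        last_artifact = str(out / "kinship.tsv")
        if kin.ridge:
            logger.warning("kinship ridge-repaired with delta=%.3g", kin.ridge)

        # ------------------------------------------------------- structure
        stage = "structure"
        n_comp = min(config.n_components, geno.n_accessions - 1)
        pca = pca_markers(geno, n_comp)
        weights = build_spatial_weights(geo, scheme=config.weights_scheme,
                                        k=config.weights_k)
        sel = select_informative_pcs(pca, weights, alpha=config.structure_alpha)
        retained = sel["retained"]
        scores = pca.scores[:, retained] if retained else pca.scores[:, :1]
        groups = ward_cluster(scores, config.n_groups,
                              accession_ids=geno.accession_ids)
        gdf = pd.DataFrame(
            {"accession_id": list(groups.assignment),
             "group": list(groups.assignment.values())}
        ).set_index("accession_id")
        _write_with_header(gdf, out / "groups.csv", header)
        (out / "ward_tree.nwk").write_text(
            ward_tree_newick(groups, geno.accession_ids))
        artifacts.update(pca=pca, informative_pcs=sel, groups=groups)
        last_artifact = str(out / "groups.csv")

        # ------------------------------------------------------- responses
        stage = "responses"
        means = {}
        fits = {}
        for e, table in bioassays.items():
            fits[e] = fit_experiment_lmm(table, e)
            means[e] = predicted_means(fits[e])
        responses = derive_stress_responses(means)
        _write_with_header(responses, out / "responses.csv", header)
        lc = classify_life_cycle(flowering,
                                 threshold_days=config.life_cycle_threshold)
        _write_with_header(lc, out / "life_cycle.csv", header)
        artifacts.update(responses=responses, life_cycle=lc, lmm_fits=fits)
        last_artifact = str(out / "responses.csv")

        # group-effect ANOVA after life-cycle correction
        common = responses.index.intersection(lc.index)
        anova = cluster_phenotype_anova(responses.loc[common], groups,
                                        lc.loc[common, "strategy"])
        _write_with_header(anova, out / "group_anova.csv", header)
        artifacts["group_anova"] = anova

        # -------------------------------------------------------------- h2
        stage = "heritability"
        h2 = h2_table(responses, kin)
        _write_with_header(h2, out / "h2_table.csv", header)
        artifacts["h2_table"] = h2
        last_artifact = str(out / "h2_table.csv")

        # ---------------------------------------------------- animal models
        stage = "animal_models"
        geo_df = pd.DataFrame(
            {"accession_id": [g.accession_id for g in geo],
             "latitude": [g.latitude for g in geo],
             "longitude": [g.longitude for g in geo],
             "elevation": [g.elevation for g in geo]}
        ).set_index("accession_id")
        ids = [a for a in responses.index if a in geo_df.index and a in lc.index]
        names1 = ["(Intercept)", "life_cycle[winter]", "elevation", "latitude",
                  "longitude"]

        def geo_design(trait_ids: list[str]) -> np.ndarray:
            w = (lc.loc[trait_ids, "strategy"] == "winter").to_numpy(float)
            return np.column_stack([
                np.ones(len(trait_ids)),
                w,
                geo_df.loc[trait_ids, "elevation"].to_numpy(float),
                geo_df.loc[trait_ids, "latitude"].to_numpy(float),
                geo_df.loc[trait_ids, "longitude"].to_numpy(float),
            ])

        rows = []
        for i, trait in enumerate(responses.columns):
            # complete cases per trait (experiments may drop accessions)
            tids = [a for a in ids if pd.notna(responses.loc[a, trait])]
            summ = fit_gaussian_animal_model(
                responses.loc[tids, trait].to_numpy(float), geo_design(tids),
                kin.align(tids),
                prior=default_prior_gaussian(),
                mcmc=config.mcmc_type1.settings(config.seed + 100 + i),
                term_names=names1,
            )
            for term, r in summ.fixed.iterrows():
                rows.append({"response": trait, "term": term, **r.to_dict()})
            rows.append({"response": trait, "term": "genetic_variance",
                         **summ.variances.loc["genetic_variance"].to_dict()})
        # type 2: life cycle on gradients
        winter = (lc.loc[ids, "strategy"] == "winter").to_numpy(float)
        Ka = kin.align(ids)
        if len(set(winter)) == 2:
            summ2 = fit_threshold_animal_model(
                winter.astype(int), geo_design(ids)[:, [0, 2, 3, 4]], Ka,
                prior=default_prior_threshold(),
                mcmc=config.mcmc_type2.settings(config.seed + 200),
                term_names=["(Intercept)", "elevation", "latitude", "longitude"],
            )
            for term, r in summ2.fixed.iterrows():
                rows.append({"response": "Flowering type", "term": term,
                             **r.to_dict()})
            artifacts["type2"] = summ2
        table2 = pd.DataFrame(rows).set_index(["response", "term"])
        _write_with_header(table2, out / "animal_models_geography.csv", header)
        artifacts["table2"] = table2
        last_artifact = str(out / "animal_models_geography.csv")

        # type 3: trade-offs
        stage = "trade_offs"
        trade = trade_off_models(
            responses, lc["strategy"], kin,
            prior=default_prior_gaussian(),
            mcmc=config.mcmc_type3.settings(config.seed + 300),
        )
        table3 = trade_off_table(trade)
        _write_with_header(table3, out / "trade_offs.csv", header)
        artifacts["trade_offs"] = trade
        artifacts["table3"] = table3
        last_artifact = str(out / "trade_offs.csv")

        # ------------------------------------------------------------ MTMM
        stage = "mtmm"
        tv = build_trait_vectors(responses)
        geno_m = geno.subset_accessions(tv.accession_ids)
        Km = kin.align(tv.accession_ids)
        mfit = fit_mtmm_varcomp(tv.p1, tv.p2, Km)
        snp = gls_f_tests(geno_m, mfit, tv.p1, tv.p2, Km,
                          maf_min=config.mtmm_maf)
        snp.to_csv(out / "mtmm_results.tsv", sep="\t", index=False)
        regions = select_qtl_regions(snp, test=config.mtmm_test,
                                     neg_log10_threshold=config.mtmm_threshold,
                                     window_bp=config.mtmm_window_bp)
        regions_to_bed(regions).to_csv(out / "qtl_regions.bed", sep="\t",
                                       header=False, index=False)
        artifacts.update(trait_vectors=tv, mtmm_fit=mfit, snp_tests=snp,
                         qtl_regions=regions)
        last_artifact = str(out / "qtl_regions.bed")

        # ------------------------------------------------------ provenance
        stage = "provenance"
        prov = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_accessions": geno.n_accessions,
            "n_markers": geno.n_markers,
            "elapsed_s": round(time.time() - t_start, 2),
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
        artifacts["provenance"] = prov
        return artifacts
    except Exception as exc:
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, last_artifact, exc) from exc
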