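"""End-to-end orchestration of the microbiome-driven breeding analysis.

Stages run in dependency order — simulate -> coda -> grm -> fit -> screen ->
select -> predict -> report — each consuming and producing only declared
on-disk artifacts, so stages can be rerun individually and deleting a
downstream artifact never touches an upstream one. A provenance manifest
records the configuration hash, the global seed and the SHA-256 of every
artifact; a rerun with an identical configuration reproduces identical
artifacts.

Seeding: one global seed; each stage (and each per-feature chain) derives its
own seed by stable hashing of (global seed, stage name, item id), so
feature-level analyses are reproducible independently of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import breeding, coda, genomics, network, screening
from .gblup import (
    GBLUP,
    McmcConfig,
    bayes_factor,
    hpd_interval,
    log_bayes_factor,
    p0_sign_probability,
)
from .simulate import SimulationSpec, simulate_population

logger = logging.getLogger("microbreed.pipeline")

STAGES = ("simulate", "coda", "grm", "fit", "screen", "select", "predict", "report")


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass
class PipelineConfig:
    """All stage parameters with their published defaults, plus paths.

    Unknown keys in a YAML file are rejected so typos cannot silently fall
    back to defaults.
    """

    seed: int = 0
    outdir: str = "pipeline_out"
    # inputs; empty strings mean "use the simulate stage's outputs"
    genotype_path: str = ""  # dosage TSV or VCF (.vcf)
    microbiome_path: str = ""  # counts/proportions TSV, features x samples
    phenotype_path: str = ""  # CSV with goal traits + fixed_level column
    goal_traits: list[str] = field(default_factory=lambda: ["N3", "CLA"])
    # simulate
    simulation: dict = field(default_factory=dict)  # SimulationSpec overrides
    # coda
    min_occupancy: float = 0.70
    min_mean_ra: float = 1e-5
    alr_epsilon: float = 0.005
    # genotype QC
    snp_call_rate: float = 0.95
    hwe_p_cut: float = 1e-8
    maf_cut: float = 0.05
    animal_call_rate: float = 0.90
    grm_ridge: float = 1e-6
    # chains
    n_iter: int = 20_000
    burn_in: int = 4_000
    thin: int = 4
    paper_scale: bool = False
    # screening
    dic_cut: float = -20.0
    bf_alpha: float = 1e-4
    p0_cut: float = 0.95
    # network / selection
    r_threshold: float = 0.30
    mcl_inflation: float = 2.0
    min_cluster_size: int = 2
    abundance_floor: float = 1e-4
    rda_alpha: float = 0.05
    rda_n_perm: int = 999
    # index
    bending_tolerance: float = 0.001
    selection_proportions: list[float] = field(
        default_factory=lambda: list(breeding.SELECTION_PROPORTIONS)
    )

    def __post_init__(self) -> None:
        _check_range("min_occupancy", self.min_occupancy, 0.0, 1.0)
        _check_range("min_mean_ra", self.min_mean_ra, 0.0, 1.0)
        _check_range("snp_call_rate", self.snp_call_rate, 0.0, 1.0)
        _check_range("hwe_p_cut", self.hwe_p_cut, 0.0, 1.0)
        _check_range("maf_cut", self.maf_cut, 0.0, 0.5)
        _check_range("animal_call_rate", self.animal_call_rate, 0.0, 1.0)
        _check_range("bf_alpha", self.bf_alpha, 0.0, 1.0)
        _check_range("p0_cut", self.p0_cut, 0.5, 1.0)
        _check_range("r_threshold", self.r_threshold, 0.0, 1.0)
        _check_range("abundance_floor", self.abundance_floor, 0.0, 1.0)
        _check_range("rda_alpha", self.rda_alpha, 0.0, 1.0)
        if self.dic_cut >= 0:
            raise ValueError("dic_cut must be negative (full model must improve)")
        if self.bending_tolerance <= 0:
            raise ValueError("bending_tolerance must be positive")
        for p in self.selection_proportions:
            _check_range("selection proportion", p, 0.0, 1.0)
        if not self.goal_traits:
            raise ValueError("goal_traits must be non-empty")
        unknown_sim = set(self.simulation) - {
            f.name for f in dataclasses.fields(SimulationSpec)
        }
        if unknown_sim:
            raise ValueError(f"unknown simulation keys: {sorted(unknown_sim)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def canonical(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()

    def chain_config(self, stage: str, item: str = "") -> McmcConfig:
        base = McmcConfig.paper_scale() if self.paper_scale else McmcConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin
        )
        return dataclasses.replace(base, seed=stage_seed(self.seed, stage, item))


def stage_seed(global_seed: int, stage: str, item: str = "") -> int:
    """Deterministic per-stage/per-item seed from the global seed."""
    digest = hashlib.sha256(f"{global_seed}|{stage}|{item}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact is absent; names the stage that produces it."""

    def __init__(self, path: Path, producer: str):
        super().__init__(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
        self.producer = producer


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class PipelineRunner:
    """Executes stages against an output directory of artifacts."""

    def __init__(self, config: PipelineConfig, outdir: str | Path | None = None):
        self.config = config
        self.outdir = Path(outdir if outdir is not None else config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ paths
    def path(self, name: str) -> Path:
        return self.outdir / name

    _PRODUCERS = {
        "genotypes.tsv": "simulate",
        "phenotypes.csv": "simulate",
        "microbiome.tsv": "simulate",
        "fatty_acids.csv": "simulate",
        "alr.tsv": "coda",
        "alr_reference.csv": "coda",
        "indices.csv": "coda",
        "grm.tsv": "grm",
        "feature_stats.csv": "fit",
        "feature_ebv.csv": "fit",
        "goal_stats.csv": "fit",
        "screening.csv": "screen",
        "screen_counts.json": "screen",
        "network_edges.tsv": "select",
        "clusters.csv": "select",
        "selected_features.txt": "select",
        "rda_pvalues.csv": "select",
        "ebv.csv": "predict",
        "variance_components.json": "predict",
        "ebv_draws.npz": "predict",
        "selection_report.csv": "report",
        "summary.json": "report",
    }

    def _require(self, name: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise MissingArtifactError(p, self._PRODUCERS[name])
        return p

    # ------------------------------------------------------------ input loads
    def _load_phenotypes(self) -> pd.DataFrame:
        src = self.config.phenotype_path or self._require("phenotypes.csv")
        df = pd.read_csv(src, index_col=0)
        df.index = df.index.astype(str)
        if "fixed_level" not in df.columns:
            raise ValueError("phenotype table needs a 'fixed_level' column")
        return df

    def _load_genotypes(self) -> genomics.GenotypeMatrix:
        src = self.config.genotype_path
        if src:
            if str(src).endswith((".vcf", ".vcf.gz")):
                return genomics.read_vcf(src)
            return genomics.read_dosage_tsv(src)
        return genomics.read_dosage_tsv(self._require("genotypes.tsv"))

    def _load_microbiome(self) -> coda.CompositionTable:
        src = self.config.microbiome_path or self._require("microbiome.tsv")
        return coda.CompositionTable.read_tsv(src)

    def _load_alr(self) -> pd.DataFrame:
        df = pd.read_csv(self._require("alr.tsv"), sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return df

    def _load_grm(self) -> genomics.Grm:
        return genomics.Grm.read_tsv(self._require("grm.tsv"))

    # ---------------------------------------------------------------- stages
    def run(self, stages: list[str] | None = None) -> dict:
        todo = list(stages) if stages else list(STAGES)
        unknown = set(todo) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        todo = [s for s in STAGES if s in todo]
        manifest = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "stages": {},
            "artifacts": {},
        }
        for stage in todo:
            t0 = time.time()
            logger.info("stage %s: start", stage)
            produced = getattr(self, f"stage_{stage}")()
            elapsed = time.time() - t0
            logger.info("stage %s: done in %.1fs", stage, elapsed)
            manifest["stages"][stage] = {"elapsed_s": round(elapsed, 3)}
            for name in produced:
                manifest["artifacts"][name] = _sha256(self.path(name))
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest

    def stage_simulate(self) -> list[str]:
        overrides = dict(self.config.simulation)
        overrides.setdefault("seed", stage_seed(self.config.seed, "simulate"))
        spec = SimulationSpec(**overrides)
        pop = simulate_population(spec)
        genomics.write_dosage_tsv(pop.genotypes, self.path("genotypes.tsv"))
        pop.traits.to_csv(self.path("phenotypes.csv"), index_label="animal")
        pop.microbiome.write_tsv(self.path("microbiome.tsv"))
        pop.fatty_acids.write_csv(self.path("fatty_acids.csv"))
        truth = {
            "goal_h2": pop.truth.true_h2,
            "goal_rg": pop.truth.true_rg.to_dict(),
            "feature_h2": dict(
                zip(pop.microbiome.part_ids, map(float, pop.truth.feature_h2))
            ),
            "realized_zero_fraction": float(pop.truth.realized_zero_fraction),
        }
        with open(self.path("truth.json"), "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        return [
            "genotypes.tsv",
            "phenotypes.csv",
            "microbiome.tsv",
            "fatty_acids.csv",
            "truth.json",
        ]

    def stage_coda(self) -> list[str]:
        cfg = self.config
        table = self._load_microbiome()
        core, report = coda.filter_core(table, cfg.min_occupancy, cfg.min_mean_ra)
        logger.info("coda: %d/%d parts retained", report["n_retained"], report["n_in"])
        replaced = coda.replace_zeros_gbm(core)
        ref = coda.select_alr_reference(replaced, epsilon=cfg.alr_epsilon)
        logger.info("coda: alr reference %s", ref.best)
        alr = coda.alr_transform(replaced, ref.best)
        alr.to_frame().to_csv(self.path("alr.tsv"), sep="\t", index_label="sample")
        ref.table.to_csv(self.path("alr_reference.csv"))
        out = ["alr.tsv", "alr_reference.csv"]
        fa_path = self.path("fatty_acids.csv")
        if fa_path.exists():
            fa = coda.FattyAcidTable.read_csv(fa_path)
            coda.compute_fatty_acid_indices(fa).to_csv(
                self.path("indices.csv"), index_label="animal"
            )
            out.append("indices.csv")
        return out

    def stage_grm(self) -> list[str]:
        cfg = self.config
        geno = self._load_genotypes()
        filtered, report = genomics.qc_filter(
            geno,
            snp_call_rate=cfg.snp_call_rate,
            hwe_p_cut=cfg.hwe_p_cut,
            maf_cut=cfg.maf_cut,
            animal_call_rate=cfg.animal_call_rate,
        )
        logger.info("grm: QC report %s", report)
        imputed = genomics.mean_impute(filtered)
        grm = genomics.compute_grm_vanraden2(imputed, ridge_epsilon=cfg.grm_ridge)
        grm.write_tsv(self.path("grm.tsv"))
        return ["grm.tsv"]

    def stage_fit(self) -> list[str]:
        cfg = self.config
        alr = self._load_alr()
        grm = self._load_grm()
        pheno = self._load_phenotypes()
        common = [a for a in alr.index if a in pheno.index and a in grm.animal_ids]
        alr = alr.loc[common]
        pheno = pheno.loc[common]
        fixed = pheno["fixed_level"]
        goals = [g for g in cfg.goal_traits if g in pheno.columns]
        if set(goals) != set(cfg.goal_traits):
            raise ValueError("phenotype table lacks some goal traits")
        feat_rows, ebv_cols, goal_rows = [], {}, []
        for feat in alr.columns:
            ccfg = cfg.chain_config("fit", feat)
            full = GBLUP(alr[[feat]], grm, fixed).fit(ccfg)
            reduced = GBLUP(alr[[feat]], grm, fixed, include_genomic=False).fit(ccfg)
            h2d = full.heritability_draws(feat)
            lo, hi = hpd_interval(h2d)
            feat_rows.append(
                {
                    "feature": feat,
                    "h2": float(h2d.mean()),
                    "h2_low": lo,
                    "h2_high": hi,
                    "dic_diff": full.dic() - reduced.dic(),
                    "bf": bayes_factor(full, reduced),
                    "log_bf": log_bayes_factor(full, reduced),
                }
            )
            ebv_cols[feat] = full.ebv[feat]
            for goal in goals:
                bcfg = cfg.chain_config("fit", f"{feat}|{goal}")
                biv = GBLUP(
                    pd.concat([alr[[feat]], pheno[[goal]]], axis=1), grm, fixed
                ).fit(bcfg)
                rgd = biv.genomic_correlation_draws(feat, goal)
                glo, ghi = hpd_interval(rgd)
                goal_rows.append(
                    {
                        "feature": feat,
                        "goal": goal,
                        "rg": float(rgd.mean()),
                        "rg_low": glo,
                        "rg_high": ghi,
                        "p0": p0_sign_probability(rgd),
                    }
                )
        pd.DataFrame(feat_rows).set_index("feature").to_csv(self.path("feature_stats.csv"))
        pd.DataFrame(ebv_cols).to_csv(self.path("feature_ebv.csv"), index_label="animal")
        pd.DataFrame(goal_rows).to_csv(self.path("goal_stats.csv"), index=False)
        return ["feature_stats.csv", "feature_ebv.csv", "goal_stats.csv"]

    def stage_screen(self) -> list[str]:
        cfg = self.config
        feat = pd.read_csv(self._require("feature_stats.csv"), index_col=0)
        goal = pd.read_csv(self._require("goal_stats.csv"))
        goal_stats = {
            g: sub.set_index("feature")[["rg", "rg_low", "rg_high", "p0"]]
            for g, sub in goal.groupby("goal")
        }
        result = screening.screen_features(
            feat,
            goal_stats,
            alpha=cfg.bf_alpha,
            p0_cut=cfg.p0_cut,
            dic_cut=cfg.dic_cut,
        )
        result.write_csv(self.path("screening.csv"))
        counts = result.counts()
        counts["bf_threshold"] = result.bf_threshold
        counts["pi0"] = result.pi0
        with open(self.path("screen_counts.json"), "w") as fh:
            json.dump(counts, fh, indent=2, sort_keys=True)
        logger.info("screen: %s", counts)
        return ["screening.csv", "screen_counts.json"]

    def stage_select(self) -> list[str]:
        cfg = self.config
        screen = pd.read_csv(self._require("screening.csv"), index_col=0)
        alr = self._load_alr()
        pheno = self._load_phenotypes()
        micro = self._load_microbiome()
        ebv = pd.read_csv(self._require("feature_ebv.csv"), index_col=0)
        ebv.index = ebv.index.astype(str)

        goals = cfg.goal_traits
        sig_cols = [f"sig_{g}" for g in goals]
        sig_any = screen[sig_cols].any(axis=1)
        same_sign = list(screen.index[sig_any & screen["same_sign"]])
        logger.info("select: %d significant same-sign candidates", len(same_sign))

        # co-abundance network on pre-corrected alr abundances
        fixed = pheno.loc[alr.index, "fixed_level"]
        resid, _ = network.precorrect_phenotypes(alr, fixed)
        graph = network.build_network(
            resid[same_sign] if same_sign else resid, r_threshold=cfg.r_threshold
        )
        graph.write_edge_tsv(self.path("network_edges.tsv"))
        if graph.graph.number_of_nodes():
            clusters = network.mcl_cluster(
                graph, inflation=cfg.mcl_inflation, min_cluster_size=cfg.min_cluster_size
            )
            clusters.write_csv(self.path("clusters.csv"))
        else:
            pd.Series(dtype=object, name="cluster").to_csv(
                self.path("clusters.csv"), index_label="node"
            )

        candidates = network.abundance_filter(same_sign, micro, cfg.abundance_floor)
        logger.info("select: %d candidates pass the abundance floor", len(candidates))
        mode = "significant-same-sign"
        if not candidates:
            # Graceful degradation for small datasets: when no feature clears
            # the goal-significance bar, fall back to the host-genomically
            # influenced (HGFC) features so an index can still be formed.
            # Thresholds are never relaxed; the fallback is recorded below.
            hgfc = list(screen.index[screen["hgfc"].astype(bool)])
            fallback = network.abundance_filter(hgfc, micro, cfg.abundance_floor) or hgfc
            if fallback:
                mode = "fallback-hgfc"
                same_sign, candidates = hgfc, fallback
                logger.warning(
                    "select: no significant same-sign candidate; falling back "
                    "to %d HGFC features",
                    len(candidates),
                )
        if candidates and len(candidates) < len(ebv):
            retained, pvals = network.rda_redundancy_select(
                ebv[same_sign],
                ebv[candidates],
                alpha=cfg.rda_alpha,
                n_perm=cfg.rda_n_perm,
                seed=stage_seed(cfg.seed, "select", "rda"),
            )
            if not retained:
                # all candidates mutually redundant: keep the single best
                retained = [pvals.idxmin()]
                mode += "+keep-best-redundant"
        else:
            retained, pvals = candidates, pd.Series(dtype=float, name="p_value")
        pvals.to_csv(self.path("rda_pvalues.csv"), index_label="feature")
        self.path("selected_features.txt").write_text("\n".join(retained) + "\n")
        with open(self.path("selection_meta.json"), "w") as fh:
            json.dump(
                {
                    "mode": mode,
                    "n_same_sign": len(same_sign),
                    "n_abundance_filtered": len(candidates),
                    "n_retained": len(retained),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        logger.info("select: %d features retained (%s)", len(retained), mode)
        return [
            "network_edges.tsv",
            "clusters.csv",
            "rda_pvalues.csv",
            "selected_features.txt",
            "selection_meta.json",
        ]

    def stage_predict(self) -> list[str]:
        cfg = self.config
        selected = [
            s
            for s in self._require("selected_features.txt").read_text().splitlines()
            if s
        ]
        if not selected:
            raise ValueError("no selected features; nothing to predict from")
        alr = self._load_alr()
        grm = self._load_grm()
        pheno = self._load_phenotypes()
        fixed = pheno.loc[alr.index, "fixed_level"]
        goals = cfg.goal_traits
        cols = selected + goals
        endog_all = pd.concat([alr[selected], pheno.loc[alr.index, goals]], axis=1)

        rows = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                a, b = cols[i], cols[j]
                ccfg = cfg.chain_config("predict", f"{a}|{b}")
                res = GBLUP(endog_all[[a, b]], grm, fixed).fit(ccfg)
                ch = res.chain
                rows.append(
                    {
                        "trait_a": a,
                        "trait_b": b,
                        "cov_g": float(ch.sigma_g_draws(a, b).mean()),
                        "var_g_a": float(ch.sigma_g_draws(a, a).mean()),
                        "var_g_b": float(ch.sigma_g_draws(b, b).mean()),
                        "cov_e": float(ch.sigma_e_draws(a, b).mean()),
                        "var_e_a": float(ch.sigma_e_draws(a, a).mean()),
                        "var_e_b": float(ch.sigma_e_draws(b, b).mean()),
                    }
                )
        vc = breeding.assemble_covariance(pd.DataFrame(rows)).bend(cfg.bending_tolerance)
        with open(self.path("variance_components.json"), "w") as fh:
            json.dump(
                {
                    "trait_ids": vc.trait_ids,
                    "sigma_g": vc.sigma_g.tolist(),
                    "sigma_e": vc.sigma_e.tolist(),
                    "bending": vc.bending_log,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        result = breeding.predict_goal_ebvs(
            alr[selected],
            grm,
            vc,
            fixed,
            goals,
            config=cfg.chain_config("predict", "ebv"),
        )
        result.write_csv(self.path("ebv.csv"))
        np.savez(
            self.path("ebv_draws.npz"),
            animal_ids=np.array(result.animal_ids),
            **{f"draws_{t}": d for t, d in result.ebv_draws.items()},
        )
        return ["variance_components.json", "ebv.csv", "ebv_draws.npz"]

    def stage_report(self) -> list[str]:
        cfg = self.config
        pheno = self._load_phenotypes()
        ebv_long = pd.read_csv(self._require("ebv.csv"))
        draws_npz = np.load(self._require("ebv_draws.npz"), allow_pickle=False)
        animal_ids = [str(a) for a in draws_npz["animal_ids"]]
        goals = cfg.goal_traits
        ebv_mean = ebv_long.pivot(index="animal", columns="trait", values="ebv")
        ebv_mean.index = ebv_mean.index.astype(str)
        ebv_mean = ebv_mean.loc[animal_ids, goals]
        ranking = breeding.aggregate_rank(ebv_mean)
        rows = []
        for p in cfg.selection_proportions:
            for goal in goals:
                res = breeding.response_to_selection(
                    draws_npz[f"draws_{goal}"],
                    ranking,
                    animal_ids,
                    p,
                    phenotypic_sd=float(pheno[goal].std(ddof=1)),
                )
                res.pop("selected")
                res["trait"] = goal
                rows.append(res)
        table = pd.DataFrame(rows)[
            ["trait", "proportion", "intensity", "n_selected", "response_mean", "response_sd"]
        ]
        table.to_csv(self.path("selection_report.csv"), index=False)
        acc = ebv_long.groupby("trait")["accuracy"].mean().to_dict()
        summary = {
            "n_animals": len(animal_ids),
            "goal_traits": goals,
            "mean_accuracy": {k: float(v) for k, v in acc.items()},
            "ranking_top10": ranking[:10],
        }
        with open(self.path("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return ["selection_report.csv", "summary.json"]


def run_pipeline(
    config: PipelineConfig,
    stages: list[str] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the requested stages (all by default) and return the manifest."""
    return PipelineRunner(config, outdir).run(stages)


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("microbreed")
    root.handlers[:] = [handler]
    root.setLevel(logging.INFO if verbose else logging.WARNING)
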