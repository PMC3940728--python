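"""End-to-end orchestration: QC -> GRM/REML per age -> scans at the most
heritable ages -> genomic control -> clumping -> permutation null -> report.

A run is driven by a single YAML document (see :class:`RunConfig`). Every
stage persists its artifact under the output directory together with a
state file carrying the config hash and seed; re-running a completed stage
is a no-op unless forced, and a failed stage leaves a resumable state.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genio
from .assoc import genomic_control, gwas_scan
from .clump import ClumpedRegion, clump_region, select_index_snps
from .data import GeneSet, GenotypeMatrix, PhenotypePanel
from .genio import QcThresholds, qc_filter
from .grm import compute_grm, read_grm, write_grm
from .permutation import PermutationSpec, run_permutation_null
from .reml import reml_bivariate, reml_univariate
from .sim import SimConfig, simulate_gene_annotation, simulate_genotypes, simulate_phenotype_panel
from .transform import adjust_and_rank_transform

log = logging.getLogger("countgwas")

STAGES = ["simulate", "qc", "grm", "reml", "scan", "clump", "permute", "report"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration; exactly one of ``sim`` (a generator
    block) or ``inputs`` (paths to genotype/phenotype/gene files)."""

    output_dir: Path
    seed: int = 0
    sim: SimConfig | None = None
    inputs: dict | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    scan_ages: int = 2
    clump_window_kb: float = 500.0
    clump_r2: float = 0.3
    permutation_S: int = 100
    permutation_thresholds: tuple[float, ...] | None = None
    n_genes: int = 400
    candidate_fraction: float = 0.02
    mean_gene_len_bp: float = 50_000.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'sim' or 'inputs' must be configured")
        if self.scan_ages < 1:
            raise ConfigError("scan_ages must be >= 1")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ConfigError("clump r2 must be in [0, 1]")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "RunConfig":
        try:
            kw = dict(raw)
            if seed is not None:
                kw["seed"] = seed
            if "sim" in kw and kw["sim"] is not None:
                sim = dict(kw["sim"])
                sim.setdefault("seed", kw.get("seed", 0))
                for key in ("timepoints", "h2_by_timepoint", "maf_range", "impute_r2_range"):
                    if key in sim and isinstance(sim[key], list):
                        sim[key] = tuple(sim[key])
                kw["sim"] = SimConfig(**sim)
            if "qc" in kw and kw["qc"] is not None:
                kw["qc"] = QcThresholds(**kw["qc"])
            clump = kw.pop("clump", None)
            if clump:
                kw["clump_window_kb"] = clump.get("window_kb", 500.0)
                kw["clump_r2"] = clump.get("r2_max", 0.3)
            perm = kw.pop("permutation", None)
            if perm:
                kw["permutation_S"] = perm.get("S", 100)
                thr = perm.get("thresholds")
                kw["permutation_thresholds"] = tuple(thr) if thr else None
            genes = kw.pop("genes", None)
            if genes:
                kw["n_genes"] = genes.get("n_genes", 400)
                kw["candidate_fraction"] = genes.get("candidate_fraction", 0.02)
                kw["mean_gene_len_bp"] = genes.get("mean_len_bp", 50_000.0)
            return cls(**kw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def canonical(self) -> dict:
        d = {
            "seed": self.seed,
            "sim": None if self.sim is None else {
                k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                for k, v in vars(self.sim).items()
            },
            "inputs": self.inputs,
            "qc": vars(self.qc),
            "scan_ages": self.scan_ages,
            "clump_window_kb": self.clump_window_kb,
            "clump_r2": self.clump_r2,
            "permutation_S": self.permutation_S,
            "permutation_thresholds": (
                list(self.permutation_thresholds) if self.permutation_thresholds else None
            ),
            "n_genes": self.n_genes,
            "candidate_fraction": self.candidate_fraction,
            "mean_gene_len_bp": self.mean_gene_len_bp,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _regions_to_tsv(regions: dict[str, ClumpedRegion], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "index_snp": r.index_snp,
                "chr": r.chrom,
                "start": r.start_bp,
                "end": r.end_bp,
                "n_members": len(r.members),
                "members": ",".join(r.members),
            }
            for r in regions.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def _regions_from_tsv(path: Path) -> dict[str, ClumpedRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    return {
        row.index_snp: ClumpedRegion(
            index_snp=row.index_snp,
            chrom=str(row.chr),
            start_bp=int(row.start),
            end_bp=int(row.end),
            members=str(row.members).split(","),
        )
        for row in df.itertuples()
    }


class Pipeline:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = cfg.output_dir
        self.out.mkdir(parents=True, exist_ok=True)
        self.state_path = self.out / "state.json"
        self.state = self._load_state()
        logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    # -- state ------------------------------------------------------------
    def _load_state(self) -> dict:
        if self.state_path.exists():
            state = json.loads(self.state_path.read_text())
            if state.get("config_hash") == self.cfg.config_hash():
                return state
        return {"config_hash": self.cfg.config_hash(), "seed": self.cfg.seed, "completed": []}

    def _mark(self, stage: str) -> None:
        if stage not in self.state["completed"]:
            self.state["completed"].append(stage)
        self.state_path.write_text(json.dumps(self.state, indent=2, sort_keys=True))

    def _done(self, stage: str, force: bool) -> bool:
        return (not force) and stage in self.state["completed"]

    # -- stages -----------------------------------------------------------
    def stage_simulate(self, force: bool = False):
        gpath = self.out / "genotypes.dosage.tsv"
        ppath = self.out / "phenotypes.tsv"
        bpath = self.out / "genes.bed"
        if self.cfg.sim is None:
            inp = self.cfg.inputs
            G = genio.read_genotypes(inp["genotypes"], inp.get("genotype_format", "plink-bed"))
            panel = genio.read_phenotypes(inp["phenotypes"], inp["timepoints"])
            genes = genio.read_gene_bed(inp["genes"])
            return G, panel, genes
        if self._done("simulate", force):
            G = genio.read_genotypes(gpath, "dosage-tsv")
            panel = genio.read_phenotypes(ppath, list(self.cfg.sim.timepoints))
            genes = genio.read_gene_bed(bpath)
            log.info("simulate: reused %d SNPs x %d individuals", G.n_snps, G.n_individuals)
            return G, panel, genes
        G = simulate_genotypes(self.cfg.sim)
        panel = simulate_phenotype_panel(G, self.cfg.sim)
        genes = simulate_gene_annotation(
            self.cfg.sim, self.cfg.n_genes, self.cfg.candidate_fraction,
            self.cfg.mean_gene_len_bp,
        )
        genio.write_dosage_tsv(G, gpath)
        genio.write_phenotypes(panel, ppath)
        genio.write_gene_bed(genes, bpath)
        self._mark("simulate")
        log.info("simulate: %d SNPs x %d individuals, %d genes",
                 G.n_snps, G.n_individuals, len(genes))
        return G, panel, genes

    def stage_qc(self, G: GenotypeMatrix, force: bool = False) -> GenotypeMatrix:
        rpath = self.out / "qc_report.tsv"
        G_qc, report = qc_filter(G, self.cfg.qc)
        report.to_csv(rpath, sep="\t", index=False)
        self._mark("qc")
        log.info("qc: %d of %d SNPs retained", G_qc.n_snps, G.n_snps)
        return G_qc

    def stage_grm(self, G: GenotypeMatrix, force: bool = False):
        prefix = self.out / "grm"
        if self._done("grm", force) and (self.out / "grm.grm.bin").exists():
            grm = read_grm(prefix)
            log.info("grm: reused %d x %d", grm.n, grm.n)
            return grm
        grm = compute_grm(G)
        write_grm(grm, prefix)
        self._mark("grm")
        log.info("grm: %d individuals, mean diagonal %.3f",
                 grm.n, float(np.mean(np.diag(grm.values))))
        return grm

    def stage_reml(self, grm, panel: PhenotypePanel, force: bool = False) -> pd.DataFrame:
        rows = []
        for t in panel.timepoints:
            y = panel.scores(t)
            X = panel.covariates(t)
            z = adjust_and_rank_transform(y, X)
            fit = reml_univariate(grm, z)
            rows.append(
                {
                    "age": t,
                    "h2": fit.h2,
                    "se_h2": fit.se_h2,
                    "var_g": fit.var_g,
                    "var_e": fit.var_e,
                    "lrt": fit.lrt_stat,
                    "lrt_df": fit.lrt_df,
                    "p_value": fit.p_value,
                    "n": fit.n,
                }
            )
            log.info("reml: age %s h2=%.3f (SE %.3f) n=%d", t, fit.h2, fit.se_h2, fit.n)
        df = pd.DataFrame(rows)
        df.to_csv(self.out / "reml.tsv", sep="\t", index=False)
        self._mark("reml")
        return df

    def stage_scan(self, G, panel, reml_table: pd.DataFrame, force: bool = False):
        chosen = (
            reml_table.sort_values("h2", ascending=False)["age"]
            .head(self.cfg.scan_ages)
            .tolist()
        )
        chosen = sorted(chosen)
        scans: dict[float, pd.DataFrame] = {}
        lambdas: dict[float, float] = {}
        for t in chosen:
            table = gwas_scan(G, panel, t)
            gc, table = genomic_control(table)
            lambdas[t] = gc.lambda_gc
            scans[t] = table
            table.to_csv(self.out / f"assoc_age{PhenotypePanel._label(t)}.tsv",
                         sep="\t", index=False)
            log.info("scan: age %s, %d SNPs, lambda_GC=%.3f", t, len(table), gc.lambda_gc)
        self._mark("scan")
        return chosen, scans, lambdas

    def stage_clump(self, G, scans: dict, force: bool = False):
        # prune on the scan with the most strongly associated single signal
        best_age = min(scans, key=lambda t: float(np.nanmin(scans[t]["p_gc"])))
        index_set = select_index_snps(
            scans[best_age], G, window_kb=self.cfg.clump_window_kb, r2_max=self.cfg.clump_r2
        )
        index_set.index_snps.to_csv(self.out / "index_snps.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(index_set.assignment.items()), columns=["snp_id", "index_snp"]
        ).to_csv(self.out / "clump_membership.tsv", sep="\t", index=False)
        regions = {
            sid: clump_region(sid, G, window_kb=self.cfg.clump_window_kb,
                              r2_min=self.cfg.clump_r2)
            for sid in index_set.snp_ids
        }
        _regions_to_tsv(regions, self.out / "regions.tsv")
        self._mark("clump")
        log.info("clump: %d index SNPs (pruned on age %s)", len(index_set.snp_ids), best_age)
        return best_age, index_set, regions

    def stage_permute(self, G, panel, genes, scans, index_set, regions, force: bool = False):
        idx = [G.snp_index(s) for s in index_set.snp_ids]
        G_index = G.take_snps(np.sort(idx))
        if self.cfg.permutation_thresholds is not None:
            thresholds = self.cfg.permutation_thresholds
        else:
            # observed analogue of the study's construction: the GC-corrected
            # p-value of the strongest observed signal is the threshold
            thresholds = (float(min(np.nanmin(s["p_gc"]) for s in scans.values())),)
        spec = PermutationSpec(
            S=self.cfg.permutation_S,
            thresholds=thresholds,
            timepoints=tuple(scans.keys()),
            seed=self.cfg.seed,
        )
        result = run_permutation_null(G_index, panel, spec, regions, genes)
        result.write_json(self.out / "permutation.json")
        result.write_minima_tsv(self.out / "permutation_minima.tsv")
        self._mark("permute")
        log.info("permute: S=%d completed, %d failures", result.S_completed, result.n_failures)
        return result


def run_pipeline(cfg: RunConfig, force: bool = False, stop_after: str | None = None) -> dict:
    """Execute the full analysis; returns the machine-readable run report
    (also written to ``<output_dir>/report.json``)."""
    pipe = Pipeline(cfg)
    stage = "simulate"
    try:
        G_raw, panel, genes = pipe.stage_simulate(force)
        if stop_after == "simulate":
            return {"stopped_after": "simulate"}
        stage = "qc"
        G = pipe.stage_qc(G_raw, force)
        if stop_after == "qc":
            return {"stopped_after": "qc"}
        stage = "grm"
        grm = pipe.stage_grm(G, force)
        if stop_after == "grm":
            return {"stopped_after": "grm"}
        stage = "reml"
        reml_table = pipe.stage_reml(grm, panel, force)
        if stop_after == "reml":
            return {"stopped_after": "reml"}
        stage = "scan"
        chosen, scans, lambdas = pipe.stage_scan(G, panel, reml_table, force)
        if stop_after == "scan":
            return {"stopped_after": "scan"}
        stage = "clump"
        best_age, index_set, regions = pipe.stage_clump(G, scans, force)
        if stop_after == "clump":
            return {"stopped_after": "clump"}
        stage = "permute"
        perm = pipe.stage_permute(G, panel, genes, scans, index_set, regions, force)
        stage = "report"
        lead = {}
        for t, s in scans.items():
            best = s.loc[s["p_gc"].idxmin()]
            lead[str(t)] = {
                "snp_id": str(best["snp_id"]),
                "beta": float(best["beta"]),
                "se": float(best["se"]),
                "p_gc": float(best["p_gc"]),
            }
        report = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "n_snps_input": int(G_raw.n_snps),
            "n_snps_qc": int(G.n_snps),
            "n_individuals": int(G.n_individuals),
            "heritability": reml_table.to_dict(orient="records"),
            "scan_ages": [float(t) for t in chosen],
            "lambda_gc": {str(t): float(v) for t, v in lambdas.items()},
            "lead_snps": lead,
            "clump_age": float(best_age),
            "n_index_snps": int(len(index_set.snp_ids)),
            "permutation": perm.to_dict(),
        }
        (cfg.output_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        pipe._mark("report")
        return report
    except StageError:
        raise
    except Exception as exc:  # persist resumable state, then surface stage name
        pipe.state_path.write_text(json.dumps(pipe.state, indent=2, sort_keys=True))
        raise StageError(stage, exc) from exc


def bivariate_correlations(cfg: RunConfig) -> pd.DataFrame:
    """All pairwise genetic/residual correlations between time-points
    (run after the univariate stages; reuses persisted artifacts)."""
    pipe = Pipeline(cfg)
    G_raw, panel, _ = pipe.stage_simulate()
    G = pipe.stage_qc(G_raw)
    grm = pipe.stage_grm(G)
    z = {
        t: adjust_and_rank_transform(panel.scores(t), panel.covariates(t))
        for t in panel.timepoints
    }
    rows = []
    ts = panel.timepoints
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            fit = reml_bivariate(grm, z[ts[i]], z[ts[j]])
            rows.append(
                {
                    "age1": ts[i],
                    "age2": ts[j],
                    "rg": fit.rg,
                    "se_rg": fit.se_rg,
                    "re": fit.re,
                    "se_re": fit.se_re,
                    "n": fit.n,
                    "converged": fit.converged,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(cfg.output_dir / "bivariate.tsv", sep="\t", index=False)
    return df
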