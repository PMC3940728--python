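"""Joint-permutation empirical significance and candidate-gene co-location.

The multi-age phenotype record of each individual (scores and ages at every
time-point) is relabelled as a single vector against the genotype + sex +
ancestry record, which preserves the cross-age phenotypic correlation under
the null of no genotype-phenotype association. For each permutation the
index-SNP panel is rescanned at every configured age, genomic control is
re-estimated within the permuted scan, and the minimum GC-corrected p-value
over all index SNPs and ages is recorded. The familywise empirical p-value
at a threshold is the fraction of permutations whose minimum beats it; the
co-location p additionally requires a passing SNP whose precomputed clumped
region overlaps at least one candidate gene (joint event; the conditional
version is also reported).

Per-permutation seeds are spawned from the master seed by counter, so
chunked and single-run executions produce identical counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import genomic_control, gwas_scan
from .clump import ClumpedRegion, region_overlaps_genes
from .data import GeneSet, GenotypeMatrix, PhenotypePanel


def binomial_se(p_hat: float, S: int) -> float:
    """Binomial standard error sqrt(p(1-p)/S) of an empirical proportion."""
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must be in [0, 1]")
    if S < 1:
        raise ValueError("S must be >= 1")
    return float(np.sqrt(p_hat * (1.0 - p_hat) / S))


@dataclass
class PermutationSpec:
    S: int = 1000
    thresholds: tuple[float, ...] = (9.3e-9, 7.9e-8)
    timepoints: tuple[float, ...] = (8.0, 17.0)
    seed: int = 0
    candidate_only: bool = True
    reestimate_gc: bool = True
    small_sample_correction: bool = False  # (k+1)/(S+1) estimator
    scores_only: bool = False              # permute scores, leave ages in place

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if any(not (0.0 < t < 1.0) for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")


def permute_panel(
    panel: PhenotypePanel,
    seed_or_rng,
    scores_only: bool = False,
) -> PhenotypePanel:
    """One joint relabelling of the per-individual phenotype records.

    Scores (and, unless ``scores_only``, ages at measurement) at all
    time-points travel together; sex and the ancestry covariates stay with
    the genotype record. Per-age score multisets are preserved exactly.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    perm = rng.permutation(panel.n_individuals)
    table = panel.table.copy()
    cols = []
    for t in panel.timepoints:
        cols.append(panel.score_col(t))
        if not scores_only:
            cols.append(panel.age_col(t))
    table[cols] = table[cols].to_numpy()[perm]
    return PhenotypePanel(table=table, timepoints=list(panel.timepoints))


@dataclass
class PermutationResult:
    spec: PermutationSpec
    k_exceed: dict[float, int]
    k_coloc: dict[float, int]
    per_perm_min_p: np.ndarray = field(repr=False)
    n_failures: int = 0
    failure_flag: bool = False

    @property
    def S_completed(self) -> int:
        return int(self.per_perm_min_p.size)

    def empirical_p(self, threshold: float) -> float:
        k = self.k_exceed[threshold]
        if self.spec.small_sample_correction:
            return (k + 1) / (self.S_completed + 1)
        return k / self.S_completed

    def empirical_p_coloc(self, threshold: float) -> float:
        k = self.k_coloc[threshold]
        if self.spec.small_sample_correction:
            return (k + 1) / (self.S_completed + 1)
        return k / self.S_completed

    def empirical_p_coloc_conditional(self, threshold: float) -> float:
        ke = self.k_exceed[threshold]
        return self.k_coloc[threshold] / ke if ke > 0 else float("nan")

    def to_dict(self) -> dict:
        S = self.S_completed
        return {
            "S": S,
            "seed": self.spec.seed,
            "timepoints": list(self.spec.timepoints),
            "n_failures": self.n_failures,
            "failure_flag": self.failure_flag,
            "thresholds": [
                {
                    "threshold": thr,
                    "k_exceed": self.k_exceed[thr],
                    "k_coloc": self.k_coloc[thr],
                    "empirical_p": self.empirical_p(thr),
                    "se_empirical_p": binomial_se(self.k_exceed[thr] / S, S),
                    "empirical_p_coloc": self.empirical_p_coloc(thr),
                    "se_empirical_p_coloc": binomial_se(self.k_coloc[thr] / S, S),
                    "empirical_p_coloc_conditional": self.empirical_p_coloc_conditional(thr),
                }
                for thr in self.spec.thresholds
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def write_minima_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"perm": np.arange(self.per_perm_min_p.size), "min_p_gc": self.per_perm_min_p}
        ).to_csv(path, sep="\t", index=False)


def _perm_rng(master_seed: int, perm_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(perm_index,))
    )


def _one_permutation(
    s: int,
    G_index: GenotypeMatrix,
    panel: PhenotypePanel,
    spec: PermutationSpec,
    regions: dict[str, ClumpedRegion],
    genes: GeneSet,
):
    permuted = permute_panel(panel, _perm_rng(spec.seed, s), scores_only=spec.scores_only)
    min_p = np.inf
    per_snp_min = np.full(G_index.n_snps, np.inf)
    for age in spec.timepoints:
        table = gwas_scan(G_index, permuted, age)
        if spec.reestimate_gc:
            _, table = genomic_control(table)
            pcol = "p_gc"
        else:
            pcol = "p"
        pv = table[pcol].to_numpy(dtype=float)
        pv = np.where(np.isfinite(pv), pv, np.inf)
        per_snp_min = np.minimum(per_snp_min, pv)
        min_p = min(min_p, float(pv.min()))
    snp_ids = G_index.snp_map["snp_id"].to_numpy()
    hits = {}
    for thr in spec.thresholds:
        passing = snp_ids[per_snp_min <= thr]
        exceed = passing.size > 0
        coloc = False
        if exceed:
            for sid in passing:
                region = regions.get(str(sid))
                if region is None:
                    continue
                flag, _ = region_overlaps_genes(
                    region, genes, candidate_only=spec.candidate_only
                )
                if flag:
                    coloc = True
                    break
        hits[thr] = (exceed, coloc)
    return min_p, hits


def run_permutation_null(
    G_index: GenotypeMatrix,
    panel: PhenotypePanel,
    spec: PermutationSpec,
    regions: dict[str, ClumpedRegion],
    genes: GeneSet,
    perm_range: tuple[int, int] | None = None,
) -> PermutationResult:
    """Execute permutations ``perm_range`` (default ``(0, spec.S)``) and
    count threshold exceedances and candidate-gene co-locations.

    ``G_index`` must be restricted to the observed-data index SNPs and
    ``regions`` precomputed for them; both stay fixed across permutations.
    Results from disjoint chunks sharing the master seed can be combined
    with :func:`combine_results` and equal the single-run counts exactly.
    """
    lo, hi = perm_range if perm_range is not None else (0, spec.S)
    k_exceed = {thr: 0 for thr in spec.thresholds}
    k_coloc = {thr: 0 for thr in spec.thresholds}
    minima = []
    n_fail = 0
    for s in range(lo, hi):
        try:
            min_p, hits = _one_permutation(s, G_index, panel, spec, regions, genes)
        except Exception:
            n_fail += 1
            continue
        minima.append(min_p)
        for thr, (exceed, coloc) in hits.items():
            k_exceed[thr] += int(exceed)
            k_coloc[thr] += int(coloc)
    return PermutationResult(
        spec=spec,
        k_exceed=k_exceed,
        k_coloc=k_coloc,
        per_perm_min_p=np.array(minima),
        n_failures=n_fail,
        failure_flag=n_fail > 0.01 * spec.S,
    )


def combine_results(chunks: list[PermutationResult]) -> PermutationResult:
    """Merge chunked runs that share spec and master seed."""
    if not chunks:
        raise ValueError("no chunks to combine")
    spec = chunks[0].spec
    k_exceed = {thr: sum(c.k_exceed[thr] for c in chunks) for thr in spec.thresholds}
    k_coloc = {thr: sum(c.k_coloc[thr] for c in chunks) for thr in spec.thresholds}
    return PermutationResult(
        spec=spec,
        k_exceed=k_exceed,
        k_coloc=k_coloc,
        per_perm_min_p=np.concatenate([c.per_perm_min_p for c in chunks]),
        n_failures=sum(c.n_failures for c in chunks),
        failure_flag=sum(c.n_failures for c in chunks) > 0.01 * spec.S,
    )
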