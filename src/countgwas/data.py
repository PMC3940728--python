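"""Core in-memory containers shared across the pipeline.

Genotypes are held as an individuals x SNPs dosage matrix (effect-allele
counts in [0, 2], ``NaN`` for missing) plus a per-SNP map; phenotypes as a
wide per-individual table with one (age, score) pair per time-point; gene
annotations as 0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_MAP_COLUMNS = ["snp_id", "chrom", "bp", "ea", "oa", "impute_r2"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix with per-SNP map metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_individuals, n_snps)
        Effect-allele dosages in [0, 2]; ``NaN`` marks missing calls.
    snp_map : DataFrame
        Columns ``snp_id, chrom, bp, ea, oa, impute_r2``; ``bp`` is 1-based
        and strictly increasing within each chromosome.
    sample_ids : list of str
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs matrix")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snp_map) != m:
            raise ValueError(f"{len(self.snp_map)} snp_map rows for {m} SNP columns")
        missing = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing:
            raise ValueError(f"snp_map lacks columns {missing}")
        self.snp_map = self.snp_map.reset_index(drop=True)
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError("bp positions must be strictly increasing within chromosome")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(self.dosages, initial=0.0) > 2 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Effect-allele frequency per SNP from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            snp_map=self.snp_map.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            snp_map=self.snp_map.copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def snp_index(self, snp_id: str) -> int:
        pos = self.snp_map.index[self.snp_map["snp_id"] == snp_id]
        if len(pos) == 0:
            raise KeyError(f"unknown SNP {snp_id!r}")
        return int(pos[0])


@dataclass
class PhenotypePanel:
    """Longitudinal count-phenotype table.

    ``table`` is wide: one row per individual with columns ``id, sex, pc1,
    pc2`` plus ``age_<t>`` (age at measurement, years) and ``score_<t>``
    (non-negative integer count) for every time-point label ``t``. Missing
    measurements are ``NaN``. ``latent`` and ``genetic_values`` carry the
    simulated ground-truth liabilities when the panel comes from the
    generator (``None`` for real data).
    """

    table: pd.DataFrame
    timepoints: list[float]
    latent: np.ndarray | None = None
    genetic_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        for col in ("id", "sex", "pc1", "pc2"):
            if col not in self.table.columns:
                raise ValueError(f"phenotype table lacks column {col!r}")
        for t in self.timepoints:
            for col in (self.age_col(t), self.score_col(t)):
                if col not in self.table.columns:
                    raise ValueError(f"phenotype table lacks column {col!r}")
            s = self.table[self.score_col(t)]
            ok = s.dropna()
            if len(ok) and (np.any(ok < 0) or np.any(ok != np.round(ok))):
                raise ValueError("scores must be non-negative integers")
        self.table = self.table.reset_index(drop=True)

    @staticmethod
    def _label(t: float) -> str:
        return str(int(t)) if float(t) == int(t) else str(t)

    def age_col(self, t: float) -> str:
        return f"age_{self._label(t)}"

    def score_col(self, t: float) -> str:
        return f"score_{self._label(t)}"

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    def scores(self, t: float) -> np.ndarray:
        return self.table[self.score_col(t)].to_numpy(dtype=float)

    def ages(self, t: float) -> np.ndarray:
        return self.table[self.age_col(t)].to_numpy(dtype=float)

    def covariates(self, t: float) -> np.ndarray:
        """Per-age covariate design block: age, sex, pc1, pc2 (n x 4)."""
        return np.column_stack(
            [
                self.ages(t),
                self.table["sex"].to_numpy(dtype=float),
                self.table["pc1"].to_numpy(dtype=float),
                self.table["pc2"].to_numpy(dtype=float),
            ]
        )


@dataclass
class GeneSet:
    """Gene intervals in 0-based half-open coordinates."""

    intervals: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("chrom", "start", "end", "name", "is_candidate")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.intervals.columns]
        if missing:
            raise ValueError(f"gene table lacks columns {missing}")
        if len(self.intervals) and np.any(
            self.intervals["start"].to_numpy() >= self.intervals["end"].to_numpy()
        ):
            raise ValueError("gene intervals require start < end")
        self.intervals = self.intervals.reset_index(drop=True)

    def candidates(self) -> "GeneSet":
        return GeneSet(self.intervals[self.intervals["is_candidate"]].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.intervals)
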