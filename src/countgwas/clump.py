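"""Pairwise LD, greedy index-variant selection and clumped regions.

LD between two markers is the squared Pearson correlation of their dosage
vectors (composite LD; no phasing required). Index selection is
p-value-ordered greedy clumping: the smallest-p unassigned SNP becomes an
index and absorbs every unassigned SNP within the physical window whose
r^2 with it exceeds the threshold. Ties on p break to the smaller genomic
coordinate. Regions span the member SNP positions and are compared to gene
intervals in 0-based half-open coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GeneSet, GenotypeMatrix


def pairwise_r2(G: GenotypeMatrix, i: int | str, j: int | str) -> float:
    """Squared dosage correlation between SNPs ``i`` and ``j`` over shared
    non-missing samples; raises on monomorphic input."""
    i = G.snp_index(i) if isinstance(i, str) else i
    j = G.snp_index(j) if isinstance(j, str) else j
    a, b = G.dosages[:, i], G.dosages[:, j]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("r^2 undefined for a monomorphic SNP")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_vector(G: GenotypeMatrix, i: int, idx: np.ndarray) -> np.ndarray:
    """r^2 of SNP i against each SNP in idx (complete-case per pair;
    vectorised when no calls are missing)."""
    a = G.dosages[:, i]
    B = G.dosages[:, idx]
    if np.isfinite(a).all() and np.isfinite(B).all():
        ac = a - a.mean()
        Bc = B - B.mean(axis=0)
        denom = np.sqrt(np.sum(ac**2) * np.sum(Bc**2, axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, (ac @ Bc) / denom, 0.0)
        return r * r
    out = np.empty(idx.size)
    for k in range(idx.size):
        b = B[:, k]
        ok = np.isfinite(a) & np.isfinite(b)
        av, bv = a[ok], b[ok]
        if av.std() == 0 or bv.std() == 0:
            out[k] = 0.0
        else:
            r = np.corrcoef(av, bv)[0, 1]
            out[k] = r * r
    return out


@dataclass
class IndexSet:
    """Greedy clumping result: ordered index SNPs and the SNP -> index
    assignment (indices map to themselves)."""

    index_snps: pd.DataFrame          # snp_id, chrom, bp, p (selection order)
    assignment: dict[str, str] = field(repr=False, default_factory=dict)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.index_snps["snp_id"])

    def members(self, index_id: str) -> list[str]:
        return [s for s, i in self.assignment.items() if i == index_id]


def select_index_snps(
    table: pd.DataFrame,
    G: GenotypeMatrix,
    window_kb: float = 500.0,
    r2_max: float = 0.3,
    p_column: str = "p_gc",
) -> IndexSet:
    """P-value-ordered greedy reduction to approximately independent index
    variants (window in kb each side, absorb when r^2 > ``r2_max``)."""
    snp_ids = G.snp_map["snp_id"].to_numpy()
    chrom = G.snp_map["chrom"].to_numpy()
    bp = G.snp_map["bp"].to_numpy(dtype=float)
    tbl = table.set_index("snp_id")
    pvals = tbl.loc[snp_ids, p_column].to_numpy(dtype=float)
    if p_column == "p_gc" and not np.isfinite(pvals).any():
        pvals = tbl.loc[snp_ids, "p"].to_numpy(dtype=float)
    order = np.lexsort((bp, chrom, np.where(np.isfinite(pvals), pvals, np.inf)))
    window_bp = window_kb * 1000.0
    assigned = np.zeros(len(snp_ids), dtype=bool)
    assignment: dict[str, str] = {}
    records = []
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        assignment[snp_ids[i]] = snp_ids[i]
        records.append(
            {"snp_id": snp_ids[i], "chrom": chrom[i], "bp": int(bp[i]), "p": pvals[i]}
        )
        near = np.flatnonzero(
            (~assigned)
            & (chrom == chrom[i])
            & (np.abs(bp - bp[i]) <= window_bp)
        )
        if near.size:
            r2 = _r2_vector(G, i, near)
            grab = near[r2 > r2_max]
            assigned[grab] = True
            for j in grab:
                assignment[snp_ids[j]] = snp_ids[i]
    return IndexSet(index_snps=pd.DataFrame(records), assignment=assignment)


def prune_sliding_window(
    G: GenotypeMatrix,
    window_kb: float = 500.0,
    r2_max: float = 0.3,
) -> IndexSet:
    """Association-agnostic pruning: walk SNPs in genomic order, keeping a
    SNP only if its r^2 with every retained SNP inside the window stays at
    or below the threshold. Alternative to p-value-ordered clumping."""
    snp_ids = G.snp_map["snp_id"].to_numpy()
    chrom = G.snp_map["chrom"].to_numpy()
    bp = G.snp_map["bp"].to_numpy(dtype=float)
    window_bp = window_kb * 1000.0
    kept: list[int] = []
    assignment: dict[str, str] = {}
    records = []
    for i in range(len(snp_ids)):
        near = [
            j for j in kept
            if chrom[j] == chrom[i] and abs(bp[j] - bp[i]) <= window_bp
        ]
        absorbed = None
        if near:
            r2 = _r2_vector(G, i, np.array(near))
            hit = np.flatnonzero(r2 > r2_max)
            if hit.size:
                absorbed = near[int(hit[0])]
        if absorbed is None:
            kept.append(i)
            assignment[snp_ids[i]] = snp_ids[i]
            records.append(
                {"snp_id": snp_ids[i], "chrom": chrom[i], "bp": int(bp[i]),
                 "p": np.nan}
            )
        else:
            assignment[snp_ids[i]] = snp_ids[absorbed]
    return IndexSet(index_snps=pd.DataFrame(records), assignment=assignment)


@dataclass
class ClumpedRegion:
    index_snp: str
    chrom: str
    start_bp: int            # 1-based inclusive over member positions
    end_bp: int
    members: list[str]


def clump_region(
    index: int | str,
    G: GenotypeMatrix,
    window_kb: float = 500.0,
    r2_min: float = 0.3,
) -> ClumpedRegion:
    """All SNPs within the window in LD (r^2 > ``r2_min``) with the index,
    plus the index itself; the span covers member positions."""
    i = G.snp_index(index) if isinstance(index, str) else index
    chrom = G.snp_map["chrom"].to_numpy()
    bp = G.snp_map["bp"].to_numpy(dtype=float)
    near = np.flatnonzero(
        (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window_kb * 1000.0)
    )
    near = near[near != i]
    members = [i]
    if near.size:
        r2 = _r2_vector(G, i, near)
        members.extend(near[r2 > r2_min].tolist())
    pos = bp[members]
    return ClumpedRegion(
        index_snp=str(G.snp_map["snp_id"].iloc[i]),
        chrom=str(chrom[i]),
        start_bp=int(pos.min()),
        end_bp=int(pos.max()),
        members=[str(G.snp_map["snp_id"].iloc[j]) for j in sorted(members)],
    )


def region_overlaps_genes(
    region: ClumpedRegion,
    genes: GeneSet,
    candidate_only: bool = True,
) -> tuple[bool, list[str]]:
    """Does the region span overlap (>= 1 bp) any gene interval?

    The 1-based inclusive span [start, end] converts to the half-open
    interval [start - 1, end); genes already use 0-based half-open.
    """
    gset = genes.candidates() if candidate_only else genes
    df = gset.intervals
    if len(df) == 0:
        return False, []
    same = df["chrom"].astype(str) == str(region.chrom)
    if not same.any():
        warnings.warn(
            f"no genes on chromosome {region.chrom}; treating as no overlap",
            stacklevel=2,
        )
        return False, []
    sub = df[same]
    r_start = region.start_bp - 1
    r_end = region.end_bp
    hit = (sub["start"].to_numpy() < r_end) & (r_start < sub["end"].to_numpy())
    return bool(hit.any()), list(sub["name"].to_numpy()[hit])
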