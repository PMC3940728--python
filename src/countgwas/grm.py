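"""Genetic relationship matrix (GRM) construction and IO.

The GRM entry for individuals j, k averages, over SNPs non-missing in both,
the product of their allele-frequency-standardised dosages:

    A_jk = (1/m_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with p_i the sample effect-allele frequency. Monomorphic SNPs are excluded
with a warning. The binary layout written/read here is the GCTA-compatible
one: a float32 stream of the lower triangle (diagonal included, row-major),
a float32 stream of per-pair marker counts, and a two-column id file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix


@dataclass
class GRM:
    values: np.ndarray          # n x n symmetric
    n_markers: np.ndarray       # n x n per-pair non-missing SNP counts
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def align(self, ids: list[str]) -> "GRM":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in ids])
        return GRM(
            values=self.values[np.ix_(idx, idx)],
            n_markers=self.n_markers[np.ix_(idx, idx)],
            sample_ids=list(ids),
        )


def compute_grm(G: GenotypeMatrix) -> GRM:
    """Allele-frequency-standardised relationship matrix with pairwise
    non-missing marker counts."""
    p = G.allele_freq()
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic SNPs from the GRM", stacklevel=2
        )
    dos = G.dosages[:, poly]
    p = p[poly]
    if dos.shape[1] == 0:
        raise ValueError("no polymorphic SNPs available for the GRM")
    z = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    obs = ~np.isnan(z)
    z = np.nan_to_num(z)
    num = z @ z.T
    counts = obs.astype(float) @ obs.astype(float).T
    if np.any(counts == 0):
        raise ValueError("some individual pairs share no non-missing SNPs")
    values = num / counts
    return GRM(values=values, n_markers=counts, sample_ids=list(G.sample_ids))


def write_grm(grm: GRM, prefix: str | Path) -> None:
    prefix = Path(prefix)
    tri = np.tril_indices(grm.n)
    grm.values[tri].astype("<f4").tofile(str(prefix) + ".grm.bin")
    grm.n_markers[tri].astype("<f4").tofile(str(prefix) + ".grm.N.bin")
    pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids}).to_csv(
        str(prefix) + ".grm.id", sep="\t", header=False, index=False
    )


def read_grm(prefix: str | Path) -> GRM:
    prefix = Path(prefix)
    ids = pd.read_csv(str(prefix) + ".grm.id", sep="\t", header=None)
    n = len(ids)
    vals = np.fromfile(str(prefix) + ".grm.bin", dtype="<f4").astype(float)
    counts = np.fromfile(str(prefix) + ".grm.N.bin", dtype="<f4").astype(float)
    expect = n * (n + 1) // 2
    if vals.size != expect or counts.size != expect:
        raise ValueError("GRM stream length inconsistent with id file")
    tri = np.tril_indices(n)
    A = np.zeros((n, n))
    N = np.zeros((n, n))
    A[tri] = vals
    N[tri] = counts
    A = A + A.T - np.diag(np.diag(A))
    N = N + N.T - np.diag(np.diag(N))
    return GRM(values=A, n_markers=N, sample_ids=list(ids[1].astype(str)))


def write_grm_tsv(grm: GRM, path: str | Path) -> None:
    pd.DataFrame(grm.values, index=grm.sample_ids, columns=grm.sample_ids).to_csv(
        path, sep="\t"
    )
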