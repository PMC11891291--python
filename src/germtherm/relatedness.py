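"""Genomic relationship matrix, dissimilarity transform and classical MDS."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix


@dataclass
class RelationshipSet:
    """G, its correlation form G*, and the dissimilarity 1 - G*."""

    G: np.ndarray
    G_star: np.ndarray
    D: np.ndarray
    accession_ids: list
    n_snps: int = 0

    def __post_init__(self) -> None:
        for M in (self.G, self.G_star, self.D):
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError("relationship matrices must be symmetric")
            if not np.isfinite(M).all():
                raise ValueError("relationship matrices must be finite")
        if not np.allclose(np.diag(self.G_star), 1.0, atol=1e-10):
            raise ValueError("diag(G*) must be 1")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-10):
            raise ValueError("diag(D) must be 0")


@dataclass
class MdsResult:
    """Classical-MDS coordinates with per-axis variance explained."""

    coordinates: np.ndarray        # (n, n_axes)
    eigenvalues: np.ndarray        # all eigenvalues, descending
    pct_variance: np.ndarray       # per retained axis, % of positive-eigenvalue sum
    accession_ids: list | None = None


def compute_grm(genotypes: GenotypeMatrix) -> RelationshipSet:
    """GCTA-default genomic relationship matrix.

    G_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
    with p_i the observed allele frequency in the current accession set.
    G* rescales G to unit diagonal (cov2cor) and D = 1 - G*.
    """
    X = np.asarray(genotypes.dosages, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need at least one SNP")
    p = X.mean(axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0) | (np.ptp(X, axis=0) == 0)
    if mono.any():
        raise ValueError(
            f"{int(mono.sum())} monomorphic SNPs; filter them before the GRM"
        )
    W = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    G = (W @ W.T) / X.shape[1]
    d = np.diag(G)
    if (d <= 0).any():
        raise ValueError("zero diagonal entry in G; cannot form the correlation matrix")
    inv_sd = 1.0 / np.sqrt(d)
    G_star = G * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(G_star, 1.0)
    D = 1.0 - G_star
    np.fill_diagonal(D, 0.0)
    return RelationshipSet(
        G=G, G_star=G_star, D=D,
        accession_ids=list(genotypes.accession_ids),
        n_snps=genotypes.n_snps,
    )


def classical_mds(D: np.ndarray, n_axes: int = 2, accession_ids=None) -> MdsResult:
    """Classical (Torgerson) MDS of a dissimilarity matrix.

    Double-centers B = -1/2 J D^(2) J, eigendecomposes, and returns
    coordinates sqrt(lambda_k) v_k for positive eigenvalues only; the
    per-axis percentage of variance uses the positive-eigenvalue sum as
    denominator.  Each axis is oriented so the first accession's
    coordinate is non-negative.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be a symmetric square matrix")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("D must have a zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(1e-12, 1e-9 * max(abs(w[0]), 1.0))
    pos = w > tol
    if not pos.any():
        if np.allclose(D, 0.0):
            k = min(n_axes, n)
            return MdsResult(
                coordinates=np.zeros((n, k)),
                eigenvalues=w,
                pct_variance=np.zeros(k),
                accession_ids=accession_ids,
            )
        raise ValueError("degenerate dissimilarity: no positive eigenvalues")
    n_pos = int(pos.sum())
    k = min(n_axes, n_pos)
    coords = V[:, :k] * np.sqrt(w[:k])
    flip = np.where(coords[0, :] < 0, -1.0, 1.0)
    coords = coords * flip
    pct = 100.0 * w[:k] / w[:n_pos].sum()
    return MdsResult(
        coordinates=coords, eigenvalues=w, pct_variance=pct,
        accession_ids=accession_ids,
    )


def mds_of_relationships(rel: RelationshipSet, n_axes: int = 2) -> MdsResult:
    return classical_mds(rel.D, n_axes=n_axes, accession_ids=rel.accession_ids)


def write_gcta_grm(rel: RelationshipSet, prefix) -> None:
    """Write G in GCTA text format (.grm + .grm.id) and as a square TSV."""
    ids = rel.accession_ids
    with open(f"{prefix}.grm.id", "w") as fh:
        for a in ids:
            fh.write(f"FAM\t{a}\n")
    with open(f"{prefix}.grm", "w") as fh:
        for i in range(len(ids)):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{rel.n_snps}\t{rel.G[i, j]:.10g}\n")
    pd.DataFrame(rel.G, index=ids, columns=ids).to_csv(f"{prefix}.grm.tsv", sep="\t")


def read_grm_tsv(path) -> RelationshipSet:
    df = pd.read_csv(path, sep="\t", index_col=0)
    G = df.to_numpy(dtype=float)
    G = (G + G.T) / 2.0
    d = np.diag(G)
    inv_sd = 1.0 / np.sqrt(d)
    G_star = G * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(G_star, 1.0)
    D = 1.0 - G_star
    np.fill_diagonal(D, 0.0)
    return RelationshipSet(G=G, G_star=G_star, D=D, accession_ids=list(df.index))
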