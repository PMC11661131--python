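"""Genotype panel container and kinship (genetic relatedness) computation.

Genotypes are strain-level calls for fully inbred lines, coded 0/2 for the
two homozygous states (heterozygotes do not occur on an inbred panel);
missing calls are NaN. SNP positions are 1-based and strictly increasing
within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_TOKEN = "."


@dataclass
class GenotypePanel:
    """Strain x SNP homozygous genotype matrix with map positions.

    Attributes
    ----------
    strain_ids : list of str
    snps : DataFrame indexed by snp id with columns ``chrom`` and ``bp``.
    genotypes : float array (n_strains, n_snps) with values in {0, 2, NaN}.
    """

    strain_ids: list[str]
    snps: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.strain_ids), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.snps)} SNPs"
            )
        valid = np.isnan(self.genotypes) | (self.genotypes == 0) | (self.genotypes == 2)
        if not valid.all():
            raise ValueError("non-missing genotype calls must be 0 or 2")
        for _, grp in self.snps.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps.index.to_numpy()

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.genotypes, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.genotypes).mean(axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            strain_ids=list(self.strain_ids),
            snps=self.snps.loc[np.asarray(mask)].copy(),
            genotypes=self.genotypes[:, np.asarray(mask)],
        )

    def dosage(self, snp_id: str) -> np.ndarray:
        j = self.snps.index.get_loc(snp_id)
        return self.genotypes[:, j]

    # --- text interchange -------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Native TSV: snp, chrom, bp, then one column per strain ('.' = missing)."""
        df = self.snps.copy()
        df.insert(0, "snp", df.index)
        geno = pd.DataFrame(
            self.genotypes.T, columns=self.strain_ids, index=df.index
        )
        out = pd.concat([df.reset_index(drop=True), geno.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN, float_format="%g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN])
        meta_cols = ["snp", "chrom", "bp"]
        strains = [c for c in df.columns if c not in meta_cols]
        snps = df[["chrom", "bp"]].copy()
        snps.index = pd.Index(df["snp"].astype(str), name="snp")
        snps["chrom"] = snps["chrom"].astype(str)
        return cls(strain_ids=strains, snps=snps, genotypes=df[strains].to_numpy().T)

    def write_plink_map(self, prefix: str | Path) -> None:
        """PLINK-style .map plus a transposed genotype TSV (SNP rows)."""
        prefix = Path(prefix)
        mapdf = pd.DataFrame(
            {
                "chrom": self.snps["chrom"],
                "snp": self.snps.index,
                "cm": 0.0,
                "bp": self.snps["bp"],
            }
        )
        mapdf.to_csv(prefix.with_suffix(".map"), sep="\t", index=False, header=False)
        self.to_tsv(prefix.with_suffix(".geno.tsv"))


@dataclass
class KinshipMatrix:
    """Symmetric PSD strain x strain genetic relatedness matrix."""

    strain_ids: list[str]
    values: np.ndarray
    n_snps_used: int = 0
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strain_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square and aligned to strain ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        if np.linalg.eigvalsh(self.values).min() < -1e-8:
            raise ValueError("kinship matrix must be positive semidefinite")
        self._index = {s: i for i, s in enumerate(self.strain_ids)}

    def expand(self, strains: list[str] | np.ndarray) -> np.ndarray:
        """Expand to a unit-level (e.g. per-mouse or per-sample) matrix."""
        idx = np.array([self._index[s] for s in strains])
        return self.values[np.ix_(idx, idx)]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.strain_ids, columns=self.strain_ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(strain_ids=[str(s) for s in df.index], values=df.to_numpy())


def compute_grm(panel: GenotypePanel) -> KinshipMatrix:
    """Genetic relatedness matrix from column-standardized genotypes.

    Missing calls are imputed to the per-SNP mean (inside this computation
    only); monomorphic and all-missing SNPs are excluded. The cross-product
    of standardized columns is divided by the SNP count, so the diagonal is
    ~1 in expectation, and the result is made PSD by clipping any negative
    eigenvalues at zero.
    """
    if panel.n_strains < 2:
        raise ValueError("kinship requires at least two strains")
    X = panel.genotypes.copy()
    all_missing = np.isnan(X).all(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(all_missing[None, :], 0.0, X), axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = mean[inds[1]]
    sd = X.std(axis=0)
    keep = (~all_missing) & (sd > 0)
    if not keep.any():
        raise ValueError("no polymorphic SNP available for kinship computation")
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    G = Z @ Z.T / keep.sum()
    G = (G + G.T) / 2.0
    w, V = np.linalg.eigh(G)
    if w.min() < 0:
        G = (V * np.clip(w, 0.0, None)) @ V.T
        G = (G + G.T) / 2.0
    return KinshipMatrix(strain_ids=list(panel.strain_ids), values=G, n_snps_used=int(keep.sum()))
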