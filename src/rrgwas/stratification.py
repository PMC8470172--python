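"""Genotype principal components as population-stratification covariates.

Cryptic substructure inflates association statistics; the standard remedy is
to include the leading principal components of the (frequency-standardized)
genotype matrix as fixed covariates.  Columns are centered by ``2*p_hat`` and
scaled by ``sqrt(2*p_hat*(1-p_hat))`` (Patterson scaling) before the
eigendecomposition, and missing calls are mean-imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plinkio import GenotypeDataset

__all__ = ["PcResult", "genotype_pca", "attach_pcs"]


@dataclass
class PcResult:
    """Per-individual component scores and explained-variance fractions."""

    samples: list[str]
    scores: np.ndarray          # individuals x k
    explained_variance: np.ndarray  # k fractions, non-increasing

    def to_frame(self) -> pd.DataFrame:
        k = self.scores.shape[1]
        df = pd.DataFrame(self.scores, columns=[f"PC{i + 1}" for i in range(k)])
        df.insert(0, "id", self.samples)
        return df

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            ev = " ".join(f"{v:.6g}" for v in self.explained_variance)
            fh.write(f"# explained_variance_fraction: {ev}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def genotype_pca(data: GenotypeDataset, k: int = 2) -> PcResult:
    """Leading ``k`` principal components of the standardized genotype matrix.

    Signs are fixed by making each component's largest-magnitude SNP loading
    positive, so scores are deterministic.
    """
    n = data.n_samples
    if not 1 <= k <= min(n - 1, data.n_snps):
        raise ValueError(f"k={k} must be in [1, min(n_samples-1, n_snps)]")
    x = data.impute_missing_mean()
    p_hat = x.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    poly = denom > 0
    z = (x[:, poly] - 2.0 * p_hat[poly]) / denom[poly]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # sign convention: largest |loading| positive per component
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u[:, :k] * s[:k]
    total = (s**2).sum()
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PcResult(samples=list(data.samples), scores=scores, explained_variance=frac)


def attach_pcs(pheno: pd.DataFrame, pcs: PcResult, count: int = 2, id_col: str = "id") -> pd.DataFrame:
    """Merge PC1..PCcount onto a long-format phenotype table as covariates."""
    if count == 0:
        return pheno.copy()
    if count > pcs.scores.shape[1]:
        raise ValueError(f"requested {count} PCs but only {pcs.scores.shape[1]} computed")
    pc_df = pcs.to_frame().iloc[:, : count + 1]
    missing = set(pheno[id_col].astype(str)) - set(pc_df["id"].astype(str))
    if missing:
        raise KeyError(f"individuals without PC scores: {sorted(missing)[:5]}")
    merged = pheno.merge(pc_df, left_on=id_col, right_on="id", how="left", suffixes=("", "_pc"))
    if "id_pc" in merged.columns:
        merged = merged.drop(columns=["id_pc"])
    return merged
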