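"""Genome scan with a time-varying fixed SNP effect (fGWAS-C).

Each SNP adds a fixed regression term ``x_i * SNP(t)`` to the null random
regression model, where ``x_i`` is the 0/1/2 dosage and
``SNP(t) = sum_l eta_l phi_l(t*)`` is a Legendre curve.  Variance
components stay fixed at their null-model REML estimates; the augmented
mixed model equations are re-solved exactly for every SNP via a Schur
complement on the prefactorized null coefficient matrix, and the
coefficient vector ``eta`` is tested jointly with a Wald chi-square on
``snp_order + 1`` degrees of freedom.  Monomorphic or collinear SNPs are
reported as not testable (NaN p-value) rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.stats import chi2

from .basis import design_matrix
from .plinkio import GenotypeDataset
from .significance import SignificanceCall, fdr_threshold

__all__ = ["ScanResult", "snp_covariates", "test_snp", "run_scan"]


@dataclass
class ScanResult:
    """Per-SNP curve coefficients, Wald statistics and p-values."""

    frame: pd.DataFrame
    snp_order: int
    method: str
    effect_ages: np.ndarray
    null_loglike: float

    @property
    def p_values(self) -> np.ndarray:
        return self.frame["p_value"].to_numpy()

    def significant(self, fdr: float = 0.05) -> tuple[pd.DataFrame, SignificanceCall]:
        call = fdr_threshold(self.p_values, fdr=fdr)
        return self.frame.iloc[call.significant_idx], call

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")

    def __len__(self) -> int:
        return len(self.frame)


def snp_covariates(
    dosages: np.ndarray, record_individual: np.ndarray, phi_snp: np.ndarray
) -> np.ndarray:
    """Per-record SNP covariate rows ``x_k * [phi_0(t*) ... phi_q(t*)]``."""
    d = np.asarray(dosages, float)
    if np.isnan(d).any():
        raise ValueError(
            "missing dosage; mean-impute genotypes (GenotypeDataset.impute_missing_mean) first"
        )
    return d[record_individual, None] * phi_snp


def test_snp(
    null_fit, dosages: np.ndarray, snp_order: int | None = None, snp_id: str = "snp"
) -> pd.Series:
    """Test one SNP given its per-individual dosage vector.

    Convenience wrapper over :func:`run_scan`; ``dosages`` is ordered like
    the null model's phenotyped individuals.  Returns the single result row.
    """
    ids = null_fit.model.sys.pheno_ids
    d = np.asarray(dosages, float)
    if d.shape != (len(ids),):
        raise ValueError(f"expected {len(ids)} dosages, got {d.shape}")
    snps = pd.DataFrame(
        {"chrom": ["1"], "snp_id": [snp_id], "cm": [0.0], "pos": [1],
         "allele_a": ["A"], "allele_b": ["B"]}
    )
    rounded = np.round(d).astype(np.int8)
    if not np.allclose(d, rounded):
        raise ValueError("test_snp expects integer 0/1/2 dosages; imputed "
                         "fractional dosages go through run_scan")
    geno = GenotypeDataset(samples=list(ids), snps=snps, calls=rounded[:, None])
    return run_scan(geno, null_fit, snp_order=snp_order).frame.iloc[0]


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    num = pd.to_numeric(chrom, errors="coerce")
    return num.fillna(np.inf)


def run_scan(
    genotypes: GenotypeDataset,
    null_fit,
    snp_order: int | None = None,
    method: str = "wald",
    effect_ages: np.ndarray | None = None,
) -> ScanResult:
    """Test every SNP for a time-varying additive effect.

    Parameters
    ----------
    genotypes
        QC'd dataset; missing calls are mean-imputed here.
    null_fit
        Converged :class:`~rrgwas.model.RandomRegressionResults`.
    snp_order
        Legendre degree of the SNP curve; defaults to
        ``min(order_fixed, n_distinct_ages - 1)``.
    method
        ``"wald"`` (default) or ``"lrt"`` — a fixed-variance-component
        likelihood-ratio refit, kept for cross-checking the Wald algebra.
    """
    if method not in ("wald", "lrt"):
        raise ValueError(f"unknown method {method!r}")
    model = null_fit.model
    sys = model.sys
    ages = np.unique(sys.ages)
    if snp_order is None:
        snp_order = min(model.spec.order_fixed, len(ages) - 1)
    q = snp_order + 1

    geno_pos = {s: k for k, s in enumerate(genotypes.samples)}
    missing_ids = [i for i in sys.pheno_ids if i not in geno_pos]
    if missing_ids:
        raise KeyError(
            f"phenotyped individuals without genotypes: {missing_ids[:5]}"
            + ("..." if len(missing_ids) > 5 else "")
        )
    row_of_ind = np.array([geno_pos[i] for i in sys.pheno_ids])

    dos_all = genotypes.impute_missing_mean()[row_of_ind, :]  # pheno_ind x snps

    basis_snp = sys.basis_fixed.with_order(snp_order)
    phi_snp = design_matrix(sys.ages, basis_snp)
    phi_eff_ages = np.asarray(effect_ages if effect_ages is not None else ages, float)
    phi_eff = design_matrix(phi_eff_ages, basis_snp)

    from .model import _mme_coefficient

    vc = null_fit.vc
    W, C, *_ = _mme_coefficient(sys, model._A_inv_values, vc)
    cf = sla.cho_factor(C)
    Wty = W.T @ sys.y
    sol0 = sla.cho_solve(cf, Wty)
    yPy0 = (sys.y @ sys.y - sol0 @ Wty) / vc.sigma2_e

    rows = []
    chunk = max(1, 4096 // q)
    for start in range(0, genotypes.n_snps, chunk):
        idx = np.arange(start, min(start + chunk, genotypes.n_snps))
        # stacked covariate blocks for the whole chunk: N x (len(idx)*q)
        S_all = (
            dos_all[sys.record_individual][:, idx, None] * phi_snp[:, None, :]
        ).reshape(sys.n_records, -1)
        B_all = W.T @ S_all
        CB_all = sla.cho_solve(cf, B_all)
        StS_all = np.einsum(
            "njq,njr->jqr",
            S_all.reshape(sys.n_records, len(idx), q),
            S_all.reshape(sys.n_records, len(idx), q),
        )
        Sty_all = sys.y @ S_all
        for k, j in enumerate(idx):
            info = genotypes.snps.iloc[j]
            d = dos_all[:, j]
            rec = {
                "snp_id": info["snp_id"],
                "chrom": info["chrom"],
                "pos": int(info["pos"]),
            }
            testable = bool(np.var(d) > 1e-12)
            eta = np.full(q, np.nan)
            eff = np.full(len(phi_eff_ages), np.nan)
            wald = np.nan
            pval = np.nan
            if testable:
                cols = slice(k * q, (k + 1) * q)
                B = B_all[:, cols]
                M = StS_all[k] - B.T @ CB_all[:, cols]
                scale = max(np.trace(StS_all[k]) / q, 1e-300)
                w_eig = np.linalg.eigvalsh(M)
                if w_eig.min() <= 1e-10 * scale:
                    testable = False  # collinear with the null design
                else:
                    rhs = Sty_all[cols] - B.T @ sol0
                    eta = np.linalg.solve(M, rhs)
                    # Cov(eta) = sigma2_e * M^-1; Wald = eta' Cov^-1 eta
                    wald = float(eta @ M @ eta) / vc.sigma2_e
                    if method == "lrt":
                        # exact fixed-VC refit: difference of residual quadforms
                        yPy1 = yPy0 - float(rhs @ eta) / vc.sigma2_e
                        wald = yPy0 - yPy1
                    pval = float(chi2.sf(wald, q))
                    pval = max(pval, np.finfo(float).tiny)
                    eff = phi_eff @ eta
            rec.update({f"eta_{l}": eta[l] for l in range(q)})
            rec.update({f"effect_age_{a:g}": e for a, e in zip(phi_eff_ages, eff)})
            rec.update({"wald": wald, "df": q, "p_value": pval, "testable": testable})
            rows.append(rec)

    frame = pd.DataFrame(rows)
    if len(frame):
        frame = (
            frame.assign(_ck=_chrom_sort_key(frame["chrom"]))
            .sort_values(["_ck", "pos"], kind="mergesort")
            .drop(columns="_ck")
            .reset_index(drop=True)
        )
    return ScanResult(
        frame=frame,
        snp_order=snp_order,
        method=method,
        effect_ages=phi_eff_ages,
        null_loglike=null_fit.loglike,
    )
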