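"""Descriptive statistics, genomic inflation, Manhattan and Q-Q plots.

Every plot is written together with a machine-readable CSV sidecar holding
exactly the data series drawn, so downstream checks never parse images.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["describe_phenotypes", "lambda_gc", "manhattan_qq"]

# median of the chi-square(1) distribution
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def describe_phenotypes(
    pheno: pd.DataFrame, trait: str = "weight", age_col: str = "age_months"
) -> pd.DataFrame:
    """Per-age n, mean, s.d., skewness and excess kurtosis.

    Skewness/kurtosis are reported as NaN for degenerate (zero-variance)
    ages rather than raising.
    """
    if pheno.empty:
        raise ValueError("empty phenotype table")

    def _one(g: pd.Series) -> pd.Series:
        v = g.to_numpy(float)
        sd = v.std(ddof=1) if v.size > 1 else 0.0
        degenerate = sd == 0.0
        return pd.Series(
            {
                "n": v.size,
                "mean": v.mean(),
                "sd": sd,
                "skewness": np.nan if degenerate else stats.skew(v, bias=False),
                "kurtosis": np.nan if degenerate else stats.kurtosis(v, bias=False),
            }
        )

    out = pheno.groupby(age_col)[trait].apply(_one).unstack()
    out["n"] = out["n"].astype(int)
    return out.reset_index()


def lambda_gc(p_values) -> float:
    """Genomic inflation factor: median chi-square(1) quantile of the
    observed p-values divided by the null chi-square(1) median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no (testable) p-values")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / _CHI2_1_MEDIAN)


def manhattan_qq(scan, threshold_p: float | None, out_dir) -> dict[str, Path]:
    """Write Manhattan + Q-Q plots (PNG) with CSV sidecars.

    The sidecars carry the cumulative genome coordinate, -log10(p) and
    expected quantiles, and are byte-deterministic given the scan result.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = scan.frame[~scan.frame["p_value"].isna()].copy()
    if frame.empty:
        raise ValueError("scan has no testable SNPs to plot")

    # cumulative genome coordinate, chromosome blocks in sorted order
    num = pd.to_numeric(frame["chrom"], errors="coerce").fillna(np.inf)
    frame = frame.assign(_ck=num).sort_values(["_ck", "pos"], kind="mergesort")
    offset = 0
    cum = np.empty(len(frame))
    centers = {}
    for chrom, grp in frame.groupby("_ck", sort=True):
        idx = frame["_ck"] == chrom
        cum[idx.to_numpy()] = frame.loc[idx, "pos"].to_numpy() + offset
        centers[str(frame.loc[idx, "chrom"].iloc[0])] = offset + frame.loc[idx, "pos"].max() / 2
        offset += frame.loc[idx, "pos"].max() + 1
    frame["cum_pos"] = cum
    frame["neglog10p"] = -np.log10(frame["p_value"])

    man_csv = out / "manhattan.csv"
    frame[["snp_id", "chrom", "pos", "cum_pos", "p_value", "neglog10p"]].to_csv(
        man_csv, index=False
    )
    fig, ax = plt.subplots(figsize=(9, 3.2))
    for k, (chrom, grp) in enumerate(frame.groupby("_ck", sort=True)):
        sub = frame[frame["_ck"] == chrom]
        ax.scatter(sub["cum_pos"], sub["neglog10p"], s=6,
                   color="tab:blue" if k % 2 == 0 else "tab:orange")
    if threshold_p is not None and threshold_p > 0:
        ax.axhline(-np.log10(threshold_p), color="red", ls="--", lw=1)
    ax.set_xlabel("cumulative genome position (bp)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_xticks(list(centers.values()))
    ax.set_xticklabels(list(centers.keys()), fontsize=7)
    fig.tight_layout()
    man_png = out / "manhattan.png"
    fig.savefig(man_png, dpi=120)
    plt.close(fig)

    m = len(frame)
    obs = np.sort(frame["p_value"].to_numpy())
    expected = (np.arange(1, m + 1) - 0.5) / m
    qq = pd.DataFrame(
        {"expected_neglog10p": -np.log10(expected), "observed_neglog10p": -np.log10(obs)}
    )
    qq_csv = out / "qq.csv"
    qq.to_csv(qq_csv, index=False)
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.plot(qq["expected_neglog10p"], qq["observed_neglog10p"], ".", ms=3)
    lim = max(qq.max().max(), 1.0)
    ax.plot([0, lim], [0, lim], "k-", lw=1)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    ax.set_title(f"lambda_GC = {lambda_gc(scan.p_values):.3f}", fontsize=9)
    fig.tight_layout()
    qq_png = out / "qq.png"
    fig.savefig(qq_png, dpi=120)
    plt.close(fig)

    return {"manhattan_png": man_png, "manhattan_csv": man_csv, "qq_png": qq_png, "qq_csv": qq_csv}
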