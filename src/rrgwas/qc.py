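"""Marker- and individual-level genotype quality control.

The filter battery mirrors standard chip-QC practice for pedigreed GWAS
populations: individuals with excessive missingness are dropped first, then
per-SNP filters run in a fixed, recorded order — missing map position, call
rate, minor allele frequency, Hardy-Weinberg exact test, Mendelian error
rate against the pedigree — and finally duplicated positions are collapsed.
Every removal is tallied per criterion in a :class:`QcReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree
from .plinkio import MISSING, GenotypeDataset

__all__ = [
    "QcThresholds",
    "QcReport",
    "minor_allele_frequency",
    "hwe_exact_p",
    "mendel_error_rate",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds; a marker/individual failing any is removed.

    Defaults follow common chip-QC practice for pedigreed cattle data:
    MAF < 1%, SNP call rate < 95%, HWE exact p < 1e-6, per-SNP Mendelian
    error rate > 2%, individual missingness > 10%.
    """

    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    mendel_rate_max: float = 0.02
    ind_missing_max: float = 0.10

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Per-criterion removal tallies, in application order."""

    n_samples_in: int = 0
    n_snps_in: int = 0
    removed_individual_missingness: int = 0
    removed_map_position: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_mendel: int = 0
    removed_duplicate_position: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0

    @property
    def snp_criteria(self) -> list[str]:
        return [
            "removed_map_position",
            "removed_call_rate",
            "removed_maf",
            "removed_hwe",
            "removed_mendel",
            "removed_duplicate_position",
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [("input_samples", self.n_samples_in), ("input_snps", self.n_snps_in)]
        rows.append(("individual_missingness", self.removed_individual_missingness))
        rows += [(c.removeprefix("removed_"), getattr(self, c)) for c in self.snp_criteria]
        rows += [("surviving_samples", self.n_samples_out), ("surviving_snps", self.n_snps_out)]
        return pd.DataFrame(rows, columns=["criterion", "count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def minor_allele_frequency(column: np.ndarray) -> float:
    """Folded allele frequency ``min(p, 1-p)`` of one SNP column.

    Missing calls are excluded from both numerator and denominator.
    """
    col = np.asarray(column)
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError("all calls missing; MAF undefined")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def hwe_exact_p(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the allele counts and sums the probabilities of every
    heterozygote configuration no more likely than the observed one
    (Wigginton-style exact test, no mid-p adjustment).
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom_a + n_het + n_hom_b
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_hom_a + n_het  # rarer labelling handled by symmetry below
    n_b = 2 * n_hom_b + n_het
    n_minor = min(n_a, n_b)
    if n_minor == 0:
        return 1.0

    from scipy.special import gammaln

    def log_prob(h: int) -> float:
        # P(het = h | allele counts) for 2n alleles, n_minor minor copies
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return (
            gammaln(n + 1)
            - gammaln(hom_minor + 1)
            - gammaln(h + 1)
            - gammaln(hom_major + 1)
            + h * np.log(2.0)
            + gammaln(n_a + 1)
            + gammaln(n_b + 1)
            - gammaln(2 * n + 1)
        )

    h_obs = n_het
    h_values = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = np.array([log_prob(int(h)) for h in h_values])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[h_values == h_obs][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_column_p(col: np.ndarray) -> float:
    obs = col[col != MISSING]
    return hwe_exact_p(int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum()))


_TRIO_VALID = {
    (0, 0): {0}, (0, 1): {0, 1}, (0, 2): {1},
    (1, 1): {0, 1, 2}, (1, 2): {1, 2}, (2, 2): {2},
}


def mendel_error_rate(data: GenotypeDataset, ped: Pedigree) -> np.ndarray:
    """Per-SNP Mendelian inconsistency rate from trios and duos.

    For each offspring with both parents genotyped the trio counts as one
    comparison per SNP (error when the child genotype is impossible given
    the parent pair); with one genotyped parent the duo counts instead
    (error only for opposite homozygotes).  Rate = errors / comparisons;
    SNPs with no informative comparison get rate 0.
    """
    sample_idx = {s: k for k, s in enumerate(data.samples)}
    m = data.n_snps
    errors = np.zeros(m)
    comparisons = np.zeros(m)
    calls = data.calls
    for child, sire, dam in ped.records:
        ci = sample_idx.get(child)
        if ci is None:
            continue
        si = sample_idx.get(sire) if sire != UNKNOWN else None
        di = sample_idx.get(dam) if dam != UNKNOWN else None
        if si is None and di is None:
            continue
        c = calls[ci]
        c_ok = c != MISSING
        if si is not None and di is not None:
            s, d = calls[si], calls[di]
            both = c_ok & (s != MISSING) & (d != MISSING)
            comparisons += both
            if both.any():
                lo = np.minimum(s, d)
                hi = np.maximum(s, d)
                bad = np.zeros(m, dtype=bool)
                for (a, b), valid in _TRIO_VALID.items():
                    pair = (lo == a) & (hi == b) & both
                    invalid = ~np.isin(c, list(valid))
                    bad |= pair & invalid
                errors += bad
            # fall through duos for the parent that is genotyped while the
            # other is missing
            for pi in (si, di):
                other = di if pi is si else si
                duo = c_ok & (calls[pi] != MISSING) & (calls[other] == MISSING)
                comparisons += duo
                errors += duo & (np.abs(c - calls[pi]) == 2)
        else:
            pi = si if si is not None else di
            duo = c_ok & (calls[pi] != MISSING)
            comparisons += duo
            errors += duo & (np.abs(c - calls[pi]) == 2)
    with np.errstate(invalid="ignore"):
        rate = np.where(comparisons > 0, errors / np.maximum(comparisons, 1), 0.0)
    return rate


def _call_rates(calls: np.ndarray) -> np.ndarray:
    return (calls != MISSING).mean(axis=0)


def apply_qc(
    data: GenotypeDataset,
    ped: Pedigree | None = None,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeDataset, QcReport]:
    """Run the full QC battery; returns the filtered dataset and its report.

    Order: individual missingness, then per-SNP map position / call rate /
    MAF / HWE / Mendelian rate, then duplicate-position removal (highest
    call rate kept, ties to the lexicographically first snp_id).
    """
    thr = thresholds or QcThresholds()
    report = QcReport(n_samples_in=data.n_samples, n_snps_in=data.n_snps)

    # 1. individuals with excessive missingness
    ind_missing = (data.calls == MISSING).mean(axis=1)
    keep_ind = ind_missing <= thr.ind_missing_max
    report.removed_individual_missingness = int((~keep_ind).sum())
    data = data.take_samples(keep_ind)

    keep = np.ones(data.n_snps, dtype=bool)

    def drop(mask_bad: np.ndarray, attr: str) -> None:
        newly = keep & mask_bad
        setattr(report, attr, int(newly.sum()))
        keep[newly] = False

    snps = data.snps
    chrom = snps["chrom"].astype(str)
    no_map = chrom.isin(["0", "", "nan", "NA"]).to_numpy() | (snps["pos"].to_numpy() <= 0)
    drop(no_map, "removed_map_position")

    n_obs = (data.calls != MISSING).sum(axis=0)
    cr = _call_rates(data.calls)
    drop((cr < thr.call_rate_min) | (n_obs == 0), "removed_call_rate")

    maf = np.array(
        [minor_allele_frequency(data.calls[:, j]) if keep[j] else 0.0 for j in range(data.n_snps)]
    )
    drop(keep & (maf < thr.maf_min), "removed_maf")

    hwe = np.array([_hwe_column_p(data.calls[:, j]) if keep[j] else 1.0 for j in range(data.n_snps)])
    drop(keep & (hwe < thr.hwe_p_min), "removed_hwe")

    if ped is not None:
        mrate = mendel_error_rate(data, ped)
        drop(keep & (mrate > thr.mendel_rate_max), "removed_mendel")

    # duplicate positions: keep highest call rate, ties by snp_id order
    order = np.lexsort((snps["snp_id"].to_numpy(), -cr))
    seen: set[tuple[str, int]] = set()
    dup_bad = np.zeros(data.n_snps, dtype=bool)
    for j in order:
        if not keep[j]:
            continue
        key = (chrom.iloc[j], int(snps["pos"].iloc[j]))
        if key in seen:
            dup_bad[j] = True
        else:
            seen.add(key)
    drop(dup_bad, "removed_duplicate_position")

    out = data.take_snps(keep)
    report.n_samples_out = out.n_samples
    report.n_snps_out = out.n_snps
    return out, report
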