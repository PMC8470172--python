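"""PLINK genotype I/O (.bed/.bim/.fam binary and text .ped/.map).

Genotypes are held as an individuals x SNPs dosage matrix counting copies of
``allele_b`` (the .bim A2 allele), coded 0/1/2 with ``MISSING = -1``.  The
binary format is PLINK 1 SNP-major: three magic bytes ``6c 1b 01`` then, per
SNP, ceil(n/4) bytes of 2-bit codes (00 hom A1, 01 missing, 10 het,
11 hom A2), little-endian within each byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MISSING", "GenotypeDataset", "read_plink", "write_plink"]

MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit bed code -> dosage of allele_b (A2)
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0, MISSING: 1, 1: 2, 2: 3}

_BIM_COLS = ["chrom", "snp_id", "cm", "pos", "allele_a", "allele_b"]


class PlinkFormatError(ValueError):
    pass


@dataclass
class GenotypeDataset:
    """Samples x SNPs dosage matrix with marker metadata.

    Attributes
    ----------
    samples
        Ordered individual IDs (one per matrix row).
    snps
        Marker table with columns ``chrom, snp_id, cm, pos, allele_a,
        allele_b`` (one row per matrix column).
    calls
        int8 matrix of allele_b dosages in {0, 1, 2, MISSING}.
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        valid = np.isin(self.calls, [0, 1, 2, MISSING])
        if not valid.all():
            raise ValueError("genotype calls must be 0, 1, 2 or MISSING")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps["snp_id"][self.snps["snp_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def take_samples(self, mask_or_idx) -> "GenotypeDataset":
        idx = np.arange(self.n_samples)[mask_or_idx]
        return GenotypeDataset(
            samples=[self.samples[i] for i in idx],
            snps=self.snps.copy(),
            calls=self.calls[idx, :],
        )

    def take_snps(self, mask_or_idx) -> "GenotypeDataset":
        idx = np.arange(self.n_snps)[mask_or_idx]
        return GenotypeDataset(
            samples=list(self.samples),
            snps=self.snps.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
        )

    def dosages(self, snp_id: str) -> np.ndarray:
        j = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(j) == 0:
            raise KeyError(f"unknown snp_id {snp_id!r}")
        return self.calls[:, j[0]]

    def impute_missing_mean(self) -> np.ndarray:
        """Float dosage matrix with MISSING replaced by the per-SNP mean.

        Raises on an all-missing SNP; run QC first to remove those.
        """
        x = self.calls.astype(float)
        miss = x == MISSING
        x[miss] = np.nan
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            col_mean = np.nanmean(x, axis=0)
        if np.isnan(col_mean).any():
            j = int(np.where(np.isnan(col_mean))[0][0])
            raise ValueError(
                f"SNP {self.snps['snp_id'].iloc[j]!r} has no non-missing calls"
            )
        return np.where(miss, col_mean[None, :], x)


def _read_fam(path: Path) -> list[str]:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise PlinkFormatError(f"{path}: .fam needs >= 2 columns")
    return fam.iloc[:, 1].tolist()  # within-family ID


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] != 6:
        raise PlinkFormatError(f"{path}: .bim must have 6 columns")
    bim.columns = _BIM_COLS
    bim["pos"] = bim["pos"].astype(int)
    bim["cm"] = bim["cm"].astype(float)
    return bim


def read_plink(prefix) -> GenotypeDataset:
    """Read ``prefix.bed/.bim/.fam`` (binary) or ``prefix.ped/.map`` (text)."""
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return _read_bed(prefix)
    if prefix.with_suffix(".ped").exists():
        return _read_pedmap(prefix)
    raise FileNotFoundError(f"neither {prefix}.bed nor {prefix}.ped exists")


def _read_bed(prefix: Path) -> GenotypeDataset:
    samples = _read_fam(prefix.with_suffix(".fam"))
    bim = _read_bim(prefix.with_suffix(".bim"))
    n, m = len(samples), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes (not a PLINK 1 bed file)")
    bps = (n + 3) // 4  # bytes per SNP, SNP-major
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != m * bps:
        raise PlinkFormatError(
            f"{prefix}.bed: payload is {payload.size} bytes, expected {m * bps} "
            f"for {n} samples x {m} SNPs"
        )
    codes = payload.reshape(m, bps)
    # unpack 2-bit fields, sample index runs over bits 0-1, 2-3, 4-5, 6-7
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    expanded = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    expanded = expanded.reshape(m, bps * 4)[:, :n]
    calls = _CODE_TO_DOSAGE[expanded].T  # samples x snps
    return GenotypeDataset(samples=samples, snps=bim, calls=calls)


def _read_pedmap(prefix: Path) -> GenotypeDataset:
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] != 4:
        raise PlinkFormatError(f"{prefix}.map must have 4 columns")
    ped_rows = [ln.split() for ln in prefix.with_suffix(".ped").read_text().splitlines() if ln.strip()]
    m = len(mp)
    samples, geno = [], []
    for row in ped_rows:
        if len(row) != 6 + 2 * m:
            raise PlinkFormatError(
                f"{prefix}.ped: row for {row[1] if len(row) > 1 else '?'} has "
                f"{len(row) - 6} allele fields, expected {2 * m}"
            )
        samples.append(row[1])
        geno.append(row[6:])
    alleles = np.array(geno, dtype=object).reshape(len(samples), m, 2)
    calls = np.full((len(samples), m), MISSING, dtype=np.int8)
    a_list, b_list = [], []
    for j in range(m):
        col = alleles[:, j, :]
        obs = sorted({a for a in col.ravel() if a != "0"})
        if len(obs) > 2:
            raise PlinkFormatError(f"SNP {mp.iloc[j, 1]}: more than two alleles {obs}")
        # allele_b = last observed (alphabetical), allele_a the other or '0'
        b = obs[-1] if obs else "0"
        a = obs[0] if len(obs) == 2 else "0"
        a_list.append(a)
        b_list.append(b)
        known = (col != "0").all(axis=1)
        calls[known, j] = (col[known] == b).sum(axis=1)
    bim = pd.DataFrame(
        {
            "chrom": mp.iloc[:, 0],
            "snp_id": mp.iloc[:, 1],
            "cm": mp.iloc[:, 2].astype(float),
            "pos": mp.iloc[:, 3].astype(int),
            "allele_a": a_list,
            "allele_b": b_list,
        }
    )
    return GenotypeDataset(samples=samples, snps=bim, calls=calls)


def write_plink(data: GenotypeDataset, prefix) -> None:
    """Write ``prefix.bed/.bim/.fam`` (SNP-major PLINK 1 binary)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fam = pd.DataFrame(
        {
            "fid": data.samples,
            "iid": data.samples,
            "sire": "0",
            "dam": "0",
            "sex": "0",
            "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    data.snps[_BIM_COLS].to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n, m = data.n_samples, data.n_snps
    bps = (n + 3) // 4
    code = np.zeros((m, bps * 4), dtype=np.uint8)
    calls_t = data.calls.T  # snps x samples
    lut = np.zeros(256, dtype=np.uint8)
    lut[0], lut[1], lut[2] = 0, 2, 3
    lut[np.int8(MISSING).view(np.uint8)] = 1
    code[:, :n] = lut[calls_t.view(np.uint8)]
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (code.reshape(m, bps, 4) << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
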