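from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from rrgwas.pedigree import Pedigree
from rrgwas.plinkio import MISSING, GenotypeDataset
from rrgwas.qc import (
    QcThresholds,
    apply_qc,
    hwe_exact_p,
    mendel_error_rate,
    minor_allele_frequency,
)
from rrgwas.simulate import SimConfig, simulate_study


# --- independent enumeration oracle for the exact HWE test ----------------

def hwe_enumeration_oracle(n_aa: int, n_het: int, n_bb: int) -> float:
    """Exact two-sided HWE p by full enumeration with rational arithmetic."""
    n = n_aa + n_het + n_bb
    n_a = 2 * n_aa + n_het
    n_b = 2 * n_bb + n_het
    n_minor = min(n_a, n_b)

    def prob(h: int) -> Fraction:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return Fraction(
            factorial(n) * 2**h * factorial(n_a) * factorial(n_b),
            factorial(hom_minor) * factorial(h) * factorial(hom_major) * factorial(2 * n),
        )

    probs = {h: prob(h) for h in range(n_minor % 2, n_minor + 1, 2)}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestMaf:
    @pytest.mark.parametrize(
        "col,expected",
        [([0, 0, 0, 0], 0.0), ([2, 2, 2, 2], 0.0), ([0, 1, 2, 1], 0.5), ([0, 0, 1, 1], 0.25)],
    )
    def test_examples(self, col, expected):
        assert minor_allele_frequency(np.array(col)) == pytest.approx(expected)

    def test_missing_excluded(self):
        assert minor_allele_frequency(np.array([0, 2, MISSING])) == pytest.approx(0.5)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            minor_allele_frequency(np.array([MISSING, MISSING]))

    @pytest.mark.parametrize("seed", range(20))
    def test_folding_invariance(self, seed):
        """MAF is invariant under swapping the allele labels (2 - dosage)."""
        rng = np.random.default_rng(seed)
        col = rng.integers(0, 3, size=30).astype(np.int8)
        flipped = (2 - col).astype(np.int8)
        assert minor_allele_frequency(col) == pytest.approx(
            minor_allele_frequency(flipped)
        )


class TestHwe:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(0, 0, 25) == 1.0
        assert hwe_exact_p(25, 0, 0) == 1.0

    @pytest.mark.parametrize("table", [(1, 0, 1), (5, 10, 5), (0, 2, 0), (3, 1, 7)])
    def test_matches_enumeration_examples(self, table):
        assert hwe_exact_p(*table) == pytest.approx(hwe_enumeration_oracle(*table), abs=1e-12)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_enumeration_random_tables(self, seed):
        """Exact agreement with the rational-arithmetic oracle, total <= 50."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 51))
        n_aa = int(rng.integers(0, n + 1))
        n_het = int(rng.integers(0, n - n_aa + 1))
        n_bb = n - n_aa - n_het
        assert hwe_exact_p(n_aa, n_het, n_bb) == pytest.approx(
            hwe_enumeration_oracle(n_aa, n_het, n_bb), abs=1e-12
        )

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)


def _dataset(calls, chrom=None, pos=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snps = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "snp_id": [f"s{j}" for j in range(m)],
            "cm": 0.0,
            "pos": pos if pos is not None else np.arange(1, m + 1),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    return GenotypeDataset(samples=[f"i{k}" for k in range(n)], snps=snps, calls=calls)


class TestMendel:
    def test_impossible_trio_rate_one(self):
        """Child dosage 2 with both parents 0 is a Mendelian error."""
        data = _dataset([[0], [0], [2]])
        ped = Pedigree(records=[("i0", "0", "0"), ("i1", "0", "0"), ("i2", "i0", "i1")])
        assert mendel_error_rate(data, ped)[0] == pytest.approx(1.0)
        clean, report = apply_qc(data, ped, QcThresholds(maf_min=0.0, hwe_p_min=0.0))
        assert report.removed_mendel == 1
        assert clean.n_snps == 0

    def test_consistent_trio_rate_zero(self):
        data = _dataset([[0], [2], [1]])
        ped = Pedigree(records=[("i0", "0", "0"), ("i1", "0", "0"), ("i2", "i0", "i1")])
        assert mendel_error_rate(data, ped)[0] == 0.0

    def test_duo_opposite_homozygotes(self):
        data = _dataset([[0], [2]])
        ped = Pedigree(records=[("i0", "0", "0"), ("i1", "i0", "0")])
        assert mendel_error_rate(data, ped)[0] == pytest.approx(1.0)

    def test_gene_dropped_data_has_no_errors(self, small_sim):
        """Mendelian transmission without genotyping error is consistent."""
        rates = mendel_error_rate(small_sim.genotypes, small_sim.pedigree)
        assert rates.max() == 0.0


class TestApplyQc:
    def test_maf_criterion_removes_rare_snp(self):
        # 1 het among 100 individuals: MAF = 0.005 < 0.01
        calls = np.zeros((100, 2), dtype=np.int8)
        calls[0, 0] = 1
        calls[:50, 1] = 1  # common SNP passes
        data = _dataset(calls)
        clean, report = apply_qc(data, thresholds=QcThresholds(hwe_p_min=0.0))
        assert report.removed_maf == 1
        assert clean.snps["snp_id"].tolist() == ["s1"]

    def test_clean_dataset_untouched(self, small_sim):
        clean, report = apply_qc(small_sim.genotypes, small_sim.pedigree)
        clean2, report2 = apply_qc(clean, small_sim.pedigree)
        assert clean2.n_snps == clean.n_snps
        assert clean2.n_samples == clean.n_samples
        np.testing.assert_array_equal(clean2.calls, clean.calls)
        assert sum(getattr(report2, c) for c in report2.snp_criteria) == 0

    def test_missing_map_position_removed(self):
        calls = np.tile(np.array([[0], [1], [2], [1]], dtype=np.int8), (1, 2))
        data = _dataset(calls, chrom=["0", "1"])
        clean, report = apply_qc(data, thresholds=QcThresholds(hwe_p_min=0.0))
        assert report.removed_map_position == 1

    def test_duplicate_position_keeps_higher_call_rate(self):
        calls = np.array(
            [[0, 0], [1, 1], [2, MISSING], [1, 1]], dtype=np.int8
        )
        data = _dataset(calls, pos=[100, 100])
        clean, report = apply_qc(
            data, thresholds=QcThresholds(call_rate_min=0.0, hwe_p_min=0.0, maf_min=0.0)
        )
        assert report.removed_duplicate_position == 1
        assert clean.snps["snp_id"].tolist() == ["s0"]

    def test_individual_missingness_filter(self):
        calls = np.ones((4, 10), dtype=np.int8)
        calls[0, :5] = MISSING  # 50% missing
        data = _dataset(calls)
        clean, report = apply_qc(
            data,
            thresholds=QcThresholds(maf_min=0.0, hwe_p_min=0.0, call_rate_min=0.0),
        )
        assert report.removed_individual_missingness == 1
        assert clean.n_samples == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_report_counts_are_consistent(self, seed):
        """removed + kept = input totals on random fixtures."""
        cfg = SimConfig(
            seed=seed, n_founders=20, n_generations=1, n_snps=40,
            missing_rate=0.05, genotype_error_rate=0.02, maf_range=(0.0, 0.5),
        )
        sim = simulate_study(cfg)
        clean, rep = apply_qc(sim.genotypes, sim.pedigree)
        removed_snps = sum(getattr(rep, c) for c in rep.snp_criteria)
        assert removed_snps + rep.n_snps_out == rep.n_snps_in
        assert rep.removed_individual_missingness + rep.n_samples_out == rep.n_samples_in

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        cfg = SimConfig(
            seed=50 + seed, n_founders=24, n_generations=1, n_snps=40,
            missing_rate=0.02, maf_range=(0.0, 0.5),
        )
        sim = simulate_study(cfg)
        once, _ = apply_qc(sim.genotypes, sim.pedigree)
        twice, rep2 = apply_qc(once, sim.pedigree)
        np.testing.assert_array_equal(once.calls, twice.calls)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            QcThresholds(maf_min=1.5)
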