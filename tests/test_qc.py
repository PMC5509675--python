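"""Quality-control filters, the Hardy-Weinberg exact test against an
enumeration oracle, PLINK dialect handling and cohort merging."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casevar import (
    QcThresholds,
    hwe_exact_test,
    merge_cohorts,
    qc_filter,
    read_plink,
    write_plink,
)
from casevar.datatypes import EmptyStudyError, PlinkFormatError

from conftest import make_study


def hwe_exact_bruteforce(n_AA, n_Aa, n_aa):
    """Independent oracle: exact rational enumeration of the conditional
    distribution of heterozygote counts given allele counts."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # count of the 'a' allele
    probs = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom_a = (n_a - het) // 2
        hom_A = n - het - hom_a
        if hom_A < 0 or hom_a < 0:
            continue
        # multinomial genotype configurations x 2^het phased hets,
        # over choose(2n, n_a) allele arrangements
        w = Fraction(
            comb(n, hom_a) * comb(n - hom_a, het) * 2 ** het,
            comb(2 * n, n_a))
        probs[het] = w
    p_obs = probs[n_Aa]
    return float(sum(v for v in probs.values() if v <= p_obs))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    @pytest.mark.parametrize("counts", [
        (57, 14, 50), (10, 20, 10), (0, 3, 1), (100, 50, 5), (2, 9, 2),
        (1, 1, 1), (968, 30, 2),
    ])
    def test_matches_bruteforce_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_exact_bruteforce(*counts), rel=1e-10)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_valid_probability_and_symmetry(self, a, b, c):
        if a + b + c == 0:
            return
        p = hwe_exact_test(a, b, c)
        assert 0.0 < p <= 1.0
        # relabelling the alleles cannot change the test
        assert p == pytest.approx(hwe_exact_test(c, b, a), rel=1e-12)

    def test_agrees_with_chisquare_at_large_counts(self):
        """For counts >= 1000 per genotype the exact and chi-square HWE
        tests agree within 10% relative."""
        from scipy import stats

        for counts in [(1000, 2050, 1000), (1500, 3100, 1650),
                       (1200, 2300, 1250)]:
            nAA, nAa, naa = counts
            n = sum(counts)
            p = (2 * nAA + nAa) / (2 * n)
            exp = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2]) * n
            chi = ((np.array(counts) - exp) ** 2 / exp).sum()
            p_chi = stats.chi2.sf(chi, 1)
            p_exact = hwe_exact_test(*counts)
            assert abs(p_exact - p_chi) / p_chi < 0.10


class TestQcFilter:
    def _clean_study(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, size=(200, 10)).astype(float)
        ph = rng.integers(0, 2, 200).astype(float)
        return make_study(g, phenotype=ph)

    def test_passing_study_unchanged(self):
        study = self._clean_study()
        out, report = qc_filter(study, QcThresholds())
        assert out.n_samples == study.n_samples
        assert out.n_variants == study.n_variants
        np.testing.assert_array_equal(out.genotypes, study.genotypes)
        assert report.variants_removed_total == 0
        assert report.samples_low_call == 0

    def test_low_maf_variants_removed(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, size=(2000, 5)).astype(float)
        g[:, 1] = rng.binomial(2, 0.005, size=2000)  # MAF ~0.005
        g[:, 3] = rng.binomial(2, 0.005, size=2000)
        study = make_study(g, phenotype=rng.integers(0, 2, 2000).astype(float))
        out, report = qc_filter(study, QcThresholds(maf_min=0.01))
        assert report.variants_low_maf == 2
        assert list(out.variants["snp"]) == ["snp0", "snp2", "snp4"]

    def test_sample_call_rate_removals_match_hand_count(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, size=(100, 200)).astype(float)
        # mask ~2% of genotypes in 10 chosen samples
        bad = rng.choice(100, 10, replace=False)
        for i in bad:
            g[i, rng.choice(200, 4, replace=False)] = np.nan
        study = make_study(g, phenotype=rng.integers(0, 2, 100).astype(float))
        call = 1 - np.isnan(g).mean(axis=1)
        expected_removed = int((call <= 0.99).sum())
        out, report = qc_filter(study, QcThresholds())
        assert report.samples_low_call == expected_removed
        assert out.n_samples == 100 - expected_removed

    def test_hwe_failures_removed(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, size=(500, 4)).astype(float)
        g[:, 2] = np.where(rng.random(500) < 0.4, 0.0, 2.0)  # no hets at all
        study = make_study(g, phenotype=rng.integers(0, 2, 500).astype(float))
        out, report = qc_filter(study)
        assert report.variants_hwe_fail == 1
        assert "snp2" not in set(out.variants["snp"])

    def test_nonautosomal_variants_removed(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, size=(100, 3)).astype(float)
        study = make_study(g, phenotype=rng.integers(0, 2, 100).astype(float),
                           chrom=["1", "X", "2"])
        out, report = qc_filter(study)
        assert report.variants_nonautosomal == 1
        assert set(out.variants["chrom"]) == {"1", "2"}

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, rng.uniform(0.005, 0.5, 30), size=(300, 30)).astype(float)
        g[rng.random(g.shape) < 0.02] = np.nan
        study = make_study(g, phenotype=rng.integers(0, 2, 300).astype(float))
        once, _ = qc_filter(study)
        twice, rep2 = qc_filter(once)
        assert rep2.variants_removed_total == 0 and rep2.samples_low_call == 0
        np.testing.assert_array_equal(
            np.nan_to_num(once.genotypes, nan=-1),
            np.nan_to_num(twice.genotypes, nan=-1))

    def test_empty_result_raises(self):
        g = np.zeros((50, 3))  # all monomorphic: MAF filter removes all
        study = make_study(g, phenotype=np.resize([0.0, 1.0], 50))
        with pytest.raises(EmptyStudyError):
            qc_filter(study)


class TestPlinkDialect:
    def test_missing_phenotype_codes(self, tmp_path):
        g = np.array([[0, 1], [2, 1], [1, 0.0]])
        study = make_study(g, phenotype=[1.0, 0.0, np.nan], sex=[1, 2, 0])
        write_plink(study, str(tmp_path / "t"))
        fam = (tmp_path / "t.fam").read_text().strip().splitlines()
        assert fam[0].split()[-1] == "2"   # case
        assert fam[1].split()[-1] == "1"   # control
        assert fam[2].split()[-1] == "-9"  # missing
        back = read_plink(str(tmp_path / "t"))
        assert np.isnan(back.samples["phenotype"].iloc[2])
        assert list(back.samples["sex"]) == [1, 2, 0]

    def test_missing_genotype_bed_code(self, tmp_path):
        g = np.array([[np.nan, 1], [2, np.nan], [1, 0.0]])
        study = make_study(g, phenotype=[1.0, 0.0, 0.0])
        write_plink(study, str(tmp_path / "m"))
        back = read_plink(str(tmp_path / "m"))
        np.testing.assert_array_equal(np.isnan(back.genotypes),
                                      np.isnan(g))

    def test_bad_magic_rejected(self, tmp_path):
        g = np.array([[0, 1], [2, 1.0]])
        study = make_study(g, phenotype=[1.0, 0.0])
        write_plink(study, str(tmp_path / "b"))
        raw = (tmp_path / "b.bed").read_bytes()
        (tmp_path / "b.bed").write_bytes(b"\x00\x00" + raw[2:])
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink(str(tmp_path / "b"))

    def test_truncated_bed_rejected(self, tmp_path):
        g = np.ones((5, 4))
        study = make_study(g, phenotype=[1, 0, 0, 1, 0.0])
        write_plink(study, str(tmp_path / "tr"))
        raw = (tmp_path / "tr.bed").read_bytes()
        (tmp_path / "tr.bed").write_bytes(raw[:-1])
        with pytest.raises(PlinkFormatError, match="truncated|oversized"):
            read_plink(str(tmp_path / "tr"))


class TestMergeCohorts:
    def _cohort(self, seed, n, snps, prefix):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, size=(n, len(snps))).astype(float)
        study = make_study(g, phenotype=rng.integers(0, 2, n).astype(float))
        study.samples["iid"] = [f"{prefix}{i}" for i in range(n)]
        study.samples["cohort"] = prefix
        study.variants["snp"] = snps
        return study

    def test_identical_panels_union_of_samples(self):
        a = self._cohort(0, 30, ["s1", "s2", "s3"], "A")
        b = self._cohort(1, 20, ["s1", "s2", "s3"], "B")
        merged, _ = merge_cohorts([a, b])
        assert merged.n_samples == 50
        assert list(merged.variants["snp"]) == ["s1", "s2", "s3"]
        assert set(merged.samples["cohort"]) == {"A", "B"}

    def test_common_snp_intersection(self):
        a = self._cohort(0, 10, ["s1", "s2", "s3"], "A")
        b = self._cohort(1, 10, ["s2", "s3", "s4"], "B")
        merged, _ = merge_cohorts([a, b])
        assert list(merged.variants["snp"]) == ["s2", "s3"]

    def test_swapped_alleles_flipped(self):
        a = self._cohort(0, 15, ["s1", "s2"], "A")
        b = self._cohort(1, 15, ["s1", "s2"], "B")
        b.variants.loc[0, ["a1", "a2"]] = ["G", "A"]  # swapped at s1
        orig = b.genotypes[:, 0].copy()
        merged, _ = merge_cohorts([a, b])
        j = list(merged.variants["snp"]).index("s1")
        np.testing.assert_array_equal(merged.genotypes[15:, j], 2.0 - orig)

    def test_unresolvable_alleles_dropped_with_warning(self):
        a = self._cohort(0, 10, ["s1", "s2"], "A")
        b = self._cohort(1, 10, ["s1", "s2"], "B")
        b.variants.loc[1, ["a1", "a2"]] = ["C", "T"]
        with pytest.warns(UserWarning, match="not resolvable"):
            merged, report = merge_cohorts([a, b])
        assert report.variants_unresolvable_alleles == 1
        assert list(merged.variants["snp"]) == ["s1"]

    def test_order_invariant_up_to_sample_order(self):
        a = self._cohort(0, 12, ["s1", "s2", "s3"], "A")
        b = self._cohort(1, 8, ["s3", "s1", "s2"], "B")
        m1, _ = merge_cohorts([a, b])
        m2, _ = merge_cohorts([b, a])
        d1 = pd.DataFrame(m1.genotypes, index=m1.samples["iid"],
                          columns=m1.variants["snp"])
        d2 = pd.DataFrame(m2.genotypes, index=m2.samples["iid"],
                          columns=m2.variants["snp"])
        d2 = d2.loc[d1.index, d1.columns]
        pd.testing.assert_frame_equal(d1, d2)

    def test_duplicate_sample_ids_rejected(self):
        a = self._cohort(0, 5, ["s1"], "A")
        b = self._cohort(1, 5, ["s1"], "A")  # same iid prefix -> collision
        with pytest.raises(ValueError, match="disjoint"):
            merge_cohorts([a, b])

    def test_six_cohorts_sized_like_reference_study(self):
        """Six cohorts with the reference case/control counts merge to
        19,108 samples."""
        sizes = [(997, 8414), (593, 2118), (982, 1927),
                 (237, 941), (299, 1991), (215, 394)]
        cohorts = []
        for i, (ncase, nctrl) in enumerate(sizes):
            n = ncase + nctrl
            c = self._cohort(i, n, ["s1", "s2"], f"C{i}_")
            c.samples["phenotype"] = np.r_[np.ones(ncase), np.zeros(nctrl)]
            cohorts.append(c)
        merged, _ = merge_cohorts(cohorts)
        assert merged.n_samples == 19108
        assert (merged.samples["phenotype"] == 1.0).sum() == 3323
        assert (merged.samples["phenotype"] == 0.0).sum() == 15785
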