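"""VCF ingestion, allele frequencies, HWE exact test and variant QC."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcsgwas.genotype_io import (
    allele_frequency,
    hwe_exact_test,
    minor_allele_frequency,
    qc_filter,
    read_genotypes,
    write_genotypes,
)
from lcsgwas.types import MISSING, DosageMatrix, GenotypeMatrix, VariantMeta

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# VCF reading / writing


def _write_vcf(path, body):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##INFO=<ID=INFO_SCORE,Number=1,Type=Float,Description="x">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2\n"
    )
    path.write_text(header + body)


def test_read_gt_codes_alt_allele_counts(tmp_path):
    vcf = tmp_path / "x.vcf"
    _write_vcf(vcf, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
    g = read_genotypes(vcf, field="GT")
    assert isinstance(g, GenotypeMatrix)
    np.testing.assert_array_equal(g.calls[:, 0], [0, 1, 2])


def test_multiallelic_and_indel_records_dropped(tmp_path):
    vcf = tmp_path / "x.vcf"
    _write_vcf(
        vcf,
        "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t300\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
    )
    g = read_genotypes(vcf, field="GT")
    assert g.n_variants == 1
    assert g.n_dropped_non_biallelic == 2


def test_vcf_round_trip_genotypes_and_dosages(tmp_path):
    g = make_genotypes([[0, 1, 2], [2, MISSING, 1], [1, 0, 0]])
    p1 = tmp_path / "g.vcf"
    write_genotypes(g, p1)
    g2 = read_genotypes(p1, field="GT")
    np.testing.assert_array_equal(g.calls, g2.calls)
    assert [v.key for v in g.variants] == [v.key for v in g2.variants]
    assert g.sample_ids == g2.sample_ids

    probs = np.zeros((3, 3, 3))
    probs[..., 0] = 0.25
    probs[..., 1] = 0.5
    probs[..., 2] = 0.25
    d = DosageMatrix(g.sample_ids, g.variants, np.full((3, 3), 1.0), probs)
    p2 = tmp_path / "d.vcf"
    write_genotypes(d, p2)
    d2 = read_genotypes(p2, field="DS")
    np.testing.assert_allclose(d.dosages, d2.dosages, atol=1e-5)
    d3 = read_genotypes(p2, field="GP")
    np.testing.assert_allclose(d3.probs, probs, atol=1e-5)


def test_info_score_read_from_info_tag(tmp_path):
    vcf = tmp_path / "x.vcf"
    _write_vcf(
        vcf,
        "1\t100\t.\tA\tG\t.\tPASS\tINFO_SCORE=0.87\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
    )
    g = read_genotypes(vcf, field="GT")
    assert g.variants[0].info_score == pytest.approx(0.87, abs=1e-6)
    assert g.variants[1].info_score is None


def test_unreadable_file_is_fatal(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_genotypes(tmp_path / "absent.vcf")


# ---------------------------------------------------------------------------
# allele frequency


@pytest.mark.parametrize(
    "calls, expected_p, expected_maf",
    [
        ([[0], [1], [2]], 0.5, 0.5),
        ([[2], [2], [MISSING]], 1.0, 0.0),
        ([[0], [0], [1], [1]], 0.25, 0.25),
    ],
)
def test_allele_frequency_examples(calls, expected_p, expected_maf):
    g = make_genotypes(calls)
    assert allele_frequency(g, 0) == pytest.approx(expected_p)
    assert minor_allele_frequency(g, 0) == pytest.approx(expected_maf)


def test_allele_frequency_all_missing_is_an_error():
    g = make_genotypes([[MISSING], [MISSING]])
    with pytest.raises(ValueError):
        allele_frequency(g, 0)


# ---------------------------------------------------------------------------
# HWE exact test


def _hwe_enumeration_oracle(n_homref, n_het, n_homalt):
    """Exact-fraction enumeration of the conditional het-count distribution."""
    n = n_homref + n_het + n_homalt
    na = 2 * n_homref + n_het
    nb = 2 * n - na
    def prob(h):
        ha, hb = (na - h) // 2, (nb - h) // 2
        if ha < 0 or hb < 0:
            return Fraction(0)
        return (
            Fraction(factorial(n), factorial(ha) * factorial(h) * factorial(hb))
            * 2**h
            * Fraction(factorial(na) * factorial(nb), factorial(2 * n))
        )
    probs = {h: prob(h) for h in range(min(na, nb) + 1) if (na - h) % 2 == 0}
    p_obs = probs[n_het]
    return float(sum(v for v in probs.values() if v <= p_obs))


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((100, 0, 0), 1.0),  # monomorphic: single outcome
        ((25, 50, 25), 1.0),  # perfectly at HWE proportions
        ((50, 0, 50), 1.114224180581451e-30),  # extreme het deficit
        ((10, 2, 8), 2.9479593246097e-4),
    ],
)
def test_hwe_matches_enumeration_oracle(counts, expected):
    got = hwe_exact_test(*counts)
    assert got == pytest.approx(expected, rel=1e-9)
    assert got == pytest.approx(_hwe_enumeration_oracle(*counts), rel=1e-9)


def test_hwe_extreme_case_is_tiny():
    assert hwe_exact_test(50, 0, 50) < 1e-20


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a=st.integers(0, 60), h=st.integers(0, 60), b=st.integers(0, 60)
)
def test_hwe_symmetric_and_bounded(a, h, b):
    if a + h + b == 0:
        return
    p1 = hwe_exact_test(a, h, b)
    p2 = hwe_exact_test(b, h, a)
    assert p1 == pytest.approx(p2, rel=1e-9)
    assert 0.0 <= p1 <= 1.0


# ---------------------------------------------------------------------------
# QC filter


def _qc_toy():
    """5 variants, n=100: 0 and 2 fail MAF, 1 fails missingness, 3 fails HWE."""
    n = 100
    calls = np.zeros((n, 5), dtype=np.int8)
    # variant 0: monomorphic -> MAF 0
    # variant 1: MAF fine but 15% missing
    calls[:30, 1] = 1
    calls[:15, 1] = MISSING
    # variant 2: MAF 0.03
    calls[:6, 2] = 1
    # variant 3: MAF 0.5 but extreme het deficit -> HWE fails
    calls[:50, 3] = 2
    # variant 4: clean, near HWE
    calls[:25, 4] = 2
    calls[25:75, 4] = 1
    return make_genotypes(calls)


def test_qc_filter_rule_attribution_counts():
    g = _qc_toy()
    res = qc_filter(g)
    assert res.removal_counts == (2, 1, 1, 0)
    assert res.data.n_variants == 1
    assert res.data.variants[0].pos == g.variants[4].pos
    assert list(res.report()["rule_failed"]) == ["maf", "missing", "maf", "hwe", "pass"]


def test_qc_info_score_boundary_is_strict():
    g = make_genotypes([[0], [1], [1], [2], [1], [0]])
    g.variants[0] = VariantMeta("1", 100, "A", "G", info_score=0.4)
    res = qc_filter(g)
    assert res.data.n_variants == 0
    assert res.n_removed_info == 1
    g.variants[0] = VariantMeta("1", 100, "A", "G", info_score=0.41)
    res2 = qc_filter(g)
    assert res2.data.n_variants == 1


def test_qc_permissive_thresholds_keep_everything():
    g = _qc_toy()
    res = qc_filter(g, maf_min=0.0, miss_max=1.0, hwe_min=0.0, info_min=0.0)
    # MAF rule stays strict: the monomorphic variant has MAF == 0, not > 0
    assert res.data.n_variants == 4
    res_all = qc_filter(
        g.take_variants([1, 2, 3, 4]), maf_min=0.0, miss_max=1.0, hwe_min=0.0
    )
    assert res_all.data.n_variants == 4


def test_qc_filter_is_idempotent():
    g = _qc_toy()
    once = qc_filter(g)
    twice = qc_filter(once.data)
    assert twice.removal_counts == (0, 0, 0, 0)
    assert twice.data.n_variants == once.data.n_variants
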