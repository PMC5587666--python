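"""File formats, QC filters, imputation and normalization."""

import numpy as np
import pytest
from scipy import stats

from dpreg.errors import (
    DegenerateDataError,
    EmptyPanelError,
    FormatError,
    InvalidParameterError,
)
from dpreg.genotype_io import (
    GenotypeMatrix,
    QuantileNormalizer,
    SNPRecord,
    apply_qc,
    center_genotypes,
    hwe_test,
    mean_impute,
    quantile_normalize,
    read_bimbam,
    read_plink,
    snp_statistics,
    write_bimbam,
    write_plink,
)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def _toy_gm(dosages, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    p = dosages.shape[1]
    snps = [SNPRecord(id=ids[j] if ids else f"snp{j}", chromosome="1",
                      position=j + 1) for j in range(p)]
    return GenotypeMatrix(dosages=dosages, snps=snps,
                          sample_ids=[f"s{i}" for i in range(dosages.shape[0])])


class TestPlink:
    def test_hand_built_fixture_decodes(self, tmp_path):
        """3 samples x 2 SNPs built byte-by-byte, one planted missing call."""
        prefix = tmp_path / "toy"
        (tmp_path / "toy.bim").write_text(
            "1\trs1\t0\t100\tA\tG\n1\trs2\t0\t200\tC\tT\n")
        (tmp_path / "toy.fam").write_text(
            "f1\ti1\t0\t0\t0\t-9\nf2\ti2\t0\t0\t0\t-9\nf3\ti3\t0\t0\t0\t-9\n")
        # SNP1: codes hom-a1(00), het(10), hom-a2(11) -> dosages 2,1,0
        # SNP2: het(10), missing(01), hom-a1(00)      -> dosages 1,NA,2
        snp1 = 0b00_11_10_00  # sample3|sample2|sample1 (low bits first)
        snp2 = 0b00_00_01_10
        (tmp_path / "toy.bed").write_bytes(_BED_MAGIC + bytes([snp1, snp2]))
        gm = read_plink(prefix)
        assert gm.snp_ids() == ["rs1", "rs2"]
        np.testing.assert_array_equal(gm.dosages[:, 0], [2.0, 1.0, 0.0])
        assert gm.dosages[0, 1] == 1.0 and gm.dosages[2, 1] == 2.0
        assert np.isnan(gm.dosages[1, 1]) and np.isnan(gm.dosages).sum() == 1
        assert gm.snps[0].allele1 == "A"

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        for trial in range(5):
            d = rng.choice([0.0, 1.0, 2.0, np.nan], size=(7, 4),
                           p=[0.3, 0.3, 0.3, 0.1])
            gm = _toy_gm(d)
            write_plink(gm, tmp_path / f"rt{trial}")
            back = read_plink(tmp_path / f"rt{trial}")
            np.testing.assert_array_equal(back.dosages, gm.dosages)
            assert back.snp_ids() == gm.snp_ids()

    def test_bad_magic_rejected(self, tmp_path):
        write_plink(_toy_gm([[0, 1], [1, 2]]), tmp_path / "bad")
        raw = (tmp_path / "bad.bed").read_bytes()
        (tmp_path / "bad.bed").write_bytes(b"\x00\x00" + raw[2:])
        with pytest.raises(FormatError, match="magic"):
            read_plink(tmp_path / "bad")

    def test_truncated_bed_rejected(self, tmp_path):
        write_plink(_toy_gm(np.ones((5, 3))), tmp_path / "tr")
        raw = (tmp_path / "tr.bed").read_bytes()
        (tmp_path / "tr.bed").write_bytes(raw[:-1])
        with pytest.raises(FormatError, match="inconsistent"):
            read_plink(tmp_path / "tr")

    def test_soft_dosages_rejected_on_write(self, tmp_path):
        with pytest.raises(FormatError):
            write_plink(_toy_gm([[0.5, 1.0]]), tmp_path / "soft")


class TestBimbam:
    def test_round_trip_with_missing(self, tmp_path):
        d = np.array([[0.0, 1.5], [np.nan, 2.0], [1.0, 0.0]])
        gm = _toy_gm(d, ids=["rs1", "rs2"])
        write_bimbam(gm, tmp_path / "g.txt")
        back = read_bimbam(tmp_path / "g.txt")
        np.testing.assert_array_equal(back.dosages, d)
        assert back.snp_ids() == ["rs1", "rs2"]

    def test_malformed_rows_rejected(self, tmp_path):
        (tmp_path / "bad.txt").write_text("rs1 A G 1 0\nrs2 A G 1\n")
        with pytest.raises(FormatError, match="inconsistent"):
            read_bimbam(tmp_path / "bad.txt")
        (tmp_path / "bad2.txt").write_text("rs1 A G x y\n")
        with pytest.raises(FormatError, match="non-numeric"):
            read_bimbam(tmp_path / "bad2.txt")


class TestHWE:
    def test_exact_proportions(self):
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)

    def test_all_heterozygote_fails_filter(self):
        # chi2 = 100 against expected (25, 50, 25)
        p = hwe_test((0, 100, 0))
        assert p == pytest.approx(stats.chi2.sf(100, 1), rel=1e-10)
        assert p < 1e-4

    def test_monomorphic_convention(self):
        assert hwe_test((10, 0, 0)) == 1.0
        assert hwe_test((0, 0, 7)) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            hwe_test((-1, 5, 5))


def _qc_panel(n=200, seed=0):
    """One SNP failing each rule plus one clean SNP."""
    rng = np.random.default_rng(seed)
    clean = rng.binomial(2, 0.3, n).astype(float)
    hwe_fail = np.ones(n)  # every sample heterozygous
    call_fail = rng.binomial(2, 0.3, n).astype(float)
    call_fail[: n // 10 + 1] = np.nan  # call rate just below 95%
    maf_fail = np.zeros(n)
    maf_fail[0] = 1.0  # MAF 1/(2n) << 1%
    return _toy_gm(np.column_stack([hwe_fail, call_fail, maf_fail, clean]),
                   ids=["hwe_fail", "call_fail", "maf_fail", "clean"])


class TestQC:
    def test_planted_failures_removed(self):
        filtered, report = apply_qc(_qc_panel())
        assert filtered.snp_ids() == ["clean"]
        assert dict(zip(report.snp_id, report.failed_rule)) == {
            "hwe_fail": "hwe", "call_fail": "call_rate", "maf_fail": "maf"}

    def test_zero_thresholds_keep_everything(self):
        filtered, report = apply_qc(_qc_panel(), hwe_thresh=0.0,
                                    call_thresh=0.0, maf_thresh=0.0)
        assert filtered.p == 4 and report.empty

    def test_all_removed_raises(self):
        gm = _toy_gm(np.ones((50, 2)))  # all-het columns fail HWE
        with pytest.raises(EmptyPanelError):
            apply_qc(gm)

    def test_filter_order_independence(self):
        """Survivors equal the intersection of the three individual filters."""
        gm = _qc_panel()
        combined, _ = apply_qc(gm)
        single = []
        for kw in ({"call_thresh": 0.0, "maf_thresh": 0.0},
                   {"hwe_thresh": 0.0, "maf_thresh": 0.0},
                   {"hwe_thresh": 0.0, "call_thresh": 0.0}):
            f, _ = apply_qc(gm, **kw)
            single.append(set(f.snp_ids()))
        assert set(combined.snp_ids()) == set.intersection(*single)

    def test_maf_arithmetic(self):
        gm = snp_statistics(_toy_gm(np.array([[0.0], [0.0], [1.0], [2.0]])))
        assert gm.snps[0].maf == pytest.approx(3.0 / 8.0)
        assert gm.snps[0].call_rate == 1.0


class TestImputation:
    def test_examples(self):
        gm = _toy_gm(np.array([[0.0, 2.0], [np.nan, 2.0],
                               [2.0, np.nan], [np.nan, 0.0]]))
        out = mean_impute(gm)
        np.testing.assert_allclose(out.dosages[:, 0], [0.0, 1.0, 2.0, 1.0])
        assert out.dosages[2, 1] == pytest.approx(4.0 / 3.0)

    def test_complete_column_unchanged(self):
        d = np.array([[0.0], [1.0], [2.0]])
        np.testing.assert_array_equal(mean_impute(_toy_gm(d)).dosages, d)

    def test_fully_missing_rejected(self):
        with pytest.raises(DegenerateDataError):
            mean_impute(_toy_gm(np.full((3, 1), np.nan)))


class TestQuantileNormalization:
    def test_three_value_example(self):
        out = quantile_normalize([5.0, 1.0, 9.0])
        np.testing.assert_allclose(out, [0.0, -0.9674216, 0.9674216], atol=1e-6)

    def test_monotone_and_idempotent(self):
        rng = np.random.default_rng(1)
        v = rng.exponential(size=200)
        out = quantile_normalize(v)
        assert np.all(np.argsort(out) == np.argsort(v))
        np.testing.assert_allclose(quantile_normalize(out), out, atol=1e-12)

    def test_output_is_standard_normal(self):
        rng = np.random.default_rng(2)
        out = quantile_normalize(rng.exponential(size=10_000))
        assert stats.kstest(out, "norm").pvalue > 0.01

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateDataError):
            quantile_normalize(np.ones(10))

    def test_train_test_transform_consistency(self):
        rng = np.random.default_rng(3)
        train = rng.normal(size=500)
        qn = QuantileNormalizer().fit(train)
        np.testing.assert_allclose(qn.transform(train), quantile_normalize(train),
                                   atol=1e-12)
        # transform is monotone on unseen values
        test = rng.normal(size=100)
        order = np.argsort(test)
        assert np.all(np.diff(qn.transform(test)[order]) >= 0)


class TestCentering:
    def test_basic_and_round_trip(self):
        Xc, means = center_genotypes(np.array([[0.0], [1.0], [2.0]]))
        np.testing.assert_allclose(Xc.ravel(), [-1.0, 0.0, 1.0])
        assert means[0] == 1.0
        np.testing.assert_allclose(Xc + means, [[0.0], [1.0], [2.0]])

    def test_training_means_applied_to_test(self):
        Xc, _ = center_genotypes(np.array([[0.0], [0.0]]), means=np.array([1.5]))
        np.testing.assert_allclose(Xc.ravel(), [-1.5, -1.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            center_genotypes(np.zeros((3, 2)), means=np.zeros(3))
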