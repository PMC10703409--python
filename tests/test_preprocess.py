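"""Preprocessing contracts: polarization, MAF filtering, row sorting,
width standardization, VCF ingestion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepnet.demography import HaplotypeMatrix, ParameterError
from sweepnet.preprocess import (
    PreprocessConfig,
    filter_minor_allele,
    polarize_major_minor,
    preprocess_dataset,
    read_vcf_haplotypes,
    resize_width,
    sort_rows_frequency_blocks,
    standardize_width,
)


def hap(cols, positions=None):
    alleles = np.array(cols, dtype=np.uint8).T
    if positions is None:
        positions = np.arange(alleles.shape[1], dtype=float) * 10
    return HaplotypeMatrix(alleles=alleles, positions=positions)


def from_rows(rows):
    alleles = np.array(rows, dtype=np.uint8)
    return HaplotypeMatrix(alleles=alleles, positions=np.arange(alleles.shape[1], dtype=float))


@st.composite
def binary_matrices(draw):
    n = draw(st.integers(2, 10))
    k = draw(st.integers(1, 12))
    bits = draw(st.lists(st.integers(0, 1), min_size=n * k, max_size=n * k))
    return from_rows(np.array(bits).reshape(n, k))


class TestPolarization:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([1, 1, 1, 0], [0, 0, 0, 1]),  # derived is major: flip
            ([1, 0, 0, 0], [1, 0, 0, 0]),  # derived already minor
            ([1, 1, 0, 0], [1, 1, 0, 0]),  # exact tie: keep coding
        ],
    )
    def test_column_rules(self, column, expected):
        out = polarize_major_minor(hap([column]))
        assert out.alleles[:, 0].tolist() == expected

    @given(binary_matrices())
    @settings(max_examples=40, deadline=None)
    def test_allele_one_never_major(self, m):
        out = polarize_major_minor(m)
        assert (out.alleles.mean(axis=0) <= 0.5 + 1e-12).all()

    @given(binary_matrices())
    @settings(max_examples=40, deadline=None)
    def test_filter_polarize_commute(self, m):
        a = filter_minor_allele(polarize_major_minor(m), 0.25)
        b = polarize_major_minor(filter_minor_allele(m, 0.25))
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)


class TestMafFilter:
    def test_one_percent_rule_at_n128(self):
        singleton = np.zeros((128, 1), dtype=np.uint8)
        singleton[0] = 1
        doubleton = np.zeros((128, 1), dtype=np.uint8)
        doubleton[:2] = 1
        m = HaplotypeMatrix(
            alleles=np.hstack([singleton, doubleton]),
            positions=np.array([10.0, 20.0]),
        )
        out = filter_minor_allele(m, 0.01)
        assert out.n_sites == 1  # 1/128 < 1% removed; 2/128 kept
        assert out.positions.tolist() == [20.0]

    def test_zero_threshold_noop(self):
        m = from_rows([[0, 1, 0], [1, 0, 0], [1, 1, 1]])
        out = filter_minor_allele(m, 0.0)
        assert np.array_equal(out.alleles, m.alleles)

    def test_positions_filtered_in_lockstep(self):
        m = hap([[1, 0, 0, 0, 0, 0, 0, 0], [1, 1, 1, 1, 0, 0, 0, 0]],
                positions=np.array([5.0, 7.0]))
        out = filter_minor_allele(m, 0.25)
        assert out.positions.tolist() == [7.0]


class TestRowSorting:
    def test_frequency_order(self):
        a, b = [0, 1, 0], [1, 0, 1]
        out = sort_rows_frequency_blocks(from_rows([b, a, a]))
        assert out.alleles.tolist() == [a, a, b]

    def test_single_block_unchanged(self):
        m = from_rows([[1, 0, 1]] * 4)
        out = sort_rows_frequency_blocks(m)
        assert np.array_equal(out.alleles, m.alleles)

    def test_tie_breaks_lexicographic(self):
        # exhaustive over distinct 2-row matrices of width 2
        for a in range(4):
            for b in range(4):
                if a == b:
                    continue
                rows = [[a >> 1, a & 1], [b >> 1, b & 1]]
                out = sort_rows_frequency_blocks(from_rows(rows))
                assert out.alleles.tolist() == sorted(rows)

    @given(binary_matrices())
    @settings(max_examples=40, deadline=None)
    def test_idempotent_and_permutation_invariant(self, m):
        once = sort_rows_frequency_blocks(m)
        twice = sort_rows_frequency_blocks(once)
        assert np.array_equal(once.alleles, twice.alleles)
        rng = np.random.default_rng(0)
        shuffled = HaplotypeMatrix(
            alleles=m.alleles[rng.permutation(m.n_haplotypes)],
            positions=m.positions,
        )
        assert np.array_equal(
            sort_rows_frequency_blocks(shuffled).alleles, once.alleles
        )
        # multiset of rows preserved
        assert sorted(map(tuple, once.alleles)) == sorted(map(tuple, m.alleles))


class TestWidthStandardization:
    def test_zero_pad_targets_and_placement(self):
        ms = [from_rows(np.ones((4, 41), dtype=int)), from_rows(np.ones((4, 77), dtype=int))]
        out = standardize_width(ms, PreprocessConfig(width_strategy="zero_pad"))
        assert all(im.pixels.shape == (4, 80) for im in out)
        first = out[0].pixels
        # 39 zero columns split 19 left / 20 right
        assert (first[:, :19] == 0).all() and (first[:, -20:] == 0).all()
        assert (first[:, 19:-20] == 1).all()
        assert {im.source_width for im in out} == {41, 77}

    def test_trim_targets_and_centering(self):
        wide = np.zeros((4, 77), dtype=int)
        wide[:, 18] = 1  # first retained column after centering
        ms = [from_rows(np.ones((4, 41), dtype=int)), from_rows(wide)]
        out = standardize_width(ms, PreprocessConfig(width_strategy="trim"))
        assert all(im.pixels.shape == (4, 40) for im in out)
        assert out[1].pixels[0, 0] == 1

    def test_trim_zero_target_rejected(self):
        ms = [from_rows([[0, 1, 1]])]
        with pytest.raises(ParameterError):
            standardize_width(ms, PreprocessConfig(width_strategy="trim"))

    def test_binarity_and_range_preserved(self):
        rng = np.random.default_rng(3)
        ms = [
            from_rows((rng.random((6, w)) < 0.4).astype(int))
            for w in (35, 52, 60)
        ]
        for strategy in ("zero_pad", "trim"):
            for im in standardize_width(ms, PreprocessConfig(width_strategy=strategy)):
                assert set(np.unique(im.pixels)) <= {0.0, 1.0}
        for im in standardize_width(ms, PreprocessConfig(width_strategy="resize")):
            assert im.pixels.shape[1] == 128
            assert im.pixels.min() >= 0 and im.pixels.max() <= 1

    def test_resize_constant_image_and_identity(self):
        ones = np.ones((5, 37))
        assert np.allclose(resize_width(ones, 128), 1.0)
        img = np.random.default_rng(0).random((5, 10))
        assert np.allclose(resize_width(img, 10), img)

    def test_resize_matches_reference_algorithm(self):
        from skimage.transform import resize as sk_resize

        rng = np.random.default_rng(1)
        for w, target in ((200, 128), (60, 128)):
            img = (rng.random((16, w)) < 0.5).astype(float)
            ours = resize_width(img, target)
            ref = sk_resize(
                img, (16, target), order=1, mode="reflect",
                anti_aliasing=w > target, preserve_range=True,
            )
            assert np.allclose(ours, np.clip(ref, 0, 1), atol=1e-6)


class TestSourceWidthSignal:
    def test_sweep_images_narrower_on_average(self, paired_batches):
        from sweepnet.preprocess import preprocess_matrix

        cfg = PreprocessConfig()
        neutral, swept = paired_batches
        w_neu = np.mean([preprocess_matrix(m, cfg).n_sites for m in neutral])
        w_swp = np.mean([preprocess_matrix(m, cfg).n_sites for m in swept])
        assert w_swp < w_neu


class TestVcfIngestion:
    VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1
chr1\t200\t.\tG\tC,T\t.\tPASS\t.\tGT\t0|1\t0|2
chr1\t300\t.\tC\tG\t.\tPASS\t.\tGT\t0|0\t0|1
chr1\t400\t.\tT\tA\t.\tPASS\t.\tGT\t1|0\t0|0
"""

    def test_reads_phased_biallelic_sites(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(self.VCF)
        m = read_vcf_haplotypes(path)
        assert m.n_haplotypes == 4  # two diploid samples
        assert m.positions.tolist() == [100.0, 300.0, 400.0]  # multi-allelic dropped
        assert m.alleles[:, 0].tolist() == [0, 1, 1, 1]

    def test_region_filter(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(self.VCF)
        m = read_vcf_haplotypes(path, region=("chr1", 250, 450))
        assert m.positions.tolist() == [300.0, 400.0]


class TestEndToEnd:
    def test_preprocess_dataset_uniform_shape(self, paired_batches):
        neutral, swept = paired_batches
        images = preprocess_dataset(neutral[:5] + swept[:5], PreprocessConfig())
        shapes = {im.pixels.shape for im in images}
        assert shapes == {(128, 128)}
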