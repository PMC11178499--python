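"""PET container, pairs/BEDPE I/O, binning, VC_SQRT, down-sampling, distance bands."""

import numpy as np
import pytest

from petdiff import contacts
from petdiff.contacts import (
    GenomeBins,
    PETSet,
    bin_pets,
    distance_density,
    downsample_pets,
    read_pairs,
    vc_sqrt_normalize,
    write_pairs,
)


def _petset(pairs, chrom="chr1", sample="s"):
    p1 = np.array([a for a, _ in pairs])
    p2 = np.array([b for _, b in pairs])
    c = np.full(len(pairs), chrom, dtype=object)
    return PETSet(sample, c, p1, c.copy(), p2)


class TestPairsIO:
    def test_canonical_order_on_construction(self):
        pets = _petset([(500, 200)])
        assert (pets.pos1[0], pets.pos2[0]) == (200, 500)

    def test_read_canonicalizes_and_skips_headers(self, tmp_path):
        f = tmp_path / "x.pairs"
        f.write_text("# header\nchr1\t500\tchr1\t200\nchr2\t10\tchr1\t30\n")
        pets = read_pairs(f)
        assert (pets.pos1[0], pets.pos2[0]) == (200, 500)
        # lexicographic chrom order puts chr1 first
        assert (pets.chrom1[1], pets.chrom2[1]) == ("chr1", "chr2")
        assert (pets.pos1[1], pets.pos2[1]) == (30, 10)

    def test_empty_file(self, tmp_path):
        f = tmp_path / "empty.pairs"
        f.write_text("")
        assert len(read_pairs(f)) == 0

    def test_roundtrip_identity(self, tmp_path, rng):
        n = 500
        pos1 = rng.integers(0, 10**6, n)
        pos2 = rng.integers(0, 10**6, n)
        pets = PETSet("s", np.full(n, "chr9", object), pos1, np.full(n, "chr9", object), pos2)
        f = tmp_path / "rt.pairs"
        write_pairs(pets, f)
        back = read_pairs(f)
        np.testing.assert_array_equal(back.pos1, pets.pos1)
        np.testing.assert_array_equal(back.pos2, pets.pos2)

    def test_bedpe_uses_interval_starts(self, tmp_path):
        f = tmp_path / "x.bedpe"
        f.write_text("chr1\t100\t150\tchr1\t900\t950\t.\t0\n")
        pets = read_pairs(f, dialect="bedpe")
        assert (pets.pos1[0], pets.pos2[0]) == (100, 900)

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "bad.pairs"
        f.write_text("chr1\t1\tchr1\t2\nchr1\toops\tchr1\t5\n")
        with pytest.raises(ValueError, match="line 2"):
            read_pairs(f)

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_pairs(tmp_path / "x", dialect="cooler")


class TestBinPets:
    bins = GenomeBins({"chr1": 1000}, 100)

    def test_single_pet_off_diagonal(self):
        m = bin_pets(_petset([(150, 250)]), self.bins, "chr1")
        a = m.toarray()
        assert a[1, 2] == 1 and a[2, 1] == 1
        assert a.sum() == 2

    def test_diagonal_pet_counted_once(self):
        m = bin_pets(_petset([(0, 0)]), self.bins, "chr1")
        assert m.toarray()[0, 0] == 1

    def test_repeated_bin_pair_accumulates(self):
        m = bin_pets(_petset([(310, 720)] * 4), self.bins, "chr1")
        a = m.toarray()
        assert a[3, 7] == 4
        assert np.triu(a).sum() == 4

    def test_cis_count_conservation(self, rng):
        # upper triangle + diagonal equals the number of cis PETs
        n = 2000
        pos = np.sort(rng.integers(0, 1000, size=(n, 2)), axis=1)
        pets = _petset(list(map(tuple, pos)))
        a = bin_pets(pets, self.bins, "chr1").toarray()
        assert np.triu(a).sum() == n

    def test_position_beyond_chrom_length_raises(self):
        with pytest.raises(ValueError, match="length"):
            bin_pets(_petset([(10, 5000)]), self.bins, "chr1")

    def test_trans_pets_excluded(self):
        pets = PETSet(
            "s",
            np.array(["chr1", "chr1"], object),
            np.array([10, 20]),
            np.array(["chr1", "chr2"], object),
            np.array([230, 40]),
        )
        m = bin_pets(pets, self.bins, "chr1")
        assert m.toarray().sum() == 2  # only the cis PET, symmetric


class TestVcSqrt:
    def test_uniform_matrix(self):
        from scipy import sparse

        n = 4
        m = contacts.BinnedMatrix("c", 10, sparse.csr_matrix(np.ones((n, n))))
        out = vc_sqrt_normalize(m)
        np.testing.assert_allclose(out.toarray(), np.full((n, n), 1 / n))

    def test_hand_computed_2x2(self):
        from scipy import sparse

        m = contacts.BinnedMatrix("c", 10, sparse.csr_matrix(np.array([[4, 2], [2, 1]])))
        out = vc_sqrt_normalize(m).toarray()
        np.testing.assert_allclose(
            out, [[0.6667, 0.4714], [0.4714, 0.3333]], atol=1e-4
        )

    def test_zero_row_masked(self):
        from scipy import sparse

        a = np.array([[2, 0, 1], [0, 0, 0], [1, 0, 3]])
        out = vc_sqrt_normalize(contacts.BinnedMatrix("c", 10, sparse.csr_matrix(a)))
        assert out.mask[1]
        assert np.all(out.toarray()[1] == 0) and np.all(out.toarray()[:, 1] == 0)

    def test_scaling_invariance(self, rng):
        from scipy import sparse

        a = rng.integers(1, 20, size=(6, 6))
        a = a + a.T
        base = vc_sqrt_normalize(contacts.BinnedMatrix("c", 10, sparse.csr_matrix(a))).toarray()
        for s in (2, 7):
            scaled = vc_sqrt_normalize(
                contacts.BinnedMatrix("c", 10, sparse.csr_matrix(s * a))
            ).toarray()
            np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_double_normalization_rejected(self):
        from scipy import sparse

        m = contacts.BinnedMatrix("c", 10, sparse.csr_matrix(np.ones((3, 3))))
        with pytest.raises(ValueError, match="already"):
            vc_sqrt_normalize(vc_sqrt_normalize(m))


class TestDownsample:
    def test_full_size_is_identity_multiset(self, rng):
        pets = _petset(list(zip(rng.integers(0, 100, 50), rng.integers(100, 200, 50))))
        (out,) = downsample_pets([pets], len(pets), seed=1)
        assert sorted(zip(out.pos1, out.pos2)) == sorted(zip(pets.pos1, pets.pos2))

    def test_target_zero(self):
        pets = _petset([(1, 2), (3, 4)])
        (out,) = downsample_pets([pets], 0, seed=1)
        assert len(out) == 0

    def test_oversized_target_names_sample(self):
        pets = _petset([(1, 2)], sample="tiny_sample")
        with pytest.raises(ValueError, match="tiny_sample"):
            downsample_pets([pets], 5, seed=1)

    def test_resampled_mean_distance_close(self, rng):
        n1, n2, target = 100_000, 200_000, 100_000
        sets = []
        for n, name in ((n1, "a"), (n2, "b")):
            p1 = rng.integers(0, 10**7, n)
            d = rng.integers(1000, 10**6, n)
            sets.append(
                PETSet(name, np.full(n, "c", object), p1, np.full(n, "c", object), p1 + d)
            )
        outs = downsample_pets(sets, target, seed=3)
        assert all(len(o) == target for o in outs)
        src = sets[1]
        out = outs[1]
        d_src = (src.pos2 - src.pos1).astype(float)
        d_out = (out.pos2 - out.pos1).astype(float)
        se = d_src.std() / np.sqrt(target)
        assert abs(d_out.mean() - d_src.mean()) < 2 * se

    def test_deterministic_given_seed(self):
        pets = _petset([(i, i + 10) for i in range(100)])
        a = downsample_pets([pets], 30, seed=9)[0]
        b = downsample_pets([pets], 30, seed=9)[0]
        np.testing.assert_array_equal(a.pos1, b.pos1)


class TestDistanceDensity:
    def test_point_mass(self):
        pets = _petset([(0, 10**5)] * 10)
        dd = distance_density(pets)
        centers = (dd.log10_edges[:-1] + dd.log10_edges[1:]) / 2
        assert abs(centers[np.argmax(dd.density)] - 5.0) < 0.1
        np.testing.assert_allclose(dd.band_fractions, [1.0, 0.0])

    def test_equal_split_around_10mb(self):
        pets = _petset([(0, 10**6)] * 5 + [(0, 2 * 10**7)] * 5)
        dd = distance_density(pets)
        np.testing.assert_allclose(dd.band_fractions, [0.5, 0.5])

    def test_density_integrates_to_one(self, rng):
        pets = _petset(list(zip(np.zeros(1000, int), rng.integers(1, 10**7, 1000))))
        dd = distance_density(pets)
        widths = np.diff(dd.log10_edges)
        assert abs((dd.density * widths).sum() - 1.0) < 1e-9

    def test_no_cis_pets_raises(self):
        pets = PETSet(
            "s", np.array(["chr1"], object), np.array([5]), np.array(["chr2"], object), np.array([9])
        )
        with pytest.raises(ValueError, match="cis"):
            distance_density(pets)

    def test_band_edges_must_increase(self):
        pets = _petset([(0, 100)])
        with pytest.raises(ValueError, match="increasing"):
            distance_density(pets, band_edges=(10, 10))
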