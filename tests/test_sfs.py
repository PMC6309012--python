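"""Genotype reading, polarization, hypergeometric projection, and SFS IO."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cochise import sfs as S
from conftest import make_gm

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)

POPMAP = {"s1": "SON", "s2": "CHI", "s3": "CAR"}


def write_vcf(tmp_path, body):
    path = tmp_path / "t.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestReadGenotypes:
    def test_gt_to_dosage(self, tmp_path):
        vcf = write_vcf(tmp_path, "chr1\t10\tL1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        gm = S.read_genotypes(vcf, POPMAP)
        assert gm.calls.tolist() == [[0, 1, 2]]
        assert gm.sites[0].locus_id == "L1"

    def test_missing_genotype_kept_as_missing(self, tmp_path):
        vcf = write_vcf(tmp_path, "chr1\t10\tL1\tA\tT\t.\tPASS\t.\tGT\t0/0\t./.\t1/1\n")
        gm = S.read_genotypes(vcf, POPMAP)
        assert gm.n_sites == 1
        assert gm.calls[0, 1] == S.MISSING

    def test_multiallelic_skipped_and_counted(self, tmp_path):
        body = (
            "chr1\t10\tL1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "chr1\t20\tL2\tC\tA,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        gm = S.read_genotypes(write_vcf(tmp_path, body), POPMAP)
        assert gm.n_sites == 1
        assert gm.meta["skipped_multiallelic"] == 1

    def test_unmapped_sample_errors(self, tmp_path):
        vcf = write_vcf(tmp_path, "chr1\t10\tL1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        with pytest.raises(KeyError, match="s3"):
            S.read_genotypes(vcf, {"s1": "SON", "s2": "CHI"})


class TestThinToUnlinked:
    def test_one_site_per_locus(self):
        calls = np.zeros((4, 2), dtype=np.int8)
        gm = make_gm(calls, ["SON", "CHI"])
        for i in range(3):
            gm.sites[i] = S.SiteRecord("c", i + 1, "locusA", "A", "T")
        thinned = S.thin_to_unlinked(gm, seed=1)
        assert thinned.n_sites == 2
        assert len({s.locus_id for s in thinned.sites}) == 2

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(120, 4)).astype(np.int8)
        gm = make_gm(calls, ["SON", "SON", "CHI", "CHI"])
        for i in range(120):
            gm.sites[i] = S.SiteRecord("c", i + 1, f"locus{i // 3}", "A", "T")
        a = S.thin_to_unlinked(gm, seed=42)
        b = S.thin_to_unlinked(gm, seed=42)
        assert [s.pos for s in a.sites] == [s.pos for s in b.sites]
        assert a.n_sites == 40  # 40 loci x 3 SNPs


class TestPolarize:
    def test_outgroup_homref_derived_is_alt(self):
        gm = make_gm([[1, 2, 0, 0]], ["SON", "SON", "CHI", "OUTGROUP"])
        pol = S.polarize_sites(gm, ["ind3"])
        assert pol.derived.tolist() == [[3, 0]]
        assert pol.n_chrom.tolist() == [[4, 2]]

    def test_outgroup_homalt_flips_counts(self):
        gm = make_gm([[1, 2, 0, 2]], ["SON", "SON", "CHI", "OUTGROUP"])
        pol = S.polarize_sites(gm, ["ind3"])
        assert pol.derived.tolist() == [[1, 2]]

    def test_het_outgroup_dropped(self, tiny_gm):
        pol = S.polarize_sites(tiny_gm, ["ind6"], populations=("SON", "CHI", "CAR"))
        assert pol.n_dropped == 1
        assert pol.derived.shape == (2, 3)

    def test_all_dropped_errors(self):
        gm = make_gm([[0, 1]], ["SON", "OUTGROUP"])
        gm.calls[0, 1] = 1  # het outgroup at the only site
        with pytest.raises(ValueError, match="no polarizable sites"):
            S.polarize_sites(gm, ["ind1"])

    def test_flip_symmetry(self):
        """Allele relabelling symmetry of the polarized SFS.

        Swapping ref/alt in ingroup calls AND the outgroup genotype leaves
        the SFS unchanged (the labels are arbitrary); swapping only which
        allele the outgroup carries mirrors the SFS.
        """
        rng = np.random.default_rng(5)
        n_sites, pops = 40, ["SON"] * 3 + ["CHI"] * 3 + ["OUTGROUP"]
        calls = rng.integers(0, 3, size=(n_sites, 7)).astype(np.int8)
        calls[:, 6] = 0  # homozygous-ancestral outgroup
        gm = make_gm(calls, pops)
        a = S.build_joint_sfs(S.polarize_sites(gm, ["ind6"]), (6, 6))

        swapped_all = make_gm(2 - calls, pops)
        b = S.build_joint_sfs(S.polarize_sites(swapped_all, ["ind6"]), (6, 6))
        assert np.allclose(a.counts, b.counts)

        flipped_outgroup = calls.copy()
        flipped_outgroup[:, 6] = 2  # ancestral allele now the alternate
        c = S.build_joint_sfs(S.polarize_sites(make_gm(flipped_outgroup, pops), ["ind6"]), (6, 6))
        assert np.allclose(a.counts, c.counts[::-1, ::-1])


def brute_force_projection(d, n, m):
    """Enumerate all C(n, m) subsamples of n chromosomes with d derived."""
    chroms = [1] * d + [0] * (n - d)
    counts = [0] * (m + 1)
    total = 0
    for combo in itertools.combinations(range(n), m):
        counts[sum(chroms[i] for i in combo)] += 1
        total += 1
    return [Fraction(c, total) for c in counts]


class TestProjectSite:
    def test_matches_exhaustive_enumeration_up_to_n8(self):
        for n in range(1, 9):
            for m in range(1, n + 1):
                for d in range(n + 1):
                    expected = brute_force_projection(d, n, m)
                    got = S.project_site(d, n, m)
                    assert np.allclose(got, [float(f) for f in expected], atol=1e-12), (
                        d, n, m,
                    )

    def test_worked_example(self):
        assert np.allclose(S.project_site(2, 4, 2), (1 / 6, 4 / 6, 1 / 6))

    def test_point_masses(self):
        assert np.allclose(S.project_site(0, 7, 3), (1, 0, 0, 0))
        assert np.allclose(S.project_site(3, 5, 5), (0, 0, 0, 1, 0, 0))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            S.project_site(5, 4, 2)
        with pytest.raises(ValueError):
            S.project_site(1, 4, 0)

    @given(
        st.integers(1, 20).flatmap(
            lambda n: st.tuples(
                st.just(n), st.integers(0, n), st.integers(1, n)
            )
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_sums_to_one(self, ndm):
        n, d, m = ndm
        assert abs(sum(S.project_site(d, n, m)) - 1.0) < 1e-9


class TestBuildJointSfs:
    def test_fixed_derived_single_site(self):
        gm = make_gm([[2, 2, 0, 0, 0]], ["SON", "SON", "CHI", "CAR", "OUTGROUP"])
        pol = S.polarize_sites(gm, ["ind4"], populations=("SON", "CHI", "CAR"))
        sfs = S.build_joint_sfs(pol, (2, 2, 2))
        assert sfs.counts[2, 0, 0] == pytest.approx(
            float(S.project_site(4, 4, 2)[2])
        )

    def test_projection_conservation_complete_data(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(100, 7)).astype(np.int8)
        calls[:, 6] = 0
        gm = make_gm(calls, ["SON"] * 3 + ["CHI"] * 3 + ["OUTGROUP"])
        pol = S.polarize_sites(gm, ["ind6"])
        sfs = S.build_joint_sfs(pol, (6, 6))
        assert sfs.total_mass() == pytest.approx(100.0, abs=1e-9)

    def test_study_projection_shape(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(20, 13)).astype(np.int8)
        calls[:, 12] = 0
        gm = make_gm(calls, ["SON"] * 6 + ["CHI"] * 5 + ["CAR"] + ["OUTGROUP"])
        pol = S.polarize_sites(gm, ["ind12"], populations=("SON", "CHI", "CAR"))
        sfs = S.build_joint_sfs(pol, (10, 10, 2))
        assert sfs.counts.shape == (11, 11, 3)
        assert sfs.mask[0, 0, 0] and sfs.mask[10, 10, 2]

    def test_short_sites_dropped(self):
        gm = make_gm([[1, S.MISSING, 0]], ["SON", "SON", "OUTGROUP"])
        pol = S.polarize_sites(gm, ["ind2"])
        with pytest.raises(ValueError, match="enough observed chromosomes"):
            S.build_joint_sfs(pol, (4,))


class TestSfsIO:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(4)
        counts = rng.random((3, 3, 3)) * 10
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[2, 2, 2] = mask[1, 2, 0] = True
        sfs = S.JointSFS(counts, (2, 2, 2), mask)
        path = tmp_path / "x.sfs"
        S.write_sfs(path, sfs)
        back = S.read_sfs(path)
        assert np.allclose(back.counts, counts, rtol=1e-12)
        assert np.array_equal(back.mask, mask)
        assert back.polarized

    def test_hand_written_file(self, tmp_path):
        path = tmp_path / "h.sfs"
        path.write_text(
            "2 2 2 unfolded\n"
            "0 1 2 3 4 5 6 7\n"
            "1 0 0 0 0 0 0 1\n"
        )
        sfs = S.read_sfs(path)
        assert sfs.counts[0, 1, 0] == 2.0
        assert sfs.counts[1, 1, 1] == 7.0
        assert sfs.mask[0, 0, 0] and sfs.mask[1, 1, 1] and not sfs.mask[0, 1, 0]

    def test_dimension_mismatch_errors(self, tmp_path):
        path = tmp_path / "bad.sfs"
        path.write_text("2 2 unfolded\n0 1 2\n0 0 0\n")
        with pytest.raises(ValueError, match="dimensions"):
            S.read_sfs(path)
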