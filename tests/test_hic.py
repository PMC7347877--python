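"""Contact-matrix statistics against brute-force enumeration oracles."""
import math

import numpy as np
import pytest
import scipy.sparse as sp

from domainweaver.hic import (
    ContactMatrix,
    apa,
    compartment_eigenvector,
    domain_contacts,
    domain_eigenvalue,
    insulation_score,
    loop_contacts,
    read_triples,
    write_triples,
)
from domainweaver.intervals import Domain, GenomicInterval, Loop

RES = 10_000


def cm_from_dense(upper: np.ndarray, chrom="c", res=RES) -> ContactMatrix:
    return ContactMatrix(chrom, res, sp.csr_matrix(np.triu(upper)))


def random_cm(rng: np.random.Generator, n_bins: int, density=0.4) -> ContactMatrix:
    dense = rng.random((n_bins, n_bins)) * (rng.random((n_bins, n_bins)) < density)
    return cm_from_dense(dense)


# --- brute-force oracles -----------------------------------------------------

def brute_domain_contacts(cm: ContactMatrix, d: Domain) -> float:
    res = cm.resolution
    bins = [b for b in range(cm.n_bins)
            if b * res >= d.interval.start and (b + 1) * res <= d.interval.end]
    vals = [cm.value(i, j) for i in bins for j in bins if i < j]
    return sum(vals) / len(vals)


def brute_loop_contacts(cm: ContactMatrix, lp: Loop) -> float:
    res = cm.resolution
    b1 = [b for b in range(cm.n_bins)
          if b * res < lp.anchor1.end and (b + 1) * res > lp.anchor1.start]
    b2 = [b for b in range(cm.n_bins)
          if b * res < lp.anchor2.end and (b + 1) * res > lp.anchor2.start]
    vals = [cm.value(i, j) for i in b1 for j in b2]
    return sum(vals) / len(vals)


def brute_insulation(cm: ContactMatrix, b: int, L: int, eps=1e-6) -> float:
    window = range(b - L, b + L)
    total = sum(cm.value(i, j) for i in window for j in window if i < j)
    crossing = sum(cm.value(i, j) for i in window for j in window
                   if i < b <= j and i < j)
    return -math.log2((crossing + eps) / (total + eps))


def brute_apa_one(cm: ContactMatrix, loops, w):
    dense = cm.dense_symmetric()
    windows = []
    for lp in loops:
        ci = lp.anchor1.center // cm.resolution
        cj = lp.anchor2.center // cm.resolution
        if ci - w < 0 or cj + w >= cm.n_bins or ci + w >= cj - w:
            continue
        windows.append(dense[ci - w : ci + w + 1, cj - w : cj + w + 1])
    agg = np.mean(windows, axis=0)
    c = math.ceil(w / 2)
    return agg, agg[w, w] / agg[-c:, :c].mean()


# --- tests -------------------------------------------------------------------

class TestTriplesIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        cm = random_cm(rng, 20)
        path = write_triples(cm, tmp_path / "m.txt")
        back = read_triples(path, RES, "c")
        assert (back.matrix != cm.matrix).nnz == 0

    def test_single_record_bins(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0\t10000\t1.5\n")
        cm = read_triples(p, 10_000, "c")
        assert cm.value(0, 1) == 1.5

    def test_lower_triangle_mirrored(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("20000\t0\t2.0\n")
        assert read_triples(p, 10_000, "c").value(0, 2) == 2.0

    def test_empty_file(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("")
        assert read_triples(p, 10_000, "c").n_bins == 0

    def test_duplicate_pixel_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0\t10000\t1.0\n10000\t0\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_triples(p, 10_000, "c")

    def test_non_multiple_position_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("5\t10000\t1.0\n")
        with pytest.raises(ValueError, match="multiple"):
            read_triples(p, 10_000, "c")


class TestDomainContacts:
    def test_uniform_matrix(self):
        cm = cm_from_dense(np.ones((10, 10)))
        d = Domain(GenomicInterval("c", 0, 5 * RES))
        assert domain_contacts(cm, d) == pytest.approx(1.0)

    def test_three_bin_enumeration(self):
        dense = np.zeros((3, 3))
        dense[0, 1], dense[0, 2], dense[1, 2] = 2, 1, 3
        cm = cm_from_dense(dense)
        d = Domain(GenomicInterval("c", 0, 3 * RES))
        assert domain_contacts(cm, d) == pytest.approx(2.0)

    def test_short_domain_rejected(self):
        cm = cm_from_dense(np.ones((10, 10)))
        with pytest.raises(ValueError):
            domain_contacts(cm, Domain(GenomicInterval("c", 0, RES)))

    def test_linear_in_matrix(self):
        rng = np.random.default_rng(1)
        cm = random_cm(rng, 20)
        d = Domain(GenomicInterval("c", 2 * RES, 9 * RES))
        assert domain_contacts(cm.scaled(3.0), d) == pytest.approx(
            3.0 * domain_contacts(cm, d)
        )

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(6, 50))
            cm = random_cm(rng, n)
            lo = int(rng.integers(0, n - 4))
            hi = int(rng.integers(lo + 2, min(lo + 12, n) + 1))
            d = Domain(GenomicInterval("c", lo * RES, hi * RES))
            assert domain_contacts(cm, d) == pytest.approx(
                brute_domain_contacts(cm, d), abs=1e-12
            )


class TestLoopContacts:
    def test_single_pixel(self):
        dense = np.zeros((10, 10))
        dense[1, 7] = 4.2
        cm = cm_from_dense(dense)
        lp = Loop(GenomicInterval("c", RES, 2 * RES), GenomicInterval("c", 7 * RES, 8 * RES))
        assert loop_contacts(cm, lp) == pytest.approx(4.2)

    def test_2x2_rectangle_mean(self):
        dense = np.zeros((10, 10))
        dense[1, 6], dense[1, 7], dense[2, 6], dense[2, 7] = 1, 2, 3, 4
        cm = cm_from_dense(dense)
        lp = Loop(GenomicInterval("c", RES, 3 * RES), GenomicInterval("c", 6 * RES, 8 * RES))
        assert loop_contacts(cm, lp) == pytest.approx(2.5)

    def test_overlapping_anchors_rejected(self):
        cm = cm_from_dense(np.ones((10, 10)))
        lp = Loop(GenomicInterval("c", 0, 3 * RES), GenomicInterval("c", 3 * RES, 5 * RES))
        # anchors abut: allowed; overlapping bins rejected below
        loop_contacts(cm, lp)
        bad = Loop.__new__(Loop)  # bypass Loop validation to hit matrix check
        object.__setattr__(bad, "anchor1", GenomicInterval("c", 0, 4 * RES))
        object.__setattr__(bad, "anchor2", GenomicInterval("c", 3 * RES, 6 * RES))
        with pytest.raises(ValueError):
            loop_contacts(cm, bad)


class TestInsulation:
    @pytest.mark.parametrize("L", range(1, 11))
    def test_closed_form_on_uniform(self, L):
        # crossing = L^2, total = L(2L-1) -> score = -log2(L / (2L-1))
        cm = cm_from_dense(np.ones((2 * L + 2, 2 * L + 2)))
        score = insulation_score(cm, L + 1, L, eps=0)
        assert score == pytest.approx(-math.log2(L / (2 * L - 1)), abs=1e-12)
        assert score == pytest.approx(brute_insulation(cm, L + 1, L, eps=0), abs=1e-12)

    def test_uniform_l2_value(self):
        cm = cm_from_dense(np.ones((6, 6)))
        assert insulation_score(cm, 2, 2) == pytest.approx(-math.log2(4 / 6), abs=1e-4)

    def test_perfect_insulation_large_score(self):
        dense = np.zeros((8, 8))
        dense[0, 1], dense[2, 3] = 1.0, 1.0  # no boundary-crossing pairs
        cm = cm_from_dense(dense)
        assert insulation_score(cm, 2, 2) > 15

    def test_window_out_of_range(self):
        cm = cm_from_dense(np.ones((6, 6)))
        with pytest.raises(ValueError):
            insulation_score(cm, 1, 3)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(8, 50))
            cm = random_cm(rng, n)
            L = int(rng.integers(1, min(8, n // 2)))
            b = int(rng.integers(L, n - L + 1))
            assert insulation_score(cm, b, L) == pytest.approx(
                brute_insulation(cm, b, L), abs=1e-12
            )


class TestAPA:
    def loop_at(self, ci, cj):
        return Loop(
            GenomicInterval("c", ci * RES, (ci + 1) * RES),
            GenomicInterval("c", cj * RES, (cj + 1) * RES),
        )

    def test_uniform_background_p2ll_one(self):
        cm = cm_from_dense(np.ones((60, 60)))
        res, _ = apa(cm, cm, [self.loop_at(15, 45)], w=10)
        assert res.p2ll == pytest.approx(1.0)
        assert np.allclose(res.aggregate, 1.0)

    def test_single_planted_peak(self):
        dense = np.ones((60, 60))
        dense[15, 45] = 5.0
        cm = cm_from_dense(dense)
        res, _ = apa(cm, cm, [self.loop_at(15, 45)], w=10)
        assert res.p2ll == pytest.approx(5.0)

    def test_close_to_diagonal_skipped(self):
        cm = cm_from_dense(np.ones((60, 60)))
        with pytest.raises(ValueError):
            apa(cm, cm, [self.loop_at(20, 30)], w=10)  # window crosses diagonal

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            cm = random_cm(rng, 50, density=0.8)
            loops = [self.loop_at(int(rng.integers(5, 15)), int(rng.integers(35, 45)))
                     for _ in range(3)]
            res, _ = apa(cm, cm, loops, w=4)
            agg, p2ll = brute_apa_one(cm, loops, 4)
            assert np.allclose(res.aggregate, agg, atol=1e-12)
            assert res.p2ll == pytest.approx(p2ll, abs=1e-12)


class TestCompartments:
    def block_cm(self, labels, hi=2.0, lo=0.5):
        lab = np.asarray(labels, dtype=bool)
        dense = np.where(lab[:, None] == lab[None, :], hi, lo)
        return cm_from_dense(dense, res=150_000)

    def test_two_block_partition(self):
        labels = [1] * 10 + [0] * 10
        cm = self.block_cm(labels)
        ac = np.array([1.0] * 10 + [0.1] * 10)
        track = compartment_eigenvector(cm, ac)
        signs = np.sign(track.eigenvalues)
        assert (signs[:10] > 0).all() and (signs[10:] < 0).all()

    def test_scaling_invariance(self):
        labels = [1, 1, 1, 0, 0, 0, 1, 1, 0, 0]
        cm = self.block_cm(labels)
        ac = np.array(labels, dtype=float) + 0.1
        t1 = compartment_eigenvector(cm, ac)
        t2 = compartment_eigenvector(cm.scaled(7.0), ac)
        assert np.allclose(t1.eigenvalues, t2.eigenvalues)

    def test_negated_h3k27ac_flips_sign_only(self):
        labels = [1] * 6 + [0] * 6
        cm = self.block_cm(labels)
        ac = np.array(labels, dtype=float) + 0.1
        t1 = compartment_eigenvector(cm, ac)
        t2 = compartment_eigenvector(cm, -ac)
        assert np.allclose(t1.eigenvalues, -t2.eigenvalues)

    def test_zero_variance_h3k27ac_rejected(self):
        cm = self.block_cm([1] * 5 + [0] * 5)
        with pytest.raises(ValueError):
            compartment_eigenvector(cm, np.ones(10))

    def test_domain_eigenvalue_means(self):
        from domainweaver.hic import CompartmentTrack
        track = CompartmentTrack("c", 150_000, np.array([0.1, 0.2, 0.6]))
        d = Domain(GenomicInterval("c", 0, 450_000))
        assert domain_eigenvalue(track, d) == pytest.approx(0.3)
        one_bin = Domain(GenomicInterval("c", 10_000, 80_000))
        assert domain_eigenvalue(track, one_bin) == pytest.approx(0.1)

    def test_all_missing_bins_flagged(self):
        from domainweaver.hic import CompartmentTrack
        track = CompartmentTrack("c", 150_000, np.array([np.nan, np.nan]))
        d = Domain(GenomicInterval("c", 0, 200_000))
        assert math.isnan(domain_eigenvalue(track, d))
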