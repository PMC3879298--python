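"""The eight measures: hand toys, naive-oracle parity, ranges, invariances."""

import numpy as np
import pytest

from metasig.dissimilarity import (
    CenteredSignature,
    DissimilarityMatrix,
    center_signature,
    d2,
    d2s,
    d2star,
    hao,
    is_valid_combination,
    lp_distance,
    pairwise_matrix,
    s2,
)
from metasig.errors import DegenerateSampleError, LabelError, ParameterError
from metasig.kmer_signature import KTupleSignature, count_ktuples, reverse_complement
from metasig.markov_background import fit_markov
from metasig.sequence_io import ReadSet

import _naive
from conftest import random_readset


def _sig(counts, sample="t", k=1, n=None):
    counts = np.asarray(counts, dtype=np.int64)
    return KTupleSignature(sample, k, counts, int(counts.sum()) if n is None else n)


class TestToyExamples:
    def test_d2_identity_and_orthogonal(self):
        a = _sig([3, 4, 0, 0])
        assert d2(a, a) == pytest.approx(0.0, abs=1e-15)
        x = _sig([1, 0, 0, 0])
        y = _sig([0, 1, 0, 0])
        assert d2(x, y) == pytest.approx(0.5)

    def test_d2_hand_cosine(self):
        # X=(3,4), Y=(4,3): cos = 24/25 -> (1 - 24/25)/2 = 0.02
        x = _sig([3, 4, 0, 0])
        y = _sig([4, 3, 0, 0])
        assert d2(x, y) == pytest.approx(0.02)

    def test_d2s_attains_bounds(self):
        cs = lambda c: CenteredSignature("t", 1, 0, np.array(c, float), np.ones(4), 10)
        assert d2s(cs([1, -1, 0, 0]), cs([1, -1, 0, 0])) == pytest.approx(0.0)
        assert d2s(cs([1, -1, 0, 0]), cs([-1, 1, 0, 0])) == pytest.approx(1.0)

    def test_d2star_attains_bounds(self):
        cs = lambda c: CenteredSignature("t", 1, 0, np.array(c, float), np.ones(4), 10)
        assert d2star(cs([1, -1, 0, 0]), cs([1, -1, 0, 0])) == pytest.approx(0.0)
        assert d2star(cs([1, -1, 0, 0]), cs([-1, 1, 0, 0])) == pytest.approx(1.0)

    def test_lp_hand_values(self):
        fx = np.array([0.5, 0.5, 0.0, 0.0])
        fy = np.array([0.0, 0.0, 0.5, 0.5])
        assert lp_distance(fx, fy, "manhattan") == pytest.approx(2.0)
        assert lp_distance(fx, fy, "euclidean") == pytest.approx(1.0)
        assert lp_distance(fx, fy, "chebyshev") == pytest.approx(0.5)
        assert lp_distance(fx, fx, "manhattan") == 0.0

    def test_s2_one_sided_log2(self):
        # F_X = (1,0) against P = (0.5,0.5): the one-sided term is ln 2
        reads = ["AAAA" * 5]  # only AA/TT words -> F over {AA,TT} = (.5,.5)
        rsX = ReadSet("x", reads)
        sigX = count_ktuples(rsX, 2)
        mX = fit_markov(rsX, 0)
        val = s2(sigX, sigX, mX, mX, form="self")
        naive = _naive.naive_s2(reads, reads, 2, 0)
        assert val == pytest.approx(naive, rel=1e-12)
        # direct hand case: F=(1,0), P=(0.5, 0.5)
        f = np.array([1.0, 0.0])
        p = np.array([0.5, 0.5])
        term = float(np.sum(f[f > 0] * np.log(f[f > 0] / p[f > 0])))
        assert term == pytest.approx(np.log(2))

    def test_hao_identical_samples(self):
        rs = random_readset(40, n_reads=50, length=40)
        sigs = tuple(count_ktuples(rs, kk) for kk in (4, 3, 2))
        assert hao(sigs, sigs) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("k", [2, 3, 4, 5])
@pytest.mark.parametrize("measure", ["d2", "d2s", "d2star", "s2", "hao", "ma", "eu", "ch"])
def test_measures_match_naive_oracle(measure, k):
    """Vectorised implementations agree with plain-dict summation to 1e-10."""
    if measure == "hao" and k < 3:
        pytest.skip("hao undefined below k=3")
    a = random_readset(41 + k, n_reads=30, length=35, base_probs=[0.4, 0.1, 0.2, 0.3])
    b = random_readset(51 + k, n_reads=25, length=35, base_probs=[0.2, 0.3, 0.3, 0.2])
    r = 1
    if measure == "d2":
        got = d2(count_ktuples(a, k), count_ktuples(b, k))
        want = _naive.naive_d2(a.reads, b.reads, k)
    elif measure in ("ma", "eu", "ch"):
        got = lp_distance(
            count_ktuples(a, k).frequencies(), count_ktuples(b, k).frequencies(), measure
        )
        want = _naive.naive_lp(a.reads, b.reads, k, measure)
    elif measure == "d2s":
        got = d2s(
            center_signature(count_ktuples(a, k), fit_markov(a, r)),
            center_signature(count_ktuples(b, k), fit_markov(b, r)),
        )
        want = _naive.naive_d2s(a.reads, b.reads, k, r)
    elif measure == "d2star":
        got = d2star(
            center_signature(count_ktuples(a, k), fit_markov(a, r)),
            center_signature(count_ktuples(b, k), fit_markov(b, r)),
        )
        want = _naive.naive_d2star(a.reads, b.reads, k, r)
    elif measure == "s2":
        got = s2(count_ktuples(a, k), count_ktuples(b, k), fit_markov(a, r), fit_markov(b, r))
        want = _naive.naive_s2(a.reads, b.reads, k, r)
    else:
        got = hao(
            tuple(count_ktuples(a, kk) for kk in (k, k - 1, k - 2)),
            tuple(count_ktuples(b, kk) for kk in (k, k - 1, k - 2)),
        )
        want = _naive.naive_hao(a.reads, b.reads, k)
    assert got == pytest.approx(want, abs=1e-10)


def test_centered_signature_sums_to_zero(small_readset):
    for r in (0, 1):
        cs = center_signature(count_ktuples(small_readset, 3), fit_markov(small_readset, r))
        assert abs(cs.centered.sum()) < 1e-6 * cs.n


@pytest.mark.parametrize("seed", range(6))
def test_normalised_measures_stay_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    a = random_readset(100 + seed, n_reads=40, length=30, base_probs=rng.dirichlet(np.ones(4)))
    b = random_readset(200 + seed, n_reads=40, length=30, base_probs=rng.dirichlet(np.ones(4)))
    sa, sb = count_ktuples(a, 3), count_ktuples(b, 3)
    ma_, mb = fit_markov(a, 0), fit_markov(b, 0)
    ca, cb = center_signature(sa, ma_), center_signature(sb, mb)
    assert 0.0 <= d2s(ca, cb) <= 1.0
    assert 0.0 <= d2star(ca, cb) <= 1.0
    assert 0.0 <= d2(sa, sb) <= 0.5
    assert s2(sa, sb, ma_, mb) >= 0.0  # Gibbs' inequality
    h = hao(
        tuple(count_ktuples(a, kk) for kk in (3, 2, 1)),
        tuple(count_ktuples(b, kk) for kk in (3, 2, 1)),
    )
    assert 0.0 <= h <= 1.0
    # norm ordering for the Lp family
    fa, fb = sa.frequencies(), sb.frequencies()
    assert (
        lp_distance(fa, fb, "ch")
        <= lp_distance(fa, fb, "eu")
        <= lp_distance(fa, fb, "ma")
    )


def test_strand_and_read_order_invariance(readset_pair):
    a, b = readset_pair
    k, r = 3, 0
    base = d2s(
        center_signature(count_ktuples(a, k), fit_markov(a, r)),
        center_signature(count_ktuples(b, k), fit_markov(b, r)),
    )
    flipped = ReadSet(a.sample_id, [reverse_complement(x) for x in a.reads])
    flip_val = d2s(
        center_signature(count_ktuples(flipped, k), fit_markov(flipped, r)),
        center_signature(count_ktuples(b, k), fit_markov(b, r)),
    )
    assert flip_val == base
    shuffled = ReadSet(a.sample_id, list(reversed(a.reads)))
    shuf_val = d2s(
        center_signature(count_ktuples(shuffled, k), fit_markov(shuffled, r)),
        center_signature(count_ktuples(b, k), fit_markov(b, r)),
    )
    assert shuf_val == base


class TestValidityRules:
    @pytest.mark.parametrize(
        "measure,k,order,valid",
        [
            ("d2s", 2, 2, False),
            ("d2s", 3, 2, True),
            ("d2s", 2, 3, False),
            ("d2s", 3, 3, False),
            ("d2s", 4, 3, True),
            ("d2star", 2, 2, False),
            ("s2", 2, 2, False),
            ("hao", 2, None, False),
            ("hao", 3, None, True),
            ("d2", 2, None, True),
            ("ma", 2, None, True),
        ],
    )
    def test_na_pattern(self, measure, k, order, valid):
        assert is_valid_combination(measure, k, order) is valid

    def test_invalid_combination_yields_na_matrix(self):
        panel = [random_readset(s, n_reads=20, length=30) for s in (61, 62, 63)]
        dm = pairwise_matrix(panel, "d2s", 2, 2)
        assert not dm.valid
        assert np.isnan(dm.values).all()


class TestPairwiseMatrix:
    def test_identical_samples_give_zero_offdiagonal(self):
        base = random_readset(70, n_reads=30, length=40)
        panel = [
            ReadSet(f"c{i}", list(base.reads)) for i in range(3)
        ]
        for measure, order in [("d2", None), ("d2s", 0), ("d2star", 0), ("ma", None), ("hao", None)]:
            dm = pairwise_matrix(panel, measure, 3, order)
            assert np.allclose(dm.values, 0.0, atol=1e-12)

    def test_symmetry_and_zero_diagonal(self, readset_pair):
        a, b = readset_pair
        c = random_readset(13)
        dm = pairwise_matrix([a, b, c], "d2s", 3, 1)
        assert np.array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)
        assert (dm.values >= 0).all()

    def test_duplicate_labels_rejected(self, readset_pair):
        a, b = readset_pair
        b2 = ReadSet(a.sample_id, b.reads)
        with pytest.raises(LabelError):
            pairwise_matrix([a, b2], "d2", 3)

    def test_matrix_file_roundtrip(self, tmp_path, readset_pair):
        a, b = readset_pair
        dm = pairwise_matrix([a, b], "d2star", 3, 1)
        back = DissimilarityMatrix.read(dm.write(tmp_path / "m.tsv"))
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values, atol=1e-12)
        assert (back.measure, back.k, back.order, back.valid) == ("d2star", 3, 1, True)


def test_subsampling_keeps_groups_separated():
    """Same-source pairs stay closer than different-source pairs at 10% depth."""
    from metasig.sequence_io import subsample_reads
    from metasig.synthetic_community import make_source_pools, sample_reads

    pools = make_source_pools(2, seed=5)
    reps = [
        sample_reads(pools[i], 2000, 150, 0, seed=100 + 2 * i + j, sample_id=f"p{i}r{j}")
        for i in range(2)
        for j in range(2)
    ]

    def d(a, b, rate=None, seed=0):
        if rate:
            a = subsample_reads(a, rate, seed)
            b = subsample_reads(b, rate, seed + 1)
        return d2s(
            center_signature(count_ktuples(a, 6), fit_markov(a, 0)),
            center_signature(count_ktuples(b, 6), fit_markov(b, 0)),
        )

    within_full = d(reps[0], reps[1])
    within_sub = d(reps[0], reps[1], rate=0.1, seed=7)
    between_sub = d(reps[0], reps[2], rate=0.1, seed=9)
    assert within_sub < between_sub
    assert within_full < between_sub
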