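import math
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

import phagelift as pl
from phagelift.background import NormalizedCounts
from phagelift.kmer import FrequencyVector, KmerCountVector
from phagelift.measures import MeasureSpec, canonical_name
from oracles import (
    naive_counts,
    naive_cvtree,
    naive_d2,
    naive_d2s,
    naive_d2star,
    naive_euf,
    naive_expected_k2,
    naive_expected_markov,
    naive_frequency_distance,
    naive_teeling,
    random_dna,
)


def freq(k, values):
    return FrequencyVector(k, np.asarray(values, dtype=float))


def counts(k, values):
    arr = np.asarray(values, dtype=np.int64)
    return KmerCountVector(k, arr, int(arr.sum()), 1)


def norm(k, centered=None, expected=None, ratio=None, observed=None):
    n = 4**k if k > 1 else 4
    z = np.zeros(n)
    exp = np.asarray(expected, dtype=float) if expected is not None else np.ones(n)
    cen = np.asarray(centered, dtype=float) if centered is not None else z.copy()
    rat = np.asarray(ratio, dtype=float) if ratio is not None else z.copy()
    obs = np.asarray(observed, dtype=float) if observed is not None else cen + exp
    return NormalizedCounts(k=k, observed=obs, expected=exp, centered=cen,
                            ratio=rat, length_basis=1)


class TestFrequencyDistances:
    def test_identity(self):
        f = freq(1, [0.25] * 4)
        for name in ("euclidean", "manhattan", "chebyshev"):
            assert pl.frequency_distance(name, f, f) == 0.0

    def test_disjoint_point_masses(self):
        fx = freq(1, [1, 0, 0, 0])
        fy = freq(1, [0, 1, 0, 0])
        assert pl.frequency_distance("manhattan", fx, fy) == pytest.approx(2.0)
        assert pl.frequency_distance("chebyshev", fx, fy) == pytest.approx(1.0)
        assert pl.frequency_distance("euclidean", fx, fy) == pytest.approx(2.0)

    def test_rooted_euclidean_flag(self):
        fx = freq(1, [1, 0, 0, 0])
        fy = freq(1, [0, 1, 0, 0])
        assert pl.frequency_distance("euclidean", fx, fy, rooted_euclidean=True) == (
            pytest.approx(math.sqrt(2.0))
        )

    @given(
        x=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        y=st.lists(st.floats(0, 1), min_size=4, max_size=4),
    )
    def test_manhattan_bounded_by_two(self, x, y):
        sx, sy = sum(x), sum(y)
        if sx == 0 or sy == 0:
            return
        fx = freq(1, [v / sx for v in x])
        fy = freq(1, [v / sy for v in y])
        assert pl.frequency_distance("manhattan", fx, fy) <= 2.0 + 1e-9

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            pl.frequency_distance("manhattan", freq(1, [0.25] * 4), freq(2, [1 / 16] * 16))


class TestD2:
    def test_self_is_zero(self):
        x = counts(1, [3, 1, 0, 0])
        assert pl.d2(x, x) == pytest.approx(0.0)

    def test_disjoint_supports_half(self):
        assert pl.d2(counts(1, [2, 0, 0, 0]), counts(1, [0, 3, 0, 0])) == pytest.approx(0.5)

    def test_worked_value(self):
        # x=(1,1), y=(1,0): 0.5*(1 - 1/sqrt(2))
        val = pl.d2(counts(1, [1, 1, 0, 0]), counts(1, [1, 0, 0, 0]))
        assert val == pytest.approx(0.5 * (1 - 1 / math.sqrt(2)))

    def test_zero_vector_rejected(self):
        z = KmerCountVector(1, np.zeros(4, dtype=np.int64), 0, 1)
        with pytest.raises(ValueError):
            pl.d2(counts(1, [1, 0, 0, 0]), z)


class TestD2Star:
    def test_self_is_zero(self):
        nx = norm(1, centered=[1, -1, 2, 0], expected=[1, 1, 1, 1])
        assert pl.d2star(nx, nx) == pytest.approx(0.0)

    def test_anticorrelated_toy_is_one(self):
        nx = norm(1, centered=[1, -1, 0, 0], expected=[1, 1, 0, 0])
        ny = norm(1, centered=[-1, 1, 0, 0], expected=[1, 1, 0, 0])
        assert pl.d2star(nx, ny) == pytest.approx(1.0)

    def test_bounded_when_expectations_positive(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            e = rng.uniform(0.5, 3.0, 16)
            nx = norm(2, centered=rng.normal(size=16), expected=e)
            ny = norm(2, centered=rng.normal(size=16), expected=e)
            assert -1e-12 <= pl.d2star(nx, ny) <= 1.0 + 1e-12


class TestD2S:
    def test_self_is_zero(self):
        nx = norm(1, centered=[2, -3, 1, 0])
        assert pl.d2s(nx, nx) == pytest.approx(0.0)

    def test_orthogonal_toy_is_half(self):
        nx = norm(1, centered=[1, -1, 0, 0])
        ny = norm(1, centered=[1, 1, 0, 0])
        assert pl.d2s(nx, ny) == pytest.approx(0.5)

    @given(
        cx=st.lists(st.floats(-5, 5), min_size=16, max_size=16),
        cy=st.lists(st.floats(-5, 5), min_size=16, max_size=16),
    )
    def test_always_in_unit_interval(self, cx, cy):
        if not any(cx) and not any(cy):
            return
        nx = norm(2, centered=cx)
        ny = norm(2, centered=cy)
        try:
            val = pl.d2s(nx, ny)
        except ValueError:
            return  # all words degenerate
        assert -1e-9 <= val <= 1.0 + 1e-9


class TestCvtree:
    def test_self_is_zero(self):
        rx = norm(1, ratio=[2, 1, 0.5, 0])
        assert pl.cvtree(rx, rx) == pytest.approx(0.0)

    def test_disjoint_support_half(self):
        rx = norm(1, ratio=[2, 0, 0, 0])
        ry = norm(1, ratio=[0, 3, 0, 0])
        assert pl.cvtree(rx, ry) == pytest.approx(0.5)

    def test_worked_value(self):
        rx = norm(1, ratio=[2, 1, 0, 0])
        ry = norm(1, ratio=[1, 2, 0, 0])
        assert pl.cvtree(rx, ry) == pytest.approx(0.1)


class TestTeeling:
    def test_self_inner_product(self):
        z = np.array([1.0, -1.0])
        assert pl.teeling(z, z) == pytest.approx(2.0)

    def test_orthogonal_is_zero(self):
        assert pl.teeling(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_bilinearity_in_scale(self):
        zx = np.array([1.0, 2.0, -1.0])
        zy = np.array([0.5, -1.0, 3.0])
        assert pl.teeling(zx, 3 * zy) == pytest.approx(3 * pl.teeling(zx, zy))


class TestEuf:
    def test_identity(self):
        rx = norm(3, ratio=np.ones(64))
        assert pl.euf(rx, rx) == 0.0

    def test_single_word_difference(self):
        a = np.ones(64)
        b = a.copy()
        b[17] += 1.0
        assert pl.euf(norm(3, ratio=a), norm(3, ratio=b)) == pytest.approx(1 / 64)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        rx = norm(3, ratio=rng.uniform(0, 2, 64))
        ry = norm(3, ratio=rng.uniform(0, 2, 64))
        assert pl.euf(rx, ry) == pl.euf(ry, rx)


class TestMeasureSpec:
    def test_alias_and_validation(self):
        assert canonical_name("hao") == "cvtree"
        assert MeasureSpec("Teeling", 4).direction == "similarity"
        with pytest.raises(ValueError):
            MeasureSpec("cvtree", 2)
        with pytest.raises(ValueError):
            MeasureSpec("d2s", 4, markov_order=4)
        with pytest.raises(ValueError):
            canonical_name("mash")


# ---------------------------------------------------------------------------
# oracle equivalence of every measure on random sequence pairs
# ---------------------------------------------------------------------------

def _sides(seq, k, order):
    """Package-side and oracle-side measure inputs for one sequence."""
    rec = pl.SequenceRecord("s", seq)
    obs = pl.count_kmers(rec, k)
    bg = pl.fit_markov(
        pl.count_kmers(rec, order + 1),
        pl.count_kmers(rec, order) if order else None,
        order,
    )
    markov = pl.expected_counts(obs, bg)
    k2 = pl.expected_counts_k2(obs, pl.count_kmers(rec, k - 1), pl.count_kmers(rec, k - 2))
    var = pl.variance_teeling(obs, pl.count_kmers(rec, k - 1), pl.count_kmers(rec, k - 2))
    return obs, markov, k2, var


@pytest.mark.parametrize("k,order", [(3, 0), (4, 1), (5, 2)])
def test_all_measures_match_naive_oracles(k, order):
    rng = random.Random(100 * k + order)
    for _ in range(6):
        sx = random_dna(rng, rng.randrange(300, 600))
        sy = random_dna(rng, rng.randrange(300, 600))
        obs_x, markov_x, k2_x, var_x = _sides(sx, k, order)
        obs_y, markov_y, k2_y, var_y = _sides(sy, k, order)

        cx, tx = naive_counts(sx, k)
        cy, ty = naive_counts(sy, k)
        fx = {w: c / tx for w, c in cx.items()}
        fy = {w: c / ty for w, c in cy.items()}
        for name in ("euclidean", "manhattan", "chebyshev"):
            got = pl.frequency_distance(
                name, pl.to_frequencies(obs_x), pl.to_frequencies(obs_y)
            )
            assert got == pytest.approx(naive_frequency_distance(name, fx, fy, k), abs=1e-9)

        assert pl.d2(obs_x, obs_y) == pytest.approx(naive_d2(cx, cy, k), abs=1e-9)

        ox, ex, _ = naive_expected_markov([sx], k, order)
        oy, ey, _ = naive_expected_markov([sy], k, order)
        assert pl.d2star(markov_x, markov_y) == pytest.approx(
            naive_d2star(ox, ex, oy, ey, k), abs=1e-9
        )
        assert pl.d2s(markov_x, markov_y) == pytest.approx(
            naive_d2s(ox, ex, oy, ey, k), abs=1e-9
        )

        ox2, ex2, vx2, rx2 = naive_expected_k2([sx], k)
        oy2, ey2, vy2, ry2 = naive_expected_k2([sy], k)
        assert pl.cvtree(k2_x, k2_y) == pytest.approx(naive_cvtree(rx2, ry2, k), abs=1e-9)
        assert pl.euf(k2_x, k2_y) == pytest.approx(naive_euf(rx2, ry2, k), abs=1e-9)
        zx = pl.teeling_zscores(k2_x, var_x)
        zy = pl.teeling_zscores(k2_y, var_y)
        assert pl.teeling(zx, zy) == pytest.approx(
            naive_teeling(ox2, ex2, vx2, oy2, ey2, vy2, k), abs=1e-9
        )


@pytest.mark.parametrize("k,order", [(4, 1)])
def test_measures_symmetric_on_random_pairs(k, order):
    rng = random.Random(77)
    sx = random_dna(rng, 400)
    sy = random_dna(rng, 400)
    obs_x, markov_x, k2_x, var_x = _sides(sx, k, order)
    obs_y, markov_y, k2_y, var_y = _sides(sy, k, order)
    assert pl.d2(obs_x, obs_y) == pytest.approx(pl.d2(obs_y, obs_x), abs=1e-12)
    assert pl.d2star(markov_x, markov_y) == pytest.approx(pl.d2star(markov_y, markov_x), abs=1e-12)
    assert pl.d2s(markov_x, markov_y) == pytest.approx(pl.d2s(markov_y, markov_x), abs=1e-12)
    assert pl.cvtree(k2_x, k2_y) == pytest.approx(pl.cvtree(k2_y, k2_x), abs=1e-12)
    assert pl.euf(k2_x, k2_y) == pytest.approx(pl.euf(k2_y, k2_x), abs=1e-12)
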