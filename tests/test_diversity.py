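import numpy as np
import pytest

from fragfit.diversity import (
    IncidenceMatrix,
    accumulation_curve,
    bray_curtis_presence,
    chao2,
    incidence_from_study,
    jackknife1,
    representation_percent,
)


def make_inc(matrix):
    m = np.asarray(matrix)
    return IncidenceMatrix(
        m,
        tuple(f"sp{i}" for i in range(m.shape[0])),
        tuple(f"s{j}" for j in range(m.shape[1])),
    )


def random_inc(rng, s=10, h=8, p=0.4):
    while True:
        m = (rng.random((s, h)) < p).astype(int)
        if (m.sum(axis=1) > 0).all():
            return make_inc(m)


class TestAccumulationCurve:
    def test_two_by_two_enumeration(self):
        # subsets of one sample: {s0} sees 2 species, {s1} sees 1 -> mean 1.5
        curve = accumulation_curve(make_inc([[1, 0], [1, 1]]))
        assert curve.loc[curve["h"] == 1, "tau"].iloc[0] == pytest.approx(1.5)

    def test_endpoint_is_observed_richness_with_zero_sd(self):
        rng = np.random.default_rng(0)
        inc = random_inc(rng)
        curve = accumulation_curve(inc)
        last = curve.iloc[-1]
        assert last["tau"] == pytest.approx(inc.S_obs)
        assert last["sd"] == pytest.approx(0.0, abs=1e-12)
        assert last["lo95"] == pytest.approx(last["hi95"])

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            curve = accumulation_curve(random_inc(rng))
            assert (np.diff(curve["tau"]) >= -1e-12).all()

    def test_variance_matches_exhaustive_enumeration(self):
        """On a 3-sample matrix every subset can be enumerated directly."""
        from itertools import combinations

        m = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1], [1, 1, 1]])
        inc = make_inc(m)
        curve = accumulation_curve(inc).set_index("h")
        for h in (1, 2, 3):
            richness = [
                int((m[:, list(cols)].sum(axis=1) > 0).sum())
                for cols in combinations(range(3), h)
            ]
            assert curve.loc[h, "tau"] == pytest.approx(np.mean(richness))
            assert curve.loc[h, "sd"] == pytest.approx(np.std(richness), abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accumulation_curve(make_inc(np.zeros((0, 3), dtype=int)))


class TestRichnessEstimators:
    def test_chao2_no_uniques_equals_observed(self):
        inc = make_inc([[1, 1], [1, 1], [0, 1]])
        assert inc.q(1) == 1  # sanity on the helper
        inc = make_inc([[1, 1], [1, 1]])
        assert chao2(inc) == pytest.approx(inc.S_obs)

    def test_chao2_hand_value(self):
        # S_obs=5, q1=2, q2=1 -> 5 + 4/2 = 7
        m = [[1, 0, 0, 0], [0, 1, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]]
        inc = make_inc(m)
        assert (inc.q(1), inc.q(2)) == (2, 1)
        assert chao2(inc) == pytest.approx(7.0)

    def test_jackknife1_hand_value(self):
        m = [[1, 0, 0, 0], [0, 1, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]]
        assert jackknife1(make_inc(m)) == pytest.approx(5 + 2 * 3 / 4)

    def test_estimators_never_below_observed(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            inc = random_inc(rng, s=8, h=6)
            assert chao2(inc) >= inc.S_obs
            assert jackknife1(inc) >= inc.S_obs


class TestSimilarity:
    def test_self_similarity_and_disjoint(self):
        assert bray_curtis_presence({"a", "b"}, {"a", "b"}) == pytest.approx(100.0)
        assert bray_curtis_presence({"a"}, {"b", "c"}) == pytest.approx(0.0)

    def test_hand_value(self):
        x = {"a", "b", "c", "d"}  # a=3 shared, b=1 only-x
        y = {"a", "b", "c", "e", "f"}  # c=2 only-y
        assert bray_curtis_presence(x, y) == pytest.approx(100 * 6 / 9)

    def test_symmetry_and_identity_characterisation(self):
        rng = np.random.default_rng(3)
        universe = [f"sp{i}" for i in range(12)]
        for _ in range(20):
            x = {s for s in universe if rng.random() < 0.5}
            y = {s for s in universe if rng.random() < 0.5}
            if not (x or y):
                continue
            assert bray_curtis_presence(x, y) == pytest.approx(
                bray_curtis_presence(y, x)
            )
            assert (bray_curtis_presence(x, y) == 100.0) == (x == y)

    def test_empty_pair_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_presence(set(), set())


class TestRepresentation:
    def test_bounds_and_hand_value(self):
        control = {f"sp{i}" for i in range(16)}
        assert representation_percent(control | {"x"}, control) == 100.0
        assert representation_percent({"x", "y"}, control) == 0.0
        frag = {"sp0", "sp1", "sp2", "other"}
        assert representation_percent(frag, control) == pytest.approx(18.75)

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            representation_percent({"a"}, set())


def test_incidence_from_study_pools_years(tiny_study):
    inc = incidence_from_study(tiny_study, "specialist", "L50")
    assert set(inc.species_ids) == {"spA", "spB"}
    assert inc.H == 2  # both L50 sites are samples
    # spA present at both sites, spB only at s1
    counts = dict(zip(inc.species_ids, inc.incidence_counts))
    assert counts == {"spA": 2, "spB": 1}
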