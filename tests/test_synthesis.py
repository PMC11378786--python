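"""The four synthesis methods: examples, tie rules, equivariance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from masynth import (
    Category,
    MAResult,
    Scenario,
    Study,
    build_scenario_data,
    coma,
    fit_random_effects,
    mama,
    rema,
    soma,
)

from conftest import make_results, make_studies


class TestSoma:
    def test_single_ma_identity(self):
        out = soma(make_results([0.3], [0.1]))
        assert out.mean == 0.3 and out.se == 0.1
        assert out.category is Category.POSITIVE

    def test_two_identical_mas(self):
        out = soma(make_results([0.3, 0.3], [0.1, 0.1]))
        assert out.detail["tau2"] == 0.0
        assert out.mean == pytest.approx(0.3)
        assert out.se == pytest.approx(0.1 / math.sqrt(2))
        assert out.ci_low == pytest.approx(0.161, abs=5e-4)
        assert out.ci_high == pytest.approx(0.439, abs=5e-4)
        assert out.category is Category.POSITIVE

    def test_symmetric_means_cancel(self):
        out = soma(make_results([-0.4, 0.4], [0.1, 0.1]))
        assert out.mean == pytest.approx(0.0, abs=1e-15)
        assert out.category is Category.NO_EFFECT

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_k_copies_shrink_se_sqrt_k(self, k):
        base = soma(make_results([0.3], [0.1]))
        out = soma(make_results([0.3] * k, [0.1] * k))
        assert out.mean == pytest.approx(base.mean)
        assert out.se == pytest.approx(base.se / math.sqrt(k))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            soma([])


class TestMama:
    def test_selects_lowest_cv(self):
        out = mama(make_results([0.2, 0.5], [0.1, 0.1]))  # CVs 0.5 vs 0.2
        assert out.detail["selected"] == 1
        assert out.mean == 0.5

    def test_singleton(self):
        out = mama(make_results([0.2], [0.1]))
        assert out.detail["selected"] == 0

    def test_zero_mean_never_selected(self):
        out = mama(make_results([0.0, 0.1], [0.01, 0.5]))
        assert out.detail["selected"] == 1

    def test_tie_broken_by_lowest_index(self):
        out = mama(make_results([0.5, 0.5], [0.1, 0.1]))
        assert out.detail["selected"] == 0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        means=st.lists(st.floats(-3, 3, allow_nan=False), min_size=1, max_size=8),
        data=st.data(),
    )
    def test_output_is_an_input(self, means, data):
        """MAMA selects, never averages: its estimate is one of the inputs."""
        ses = data.draw(st.lists(st.floats(0.01, 1.0), min_size=len(means), max_size=len(means)))
        out = mama(make_results(means, ses))
        assert out.mean in means


class TestComa:
    @staticmethod
    def _results_for(categories):
        table = {
            Category.POSITIVE: (0.5, 0.1),
            Category.NEGATIVE: (-0.5, 0.1),
            Category.NO_EFFECT: (0.0, 0.1),
        }
        return make_results(*zip(*(table[c] for c in categories)))

    @pytest.mark.parametrize("cats, expected, votes", [
        ([Category.POSITIVE, Category.POSITIVE, Category.NEGATIVE],
         Category.POSITIVE, {"positive": 2, "negative": 1, "no_effect": 0}),
        ([Category.POSITIVE, Category.NEGATIVE, Category.NO_EFFECT],
         Category.NO_EFFECT, {"positive": 1, "negative": 1, "no_effect": 1}),
        ([Category.NEGATIVE] * 3 + [Category.NO_EFFECT] * 2,
         Category.NEGATIVE, {"positive": 0, "negative": 3, "no_effect": 2}),
        ([Category.POSITIVE, Category.POSITIVE, Category.NEGATIVE, Category.NEGATIVE],
         Category.NO_EFFECT, {"positive": 2, "negative": 2, "no_effect": 0}),
    ])
    def test_vote_rule(self, cats, expected, votes):
        out = coma(self._results_for(cats))
        assert out.category is expected
        assert out.detail["votes"] == votes
        assert out.mean is None and out.se is None  # no quantitative estimate

    def test_winner_has_max_votes_unless_tied(self, rng):
        for _ in range(50):
            means = rng.normal(0, 0.5, size=5)
            out = coma(make_results(means, [0.1] * 5))
            votes = out.detail["votes"]
            top = max(votes.values())
            if sum(v == top for v in votes.values()) == 1:
                assert votes[out.category.value] == top
            else:
                assert out.category is Category.NO_EFFECT


class TestRema:
    def test_equals_single_dataset_fit(self, rng):
        studies = make_studies(rng.normal(0.2, 0.3, 12), rng.uniform(0.1, 0.3, 12))
        out = rema(studies)
        fit = fit_random_effects(studies)
        assert out.mean == fit.mean and out.se == fit.se
        assert out.category is fit.category

    def test_duplicate_ids_rejected(self):
        studies = make_studies([0.1, 0.2], [0.1, 0.1]) + make_studies([0.3], [0.1])
        with pytest.raises(ValueError):
            rema(studies)

    @pytest.mark.parametrize("p, expected_n", [(0.0, 30), (0.5, 20)])
    def test_pooled_size_contract(self, p, expected_n, rng):
        sc = Scenario(mu=0.1, n_ma=3, n_per_ma=10, overlap=p)
        out = rema(build_scenario_data(sc, rng).pooled)
        assert out.detail["n_studies"] == expected_n


class TestSignEquivariance:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        means=st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=6),
        data=st.data(),
    )
    def test_negating_inputs_flips_everything(self, means, data):
        """Flipping the sign of every effect negates means and swaps categories."""
        ses = data.draw(st.lists(st.floats(0.05, 1.0), min_size=len(means), max_size=len(means)))
        pos = make_results(means, ses)
        neg = make_results([-m for m in means], ses)
        for fn in (soma, mama, coma):
            a, b = fn(pos), fn(neg)
            assert b.category is a.category.opposite
            if a.mean is not None:
                assert b.mean == pytest.approx(-a.mean, rel=1e-9, abs=1e-9)

    def test_rema_sign_equivariance(self, rng):
        studies = make_studies(rng.normal(0.3, 0.2, 15), rng.uniform(0.1, 0.3, 15))
        flipped = [Study(-s.effect, s.within_se, s.study_id) for s in studies]
        a, b = rema(studies), rema(flipped)
        assert b.mean == pytest.approx(-a.mean)
        assert b.category is a.category.opposite


def test_soma_rema_converge_for_large_unshared_data():
    """With no overlap and many studies, SOMA and REMA agree with each other
    and with the true mean (3-SE tolerance over replicates)."""
    mu = 0.22
    sc = Scenario(mu=mu, n_ma=10, n_per_ma=50, overlap=0.0, precision="high")
    rng = np.random.default_rng(99)
    diffs, soma_means = [], []
    for _ in range(200):
        b = build_scenario_data(sc, rng)
        results = [fit_random_effects(ds) for ds in b.first_order]
        s, r = soma(results), rema(b.pooled)
        diffs.append(s.mean - r.mean)
        soma_means.append(s.mean)
    soma_means = np.array(soma_means)
    assert np.mean(np.abs(diffs)) < 0.02
    assert soma_means.mean() == pytest.approx(
        mu, abs=3 * soma_means.std() / np.sqrt(soma_means.size)
    )
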