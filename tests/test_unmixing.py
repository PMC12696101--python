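"""DCR pooling, mixture fitting and colour calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfxduet.io import IterationReading, LocalisationEvent
from mfxduet.unmixing import (
    COLOUR_A,
    COLOUR_B,
    EXCLUDED,
    NOT_DEFINED,
    ColourModel,
    DegenerateFitError,
    assign_event_colour,
    assign_trace_colour,
    fit_dcr_mixture,
    localisation_posteriors,
    pooled_dcr,
    pooled_dcr_table,
    unmix_table,
)

from conftest import make_table


def make_event(readings, trace_id="T0", event_index=0):
    return LocalisationEvent(
        trace_id=trace_id,
        event_index=event_index,
        x=0.0,
        y=0.0,
        efo=50.0,
        iterations=tuple(IterationReading(i, d, e) for i, (d, e) in enumerate(readings)),
    )


class TestPooledDCR:
    def test_single_reading_is_its_own_mean(self):
        assert pooled_dcr(make_event([(0.5, 100)])).value == 0.5

    def test_photon_weighted_mean(self):
        # (0.2*100 + 0.6*300) / 400 = 0.5
        assert pooled_dcr(make_event([(0.2, 100), (0.6, 300)])).value == pytest.approx(0.5)

    def test_zero_photon_iteration_carries_no_weight(self):
        assert pooled_dcr(make_event([(0.3, 0), (0.7, 200)])).value == pytest.approx(0.7)

    def test_all_zero_photons_raises(self):
        with pytest.raises(ValueError, match="zero photons"):
            pooled_dcr(make_event([(0.3, 0), (0.7, 0)]))

    def test_headstart_selector_drops_final_iteration(self):
        event = make_event([(0.2, 100), (0.4, 100), (0.9, 100)])
        assert pooled_dcr(event, selector="headstart").value == pytest.approx(0.3)
        assert pooled_dcr(event, selector=[0]).value == pytest.approx(0.2)

    def test_table_pooling_matches_per_event(self, small_table):
        pooled = pooled_dcr_table(small_table)
        by_event = {
            (e.trace_id, e.event_index): pooled_dcr(e).value
            for e in small_table.events()
        }
        for row in pooled.itertuples():
            assert row.pooled_dcr == pytest.approx(
                by_event[(row.trace_id, row.event_index)]
            )

    def test_table_pooling_drops_zero_photon_events(self):
        rows = [
            ("T0", 0, 0, 1.0, 1.0, 50.0, 0.3, 0),
            ("T0", 0, 1, 1.0, 1.0, 50.0, 0.7, 0),
            ("T0", 1, 0, 1.0, 1.0, 50.0, 0.4, 100),
        ]
        pooled = pooled_dcr_table(make_table(rows))
        assert len(pooled) == 1
        assert pooled.iloc[0].event_index == 1


class TestMixtureFit:
    def test_recovers_generating_parameters(self, rng):
        """EM on a 50/50 draw from N(0.30, 0.05) / N(0.65, 0.05) recovers
        the generating means (+-0.01) and weights (+-0.03), and agrees
        with an independent EM implementation."""
        x = np.concatenate(
            [rng.normal(0.30, 0.05, 5000), rng.normal(0.65, 0.05, 5000)]
        )
        x = np.clip(x, 0.0, 1.0)
        model = fit_dcr_mixture(x, seed=0)
        assert model.converged
        assert model.means[0] == pytest.approx(0.30, abs=0.01)
        assert model.means[1] == pytest.approx(0.65, abs=0.01)
        assert model.weights[0] == pytest.approx(0.5, abs=0.03)

        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(2, random_state=0, n_init=3).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(
            model.means, gm.means_.ravel()[order], atol=2e-3
        )
        np.testing.assert_allclose(
            model.sds, np.sqrt(gm.covariances_.ravel()[order]), atol=2e-3
        )

    def test_log_likelihood_monotone(self, rng):
        x = np.concatenate([rng.normal(0.3, 0.05, 500), rng.normal(0.65, 0.05, 500)])
        model = fit_dcr_mixture(np.clip(x, 0, 1))
        ll = np.array(model.log_likelihood_history)
        assert np.all(np.diff(ll) >= -1e-9)

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateFitError, match="single-population"):
            fit_dcr_mixture(np.full(100, 0.5))

    def test_separated_point_masses_recovered_exactly(self):
        x = np.concatenate([np.full(5000, 0.2), np.full(5000, 0.8)])
        model = fit_dcr_mixture(x, sigma_floor=0.01)
        assert model.means[0] == pytest.approx(0.2, abs=1e-6)
        assert model.means[1] == pytest.approx(0.8, abs=1e-6)
        assert model.weights == pytest.approx((0.5, 0.5), abs=1e-9)
        assert model.sds == pytest.approx((0.01, 0.01))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_dcr_mixture([0.2, 0.8])

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fit_dcr_mixture([0.2, 0.8, 1.4, 0.3])


def symmetric_model(mu1=0.3, mu2=0.7, sd=0.05, w1=0.5):
    return ColourModel(
        weights=(w1, 1 - w1),
        means=(mu1, mu2),
        sds=(sd, sd),
        converged=True,
        log_likelihood=0.0,
        n_points=100,
        n_iter=1,
        log_likelihood_history=(0.0,),
    )


class TestPosteriors:
    def test_midpoint_of_symmetric_model_is_half_half(self):
        post = localisation_posteriors(symmetric_model(), 0.5)
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-12)

    def test_value_at_component_mean_is_confident(self):
        model = symmetric_model(0.3, 0.7, sd=0.05)
        post = localisation_posteriors(model, 0.3)[0]
        # direct formula: pi*phi ratio with delta = 0.4 = 8 sd
        expected = 1.0 / (1.0 + np.exp(-(0.4**2 - 0.0) / (2 * 0.05**2)))
        assert post[0] == pytest.approx(expected, rel=1e-9)
        assert post[0] > 0.99

    def test_degenerate_weight_forces_posterior(self):
        model = symmetric_model(w1=1.0)
        np.testing.assert_allclose(
            localisation_posteriors(model, 0.9)[0], [1.0, 0.0]
        )

    def test_no_underflow_far_from_both_components(self):
        model = symmetric_model(0.1, 0.2, sd=0.001)
        post = localisation_posteriors(model, 1.0)[0]
        assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mirror_symmetry(self):
        """Relabelling symmetry: reflecting values and components about
        0.5 swaps the posterior columns exactly."""
        model = symmetric_model(0.3, 0.65, sd=0.04, w1=0.4)
        mirrored = symmetric_model(1 - 0.65, 1 - 0.3, sd=0.04, w1=0.6)
        values = np.linspace(0.05, 0.95, 19)
        post = localisation_posteriors(model, values)
        post_m = localisation_posteriors(mirrored, 1 - values)
        np.testing.assert_allclose(post, post_m[:, ::-1], atol=1e-12)


class TestLabels:
    @pytest.mark.parametrize(
        "posteriors,expected",
        [
            ((0.96, 0.04), COLOUR_A),
            ((0.04, 0.96), COLOUR_B),
            ((0.95, 0.05), NOT_DEFINED),  # strictly greater than
            ((0.50, 0.50), NOT_DEFINED),
        ],
    )
    def test_event_threshold(self, posteriors, expected):
        assert assign_event_colour(posteriors) == expected

    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["A", "A", "B", NOT_DEFINED], COLOUR_A),
            ([NOT_DEFINED, NOT_DEFINED, "A"], EXCLUDED),
            (["A", "B"], EXCLUDED),
            (["B", "B", "A"], COLOUR_B),
            (["A", NOT_DEFINED, "A", NOT_DEFINED], EXCLUDED),  # tie
        ],
    )
    def test_trace_majority_vote(self, labels, expected):
        assert assign_trace_colour(labels) == expected

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sampled_from(["A", "B", NOT_DEFINED]), min_size=1, max_size=12
        ),
        st.randoms(use_true_random=False),
    )
    def test_trace_vote_permutation_invariant(self, labels, rand):
        before = assign_trace_colour(labels)
        shuffled = list(labels)
        rand.shuffle(shuffled)
        assert assign_trace_colour(shuffled) == before


class TestUnmixTable:
    def test_posteriors_sum_to_one_and_labels_consistent(self):
        from mfxduet.simulate import SimulationConfig, simulate

        table, _ = simulate(SimulationConfig(seed=4, n_pairs=10))
        assigned, model = unmix_table(table)
        assert model.converged
        # posterior_b in [0,1]; labels follow the strict 0.95 rule
        pb = assigned["posterior_b"].to_numpy()
        assert ((pb >= 0) & (pb <= 1)).all()
        assert (assigned.loc[pb > 0.95, "event_label"] == COLOUR_B).all()
        assert (assigned.loc[1 - pb > 0.95, "event_label"] == COLOUR_A).all()
        mid = (pb <= 0.95) & (1 - pb <= 0.95)
        assert (assigned.loc[mid, "event_label"] == NOT_DEFINED).all()
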