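"""Scale transforms, spec validation and scenario round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixedpower import (
    DesignParams,
    EndpointSpec,
    OutcomeSpec,
    dump_scenario,
    latent_effect_from_probs,
    latent_mean_from_prob,
    load_scenario,
    ordinal_category_prob,
    standardized_effects,
    validate_spec,
)
from mixedpower.endpoint_model import (
    CorrelationError,
    OutcomeOrderError,
    ProbabilityError,
    ThresholdError,
    VarianceError,
)


class TestLatentMeanFromProb:
    @pytest.mark.parametrize(
        "pi, expected",
        [(0.5, 0.0), (0.975, 1.959964), (0.38, -0.30548)],
    )
    def test_standard_normal_quantiles(self, pi, expected):
        assert latent_mean_from_prob(pi) == pytest.approx(expected, abs=5e-6)

    @pytest.mark.parametrize("pi", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_probability_rejected(self, pi):
        with pytest.raises(ProbabilityError, match="Taper"):
            latent_mean_from_prob(pi, name="Taper")


class TestLatentEffect:
    @pytest.mark.parametrize(
        "pi_T, pi_C, expected",
        [(0.97, 0.95, 0.235940), (0.54, 0.38, 0.405915)],
    )
    def test_probit_transform_of_response_rates(self, pi_T, pi_C, expected):
        assert latent_effect_from_probs(pi_T, pi_C) == pytest.approx(
            expected, abs=5e-6
        )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.floats(0.01, 0.99),
        b=st.floats(0.01, 0.99),
    )
    def test_antisymmetry(self, a, b):
        assert latent_effect_from_probs(a, b) == pytest.approx(
            -latent_effect_from_probs(b, a), abs=1e-12
        )
        assert latent_effect_from_probs(a, a) == 0.0


class TestOrdinalCategoryProb:
    def test_full_range_is_certain(self):
        thr = (-1.0, 0.0, 1.3)
        assert ordinal_category_prob(thr, 0.7, range(4)) == pytest.approx(1.0)

    def test_binary_split_at_zero(self):
        assert ordinal_category_prob((0.0,), 0.0, [0]) == pytest.approx(0.5)

    def test_central_interval(self):
        # Phi(1) - Phi(-1)
        assert ordinal_category_prob((-1.0, 1.0), 0.0, [1]) == pytest.approx(
            0.6826895, abs=1e-6
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(mu=st.floats(-3, 3))
    def test_levels_are_additive_and_total_one(self, mu):
        thr = (-0.8, 0.1, 0.9)
        singles = [ordinal_category_prob(thr, mu, [l]) for l in range(4)]
        assert sum(singles) == pytest.approx(1.0, abs=1e-12)
        assert ordinal_category_prob(thr, mu, [1, 2]) == pytest.approx(
            singles[1] + singles[2], abs=1e-12
        )

    def test_non_contiguous_level_set_rejected(self):
        with pytest.raises(Exception, match="contiguous"):
            ordinal_category_prob((-1.0, 1.0), 0.0, [0, 2])
        with pytest.raises(Exception, match="non-empty"):
            ordinal_category_prob((-1.0, 1.0), 0.0, [])


class TestStandardizedEffects:
    def test_four_outcome_sle_design(self):
        # exact probit transforms; continuous entries effect/sd
        spec = EndpointSpec(
            outcomes=(
                OutcomeSpec(kind="continuous", effect_obs=0.88, sd=np.sqrt(18)),
                OutcomeSpec(
                    kind="continuous", effect_obs=0.38, sd=np.sqrt(0.35)
                ),
                OutcomeSpec(kind="ordinal", n_levels=5, prob_T=0.97,
                            prob_C=0.95),
                OutcomeSpec(kind="binary", prob_T=0.54, prob_C=0.38),
            ),
            corr=np.eye(4),
        )
        d = standardized_effects(spec).as_array()
        assert d == pytest.approx([0.2074, 0.6423, 0.2359, 0.4059], abs=5e-5)

    def test_all_null_gives_zero_vector(self):
        spec = EndpointSpec(
            outcomes=(
                OutcomeSpec(kind="continuous", effect_obs=0.0, sd=1.0),
                OutcomeSpec(kind="binary", prob_T=0.4, prob_C=0.4),
            ),
            corr=np.eye(2),
        )
        assert standardized_effects(spec).as_array() == pytest.approx([0, 0])

    def test_unit_variance_design_passes_through(self, grid_spec):
        d = standardized_effects(grid_spec).as_array()
        assert d == pytest.approx([0.12, 0.12, 0.12, 0.12])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_to_continuous_rescaling(self, scale):
        base = OutcomeSpec(kind="continuous", effect_obs=0.88, sd=3.0)
        scaled = OutcomeSpec(
            kind="continuous", effect_obs=0.88 * scale, sd=3.0 * scale
        )
        s1 = EndpointSpec(outcomes=(base,), corr=np.eye(1))
        s2 = EndpointSpec(outcomes=(scaled,), corr=np.eye(1))
        assert standardized_effects(s1).as_array() == pytest.approx(
            standardized_effects(s2).as_array(), rel=1e-12
        )


class TestValidation:
    def _cont(self):
        return OutcomeSpec(kind="continuous", effect_obs=1.0, sd=1.0)

    def test_valid_spec_passes(self):
        spec = EndpointSpec(outcomes=(self._cont(),), corr=np.eye(1))
        assert validate_spec(spec) is spec
        assert spec.K == 1 and spec.k_m == 1

    def test_singular_correlation_rejected(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(CorrelationError):
            EndpointSpec(
                outcomes=(self._cont(), self._cont()), corr=corr
            )

    def test_decreasing_thresholds_rejected(self):
        with pytest.raises(ThresholdError):
            OutcomeSpec(kind="ordinal", n_levels=3, prob_T=0.6, prob_C=0.4,
                        thresholds=(1.0, -1.0))

    def test_wrong_outcome_order_rejected(self):
        with pytest.raises(OutcomeOrderError):
            EndpointSpec(
                outcomes=(
                    OutcomeSpec(kind="binary", prob_T=0.6, prob_C=0.4),
                    self._cont(),
                ),
                corr=np.eye(2),
            )

    def test_discrete_sd_rejected(self):
        with pytest.raises(VarianceError):
            OutcomeSpec(kind="binary", prob_T=0.6, prob_C=0.4, sd=1.0)

    def test_counts_of_kinds(self, muse):
        assert (muse.K, muse.k_m, muse.k_o) == (4, 2, 3)


class TestScenarioRoundTrip:
    @pytest.mark.parametrize("ext", ["yaml", "json"])
    def test_load_dump_load_identity(self, tmp_path, muse, ext):
        params = DesignParams(alpha=0.025, target_power=0.8,
                              adjustment="bonferroni")
        p1 = tmp_path / f"scenario.{ext}"
        dump_scenario(muse, params, p1)
        spec2, params2 = load_scenario(p1)
        assert spec2 == muse and params2 == params
        p2 = tmp_path / f"again.{ext}"
        dump_scenario(spec2, params2, p2)
        assert p1.read_text() == p2.read_text()

    def test_equicorrelation_shorthand(self, tmp_path):
        p = tmp_path / "s.yaml"
        p.write_text(
            "outcomes:\n"
            "- {kind: continuous, effect_obs: 0.3, sd: 1.0}\n"
            "- {kind: binary, prob_T: 0.6, prob_C: 0.4}\n"
            "corr: {rho: 0.5}\n"
        )
        spec, _ = load_scenario(p)
        assert spec.corr[0, 1] == 0.5

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "s.yaml"
        p.write_text(
            "outcomes:\n- {kind: continuous, effect_obs: 1, sd: 1}\n"
            "bogus: 1\n"
        )
        with pytest.raises(Exception, match="bogus"):
            load_scenario(p)
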