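"""Parameter containers, the packaged defaults and the YAML loader."""

import pytest
import yaml

from ambucea import (
    BANDS,
    BandTransitions,
    ParameterError,
    band_of,
    beta_point_estimate,
    default_parameter_path,
    default_parameters,
    load_parameters,
)
from ambucea.parameters import parameters_from_mapping


class TestPackagedDefaults:
    def test_key_point_values(self, params):
        tm = params.transitions
        assert tm.le5.ff == 0.980
        assert tm.le5.fb == 0.020
        assert tm.le5.fe == 0.000
        assert tm.gt10.be == 0.843
        assert params.costs.ambulance_price == 300_175.00
        assert params.costs.equipment_price == 188_825.00
        assert params.effectiveness.utilization == {
            "le5": 555, "y6to10": 385, "gt10": 294,
        }
        assert params.effectiveness.optimum_utilization == 555
        assert params.maintenance.minor_per_year == {"le5": 3, "y6to10": 3, "gt10": 5}
        assert params.config.fleet_size == 1891
        assert params.config.n_cycles == 20

    def test_transition_rows_on_simplex(self, params):
        for band in BANDS:
            bt = params.transitions.band(band)
            assert bt.ff + bt.fb + bt.fe == pytest.approx(1.0, abs=1e-9)
            assert bt.bf + bt.bb + bt.be == pytest.approx(1.0, abs=1e-9)
            assert bt.ef == 1.0

    def test_beta_means_match_point_values(self, params):
        checked = 0
        for u in params.uncertainty.parameters:
            if u.dist != "beta":
                continue
            mean = beta_point_estimate(u.alpha, u.beta)
            assert mean == pytest.approx(params.point_value(u.name), abs=1e-3)
            checked += 1
        assert checked == 6  # one F->B and one B->BER row per band

    def test_ranges_are_plus_minus_twenty_percent(self, params):
        """Published low/high bounds equal the point value -/+20%, except that
        probability upper bounds are capped at 1."""
        for u in params.uncertainty.parameters:
            point = params.point_value(u.name)
            is_prob = u.name.startswith("tp_") or u.name == "mortality_without_ambulance"
            expect_low = 0.8 * point
            expect_high = min(1.2 * point, 1.0) if is_prob else 1.2 * point
            # bounds are printed rounded (3 decimals for probabilities)
            assert u.low == pytest.approx(expect_low, rel=5e-3, abs=5e-4)
            assert u.high == pytest.approx(expect_high, rel=5e-3, abs=5e-4)

    def test_resale_is_ten_percent_of_ambulance_price(self, params):
        c = params.costs
        assert c.resale_fraction == 0.10
        assert c.resale_value == pytest.approx(0.10 * c.ambulance_price, abs=0.005)

    def test_mortality_presets(self, params, params_table4):
        assert params.effectiveness.mortality_without_ambulance == 0.040
        assert params_table4.effectiveness.mortality_without_ambulance == 0.035
        with pytest.raises(ParameterError, match="preset"):
            default_parameters(mortality_preset="nope")


class TestBetaPointEstimate:
    @pytest.mark.parametrize(
        "alpha,beta,expected",
        [
            (24.480, 1199.520, 0.020),
            (3.082, 0.574, 0.843),
            (1.0, 1.0, 0.5),
        ],
    )
    def test_means(self, alpha, beta, expected):
        assert beta_point_estimate(alpha, beta) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("alpha,beta", [(0, 1), (1, 0), (-2, 3)])
    def test_rejects_non_positive(self, alpha, beta):
        with pytest.raises(ParameterError):
            beta_point_estimate(alpha, beta)


class TestValidation:
    def test_row_sum_violation_reports_row_and_sum(self):
        with pytest.raises(ParameterError, match=r"functioning row.*1\.1"):
            BandTransitions(ff=0.9, fb=0.2, fe=0.0, bf=0.3, bb=0.3, be=0.4)

    def test_missing_key_is_named(self, tmp_path):
        raw = yaml.safe_load(default_parameter_path().read_text())
        del raw["costs"]["fuel_per_trip"]
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(raw))
        with pytest.raises(ParameterError, match="fuel_per_trip"):
            load_parameters(bad)

    def test_loader_rejects_bad_row_sum(self):
        raw = yaml.safe_load(default_parameter_path().read_text())
        raw["transition_probabilities"]["le5"]["fb"] = 0.2  # row now sums to 1.18
        with pytest.raises(ParameterError, match="le5"):
            parameters_from_mapping(raw)

    def test_loader_rejects_inconsistent_resale(self):
        raw = yaml.safe_load(default_parameter_path().read_text())
        raw["costs"]["resale_value"] = 99_999.0
        with pytest.raises(ParameterError, match="resale"):
            parameters_from_mapping(raw)

    def test_loader_rejects_off_centre_beta(self):
        raw = yaml.safe_load(default_parameter_path().read_text())
        raw["uncertainty"]["parameters"]["tp_fb_le5"]["alpha"] = 50.0
        with pytest.raises(ParameterError, match="tp_fb_le5"):
            parameters_from_mapping(raw)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ParameterError, match="not found"):
            load_parameters(tmp_path / "absent.yaml")


class TestBands:
    @pytest.mark.parametrize(
        "age,band", [(1, "le5"), (5, "le5"), (6, "y6to10"), (10, "y6to10"),
                     (11, "gt10"), (40, "gt10")]
    )
    def test_band_of(self, age, band):
        assert band_of(age) == band

    def test_age_zero_rejected(self):
        with pytest.raises(ParameterError):
            band_of(0)


class TestOverrides:
    def test_probability_override_renormalizes_row(self, params):
        p = params.with_overrides({"tp_fb_gt10": 0.5})
        bt = p.transitions.gt10
        assert bt.fb == 0.5
        assert bt.ff + bt.fb + bt.fe == pytest.approx(1.0, abs=1e-12)
        # remaining mass split in the original ff:fe proportion
        assert bt.ff / bt.fe == pytest.approx(0.525 / 0.097, rel=1e-9)

    def test_probability_override_clipped(self, params):
        p = params.with_overrides({"tp_be_gt10": 1.2})
        assert p.transitions.gt10.be == 1.0
        assert p.transitions.gt10.bf == 0.0

    def test_le5_utilization_drags_optimum(self, params):
        p = params.with_overrides({"utilization_le5": 600.0})
        assert p.effectiveness.utilization["le5"] == 600.0
        assert p.effectiveness.optimum_utilization == 600.0
        # but not when the optimum is explicitly pinned
        p2 = params.with_overrides({"utilization_le5": 600.0,
                                    "optimum_utilization": 555.0})
        assert p2.effectiveness.optimum_utilization == 555.0

    def test_unknown_name_rejected(self, params):
        with pytest.raises(ParameterError, match="unknown parameter"):
            params.with_overrides({"warp_drive": 1.0})

    def test_original_untouched(self, params):
        params.with_overrides({"fuel_per_trip": 1.0})
        assert params.costs.fuel_per_trip == 18.84
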