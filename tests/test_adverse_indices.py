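"""Adverse-event detectors: constructed trigger cases, oracle equivalence,
probability aggregation."""

import numpy as np
import pytest

import agriwx as ax
from agriwx import adverse_indices as ai
from agriwx.phenology import PhenoDates
from naive_detectors import NAIVE, random_crop_year


def make_year(**overrides):
    """A benign 460-day crop year (no events fire) to perturb per test.

    Mild temperatures below the hardiness threshold, no rain, dry workable
    topsoil, no snow; sowing at index 20, anthesis 250, maturity 300.
    """
    n = 460
    base = dict(
        harvest_year=1,
        tmax=np.full(n, 12.0),
        tmin=np.full(n, 5.0),
        precip=np.zeros(n),
        at_fc=np.zeros(n, dtype=bool),
        top_saturation=np.full(n, 0.5),
        snow_depth_cm=np.zeros(n),
    )
    pheno = overrides.pop("pheno", None)
    if pheno is None:
        pheno = PhenoDates(20, 40, 250, 300, 293, 313, 158, 208, 8.0, 10.0)
    base.update(overrides)
    return ai.CropYear(pheno=pheno, **base)


class TestFrostNoSnow:
    def test_deep_frost_on_bare_ground_fires(self):
        cy = make_year()
        cy.tmin[100] = -21.0
        assert ai.detect_frost_no_snow(cy)

    def test_snow_cover_protects(self):
        cy = make_year()
        cy.tmin[100] = -21.0
        cy.snow_depth_cm[100] = 5.0
        assert not ai.detect_frost_no_snow(cy)

    def test_threshold_is_minus_20(self):
        cy = make_year()
        cy.tmin[100] = -19.9
        assert not ai.detect_frost_no_snow(cy)

    def test_mild_year_clear(self):
        assert not ai.detect_frost_no_snow(make_year())


def _warm_spell(cy, start, length):
    cy.tmax[start:start + length] = 14.0
    cy.tmin[start:start + length] = 8.0  # tmean 11 >= 10


class TestLateFrost:
    def test_frost_after_five_warm_days_fires(self):
        cy = make_year()
        _warm_spell(cy, 100, 5)
        cy.tmin[106] = -3.0
        assert ai.detect_late_frost(cy)

    def test_hardiness_regained_after_three_cold_days(self):
        cy = make_year()
        _warm_spell(cy, 100, 5)
        # three days in a row below 10 degC re-hardens the crop
        cy.tmin[108] = -3.0
        assert not ai.detect_late_frost(cy)

    def test_two_cold_days_do_not_reharden(self):
        cy = make_year()
        _warm_spell(cy, 100, 5)
        cy.tmax[105:107] = 10.0
        cy.tmin[105:107] = 4.0  # tmean 7 < 10, only 2 days
        _warm_spell(cy, 107, 1)
        cy.tmin[107] = -3.0
        cy.tmax[107] = 25.0  # keep tmean >= 10 with the frost-morning tmin
        assert ai.detect_late_frost(cy)

    def test_four_warm_days_insufficient(self):
        cy = make_year()
        _warm_spell(cy, 100, 4)
        cy.tmin[105] = -3.0
        assert not ai.detect_late_frost(cy)


class TestWetEarlySeason:
    @pytest.mark.parametrize(("n_days", "expected"), [(61, True), (60, False)])
    def test_sixty_day_threshold(self, n_days, expected):
        cy = make_year()
        cy.at_fc[30:30 + n_days] = True
        assert ai.detect_wet_early_season(cy) is expected

    def test_cold_days_not_counted(self):
        cy = make_year()
        cy.at_fc[30:100] = True
        cy.tmax[30:100] = 4.0
        cy.tmin[30:100] = 0.0  # tmean 2 < 3
        assert not ai.detect_wet_early_season(cy)

    def test_days_after_anthesis_ignored(self):
        cy = make_year()
        cy.at_fc[251:330] = True
        assert not ai.detect_wet_early_season(cy)


class TestLodging:
    def test_two_heavy_days_fire(self):
        cy = make_year()
        cy.precip[260] = 45.0
        cy.precip[270] = 45.0
        assert ai.detect_lodging_risk(cy)

    def test_one_heavy_day_insufficient(self):
        cy = make_year()
        cy.precip[260] = 45.0
        assert not ai.detect_lodging_risk(cy)

    def test_moderate_rain_on_saturated_soil(self):
        cy = make_year()
        for d in (260, 270):
            cy.at_fc[d - 1] = True
            cy.precip[d] = 25.0
        assert ai.detect_lodging_risk(cy)

    def test_heavy_days_outside_window_ignored(self):
        cy = make_year()
        cy.precip[100] = 45.0   # before anthesis
        cy.precip[298] = 45.0   # within 5 days of maturity
        assert not ai.detect_lodging_risk(cy)


class TestGrainfillHeat:
    def test_three_hot_days_fire(self):
        cy = make_year()
        for d in (258, 270, 290):
            cy.tmax[d] = 36.0
        assert ai.detect_grainfill_heat(cy)

    def test_two_hot_days_insufficient(self):
        cy = make_year()
        cy.tmax[260] = cy.tmax[270] = 36.0
        assert not ai.detect_grainfill_heat(cy)

    def test_hot_days_before_window_ignored(self):
        cy = make_year()
        for d in (251, 252, 253):  # before anthesis+5
            cy.tmax[d] = 36.0
        assert not ai.detect_grainfill_heat(cy)


class TestAdverseSowing:
    def test_saturated_window_fires(self):
        cy = make_year()
        cy.top_saturation[:60] = 0.95
        assert ai.detect_adverse_sowing(cy)

    def test_exactly_three_workable_days_clear(self):
        cy = make_year()
        cy.top_saturation[:60] = 0.95
        cy.top_saturation[10:13] = 0.5  # 3 workable days inside sowing +/- 15
        assert not ai.detect_adverse_sowing(cy)

    def test_rain_day_unworkable_but_event_clear(self):
        cy = make_year()
        cy.precip[20] = 6.0  # a 6 mm day is unworkable; the rest are fine
        assert not ai.detect_adverse_sowing(cy)

    def test_dry_topsoil_also_unworkable(self):
        cy = make_year()
        cy.top_saturation[:60] = 0.02  # below the 5% lower bound
        assert ai.detect_adverse_sowing(cy)


class TestAdverseHarvest:
    def test_persistent_drizzle_fires(self):
        cy = make_year()
        cy.precip[300:330] = 2.0
        assert ai.detect_adverse_harvest(cy)

    def test_dry_window_clear(self):
        assert not ai.detect_adverse_harvest(make_year())

    def test_light_rain_on_dry_soil_is_workable(self):
        cy = make_year()
        cy.precip[305:326] = 0.4  # < 0.5 mm: still workable
        assert not ai.detect_adverse_harvest(cy)

    def test_saturated_topsoil_fires(self):
        cy = make_year()
        cy.top_saturation[300:330] = 0.90  # >= 85%
        assert ai.detect_adverse_harvest(cy)


class TestOracleEquivalence:
    def test_detectors_match_naive_scan_on_random_years(self):
        """All seven detectors agree with independent day-by-day
        re-implementations on 300 random synthetic crop years."""
        rng = np.random.default_rng(2024)
        disagreements = []
        for i in range(300):
            cy = random_crop_year(rng)
            flags = ai.detect_all(cy).as_dict()
            for name, fn in NAIVE.items():
                if flags[name] != fn(cy):
                    disagreements.append((i, name))
        assert disagreements == []

    def test_random_years_exercise_every_event(self):
        rng = np.random.default_rng(2024)
        fired = {name: 0 for name in ai.EVENT_NAMES}
        for _ in range(300):
            flags = ai.detect_all(random_crop_year(rng)).as_dict()
            for name, v in flags.items():
                fired[name] += bool(v)
        assert all(n > 0 for n in fired.values()), fired


class TestEventProbability:
    def test_counting(self):
        flags = [ax.EventFlags(y, y < 25, False, True, False, False, False, False)
                 for y in range(250)]
        probs = ai.event_probability(flags)
        assert probs["frost_no_snow"] == pytest.approx(0.10)
        assert probs["late_frost"] == 0.0
        assert probs["wet_early_season"] == 1.0
        assert probs["n_years"] == 250

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        flags = [ax.EventFlags(y, *(bool(b) for b in rng.integers(0, 2, 7)))
                 for y in range(40)]
        shuffled = list(flags)
        rng.shuffle(shuffled)
        a = ai.event_probability(flags)
        b = ai.event_probability(shuffled)
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ai.event_probability([])

    def test_adding_qualifying_days_never_clears_events(self):
        """Monotonicity under flag implication for the count-based triggers."""
        cy = make_year()
        cy.at_fc[30:95] = True           # 65 qualifying days -> fires
        assert ai.detect_wet_early_season(cy)
        cy.at_fc[95:120] = True          # more qualifying days
        assert ai.detect_wet_early_season(cy)
        cy2 = make_year()
        cy2.precip[260] = cy2.precip[265] = 45.0
        assert ai.detect_lodging_risk(cy2)
        cy2.precip[270] = 50.0
        assert ai.detect_lodging_risk(cy2)
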