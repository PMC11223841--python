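"""Sub-scorer behaviour: worked examples, boundaries, missing data,
validation, and the scalar/array contract."""

import numpy as np
import pytest

import phoenix_score as px
from phoenix_score import PatientSnapshot, PhoenixValidationError
from phoenix_score.derived import resolve_map

nan = float("nan")


class TestRespiratory:
    @pytest.mark.parametrize(
        "pf, sf, imv, support, expected",
        [
            (None, None, None, None, 0),  # nothing recorded
            (None, None, False, False, 0),  # worked example: no resp data
            (90, None, True, True, 3),
            (90, None, False, True, 1),  # low PF but no IMV caps at 1 point
            (150, None, True, True, 2),
            (None, 140, True, True, 3),
            (None, 210, True, False, 2),  # IMV implies support
            (None, 280, False, True, 1),
            (450, 300, True, True, 0),
            (99.99, None, True, True, 3),
            (100.0, None, True, True, 2),
            (199.99, None, True, True, 2),
            (200.0, None, True, True, 1),
            (399.99, None, False, True, 1),
            (400.0, None, False, True, 0),
            (None, 147.99, True, True, 3),
            (None, 148.0, True, True, 2),
            (None, 291.99, False, True, 1),
            (None, 292.0, False, True, 0),
            (90, None, False, False, 0),  # abnormal ratio without support
        ],
    )
    def test_tiers(self, pf, sf, imv, support, expected):
        assert px.score_respiratory(pf, sf, imv, support) == expected

    def test_either_ratio_triggers_tier(self):
        # disjunction: the worse of the two ratios sets the tier
        assert px.score_respiratory(300, 140, True, True) == 3
        assert px.score_respiratory(90, 300, True, True) == 3

    def test_negative_ratio_rejected(self):
        with pytest.raises(PhoenixValidationError, match="pf_ratio"):
            px.score_respiratory(-1, None, True, True)


class TestCardiovascular:
    def test_worked_example_components(self):
        # one vasoactive + MAP 43.67 in the 1-point band at 36 months
        map_mmhg = 32 + (67 - 32) / 3
        assert px.score_cardiovascular(1, None, map_mmhg, 36) == 2

    def test_all_missing_except_age(self):
        assert px.score_cardiovascular(None, None, None, 36) == 0

    @pytest.mark.parametrize(
        "count, expected", [(None, 0), (0, 0), (1, 1), (2, 2), (6, 2)]
    )
    def test_medication_points(self, count, expected):
        assert px.score_cardiovascular(count, None, None, 36) == expected

    @pytest.mark.parametrize(
        "lactate, expected",
        [(None, 0), (4.99, 0), (5.0, 1), (10.99, 1), (11.0, 2), (0.8, 0)],
    )
    def test_lactate_points(self, lactate, expected):
        assert px.score_cardiovascular(None, lactate, None, 36) == expected

    @pytest.mark.parametrize(
        "age, map_mmhg, expected",
        [
            (0.5, 16.99, 2), (0.5, 17.0, 1), (0.5, 30.99, 1), (0.5, 31.0, 0),
            (6, 24.99, 2), (6, 25.0, 1), (6, 38.99, 1), (6, 39.0, 0),
            (18, 30.99, 2), (18, 44.0, 0),
            (36, 31.99, 2), (36, 32.0, 1), (36, 44.99, 1), (36, 45.0, 0),
            (100, 35.99, 2), (100, 49.0, 0),
            (180, 37.99, 2), (180, 38.0, 1), (180, 51.99, 1), (180, 52.0, 0),
        ],
    )
    def test_map_age_brackets(self, age, map_mmhg, expected):
        assert px.score_cardiovascular(None, None, map_mmhg, age) == expected

    def test_maximum_is_six(self):
        assert px.score_cardiovascular(2, 11.0, 16.0, 0.5) == 6

    def test_age_required(self):
        with pytest.raises(PhoenixValidationError, match="age"):
            px.score_cardiovascular(1, None, 40, None)

    def test_age_over_rubric_range_errors_by_default(self):
        with pytest.raises(PhoenixValidationError, match="age"):
            px.score_cardiovascular(None, None, 40, 216.0)

    def test_age_clamp_opt_in_scores_oldest_bracket(self):
        with pytest.warns(UserWarning, match="clamped"):
            pts = px.score_cardiovascular(None, None, 40, 240, clamp_age=True)
        assert pts == 1  # 38 <= 40 < 52 in the oldest bracket

    def test_vasoactive_count_domain(self):
        with pytest.raises(PhoenixValidationError, match="vasoactive_count"):
            px.score_cardiovascular(7, None, None, 36)


class TestCoagulation:
    @pytest.mark.parametrize(
        "platelets, inr, d_dimer, fibrinogen, expected",
        [
            (95, None, None, None, 1),  # worked example lab
            (None, None, None, None, 0),
            (50, 2.0, 5, 80, 2),  # four abnormal labs capped at 2
            (99.99, None, None, None, 1),
            (100.0, None, None, None, 0),
            (None, 1.3, None, None, 0),
            (None, 1.31, None, None, 1),
            (None, None, 2.0, None, 0),
            (None, None, 2.01, None, 1),
            (None, None, None, 99.99, 1),
            (None, None, None, 100.0, 0),
            (99, 1.4, None, None, 2),
        ],
    )
    def test_cap_and_boundaries(self, platelets, inr, d_dimer, fibrinogen,
                                expected):
        assert px.score_coagulation(platelets, inr, d_dimer,
                                    fibrinogen) == expected

    def test_negative_lab_rejected(self):
        with pytest.raises(PhoenixValidationError, match="platelets"):
            px.score_coagulation(-5, None, None, None)


class TestNeurologic:
    @pytest.mark.parametrize(
        "gcs, pupils, expected",
        [
            (None, None, 0),
            (15, False, 0),
            (11, False, 0),
            (10, False, 1),
            (3, False, 1),
            (15, True, 2),  # fixed pupils dominate any GCS
            (None, True, 2),
            (3, True, 2),
        ],
    )
    def test_pupils_dominate_gcs(self, gcs, pupils, expected):
        assert px.score_neurologic(gcs, pupils) == expected

    @pytest.mark.parametrize("bad", [2, 16, 7.5])
    def test_gcs_domain_enforced(self, bad):
        with pytest.raises(PhoenixValidationError, match="gcs"):
            px.score_neurologic(bad, None)


class TestSingleLabBlocks:
    @pytest.mark.parametrize(
        "glucose, expected",
        [(None, 0), (100, 0), (50.0, 0), (150.0, 0), (49.99, 1),
         (150.5, 1), (150.01, 1), (30, 1), (300, 1)],
    )
    def test_endocrine_closed_interval(self, glucose, expected):
        assert px.score_endocrine(glucose) == expected

    @pytest.mark.parametrize(
        "anc, alc, expected",
        [(None, None, 0), (499, None, 1), (500, None, 0), (None, 999, 1),
         (None, 1000, 0), (400, 500, 1), (600, 2000, 0)],
    )
    def test_immunologic_single_point(self, anc, alc, expected):
        assert px.score_immunologic(anc, alc) == expected

    @pytest.mark.parametrize(
        "creatinine, age, expected",
        [(None, 36, 0), (0.9, 150, 0), (1.0, 150, 1), (0.3, 6, 1),
         (0.29, 6, 0), (0.8, 0.5, 1), (0.79, 0.5, 0), (0.6, 36, 1),
         (0.7, 100, 1), (0.69, 100, 0)],
    )
    def test_renal_bracket_cutpoints(self, creatinine, age, expected):
        assert px.score_renal(creatinine, age) == expected

    @pytest.mark.parametrize(
        "bilirubin, alt, expected",
        [(None, None, 0), (4.0, None, 1), (3.99, None, 0),
         (None, 102, 0), (None, 102.5, 1), (None, 102.01, 1), (5, 300, 1)],
    )
    def test_hepatic_boundaries(self, bilirubin, alt, expected):
        assert px.score_hepatic(bilirubin, alt) == expected


class TestPhoenixTotals:
    def test_worked_example(self, worked_example):
        res = px.phoenix(worked_example)
        assert (res.respiratory, res.cardiovascular, res.coagulation,
                res.neurologic) == (0, 2, 1, 0)
        assert res.total == 3
        assert res.sepsis and res.septic_shock

    def test_empty_snapshot_scores_zero(self):
        res = px.phoenix(PatientSnapshot(age_months=36))
        assert res.total == 0
        assert not res.sepsis and not res.septic_shock

    def test_sepsis_without_cardiovascular_point_is_not_shock(self):
        snap = PatientSnapshot(age_months=36, platelets_k_ul=50, gcs=8)
        res = px.phoenix(snap)
        assert res.total == 2 and res.cardiovascular == 0
        assert res.sepsis and not res.septic_shock

    def test_phoenix8_worked_example_adds_nothing(self, worked_example):
        res8 = px.phoenix8(worked_example)
        assert res8.total8 == res8.total == 3
        assert (res8.endocrine, res8.immunologic, res8.renal,
                res8.hepatic) == (0, 0, 0, 0)

    def test_phoenix8_maximal_snapshot_reaches_17(self):
        snap = PatientSnapshot(
            age_months=36,
            pf_ratio=50,
            on_imv=True,
            vasoactive_count=3,
            lactate_mmol_l=15,
            map_mmhg=20,
            platelets_k_ul=10,
            inr=3,
            gcs=3,
            fixed_pupils_bilateral=True,
            glucose_mg_dl=500,
            anc_cells_mm3=100,
            alc_cells_mm3=100,
            creatinine_mg_dl=2.5,
            bilirubin_mg_dl=10,
            alt_iu_l=500,
        )
        res = px.phoenix8(snap)
        assert (res.respiratory, res.cardiovascular, res.coagulation,
                res.neurologic) == (3, 6, 2, 2)
        assert res.total == 13 and res.total8 == 17

    def test_worked_example_from_raw_inputs(self):
        # rebuild the snapshot from raw EHR fields instead of canonical ones
        snap = PatientSnapshot(
            age_months=36,
            vasoactive_count=px.count_vasoactives(norepinephrine=True),
            map_mmhg=resolve_map(None, 67, 32),
            platelets_k_ul=95,
        )
        assert px.phoenix(snap) == px.phoenix(px.worked_example_row())


class TestArrayContract:
    def test_scalar_in_scalar_out(self):
        out = px.score_endocrine(40)
        assert isinstance(out, int)

    def test_array_in_array_out(self):
        out = px.score_endocrine([40, 100, None])
        assert isinstance(out, np.ndarray)
        assert out.tolist() == [1, 0, 0]

    def test_length_1_broadcasts(self):
        out = px.score_cardiovascular([1], [None, 12.0], [40.0, 40.0],
                                      [36.0, 36.0])
        assert out.tolist() == [2, 4]

    def test_incompatible_lengths_rejected(self):
        with pytest.raises(PhoenixValidationError, match="lengths"):
            px.score_coagulation([1, 2], [1, 2, 3], None, None)

    def test_validation_error_reports_rows(self):
        with pytest.raises(PhoenixValidationError, match=r"rows: 1"):
            px.score_coagulation([50, -1, 30], None, None, None)


class TestSnapshotValidation:
    def test_age_required(self):
        with pytest.raises(PhoenixValidationError, match="age"):
            PatientSnapshot(age_months=None)

    def test_imv_implies_respiratory_support(self):
        snap = PatientSnapshot(age_months=10, on_imv=True)
        assert snap.on_respiratory_support is True

    def test_nan_becomes_missing(self):
        snap = PatientSnapshot(age_months=10, lactate_mmol_l=nan)
        assert snap.lactate_mmol_l is None

    @pytest.mark.parametrize(
        "field, value",
        [("gcs", 2), ("gcs", 16), ("vasoactive_count", 7),
         ("platelets_k_ul", -1), ("inr", -0.5)],
    )
    def test_field_domains(self, field, value):
        with pytest.raises(PhoenixValidationError, match=field):
            PatientSnapshot(age_months=10, **{field: value})
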