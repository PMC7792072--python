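"""Design types, config round-trips and structural validation."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from multiarm.design_model import (Arm, DesignSpec, DesignValidationError,
                                   Hypothesis, Stage, StageTrigger,
                                   load_design, save_design, spec_from_dict,
                                   spec_to_dict)


class TestBundledDesign:
    def test_structure_matches_staged_platform(self, flair):
        assert {a.name for a in flair.arms} == {"FCR", "IR", "I", "I+V"}
        assert len(flair.stages) == 3
        assert set(flair.stages[0].active_arms) == {"FCR", "IR"}
        assert set(flair.stages[1].active_arms) == {"FCR", "IR", "I", "I+V"}
        assert "IR" not in flair.stages[2].active_arms
        assert len(flair.hypotheses) == 3

    def test_even_allocation_everywhere(self, flair):
        for s in flair.stages:
            assert len(set(s.allocation_ratio)) == 1

    def test_hazard_ratio_derived_from_medians(self, flair):
        h = flair.hypothesis("iv-vs-fcr-pfs")
        assert h.hazard_ratio == pytest.approx(4.5 / 6.5)
        assert round(h.hazard_ratio, 2) == 0.69

    def test_recruitment_triggers_encode_printed_targets(self, flair):
        assert flair.stages[1].exit_trigger.count == 377
        t3 = flair.stages[2].exit_trigger
        assert (t3.arm, t3.count, t3.since_stage) == ("FCR", 274, 2)


class TestRoundTrip:
    def test_bundled_design_round_trips(self, flair, tmp_path):
        p = tmp_path / "design.yaml"
        save_design(flair, p)
        assert load_design(p) == flair

    def test_minimal_two_arm_round_trips(self, two_arm_spec, tmp_path):
        p = tmp_path / "mini.yaml"
        save_design(two_arm_spec, p)
        assert load_design(p) == two_arm_spec

    @given(
        p=st.floats(0.51, 1.0),
        rate=st.floats(10, 1000),
        medians=st.tuples(st.floats(1, 10), st.floats(1, 10)),
        count=st.integers(10, 500),
        n_centres=st.integers(2, 30),
    )
    def test_save_load_identity_on_generated_specs(self, tmp_path_factory, p, rate,
                                                   medians, count, n_centres):
        m_ctrl, m_exp = sorted(medians)
        spec = DesignSpec(
            name="gen",
            arms=(Arm("C", "control", m_ctrl, 0.1),
                  Arm("E", "experimental", m_exp + 0.5, 0.3)),
            stages=(Stage(1, ("C", "E"), (1, 1),
                          StageTrigger("arm_recruitment", arm="C", count=count)),),
            hypotheses=(Hypothesis(label="h", experimental_arm="E", control_arm="C",
                                   endpoint="time_to_event", control_median=m_ctrl,
                                   experimental_median=m_exp + 0.5),),
            stratification_factors=(
                ("sex", ("m", "f")),
                ("centre", tuple(f"c{i}" for i in range(n_centres)))),
            minimisation_random_element=p,
            accrual_rate=rate,
        ).check()
        path = tmp_path_factory.mktemp("rt") / "spec.yaml"
        save_design(spec, path)
        assert load_design(path) == spec


class TestValidation:
    def test_hypothesis_with_undeclared_arm_rejected(self, flair):
        d = spec_to_dict(flair)
        d["hypotheses"][0]["experimental_arm"] = "ghost"
        with pytest.raises(DesignValidationError, match="ghost"):
            spec_from_dict(d)

    def test_empty_stage_list_refused_on_save(self, flair, tmp_path):
        broken = dataclasses.replace(flair, stages=())
        with pytest.raises(DesignValidationError):
            save_design(broken, tmp_path / "x.yaml")

    def test_inconsistent_hr_and_medians_rejected(self, flair):
        d = spec_to_dict(flair)
        d["hypotheses"][0]["target_hr"] = 0.5  # medians imply 0.75
        with pytest.raises(DesignValidationError, match="inconsistent"):
            spec_from_dict(d)

    def test_allocation_ratio_length_mismatch_rejected(self, flair):
        d = spec_to_dict(flair)
        d["stages"][0]["ratio"] = [1, 1, 1]
        with pytest.raises(DesignValidationError, match="allocation_ratio"):
            spec_from_dict(d)

    def test_parse_error_names_file(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("arms: [unterminated")
        with pytest.raises(DesignValidationError, match="bad.yaml"):
            load_design(p)

    def test_stages_must_share_a_control_arm(self, flair):
        d = spec_to_dict(flair)
        # stage 3 keeps no control from stage 2
        d["stages"][2]["arms"] = ["IR", "I+V"]
        d["stages"][2]["ratio"] = [1, 1]
        with pytest.raises(DesignValidationError):
            spec_from_dict(d)

    def test_interim_fractions_must_end_at_one(self, flair):
        d = spec_to_dict(flair)
        d["hypotheses"][0]["interim_fractions"] = [0.25, 0.5]
        with pytest.raises(DesignValidationError, match="interim_fractions"):
            spec_from_dict(d)

    def test_centre_count_shorthand_expands(self, flair):
        centre = dict(flair.stratification_factors)["centre"]
        assert len(centre) == 100
        assert len(set(centre)) == 100
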