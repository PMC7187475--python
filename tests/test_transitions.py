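"""Transition-matrix validation, mortality folding, prevented fraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cariescea import model_core as mc
from cariescea import transitions as tr


def identity_model(ages=range(15, 76)):
    return tr.TransitionModel({a: np.eye(mc.N_STATES) for a in ages})


class TestValidation:
    def test_identity_model_valid(self):
        tr.validate_transition_model(identity_model())

    def test_non_stochastic_row_named(self):
        model = identity_model()
        model.matrices[40][2, 2] = 0.98
        with pytest.raises(tr.TransitionValidationError, match="age 40.*DentineDecay"):
            tr.validate_transition_model(model)

    def test_negative_entry_rejected(self):
        model = identity_model()
        model.matrices[20][1, 2] = -0.1
        model.matrices[20][1, 1] = 1.1
        with pytest.raises(tr.TransitionValidationError):
            tr.validate_transition_model(model)

    def test_missing_age_band(self):
        model = identity_model()
        del model.matrices[50]
        with pytest.raises(tr.TransitionValidationError, match="missing age"):
            tr.validate_transition_model(model, required_ages=range(15, 76))

    def test_nodisease_reentry_forbidden(self):
        model = identity_model()
        m = model.matrices[30]
        m[3, 0] = 0.1  # Filling -> NoDisease would reverse caries history
        m[3, 3] = 0.9
        with pytest.raises(tr.TransitionValidationError, match="NoDisease"):
            tr.validate_transition_model(model)

    def test_death_row_must_absorb(self):
        model = identity_model()
        m = model.matrices[30]
        m[mc.DEATH_STATE, mc.DEATH_STATE] = 0.9
        m[mc.DEATH_STATE, 0] = 0.1
        with pytest.raises(tr.TransitionValidationError, match="Death"):
            tr.validate_transition_model(model)


class TestMortality:
    def test_zero_mortality_is_noop(self):
        model = identity_model()
        life = tr.LifeTable({a: 0.0 for a in range(15, 85)})
        out = tr.augment_with_mortality(model, life, 0.5, end_age=85)
        for age in model.ages:
            np.testing.assert_array_equal(
                out.matrices[age], model.matrices[age]
            )
            assert out.matrices[age][:, mc.DEATH_STATE].sum() == 1.0  # Death only

    def test_certain_death_sends_all_mass_to_death(self):
        model = identity_model(range(15, 17))
        life = tr.LifeTable({15: 0.0, 16: 1.0})
        out = tr.augment_with_mortality(model, life, 0.5, end_age=17)
        m = out.matrices[16]
        assert np.allclose(m[:, mc.DEATH_STATE], 1.0)

    def test_half_year_death_probability_closed_form(self):
        model = identity_model(range(15, 16))
        life = tr.LifeTable({15: 0.02})
        out = tr.augment_with_mortality(model, life, 0.5, end_age=16)
        p = out.matrices[15][0, mc.DEATH_STATE]
        assert p == pytest.approx(1 - 0.98**0.5, abs=1e-12)
        assert p == pytest.approx(0.010050, abs=1e-6)

    def test_rows_remain_stochastic(self, core):
        out = tr.augment_with_mortality(
            core.transitions, core.life_table, 0.5, end_age=85
        )
        tr.validate_transition_model(out)
        assert out.max_age == 84  # bands continue past 75 with rising q

    def test_missing_q_raises(self):
        model = identity_model(range(15, 76))
        life = tr.LifeTable({15: 0.001})
        with pytest.raises(tr.TransitionValidationError, match="age 16"):
            tr.augment_with_mortality(model, life, 0.5)


class TestPreventedFraction:
    AFFECTED = (("NoDisease", "EnamelDecay"), ("EnamelDecay", "DentineDecay"))

    def test_pf_zero_is_identity(self, core):
        out = tr.apply_prevented_fraction(core.transitions, 0.0, self.AFFECTED)
        for age in core.transitions.ages:
            np.testing.assert_array_equal(
                out.matrices[age], core.transitions.matrices[age]
            )

    def test_pf_one_moves_all_mass_to_self(self, core):
        out = tr.apply_prevented_fraction(core.transitions, 1.0, self.AFFECTED)
        for age in out.ages:
            m = out.matrices[age]
            assert m[0, 1] == 0.0
            assert m[1, 2] == 0.0

    def test_worked_example(self):
        m = np.eye(mc.N_STATES)
        m[0, 0], m[0, 1] = 0.90, 0.10
        model = tr.TransitionModel({15: m})
        out = tr.apply_prevented_fraction(
            model, 0.43, [("NoDisease", "EnamelDecay")]
        )
        assert out.matrices[15][0, 1] == pytest.approx(0.057, abs=1e-15)
        assert out.matrices[15][0, 0] == pytest.approx(0.943, abs=1e-15)

    def test_pf_outside_unit_interval_rejected(self, core):
        with pytest.raises(ValueError, match="prevented fraction"):
            tr.apply_prevented_fraction(core.transitions, 1.2, self.AFFECTED)

    def test_self_pair_rejected(self, core):
        with pytest.raises(ValueError, match="self-transition"):
            tr.apply_prevented_fraction(
                core.transitions, 0.4, [("Filling", "Filling")]
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        p01=st.floats(0.0, 1.0),
        p12=st.floats(0.0, 0.5),
        pf=st.floats(0.0, 1.0),
    )
    def test_row_sums_preserved_exactly(self, p01, p12, pf):
        """Probability mass removed from a caries transition reappears on
        the source diagonal; row sums never drift."""
        m = np.eye(mc.N_STATES)
        m[0, 0], m[0, 1] = 1 - p01, p01
        m[1, 1], m[1, 2] = 1 - p12, p12
        model = tr.TransitionModel({15: m})
        out = tr.apply_prevented_fraction(model, pf, self.AFFECTED)
        np.testing.assert_allclose(
            out.matrices[15].sum(axis=1), m.sum(axis=1), atol=1e-12, rtol=0
        )


class TestMatrixForCycle:
    def test_cycle_zero_uses_first_band(self, core):
        m = tr.matrix_for_cycle(core.transitions, 0, core.params)
        np.testing.assert_array_equal(m, core.transitions.matrices[15])

    @pytest.mark.parametrize("cycle", [121, 139])
    def test_old_ages_clamp_to_last_band(self, core, cycle):
        m = tr.matrix_for_cycle(core.transitions, cycle, core.params)
        np.testing.assert_array_equal(m, core.transitions.matrices[75])

    def test_out_of_range(self, core):
        with pytest.raises(IndexError):
            tr.matrix_for_cycle(core.transitions, 140, core.params)
        with pytest.raises(IndexError):
            tr.matrix_for_cycle(core.transitions, -1, core.params)


class TestCsvIO:
    def test_round_trip(self, core, tmp_path):
        path = tmp_path / "trans.csv"
        tr.write_transition_csv(core.transitions, path)
        loaded = tr.read_transition_csv(path)
        assert loaded.ages == core.transitions.ages
        for age in loaded.ages:
            np.testing.assert_allclose(
                loaded.matrices[age], core.transitions.matrices[age], atol=1e-15
            )

    def test_unknown_state_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "age,from_state,to_state,probability\n15,NoDisease,Wisdom,1.0\n"
        )
        with pytest.raises(tr.TransitionValidationError, match="Wisdom"):
            tr.read_transition_csv(path)

    def test_life_table_round_trip(self, core, tmp_path):
        path = tmp_path / "life.csv"
        tr.write_life_table_csv(core.life_table, path)
        loaded = tr.read_life_table_csv(path)
        assert loaded.q == pytest.approx(core.life_table.q)
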