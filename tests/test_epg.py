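"""EPG engine: operators, closed forms, and the moving-isochromat oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbfse import (
    FlowSpec,
    TissueParams,
    apply_flow_phase,
    apply_gradient_shift,
    apply_relaxation,
    apply_rf,
    echo_signal,
    epg_init,
    isochromat_oracle,
    simulate_fse_train,
    default_timing,
)
from bbfse.epg import echo_table
from bbfse.vfa import VFATrain


def random_state(rng, max_order=8, lattice_step=1.0):
    """Random EPG state with the Hermitian longitudinal constraint."""
    s = epg_init(max_order, lattice_step)
    n = s.f.size
    s.f[:] = rng.normal(size=n) + 1j * rng.normal(size=n)
    z_half = rng.normal(size=n // 2) + 1j * rng.normal(size=n // 2)
    s.z[n // 2 + 1:] = z_half
    s.z[: n // 2] = np.conj(z_half[::-1])
    s.z[n // 2] = rng.normal()
    return s


class TestInitAndSignal:
    def test_equilibrium(self):
        s = epg_init(32, 1.0)
        assert s.z[s.n_steps] == 1.0
        assert np.all(s.f == 0)
        assert np.count_nonzero(s.z) == 1
        assert echo_signal(s) == 0

    def test_half_integer_lattice(self):
        s = epg_init(1, 0.5)
        assert s.lattice_step == 0.5
        assert s.f.size == 5  # orders -1, -1/2, 0, 1/2, 1
        assert s.z[s.n_steps] == 1.0

    @pytest.mark.parametrize("bad", [0, -1, 2.5])
    def test_invalid_max_order(self, bad):
        with pytest.raises(ValueError):
            epg_init(bad)

    def test_full_excitation(self):
        s = apply_rf(epg_init(4), 90.0, 0.0)
        assert abs(echo_signal(s)) == pytest.approx(1.0, abs=1e-15)
        assert abs(s.z[s.n_steps]) < 1e-15


class TestRF:
    def test_zero_flip_is_identity(self):
        s = random_state(np.random.default_rng(1))
        out = apply_rf(s, 0.0, 33.0)
        np.testing.assert_array_equal(out.f, s.f)
        np.testing.assert_array_equal(out.z, s.z)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        flip=st.floats(-360, 360),
        phase=st.floats(-180, 180),
        seed=st.integers(0, 1000),
    )
    def test_unitarity(self, flip, phase, seed):
        """RF preserves the total configuration norm (no relaxation)."""
        s = random_state(np.random.default_rng(seed))
        norm = np.sum(np.abs(s.f) ** 2) + np.sum(np.abs(s.z) ** 2)
        out = apply_rf(s, flip, phase)
        norm2 = np.sum(np.abs(out.f) ** 2) + np.sum(np.abs(out.z) ** 2)
        assert norm2 == pytest.approx(norm, rel=1e-12)

    def test_preserves_hermitian_z(self):
        s = random_state(np.random.default_rng(2))
        out = apply_rf(s, 137.0, 21.0)
        np.testing.assert_allclose(out.z, np.conj(out.z[::-1]), atol=1e-13)


class TestRelaxation:
    def test_dt_zero_identity(self):
        s = random_state(np.random.default_rng(3))
        out = apply_relaxation(s, TissueParams(880, 40), 0.0)
        np.testing.assert_array_equal(out.f, s.f)

    def test_t2_decay_closed_form(self):
        s = random_state(np.random.default_rng(4))
        out = apply_relaxation(s, TissueParams(880, 40), 40.0)
        np.testing.assert_allclose(out.f, s.f * np.exp(-1.0), rtol=1e-14)

    def test_t1_regrowth_closed_form(self):
        s = epg_init(4)
        s.z[s.n_steps] = 0.0
        out = apply_relaxation(s, TissueParams(880, 40), 880.0)
        assert out.z[out.n_steps].real == pytest.approx(1 - np.exp(-1.0), abs=1e-14)

    def test_negative_dt_raises(self):
        with pytest.raises(ValueError):
            apply_relaxation(epg_init(4), TissueParams(880, 40), -1.0)

    def test_unphysical_tissue_warns_not_fails(self):
        with pytest.warns(UserWarning):
            TissueParams(t1=40, t2=880)


class TestGradientShift:
    def test_shift_roundtrip(self):
        s = random_state(np.random.default_rng(5), max_order=6)
        s.f[-2:] = 0  # headroom so nothing leaks
        out = apply_gradient_shift(apply_gradient_shift(s, 1.0), -1.0)
        np.testing.assert_allclose(out.f, s.f, atol=1e-15)

    def test_shift_moves_f0_off_echo(self):
        s = apply_rf(epg_init(4), 90.0, 0.0)
        out = apply_gradient_shift(s, 1.0)
        assert echo_signal(out) == 0
        assert abs(out.f[out.n_steps + 1]) == pytest.approx(1.0)

    def test_chained_equals_summed(self):
        s = random_state(np.random.default_rng(6), max_order=8)
        s.f[-4:] = 0
        a = apply_gradient_shift(apply_gradient_shift(s, 1.0), 2.0)
        b = apply_gradient_shift(s, 3.0)
        np.testing.assert_array_equal(a.f, b.f)

    def test_off_lattice_shift_raises(self):
        with pytest.raises(ValueError):
            apply_gradient_shift(epg_init(4, 1.0), 0.5)

    def test_leak_tracking(self):
        s = apply_rf(epg_init(2), 90.0, 0.0)
        with pytest.raises(RuntimeError):
            apply_gradient_shift(apply_gradient_shift(s, 2.0), 1.0)


class TestFlowPhase:
    def test_v_zero_bit_identical(self):
        s = random_state(np.random.default_rng(7))
        out = apply_flow_phase(s, FlowSpec(0.0), dk=4.8, dt=3.0, shift_during_interval=1.0)
        np.testing.assert_array_equal(out.f, s.f)
        np.testing.assert_array_equal(out.z, s.z)

    def test_disabled_flow_identical(self):
        s = random_state(np.random.default_rng(8))
        out = apply_flow_phase(s, FlowSpec(50.0, enabled=False), dk=4.8, dt=3.0)
        np.testing.assert_array_equal(out.f, s.f)

    def test_constructed_pi_phase(self):
        """F_0 with a half-unit shift during the interval picks up phase -1 when
        dk * (1/2) * v * dt/1000 = pi."""
        s = apply_rf(epg_init(4, 0.5), 90.0, 0.0)
        f0 = s.f[s.n_steps]
        dk, dt = 4.0, 2.0
        v = np.pi / (dk * 0.5 * dt * 1e-3)
        out = apply_flow_phase(s, FlowSpec(v), dk=dk, dt=dt, shift_during_interval=1.0)
        assert out.f[out.n_steps] == pytest.approx(-f0, abs=1e-12)

    def test_invalid_args(self):
        s = epg_init(4)
        with pytest.raises(ValueError):
            apply_flow_phase(s, FlowSpec(1.0), dk=-1.0, dt=1.0)
        with pytest.raises(ValueError):
            apply_flow_phase(s, FlowSpec(1.0), dk=1.0, dt=0.0)


class TestTrainSimulation:
    def test_cpmg_mono_exponential(self):
        """All-180 train with negligible T1 reproduces exp(-t/T2) to < 1e-9."""
        timing = default_timing(n_acquired=20, n_startup=0, te_eff=6.0)
        train = VFATrain(np.full(timing.n_echoes, 180.0))
        echoes = simulate_fse_train(timing, train, TissueParams(1e9, 40.0))
        expected = np.exp(-timing.echo_times / 40.0)
        assert np.max(np.abs(np.abs(echoes) - expected)) < 1e-9

    def test_length_mismatch_raises(self):
        timing = default_timing(n_acquired=5, n_startup=0, te_eff=6.0)
        with pytest.raises(ValueError):
            simulate_fse_train(timing, VFATrain(np.full(3, 150.0)), TissueParams(880, 40))

    def test_deterministic(self):
        timing = default_timing(n_acquired=6, n_startup=2)
        train = VFATrain(np.linspace(180, 40, timing.n_echoes))
        a = simulate_fse_train(timing, train, TissueParams(880, 40), FlowSpec(33.0))
        b = simulate_fse_train(timing, train, TissueParams(880, 40), FlowSpec(33.0))
        np.testing.assert_array_equal(a, b)

    def test_v0_and_flow_disabled_identical(self):
        timing = default_timing(n_acquired=6, n_startup=2)
        train = VFATrain(np.linspace(180, 40, timing.n_echoes))
        a = simulate_fse_train(timing, train, TissueParams(880, 40), FlowSpec(0.0))
        b = simulate_fse_train(timing, train, TissueParams(880, 40), FlowSpec(77.0, enabled=False))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("velocity", [0.0, 17.5, 50.0, -42.0])
    def test_oracle_agreement(self, velocity):
        """EPG and the moving-isochromat Bloch ensemble agree to < 1e-8."""
        rng = np.random.default_rng(42)
        timing = default_timing(n_acquired=8, n_startup=4)
        train = VFATrain(rng.uniform(30, 180, timing.n_echoes))
        flow = FlowSpec(velocity)
        epg = simulate_fse_train(timing, train, TissueParams(880, 40), flow)
        bloch = isochromat_oracle(timing, train, TissueParams(880, 40), flow)
        assert np.max(np.abs(epg - bloch)) < 1e-8

    def test_oracle_warns_on_undersampling(self):
        timing = default_timing(n_acquired=4, n_startup=2)
        train = VFATrain(np.full(timing.n_echoes, 150.0))
        with pytest.warns(UserWarning, match="alias"):
            isochromat_oracle(timing, train, TissueParams(880, 40), n_isochromats=8)

    def test_echo_table_columns(self):
        timing = default_timing(n_acquired=4, n_startup=2)
        train = VFATrain(np.full(timing.n_echoes, 150.0))
        tab = echo_table(timing, simulate_fse_train(timing, train, TissueParams(880, 40)))
        assert list(tab.columns) == ["echo_index", "time_ms", "re", "im", "magnitude", "acquired_flag"]
        assert tab["acquired_flag"].tolist() == [0, 0, 1, 1, 1, 1]
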