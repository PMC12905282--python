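"""Tests of the ITC heat models, mass balance and cooperative fitting."""

import math

import numpy as np
import pytest

from coopbind import itc, synth
from coopbind.itc import (
    BindingModelOneSet,
    BindingModelTwoSets,
    NoBindingSignalError,
    TitrationProtocol,
    cumulative_heat,
    cooperativity_index,
    displaced_volume_correction,
    fit_isotherm,
    free_ligand,
    injection_heats,
    thermodynamics_from_model,
)

ONE_SET = BindingModelOneSet(n=1.0, K=1e6, dH=-10.0)


def quadratic_free_ligand(n, K, Mt, Xt):
    """Closed-form positive root of the one-set mass-balance quadratic."""
    a = K
    b = 1.0 + K * (n * Mt - Xt)
    c = -Xt
    return (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)


def bisect_free_ligand(model, Mt, Xt, iters=200):
    lo, hi = 0.0, Xt
    f = lambda X: Xt - X - Mt * sum(
        n * K * X / (1 + K * X) for n, K, _ in model.sites
    )
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestFreeLigand:
    def test_no_macromolecule_all_free(self):
        assert free_ligand(ONE_SET, 0.0, 1e-5) == 1e-5

    def test_no_binding_all_free(self):
        model = BindingModelOneSet(n=1.0, K=0.0, dH=-10.0)
        assert free_ligand(model, 15e-6, 1e-5) == 1e-5

    def test_zero_ligand(self):
        assert free_ligand(ONE_SET, 15e-6, 0.0) == 0.0

    def test_matches_quadratic_root(self):
        X = free_ligand(ONE_SET, 15e-6, 10e-6)
        Xq = quadratic_free_ligand(1.0, 1e6, 15e-6, 10e-6)
        assert X == pytest.approx(Xq, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            free_ligand(ONE_SET, np.nan, 1e-5)

    def test_mass_balance_residual_and_bisection(self):
        """1000 random draws: residual < 1e-12 Xt, agrees with bisection."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            if rng.random() < 0.5:
                model = BindingModelOneSet(
                    n=rng.uniform(0.2, 3),
                    K=10 ** rng.uniform(3, 9),
                    dH=-10,
                )
            else:
                model = BindingModelTwoSets(
                    n1=rng.uniform(0.1, 2),
                    n2=rng.uniform(0.1, 2),
                    K1=10 ** rng.uniform(3, 9),
                    K2=10 ** rng.uniform(3, 9),
                    dH1=-8,
                    dH2=-12,
                )
            Mt = rng.uniform(1e-6, 5e-5)
            Xt = rng.uniform(1e-7, 2e-4)
            X = free_ligand(model, Mt, Xt)
            resid = Xt - X - Mt * sum(
                n * K * X / (1 + K * X) for n, K, _ in model.sites
            )
            assert abs(resid) < 1e-12 * max(Xt, 1e-12)
            assert X == pytest.approx(bisect_free_ligand(model, Mt, Xt), rel=1e-10)


class TestCumulativeHeat:
    def setup_method(self):
        self.protocol = synth.default_protocol()

    def test_zero_ligand_zero_heat(self):
        assert cumulative_heat(ONE_SET, self.protocol, 15e-6, 0.0) == 0.0

    def test_saturation_limit(self):
        """Strong binding with huge ligand excess approaches Mt V0 n dH."""
        model = BindingModelOneSet(n=1.0, K=1e12, dH=-10.0)
        Q = cumulative_heat(model, self.protocol, 15e-6, 1e-2)
        expected = 15e-6 * self.protocol.cell_volume * 1.0 * -10.0
        assert Q == pytest.approx(expected, rel=1e-4)

    def test_two_sets_reduces_to_one_set(self):
        """Identical sets (K1=K2, dH1=dH2) sum to one set with n = n1+n2."""
        two = BindingModelTwoSets(n1=0.4, n2=0.6, K1=2e6, K2=2e6, dH1=-9, dH2=-9)
        one = BindingModelOneSet(n=1.0, K=2e6, dH=-9)
        for Xt in np.linspace(1e-7, 5e-5, 25):
            Q2 = cumulative_heat(two, self.protocol, 15e-6, Xt)
            Q1 = cumulative_heat(one, self.protocol, 15e-6, Xt)
            assert Q2 == pytest.approx(Q1, rel=1e-10)

    def test_vanishing_second_set_matches_one_set(self):
        two = BindingModelTwoSets(
            n1=1.0, n2=1e-12, K1=1e6, K2=1e7, dH1=-10, dH2=-5
        )
        Q2 = cumulative_heat(two, self.protocol, 15e-6, 1e-5)
        Q1 = cumulative_heat(ONE_SET, self.protocol, 15e-6, 1e-5)
        assert Q2 == pytest.approx(Q1, rel=1e-9)


class TestInjectionHeats:
    def test_correction_with_zero_dv_is_simple_difference(self):
        Q = np.array([1.0, 1.8, 2.2, 2.3])
        q = displaced_volume_correction(Q, np.zeros(4), 2e-4)
        assert q == pytest.approx([1.0, 0.8, 0.4, 0.1])

    def test_correction_with_constant_q(self):
        """Constant cumulative heat leaves only the displaced-volume term."""
        Q = np.full(5, 3.0)
        dV = np.full(5, 1e-6)
        q = displaced_volume_correction(Q, dV, 2e-4)
        # first injection starts from Q_0 = 0
        assert q[1:] == pytest.approx((1e-6 / 2e-4) * 3.0)

    def test_default_protocol_has_37_heats(self):
        iso = injection_heats(ONE_SET, synth.default_protocol())
        assert iso.n_injections == 37
        assert np.all(np.diff(iso.molar_ratio) > 0)

    def test_sum_of_heats_matches_termwise_oracle(self):
        """Sum q_i equals Q_N plus the accumulated correction terms."""
        protocol = synth.default_protocol()
        iso = injection_heats(ONE_SET, protocol)
        dV = protocol.injection_volumes
        Q = iso.Q
        Q_prev = np.concatenate([[0.0], Q[:-1]])
        oracle = Q[-1] + np.sum((dV / protocol.cell_volume) * 0.5 * (Q + Q_prev))
        assert np.sum(iso.q) == pytest.approx(oracle, rel=1e-12)

    def test_late_injections_approach_zero_at_saturation(self):
        model = BindingModelOneSet(n=1.0, K=1e8, dH=-10.0)
        iso = injection_heats(model, synth.default_protocol())
        assert abs(iso.q[-1]) < 0.02 * abs(iso.q[0])


class TestFit:
    def setup_method(self):
        self.protocol = synth.default_protocol()

    def test_noiseless_one_set_recovery(self):
        truth = BindingModelOneSet(n=1.0, K=1e7, dH=-10.0)
        iso = synth.gen_itc(truth, self.protocol, noise_sd=0.0)
        fit = fit_isotherm(iso, self.protocol, "one_set")
        assert fit.converged
        assert fit.params["n"] == pytest.approx(1.0, rel=1e-3)
        assert fit.params["K"] == pytest.approx(1e7, rel=1e-3)
        assert fit.params["dH"] == pytest.approx(-10.0, rel=1e-3)

    def test_noiseless_two_sets_cooperativity(self):
        truth = BindingModelTwoSets(
            n1=0.25, n2=0.25, K1=1e6, K2=1e8, dH1=-8.0, dH2=-12.0
        )
        iso = synth.gen_itc(truth, self.protocol, noise_sd=0.0)
        fit = fit_isotherm(iso, self.protocol, "two_sets")
        assert fit.converged
        assert fit.cooperativity_index == pytest.approx(100.0, rel=1e-2)
        assert fit.params["n1"] + fit.params["n2"] == pytest.approx(0.5, abs=1e-3)

    def test_all_zero_heats_raise(self):
        iso = injection_heats(ONE_SET, self.protocol)
        iso.q = np.zeros_like(iso.q)
        with pytest.raises(NoBindingSignalError):
            fit_isotherm(iso, self.protocol, "one_set")

    def test_c_value_warning_outside_range(self):
        weak = BindingModelOneSet(n=1.0, K=1e4, dH=-10.0)  # c = 0.15
        iso = synth.gen_itc(weak, self.protocol, noise_sd=0.0)
        fit = fit_isotherm(iso, self.protocol, "one_set")
        assert any("Wiseman" in w for w in fit.warnings)

    def test_too_few_injections_rejected(self):
        protocol = synth.default_protocol(n_injections=5)
        iso = injection_heats(ONE_SET, protocol)
        with pytest.raises(ValueError, match="too few"):
            fit_isotherm(iso, protocol, "two_sets")


class TestDerived:
    def test_dg_zero_at_unit_k(self):
        model = BindingModelOneSet(n=1.0, K=1.0, dH=-5.0)
        dG, TdS = thermodynamics_from_model(model, 298.15)
        assert dG[0] == 0.0
        assert TdS[0] == -5.0

    def test_dg_value_at_micromolar(self):
        model = BindingModelOneSet(n=1.0, K=1e6, dH=-10.0)
        dG, _ = thermodynamics_from_model(model, 298.15)
        expected = -1.987204259e-3 * 298.15 * math.log(1e6)
        assert dG[0] == pytest.approx(expected, rel=1e-12)
        assert dG[0] == pytest.approx(-8.19, abs=0.01)

    def test_identity_tds_plus_dg_is_dh(self):
        model = BindingModelTwoSets(
            n1=0.3, n2=0.7, K1=3e5, K2=9e7, dH1=-7.5, dH2=-11.2
        )
        dG, TdS = thermodynamics_from_model(model, 310.0)
        for (_, _, dH), g, ts in zip(model.sites, dG, TdS):
            assert ts + g == pytest.approx(dH, abs=1e-12)

    def test_nonpositive_k_rejected(self):
        model = BindingModelOneSet(n=1.0, K=0.0, dH=-5.0)
        with pytest.raises(ValueError):
            thermodynamics_from_model(model, 298.15)


class TestCooperativityIndex:
    def _fit(self, kd):
        return itc.ItcFitResult(
            model_kind="two_sets",
            params={},
            stderr={},
            kd=kd,
            dG=(),
            TdS=(),
            c_values=(),
            cooperativity_index=max(kd) / min(kd),
            rss=0.0,
            converged=True,
            n_obs=37,
        )

    def test_identical_sets_give_one(self):
        assert cooperativity_index(self._fit((1e-6, 1e-6))) == 1.0

    def test_hundredfold_ratio(self):
        assert cooperativity_index(self._fit((1e-6, 1e-8))) == pytest.approx(100.0)

    def test_invariant_to_set_labelling(self):
        a = cooperativity_index(self._fit((1e-6, 1e-8)))
        b = cooperativity_index(self._fit((1e-8, 1e-6)))
        assert a == b

    def test_one_set_fit_unsupported(self):
        fit = itc.ItcFitResult(
            model_kind="one_set", params={}, stderr={}, kd=(1e-6,),
            dG=(), TdS=(), c_values=(), cooperativity_index=None,
            rss=0.0, converged=True, n_obs=37,
        )
        with pytest.raises(ValueError, match="two-sets"):
            cooperativity_index(fit)


class TestProtocolValidation:
    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            TitrationProtocol(-1.0, 15e-6, 1e-4, [1e-6])

    def test_zero_injection_rejected(self):
        with pytest.raises(ValueError):
            TitrationProtocol(2e-4, 15e-6, 1e-4, [1e-6, 0.0])

    def test_perfusion_dilution_monotone(self):
        protocol = synth.default_protocol()
        Mt, Xt = protocol.cell_concentrations()
        assert np.all(np.diff(Mt) < 0)
        assert np.all(np.diff(Xt) > 0)
        assert Mt[0] < protocol.cell_concentration
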