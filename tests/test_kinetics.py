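"""Saturation-kinetics fitting, model selection and derived quantities."""

import numpy as np
import pandas as pd
import pytest

from metexpand import synth
from metexpand.kinetics import (
    EnzymeSpec,
    FitError,
    KineticModel,
    RateTable,
    activation_response,
    efficiency,
    fit_hill,
    fit_mm,
    fold_change,
    kcat,
    select_model,
)

# the full published parameter grid for the two pyruvate-kinase isoforms:
# (label, model, vmax U/mg, s50 mM, hill n)
PARAMETER_SETS = [
    ("Pyk1_ADP_noAMP", "MM", 21.0, 0.6, 1.0),
    ("Pyk2_ADP_noAMP", "MM", 1.2, 0.3, 1.0),
    ("Pyk1_ADP_AMP", "MM", 73.3, 0.2, 1.0),
    ("Pyk2_ADP_AMP", "MM", 6.7, 0.1, 1.0),
    ("Pyk1_PEP_noAMP", "Hill", 14.1, 3.5, 3.7),
    ("Pyk2_PEP_noAMP", "Hill", 0.5, 1.3, 1.5),
    ("Pyk1_PEP_AMP", "Hill", 65.5, 1.1, 1.8),
    ("Pyk2_PEP_AMP", "Hill", 9.1, 8.6, 7.1),
]


def _noiseless(model, vmax, s50, hill_n, lo=None, hi=None, n=10):
    lo = lo if lo is not None else s50 / 10
    hi = hi if hi is not None else s50 * 5
    grid = tuple(np.geomspace(lo, hi, n))
    return synth.gen_kinetic_data(
        synth.KineticSimSpec(
            model=model, vmax=vmax, s50=s50, hill_n=hill_n,
            substrate_grid=grid, noise_cv=0.0, replicates=3,
        )
    )


class TestExactRecovery:
    @pytest.mark.parametrize("label,model,vmax,s50,hill_n", PARAMETER_SETS)
    def test_noiseless_parameters_recovered_to_1e6(self, label, model, vmax, s50, hill_n):
        data = _noiseless(model, vmax, s50, hill_n)
        fit = fit_mm(data) if model == "MM" else fit_hill(data)
        assert fit.vmax == pytest.approx(vmax, rel=1e-6)
        assert fit.s50 == pytest.approx(s50, rel=1e-6)
        if model == "Hill":
            assert fit.hill_n == pytest.approx(hill_n, rel=1e-6)
        assert fit.converged

    def test_hill_fit_of_hyperbolic_data_matches_mm_fit(self):
        data = _noiseless("MM", 10.0, 0.5, 1.0)
        mm, hill = fit_mm(data), fit_hill(data)
        assert hill.vmax == pytest.approx(mm.vmax, rel=1e-6)
        assert hill.s50 == pytest.approx(mm.s50, rel=1e-6)
        assert hill.hill_n == pytest.approx(1.0, rel=1e-6)

    def test_all_zero_rates_flagged_as_failure(self):
        data = pd.DataFrame(
            {"substrate_mM": [0.1, 0.5, 1.0, 2.0], "rate_U_per_mg": [0.0] * 4}
        )
        with pytest.raises(FitError):
            fit_mm(data)


class TestFitInvariances:
    def test_row_order_invariance(self):
        data = synth.gen_kinetic_data(
            synth.KineticSimSpec(vmax=10, s50=0.5, noise_cv=0.05, seed=6)
        )
        f1 = fit_mm(data)
        f2 = fit_mm(data.sample(frac=1.0, random_state=0).reset_index(drop=True))
        assert f1.vmax == pytest.approx(f2.vmax, rel=1e-9)
        assert f1.s50 == pytest.approx(f2.s50, rel=1e-9)

    def test_rate_unit_rescaling_rescales_vmax_only(self):
        data = synth.gen_kinetic_data(
            synth.KineticSimSpec(vmax=10, s50=0.5, noise_cv=0.05, seed=7)
        )
        scaled = data.assign(rate_U_per_mg=data["rate_U_per_mg"] * 1000)
        f, fs = fit_mm(data), fit_mm(scaled)
        assert fs.vmax == pytest.approx(1000 * f.vmax, rel=1e-6)
        assert fs.s50 == pytest.approx(f.s50, rel=1e-6)

    def test_fitted_curve_monotone_in_substrate(self):
        data = _noiseless("Hill", 9.1, 8.6, 7.1)
        fit = fit_hill(data)
        s = np.linspace(0.01, 30, 200)
        assert np.all(np.diff(fit.predict(s)) >= 0)

    def test_recovery_error_shrinks_with_noise(self):
        errs = {}
        for cv in (0.02, 0.10):
            errors = []
            for seed in range(40):
                data = synth.gen_kinetic_data(
                    synth.KineticSimSpec(vmax=10, s50=0.5, noise_cv=cv, seed=seed)
                )
                errors.append(abs(fit_mm(data).vmax - 10) / 10)
            errs[cv] = np.mean(errors)
        assert errs[0.02] < errs[0.10]


class TestModelSelection:
    def test_cooperative_data_selects_hill(self):
        data = synth.gen_kinetic_data(
            synth.KineticSimSpec(
                model="Hill", vmax=14.1, s50=3.5, hill_n=3.7,
                substrate_grid=tuple(np.geomspace(0.5, 15, 10)),
                noise_cv=0.05, seed=1,
            )
        )
        selected, mm, hill = select_model(data)
        assert selected == "Hill"

    def test_hyperbolic_data_selects_mm_in_the_majority_of_replicate_studies(self):
        # the evidence margin keeps the simpler hyperbolic model most of the
        # time; occasional Hill selections on noisy draws are expected
        picks = []
        for seed in range(20):
            data = synth.gen_kinetic_data(
                synth.KineticSimSpec(
                    model="MM", vmax=10.0, s50=0.5,
                    substrate_grid=tuple(np.geomspace(0.05, 5, 10)),
                    noise_cv=0.05, seed=seed,
                )
            )
            picks.append(select_model(data)[0])
        assert picks.count("MM") >= 14

    def test_sparse_design_reported_low_confidence(self):
        data = synth.gen_kinetic_data(
            synth.KineticSimSpec(
                vmax=10.0, s50=0.5, substrate_grid=(0.1, 0.3, 1.0, 3.0),
                noise_cv=0.0,
            )
        )
        fit = fit_mm(data)
        assert fit.low_confidence

    def test_auto_model_wraps_selection(self):
        data = _noiseless("Hill", 9.1, 8.6, 7.1)
        fit = KineticModel(data, kind="auto").fit()
        assert fit.model == "Hill"
        assert "Hill" in fit.summary()


class TestDerivedQuantities:
    def test_kcat_unit_conversion(self):
        spec = EnzymeSpec("pyk1", subunit_mass_da=50_000.0)
        assert kcat(73.3, spec) == pytest.approx(61.0833, abs=1e-3)
        assert kcat(0.0, spec) == 0.0

    def test_published_kcat_ratio_exceeds_twentyfold(self):
        assert 4703 / 215 == pytest.approx(21.9, abs=0.05)
        assert 4703 / 215 >= 20

    def test_invalid_enzyme_mass_rejected(self):
        with pytest.raises(ValueError):
            EnzymeSpec("bad", subunit_mass_da=-1.0)

    def test_efficiency_ratio_and_linearity(self):
        assert efficiency(100.0, 2.0) == 50.0
        assert efficiency(200.0, 2.0) == 2 * efficiency(100.0, 2.0)
        with pytest.raises(ValueError):
            efficiency(100.0, 0.0)

    def test_amp_fold_changes_match_published_ratios(self):
        with_amp = _fit_like(vmax=73.3, s50=0.2)
        without = _fit_like(vmax=21.0, s50=0.6)
        assert round(fold_change(with_amp, without, "vmax"), 1) == 3.5
        assert round(fold_change(without, with_amp, "s50"), 1) == 3.0
        assert fold_change(with_amp, with_amp, "vmax") == 1.0


def _fit_like(vmax, s50):
    data = _noiseless("MM", vmax, s50, 1.0)
    return fit_mm(data)


class TestActivationResponse:
    def test_noiseless_activator_recovery(self):
        data = synth.gen_kinetic_data(
            synth.KineticSimSpec(
                model="MM", vmax=8.2, s50=0.01,
                substrate_grid=tuple(np.geomspace(0.001, 1.0, 8)),
                noise_cv=0.0,
            )
        )
        fit = activation_response(data)
        assert fit.vmax == pytest.approx(8.2, rel=1e-6)
        assert fit.s50 == pytest.approx(0.01, rel=1e-6)

    def test_baseline_subtraction_leaves_monotone_response(self):
        grid = (0.0, 0.001, 0.01, 0.05, 0.1, 0.5, 1.0)
        base = synth.gen_kinetic_data(
            synth.KineticSimSpec(
                model="MM", vmax=8.2, s50=0.01, substrate_grid=grid, noise_cv=0.0,
            )
        )
        base["rate_U_per_mg"] += 0.5  # constant unactivated rate
        fit = activation_response(base)
        amp = np.linspace(1e-4, 1.0, 100)
        assert np.all(np.diff(fit.predict(amp)) >= 0)

    def test_stochastic_recovery_of_activator_s50(self):
        # abbreviated version of the 200-seed recovery study
        vals = []
        for seed in range(30):
            data = synth.gen_kinetic_data(
                synth.KineticSimSpec(
                    model="MM", vmax=8.2, s50=0.01,
                    substrate_grid=tuple(np.geomspace(0.001, 1.0, 8)),
                    noise_cv=0.05, seed=seed,
                )
            )
            vals.append(activation_response(data).s50)
        assert np.median(vals) == pytest.approx(0.01, rel=0.10)


class TestRateTableValidation:
    def test_requires_four_substrate_levels(self):
        with pytest.raises(ValueError, match="distinct substrate"):
            RateTable(pd.DataFrame({"substrate_mM": [1, 1, 2], "rate_U_per_mg": [1, 1, 2]}))

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            RateTable(
                pd.DataFrame(
                    {"substrate_mM": [1, 2, 3, 4], "rate_U_per_mg": [1, -1, 2, 3]}
                )
            )
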