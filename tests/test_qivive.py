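"""Reverse dosimetry: binding correction, dose inversion, curve translation."""

import dataclasses

import numpy as np
import pytest

from mbaptox import ExposureEvent, build_model, simulate
from mbaptox.errors import DomainError, UnattainableTargetError
from mbaptox.mest import InhibitionFit
from mbaptox.qivive import (
    BindingContext,
    dose_for_cmax,
    fold_deviation,
    predict_dose_response,
    vitro_to_vivo_concentration,
)


def canonical_fit(ic50=1.40):
    return InhibitionFit(top=100.0, bottom=0.0, IC50=ic50, slope=1.0,
                         rss=0.0, converged=True)


class TestBindingCorrection:
    def test_default_context_halves_concentration(self, bundle):
        ctx = BindingContext.from_bundle(bundle)
        assert ctx.fub_in_vivo == 0.004
        assert ctx.fub_in_vitro == pytest.approx(0.002)
        assert vitro_to_vivo_concentration(1.40, ctx) == pytest.approx(0.70)

    def test_equal_fub_is_identity(self):
        ctx = BindingContext(fub_in_vivo=0.004, fub_in_vitro=0.004)
        assert vitro_to_vivo_concentration(3.3, ctx) == pytest.approx(3.3)

    def test_zero_maps_to_zero(self, bundle):
        assert vitro_to_vivo_concentration(
            0.0, BindingContext.from_bundle(bundle)) == 0.0

    def test_fub_scaling_laws(self):
        base = vitro_to_vivo_concentration(
            1.0, BindingContext(fub_in_vivo=0.004, fub_in_vitro=0.002))
        doubled_vitro = vitro_to_vivo_concentration(
            1.0, BindingContext(fub_in_vivo=0.004, fub_in_vitro=0.004))
        doubled_vivo = vitro_to_vivo_concentration(
            1.0, BindingContext(fub_in_vivo=0.008, fub_in_vitro=0.002))
        assert doubled_vitro == pytest.approx(2 * base)
        assert doubled_vivo == pytest.approx(base / 2)

    def test_invalid_fub_rejected(self):
        with pytest.raises(DomainError):
            BindingContext(fub_in_vivo=0.0)


class TestFoldDeviation:
    def test_symmetric_examples(self):
        assert fold_deviation(2.0, 1.0) == pytest.approx(2.0)
        assert fold_deviation(1.0, 2.0) == pytest.approx(2.0)
        assert fold_deviation(1.0, 1.0) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            fold_deviation(0.0, 1.0)


class TestDoseInversion:
    def test_zero_target_is_zero_dose(self, model):
        assert dose_for_cmax(model, "oral", 0.0) == 0.0

    @pytest.mark.parametrize("route,dose", [
        ("oral", 0.1), ("oral", 10.0), ("intravenous", 1.0),
        ("intratracheal", 1.0),
    ])
    def test_forward_inverse_round_trip(self, model, route, dose):
        target = simulate(model, ExposureEvent(route, dose), t_end=24.0,
                          rtol=1e-6, atol=1e-9).summary("metabolite")[0]
        recovered = dose_for_cmax(model, route, target, rel_tol=1e-3)
        assert recovered == pytest.approx(dose, rel=0.005)

    def test_larger_target_needs_larger_dose(self, model):
        d1 = dose_for_cmax(model, "oral", 0.1)
        d2 = dose_for_cmax(model, "oral", 0.3)
        assert d2 > d1

    def test_unattainable_target_raises(self, model):
        with pytest.raises(UnattainableTargetError):
            dose_for_cmax(model, "oral", 1e6, bracket=(1e-4, 50.0))


class TestDoseResponseTranslation:
    def test_linear_kinetics_limit_is_rigid_shift(self, bundle):
        """With all Km scaled far above attained concentrations (Vmax/Km
        held fixed) the PBK map is linear, so the translated curve is the
        in vitro curve rigidly shifted on the log-dose axis and the ED50
        equals the dose mapped from the IC50."""
        big = 1e6
        rx = tuple(
            dataclasses.replace(r, Vmax_in_vitro=r.Vmax_in_vitro * big,
                                Km=r.Km * big)
            for r in bundle.reactions
        )
        linear = dataclasses.replace(bundle, reactions=rx)
        model = build_model(linear)
        fit = canonical_fit(ic50=1.40)
        pred = predict_dose_response(fit, model, route="oral", n_points=12,
                                     conc_span=(0.05, 20.0))
        ctx = BindingContext.from_bundle(bundle)
        d_ic50 = dose_for_cmax(model, "oral",
                               vitro_to_vivo_concentration(fit.IC50, ctx))
        assert pred.ED50 == pytest.approx(d_ic50, rel=0.01)
        # rigid shift: dose proportional to in vitro concentration
        ratios = pred.doses / pred.in_vitro_conc
        assert ratios.std() / ratios.mean() < 0.01

    def test_translated_effect_starts_at_zero(self, model):
        pred = predict_dose_response(canonical_fit(), model, route="oral",
                                     n_points=10, conc_span=(0.05, 5.0))
        assert pred.effect.min() < 10.0
        assert pred.effect.max() > 70.0
        # constrained fit passes through 0 at zero dose by construction
        assert pred.ED50 > 0
        assert pred.slope == 1.0

    def test_ed50_stable_under_regridding(self, model):
        a = predict_dose_response(canonical_fit(), model, route="oral",
                                  n_points=14, conc_span=(0.05, 10.0))
        b = predict_dose_response(canonical_fit(), model, route="oral",
                                  n_points=24, conc_span=(0.05, 10.0))
        assert b.ED50 == pytest.approx(a.ED50, rel=0.005)
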