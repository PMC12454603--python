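"""Synthetic-data generators: determinism, noiseless limits, recovery."""

import numpy as np
import pandas as pd
import pytest

from mbaptox import ExposureEvent
from mbaptox.invitro import VelocityDataset, fit_michaelis_menten
from mbaptox.mest import differentiation_percent, fit_inhibition
from mbaptox.qivive import fold_deviation, predict_dose_response
from mbaptox.synthetic import (
    BLOOD_SAMPLING_SCHEDULE_H,
    gen_blood_timecourse,
    gen_mest_plate,
    gen_mm_velocities,
)

GRID = np.array([1.0, 2.0, 5.0, 10.0, 25.0, 50.0, 100.0])


class TestDeterminism:
    def test_mm_generator_reproducible(self):
        a = gen_mm_velocities(6.92, 15.58, GRID, cv=0.1, seed=11)
        b = gen_mm_velocities(6.92, 15.58, GRID, cv=0.1, seed=11)
        for da, db in zip(a, b):
            assert np.array_equal(da.velocity, db.velocity)

    def test_mest_generator_reproducible(self):
        c = np.geomspace(0.1, 10, 8)
        a = gen_mest_plate(1.40, 0.95, c, seed=5)
        b = gen_mest_plate(1.40, 0.95, c, seed=5)
        assert np.array_equal(a.beating, b.beating)
        assert a.solvent_control == b.solvent_control

    def test_blood_generator_reproducible(self, bundle):
        kw = dict(exposure=ExposureEvent("intravenous", 50.0), sdlog=0.3,
                  seed=7)
        a = gen_blood_timecourse(bundle, **kw)
        b = gen_blood_timecourse(bundle, **kw)
        pd.testing.assert_frame_equal(a, b)


class TestNoiselessLimits:
    def test_zero_cv_gives_exact_curve(self):
        data = gen_mm_velocities(6.92, 15.58, GRID, cv=0.0, n_replicates=1,
                                 seed=0)[0]
        assert np.allclose(data.velocity, 6.92 * GRID / (15.58 + GRID))

    def test_zero_sdlog_equals_model_prediction(self, bundle, model):
        from mbaptox.pbk import simulate

        df = gen_blood_timecourse(bundle, ExposureEvent("intravenous", 50.0),
                                  sdlog=0.0, n_animals=2, seed=0)
        res = simulate(model, ExposureEvent("intravenous", 50.0), t_end=72.0)
        t = np.asarray(BLOOD_SAMPLING_SCHEDULE_H)
        truth = res.sol(t)[model.i_p["venous_blood"]] / model.volumes["venous_blood"]
        obs = df[(df.species == "parent") & (df.animal == 0)]
        assert np.allclose(obs["concentration_uM"].to_numpy(), truth,
                           rtol=1e-9)

    def test_saturating_concentration_kills_beating(self):
        plate = gen_mest_plate(1.40, 0.95, [1e9], seed=2)
        assert plate.beating[0] == 0


class TestRecovery:
    def test_mm_fit_recovers_truth_within_10pct(self):
        data = gen_mm_velocities(6.92, 15.58, GRID, cv=0.1, n_replicates=3,
                                 seed=1)
        S = np.concatenate([d.substrate_conc for d in data])
        v = np.concatenate([d.velocity for d in data])
        fit = fit_michaelis_menten(VelocityDataset(S, v))
        assert fit.Vmax == pytest.approx(6.92, rel=0.10)
        assert fit.Km == pytest.approx(15.58, rel=0.10)

    def test_solvent_control_near_expectation(self):
        counts = [gen_mest_plate(1.4, 0.95, [1.0], seed=s).solvent_control[0]
                  for s in range(200)]
        assert np.mean(counts) == pytest.approx(0.95 * 24, rel=0.03)

    def test_blood_observations_within_twofold_of_prediction(self, bundle):
        """Per-time means over 3 animals at sdlog 0.3 stay mostly within the
        2-fold adequacy band around the model prediction."""
        df = gen_blood_timecourse(bundle, ExposureEvent("intravenous", 50.0),
                                  sdlog=0.3, seed=7)
        noiseless = gen_blood_timecourse(
            bundle, ExposureEvent("intravenous", 50.0), sdlog=0.0,
            n_animals=1, seed=0)
        folds = []
        for species in ("parent", "metabolite"):
            obs = (df[df.species == species]
                   .groupby("time_h")["concentration_uM"].mean())
            pred = (noiseless[noiseless.species == species]
                    .set_index("time_h")["concentration_uM"])
            for t in obs.index:
                if pred[t] > 0 and obs[t] > 0:
                    folds.append(fold_deviation(pred[t], obs[t]))
        assert np.median(folds) <= 2.0


class TestEndToEnd:
    def test_plate_to_ed50_recovers_truth_curve_ed50(self, model):
        """Synthetic mEST plates -> inhibition fit -> reverse dosimetry.

        At study scale (24 EBs per concentration, 3 replicate plates) the
        binomial readout alone carries ~20% median IC50 error, so the
        end-to-end ED50 deviation from the noiseless truth-curve ED50 is
        assessed as a median over replicate batches and required to stay
        within 25%.
        """
        truth = 1.40
        conc = np.geomspace(0.1, 10.0, 8)
        truth_fit = fit_inhibition(conc, 100.0 / (1.0 + conc / truth))
        kw = dict(route="oral", n_points=10, conc_span=(0.05, 10.0))
        ed50_truth = predict_dose_response(truth_fit, model, **kw).ED50

        deviations = []
        for batch in range(9):
            plates = [gen_mest_plate(truth, 0.95, conc, seed=batch * 3 + k)
                      for k in range(3)]
            c = np.concatenate([p.concentration for p in plates])
            resp = np.concatenate([differentiation_percent(p) for p in plates])
            noisy_fit = fit_inhibition(c, resp)
            ed50 = predict_dose_response(noisy_fit, model, **kw).ED50
            deviations.append(abs(ed50 / ed50_truth - 1.0))
        assert np.median(deviations) <= 0.25
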