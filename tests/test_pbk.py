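"""PBK model structure, conservation, and kinetic summary extraction."""

import dataclasses

import numpy as np
import pytest

from mbaptox import (
    ExposureEvent,
    build_model,
    extract_summary,
    mass_balance,
    simulate,
)
from mbaptox.errors import DomainError, LookupKeyError

from conftest import ROUTES


class TestStructure:
    def test_seven_intestinal_lumen_states(self, model):
        assert len(model.i_lumen) == 7
        assert sum(n.startswith("parent:lumen") for n in model.state_names) == 7

    def test_transport_matrix_is_conservative(self, model):
        # every column of the linear part sums to zero: nothing leaves the ledger
        assert np.abs(model.L.sum(axis=0)).max() < 1e-9 * np.abs(model.L).max()

    def test_unknown_route_rejected(self):
        with pytest.raises(DomainError):
            ExposureEvent("dermal", 1.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(DomainError):
            ExposureEvent("oral", -1.0)

    def test_sulfation_removal_keeps_metabolite_balance(self, bundle):
        pruned = dataclasses.replace(
            bundle,
            reactions=tuple(r for r in bundle.reactions if r.key != "sulfation"),
        )
        res = simulate(build_model(pruned), ExposureEvent("oral", 10.0),
                       t_end=24.0, rtol=1e-8, atol=1e-10)
        assert mass_balance(res) < 1e-6


class TestZeroDose:
    def test_zero_dose_is_identically_zero(self, model):
        res = simulate(model, ExposureEvent("oral", 0.0), t_end=24.0)
        assert np.all(res.states == 0.0)
        assert extract_summary(res, "parent", "blood") == (0.0, 0.0, 0.0)
        assert mass_balance(res) == 0.0


class TestConservation:
    @pytest.mark.parametrize("route", ROUTES)
    def test_mass_balance_closes(self, results_10mgkg, route):
        assert mass_balance(results_10mgkg[route]) <= 1e-6

    @pytest.mark.parametrize("route", ROUTES)
    def test_non_negativity(self, results_10mgkg, route):
        assert results_10mgkg[route].states.min() >= -1e-8

    def test_conservation_is_structural(self, model):
        """The ledger closes even at loose tolerances: conservation holds
        by construction of the transport matrix, not by solver accuracy."""
        loose = simulate(model, ExposureEvent("oral", 10.0), t_end=72.0,
                         rtol=1e-2, atol=1e-4)
        assert mass_balance(loose) <= 1e-6

    def test_solution_accuracy_monotone_in_tolerance(self, model,
                                                     results_10mgkg):
        """Loosening rtol degrades the summary kinetics monotonically."""
        ref = results_10mgkg["oral"].summary("metabolite", "blood")[0]
        errs = []
        for rtol in (1e-2, 1e-5):
            res = simulate(model, ExposureEvent("oral", 10.0), t_end=72.0,
                           rtol=rtol, atol=rtol * 1e-2)
            errs.append(abs(res.summary("metabolite", "blood")[0] - ref))
        assert errs[0] > errs[1]


class TestDoseScaling:
    def test_low_dose_linearity(self, model):
        """At doses far below saturation, Cmax scales linearly with dose."""
        cmax = {}
        for d in (1e-5, 1e-4):
            res = simulate(model, ExposureEvent("oral", d), t_end=24.0,
                           rtol=1e-9, atol=1e-18)
            cmax[d] = {
                sp: res.summary(sp, "blood")[0] for sp in ("parent", "metabolite")
            }
        for sp in ("parent", "metabolite"):
            ratio = cmax[1e-4][sp] / cmax[1e-5][sp]
            assert ratio == pytest.approx(10.0, rel=0.005)

    @pytest.mark.parametrize("route", ROUTES)
    def test_cmax_monotone_in_dose(self, model, route):
        doses = (0.1, 1.0, 10.0, 50.0)
        for sp in ("parent", "metabolite"):
            vals = []
            for d in doses:
                res = simulate(model, ExposureEvent(route, d), t_end=48.0,
                               rtol=1e-6, atol=1e-9)
                vals.append(res.summary(sp, "blood")[0])
            assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestRouteKinetics:
    def test_parent_route_ordering(self, results_10mgkg):
        """IV bolus peaks above lung absorption, which peaks above oral
        (first-pass extraction)."""
        cmax = {
            r: results_10mgkg[r].summary("parent", "blood")[0] for r in ROUTES
        }
        assert cmax["intravenous"] > cmax["intratracheal"] > cmax["oral"]

    def test_iv_fast_transfer_limit(self, bundle, results_10mgkg):
        """Kd = 1e6/h is indistinguishable from placing the dose directly
        in venous blood."""
        model = build_model(bundle)
        exposure = ExposureEvent("intravenous", 10.0)
        y0 = np.zeros(model.n_states)
        y0[model.i_p["venous_blood"]] = model.initial_state(exposure).sum()
        from scipy.integrate import solve_ivp

        res = solve_ivp(model.rhs, (0.0, 1.0), y0, method="BDF",
                        jac=model.jac, rtol=1e-8, atol=1e-10,
                        dense_output=True)
        t = np.geomspace(1e-9, 1.0, 2000)
        direct = (res.sol(t)[model.i_p["venous_blood"]]
                  / model.volumes["venous_blood"]).max()
        via_needle = results_10mgkg["intravenous"].summary("parent", "blood")[0]
        assert via_needle == pytest.approx(direct, rel=0.01)

    def test_metabolite_free_fraction_contract(self, results_10mgkg, bundle):
        res = results_10mgkg["oral"]
        total = res.concentration("metabolite", "blood")
        free = res.free_blood_concentration("metabolite")
        mask = total > 1e-9
        assert np.allclose(free[mask] / total[mask],
                           bundle.metabolite.fub_in_vivo)


class TestSummary:
    def test_unknown_species_raises(self, results_10mgkg):
        with pytest.raises(LookupKeyError):
            extract_summary(results_10mgkg["oral"], "conjugate", "blood")

    def test_unknown_compartment_raises(self, results_10mgkg):
        with pytest.raises(LookupKeyError):
            extract_summary(results_10mgkg["oral"], "parent", "brain")

    def test_auc_positive_and_tmax_within_horizon(self, results_10mgkg):
        cmax, tmax, auc = results_10mgkg["oral"].summary("metabolite", "blood")
        assert cmax > 0 and auc > 0
        assert 0 < tmax < 72.0

    def test_export_frame_layout(self, results_10mgkg):
        df = results_10mgkg["oral"].to_frame()
        assert list(df.columns) == [
            "time_h", "species", "compartment", "concentration_uM",
            "amount_umol",
        ]
        assert set(df["species"]) == {"parent", "metabolite"}
        assert (df["concentration_uM"] >= -1e-9).all()
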