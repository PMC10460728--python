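"""PBPK engine physics: closed-form limits, mass balance, turnover,
convergence, monotonicity."""
import math

import numpy as np
import pytest

from enzapbpk.engine import (
    induction_multiplier,
    inhibited_activity,
    pk_metrics,
    simulate,
)
from enzapbpk.models import (
    CompoundModel,
    InteractionSwitches,
    MetaboliteLink,
    ModelSpec,
    Regimen,
    SystemModel,
)


def probe_compound(**overrides) -> CompoundModel:
    base = dict(
        name="probe",
        mw_g_mol=400.0,
        fu=0.1,
        fu_gut=1.0,
        vss_L_kg=0.5,
        ka_per_h=1.5,
        fa=1.0,
        clint_hlm_additional_ul_min_mg=3.0,
        central_fraction_of_vss=1.0,
    )
    base.update(overrides)
    return CompoundModel(**base)


class TestLocalMechanisms:
    def test_induction_multiplier_limits(self):
        assert induction_multiplier(0.0, 11.43, 1.5) == 1.0
        assert induction_multiplier(1.5, 11.43, 1.5) == pytest.approx(
            1.0 + (11.43 - 1.0) / 2.0
        )
        assert induction_multiplier(1e9, 11.43, 1.5) == pytest.approx(11.43, rel=1e-6)
        with pytest.raises(ValueError):
            induction_multiplier(-0.1, 11.43, 1.5)

    def test_inhibited_activity(self):
        assert inhibited_activity(10.0, 0.0, 1.67) == 10.0
        assert inhibited_activity(10.0, 1.67, 1.67) == pytest.approx(5.0)
        values = [inhibited_activity(10.0, cu, 1.67) for cu in (0.1, 1, 10, 100)]
        assert values == sorted(values, reverse=True)


class TestClosedForms:
    def test_single_dose_auc_matches_analytic(self):
        """With constant clearances the oral AUC is F*Dose/CL exactly."""
        system = SystemModel(lumen_transit_per_h=0.0)
        compound = probe_compound()
        spec = ModelSpec(
            system=system, compounds=[compound], switches=InteractionSwitches.all_off()
        )
        res = simulate(spec, [Regimen(compound="probe", dose_mg=10)], duration_h=800)
        metrics = pk_metrics(res, "probe", (0, 800))
        clint = 3.0 * system.microsomal_protein_mg() * 60 / 1e6  # L/h
        fu_b = compound.fu / compound.bp_ratio
        q_h = system.hepatic_blood_flow_L_h
        f_h = q_h / (q_h + fu_b * clint)
        cl_b = q_h * fu_b * clint / (q_h + fu_b * clint)
        dose_umol = 10 * 1000 / compound.mw_g_mol
        auc_pred = f_h * dose_umol / (cl_b * compound.bp_ratio)
        assert metrics["auc"] == pytest.approx(auc_pred, rel=1e-3)

    def test_dose_linearity_without_interactions(self):
        spec = ModelSpec(compounds=[probe_compound()], switches=InteractionSwitches.all_off())
        low = simulate(spec, [Regimen(compound="probe", dose_mg=10)], duration_h=200)
        high = simulate(spec, [Regimen(compound="probe", dose_mg=20)], duration_h=200)
        m_lo = pk_metrics(low, "probe", (0, 200))
        m_hi = pk_metrics(high, "probe", (0, 200))
        assert m_hi["auc"] == pytest.approx(2 * m_lo["auc"], rel=1e-6)
        assert m_hi["cmax"] == pytest.approx(2 * m_lo["cmax"], rel=1e-6)

    def test_constant_concentration_auc(self):
        """A non-eliminated bolus settles to a constant level: AUC over a
        late window is level x width."""
        inert = probe_compound(clint_hlm_additional_ul_min_mg=0.0, ka_per_h=50.0)
        system = SystemModel(lumen_transit_per_h=0.0)
        spec = ModelSpec(system=system, compounds=[inert], switches=InteractionSwitches.all_off())
        res = simulate(spec, [Regimen(compound="probe", dose_mg=40)], duration_h=30)
        level = 40 * 1000 / 400.0 / (0.5 * 70.0)
        metrics = pk_metrics(res, "probe", (10, 30))
        assert metrics["auc"] == pytest.approx(level * 20.0, rel=1e-6)
        assert metrics["cmin"] == pytest.approx(level, rel=1e-6)

    def test_pk_metrics_window_validation(self):
        spec = ModelSpec(compounds=[probe_compound()], switches=InteractionSwitches.all_off())
        res = simulate(spec, [Regimen(compound="probe", dose_mg=10)], duration_h=24)
        with pytest.raises(ValueError, match="empty"):
            pk_metrics(res, "probe", (5, 5))
        with pytest.raises(ValueError, match="outside"):
            pk_metrics(res, "probe", (0, 100))


def constant_inducer(ind_max=5.0, indc50=None, cl_r=0.0) -> CompoundModel:
    """A non-eliminated compound whose post-absorption unbound level is
    exactly IndC50 (for a 40 mg dose), giving multiplier 1+(Indmax-1)/2."""
    level = 40 * 1000 / 400.0 / 70.0  # fu = 1, Vss 1 L/kg
    return CompoundModel(
        name="inducer",
        mw_g_mol=400.0,
        fu=1.0,
        fu_gut=1.0,
        vss_L_kg=1.0,
        ka_per_h=50.0,
        fa=1.0,
        cl_r_L_h=cl_r,
        indmax_calibrated=ind_max,
        indc50_umol_L=indc50 if indc50 is not None else level,
        central_fraction_of_vss=1.0,
    )


class TestEnzymeTurnover:
    def test_pool_follows_first_order_approach(self):
        """At constant unbound inducer concentration Cu = IndC50 the liver
        pool approaches 1+(Indmax-1)/2 with half-life ln2/kdeg."""
        system = SystemModel(lumen_transit_per_h=0.0)
        spec = ModelSpec(system=system, compounds=[constant_inducer()])
        kdeg = system.kdeg_per_h["CYP3A4"]["liver"]
        res = simulate(
            spec, [Regimen(compound="inducer", dose_mg=40)], duration_h=200
        )
        m_target = 1.0 + (5.0 - 1.0) / 2.0
        t_half = math.log(2) / kdeg
        pool = np.interp(t_half, res.time_h, res.enzyme_pool("liver"))
        assert pool == pytest.approx(1.0 + (m_target - 1.0) / 2.0, rel=0.005)
        pool_end = np.interp(200.0, res.time_h, res.enzyme_pool("liver"))
        expected = m_target - (m_target - 1.0) * math.exp(-kdeg * 200.0)
        assert pool_end == pytest.approx(expected, rel=0.005)

    def test_pools_return_to_baseline_after_washout(self):
        """Once the inducer is eliminated, pools relax to 1 within 0.1%."""
        system = SystemModel(lumen_transit_per_h=0.0)
        spec = ModelSpec(system=system, compounds=[constant_inducer(cl_r=70.0)])
        res = simulate(
            spec, [Regimen(compound="inducer", dose_mg=40)], duration_h=450
        )
        assert res.enzyme_pool("liver")[-1] == pytest.approx(1.0, abs=1e-3)
        assert res.enzyme_pool("gut")[-1] == pytest.approx(1.0, abs=1e-3)
        assert res.concentration("inducer")[-1] < 1e-12


class TestMassBalanceAndConvergence:
    def test_mass_balance_full_interaction_system(self, enzalutamide, m2, digoxin):
        spec = ModelSpec(
            compounds=[enzalutamide, m2, digoxin],
            metabolite_links=[MetaboliteLink(parent="enzalutamide", metabolite="M2")],
        )
        regs = [
            Regimen(compound="enzalutamide", dose_mg=160, interval_h=24, n_doses=10),
            Regimen(compound="digoxin", dose_mg=0.25, start_h=216),
        ]
        res = simulate(spec, regs, duration_h=264)
        for name in ("enzalutamide", "M2", "digoxin"):
            assert res.mass_balance_error(name) < 1e-6

    def test_tolerance_refinement_convergence(self, enzalutamide, m2):
        spec = ModelSpec(
            compounds=[enzalutamide, m2],
            metabolite_links=[MetaboliteLink(parent="enzalutamide", metabolite="M2")],
        )
        regs = [Regimen(compound="enzalutamide", dose_mg=160, interval_h=24, n_doses=10)]
        coarse = simulate(spec, regs, duration_h=240, rtol=1e-8, atol=1e-10)
        fine = simulate(spec, regs, duration_h=240, rtol=1e-9, atol=1e-11)
        auc_c = pk_metrics(coarse, "enzalutamide", (216, 240))["auc"]
        auc_f = pk_metrics(fine, "enzalutamide", (216, 240))["auc"]
        assert auc_c == pytest.approx(auc_f, rel=1e-4)

    def test_single_dose_profile_peaks_one_to_two_hours(self, enzalutamide, m2):
        spec = ModelSpec(
            compounds=[enzalutamide, m2],
            metabolite_links=[MetaboliteLink(parent="enzalutamide", metabolite="M2")],
        )
        res = simulate(
            spec, [Regimen(compound="enzalutamide", dose_mg=160)], duration_h=48
        )
        tmax = pk_metrics(res, "enzalutamide", (0, 48))["tmax"]
        assert 1.0 <= tmax <= 2.0


class TestInteractionMonotonicity:
    def _combo_auc(self, perpetrator, m2, victim, victim_dose, loading_days=8):
        start = loading_days * 24.0
        spec = ModelSpec(
            compounds=[perpetrator, m2, victim],
            metabolite_links=[MetaboliteLink(parent="enzalutamide", metabolite="M2")],
        )
        regs = [
            Regimen(
                compound="enzalutamide",
                dose_mg=160,
                interval_h=24,
                n_doses=loading_days + 2,
            ),
            Regimen(compound=victim.name, dose_mg=victim_dose, start_h=start),
        ]
        res = simulate(spec, regs, duration_h=start + 48)
        return pk_metrics(res, victim.name, (start, start + 48))["auc"]

    def test_victim_auc_decreases_with_ind_max(self, enzalutamide, m2):
        from enzapbpk import datasets

        midazolam = datasets.load_packaged_compound("midazolam")
        aucs = [
            self._combo_auc(
                enzalutamide.model_copy(update={"indmax_calibrated": ind_max}),
                m2,
                midazolam,
                2.0,
            )
            for ind_max in (4.0, 11.43, 25.0)
        ]
        assert aucs[0] > aucs[1] > aucs[2]

    def test_victim_auc_rises_with_pgp_inhibitory_potency(self, enzalutamide, m2, digoxin):
        """Exposure of a P-gp substrate rises as the perpetrator's K_i
        falls (stronger inhibition)."""
        aucs = [
            self._combo_auc(
                enzalutamide.model_copy(update={"ki_pgp_umol_L": ki}),
                m2.model_copy(update={"ki_pgp_umol_L": ki}),
                digoxin,
                0.25,
                loading_days=4,
            )
            for ki in (0.2, 1.67, 20.0)
        ]
        assert aucs[0] > aucs[1] > aucs[2]
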