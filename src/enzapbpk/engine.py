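"""Dynamic perpetrator-victim PBPK engine.

Model structure, per compound:

* oral depot (gut lumen) emptying first-order (ka) into a single well-mixed
  enterocyte compartment, with a parallel luminal transit loss;
* enterocyte: CYP3A metabolism (scaled by the gut CYP3A4 pool and
  competitive inhibition) and P-gp secretion back to the lumen (scaled by
  RAF/REF x the static fold-increase FI x competitive inhibition), in
  competition with villous-blood uptake to the portal vein;
* hepatic elimination by the well-stirred model, applied both as first-pass
  extraction of the portal inflow and as systemic blood clearance, with
  per-enzyme intrinsic clearances scaled by the liver CYP3A4 pool and
  inhibition; the fraction of hepatic flux tagged "metabolite" enters the
  linked metabolite's central compartment mole-for-mole;
* lumped distribution: one central and one peripheral compartment
  parameterized from Vss;
* renal clearance, optionally with an OAT3-inhibitable secretory fraction.

CYP3A4 amounts follow turnover kinetics d(E/E0)/dt = kdeg*(m - E/E0) where
the synthesis multiplier m is driven by unbound perpetrator concentrations
(hepatic inlet for the liver pool, enterocyte for the gut pool).

Concentrations are µmol/L, amounts µmol, times h, clearances and flows L/h.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .models import InteractionSwitches, ModelSpec, Regimen

__all__ = [
    "induction_multiplier",
    "inhibited_activity",
    "simulate",
    "pk_metrics",
    "EnzymePool",
    "SimulationResult",
    "SimulationError",
]

_UL_MIN_TO_L_H = 60.0 / 1e6
_N_STATES = 10  # per-compound state block, see _Compiled
(_LUMEN, _ENT, _CENTRAL, _PERIPH, _CUM_TRANSIT, _CUM_GUTMET, _CUM_HEP_OTHER,
 _CUM_HEP_MET, _CUM_RENAL, _CUM_FORMED) = range(_N_STATES)


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last state for diagnosis."""

    def __init__(self, message: str, state: Optional[np.ndarray] = None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class EnzymePool:
    enzyme: str
    site: str  # "liver" | "gut"
    relative_amount: float
    kdeg_per_h: float


def induction_multiplier(cu_umol_L: float, indmax: float, indc50: float) -> float:
    """Enzyme synthesis multiplier 1 + (Indmax - 1) * Cu / (IndC50 + Cu)."""
    if cu_umol_L < 0:
        raise ValueError("unbound concentration must be >= 0")
    return 1.0 + (indmax - 1.0) * cu_umol_L / (indc50 + cu_umol_L)


def inhibited_activity(base_activity: float, cu_umol_L: float, ki: float) -> float:
    """Competitive inhibition: base / (1 + Cu / Ki)."""
    if ki <= 0:
        raise ValueError("ki must be > 0")
    return base_activity / (1.0 + cu_umol_L / ki)


class _Compiled:
    """Parameter arrays precomputed from a ModelSpec for the RHS."""

    def __init__(self, spec: ModelSpec):
        sys_ = spec.system
        n = len(spec.compounds)
        self.names = [c.name for c in spec.compounds]
        self.n = n
        self.q_h = sys_.hepatic_blood_flow_L_h
        self.q_villi = sys_.villous_blood_flow_L_h
        self.v_ent = sys_.enterocyte_volume_L
        self.k_transit = sys_.lumen_transit_per_h
        kdeg = sys_.kdeg_per_h.get("CYP3A4", {})
        self.kdeg_liver = kdeg.get("liver", 0.0193)
        self.kdeg_gut = kdeg.get("gut", 0.029)
        sw = spec.switches
        self.induction_on = sw.cyp3a_induction
        self.inhibition_on = sw.cyp3a_inhibition
        self.pgp_inhibition_on = sw.pgp_inhibition
        self.fi_pgp = sw.pgp_fold_increase
        self.oat3_on = sw.oat3_inhibition

        def arr(fn):
            return np.array([fn(c) for c in spec.compounds], dtype=float)

        self.mw = arr(lambda c: c.mw_g_mol)
        self.ka = arr(lambda c: c.ka_per_h)
        self.fa = arr(lambda c: c.fa)
        self.fu = arr(lambda c: c.fu)
        self.fu_gut = arr(lambda c: c.fu_gut)
        self.bp = arr(lambda c: c.bp_ratio)
        vss_L = arr(lambda c: c.vss_L_kg) * sys_.body_weight_kg
        cf = arr(lambda c: c.central_fraction_of_vss)
        self.v_c = cf * vss_L
        self.v_p = np.maximum((1.0 - cf) * vss_L, 1e-12)
        self.q_ic = np.where(cf >= 1.0, 0.0, arr(lambda c: c.q_distribution_L_h))
        self.cl_r = arr(lambda c: c.cl_r_L_h)
        self.oat3_frac = arr(lambda c: c.oat3_fraction_of_clr)

        mg_protein = sys_.microsomal_protein_mg()
        abund = sys_.enzyme_abundance_pmol_per_mg
        cl3_met = np.zeros(n)
        cl3_oth = np.zeros(n)
        clf_met = np.zeros(n)
        clf_oth = np.zeros(n)
        cl_gut3 = np.zeros(n)
        for i, c in enumerate(spec.compounds):
            for e in c.clint_entries:
                whole = (
                    e.clint_ul_min_pmol * abund[e.enzyme] * mg_protein * _UL_MIN_TO_L_H
                )
                is_met = e.destination == "metabolite"
                if e.enzyme in ("CYP3A4", "CYP3A5"):
                    cl_gut3[i] += (
                        e.clint_ul_min_pmol
                        * sys_.cyp3a4_gut_abundance_pmol
                        * _UL_MIN_TO_L_H
                    )
                    if is_met:
                        cl3_met[i] += whole
                    else:
                        cl3_oth[i] += whole
                elif is_met:
                    clf_met[i] += whole
                else:
                    clf_oth[i] += whole
            clf_oth[i] += (
                c.clint_hlm_additional_ul_min_mg * mg_protein * _UL_MIN_TO_L_H
            )
        self.cl3_met, self.cl3_oth = cl3_met, cl3_oth
        self.clf_met, self.clf_oth = clf_met, clf_oth
        self.cl_gut3 = cl_gut3
        self.cl_pgp = arr(
            lambda c: c.pgp_substrate.clint_pgp_ul_min
            * c.pgp_substrate.raf_ref
            * _UL_MIN_TO_L_H
            if c.pgp_substrate
            else 0.0
        )

        inf = np.inf
        self.ki3a = arr(lambda c: c.ki_cyp3a_umol_L or inf)
        self.ki_pgp = arr(lambda c: c.ki_pgp_umol_L or inf)
        self.ki_oat3 = arr(lambda c: c.ki_oat3_umol_L or inf)
        self.indmax = arr(lambda c: c.indmax_calibrated or 1.0)
        self.indc50 = arr(lambda c: c.indc50_umol_L or 1.0)

        self.met_index = np.full(n, -1, dtype=int)
        name_to_i = {c.name: i for i, c in enumerate(spec.compounds)}
        for link in spec.metabolite_links:
            self.met_index[name_to_i[link.parent]] = name_to_i[link.metabolite]

        self.n_states = n * _N_STATES + 2  # + liver & gut CYP3A4 pools

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.n
        blocks = y[: n * _N_STATES].reshape(n, _N_STATES)
        pool_l, pool_g = y[-2], y[-1]
        lumen = blocks[:, _LUMEN]
        c_ent = blocks[:, _ENT] / self.v_ent
        c_c = blocks[:, _CENTRAL] / self.v_c
        c_p = blocks[:, _PERIPH] / self.v_p

        portal = self.q_villi * c_ent  # µmol/h into the portal vein
        cu_h = self.fu * c_c + self.fu * portal / (self.bp * self.q_h)
        cu_ent = self.fu_gut * c_ent

        if self.inhibition_on:
            terms_l = cu_h / self.ki3a
            terms_g = cu_ent / self.ki3a
            denom_l = 1.0 + terms_l.sum() - terms_l  # excludes self
            denom_g = 1.0 + terms_g.sum() - terms_g
        else:
            denom_l = denom_g = np.ones(n)
        scale_l = pool_l / denom_l
        scale_g = pool_g / denom_g

        clint = (self.cl3_met + self.cl3_oth) * scale_l + self.clf_met + self.clf_oth
        met_frac = np.where(
            clint > 0, (self.cl3_met * scale_l + self.clf_met) / np.maximum(clint, 1e-300), 0.0
        )
        fu_b = self.fu / self.bp
        e_h = fu_b * clint / (self.q_h + fu_b * clint)
        cl_b = self.q_h * e_h
        hep_total = portal * e_h + cl_b * self.bp * c_c

        gut_met = self.fu_gut * self.cl_gut3 * scale_g * c_ent
        if self.pgp_inhibition_on:
            terms_p = cu_ent / self.ki_pgp
            denom_p = 1.0 + terms_p.sum() - terms_p
        else:
            denom_p = np.ones(n)
        pgp_rate = self.fu_gut * self.cl_pgp * self.fi_pgp / denom_p * c_ent

        if self.oat3_on:
            terms_o = cu_h / self.ki_oat3
            denom_o = 1.0 + terms_o.sum() - terms_o
            cl_r_eff = self.cl_r * (1.0 - self.oat3_frac + self.oat3_frac / denom_o)
        else:
            cl_r_eff = self.cl_r
        renal = cl_r_eff * c_c

        formed = np.zeros(n)
        to_met = hep_total * met_frac
        for i in range(n):
            j = self.met_index[i]
            if j >= 0:
                formed[j] += to_met[i]

        # P-gp secretion re-enters the lumen distal to the absorptive
        # window and is treated as lost to transit (no reabsorption)
        d = np.empty_like(blocks)
        d[:, _LUMEN] = -(self.ka + self.k_transit) * lumen
        d[:, _ENT] = self.ka * lumen - portal - gut_met - pgp_rate
        d[:, _CENTRAL] = (
            portal * (1.0 - e_h)
            - cl_b * self.bp * c_c
            - renal
            - self.q_ic * (c_c - c_p)
            + formed
        )
        d[:, _PERIPH] = self.q_ic * (c_c - c_p)
        d[:, _CUM_TRANSIT] = self.k_transit * lumen + pgp_rate
        d[:, _CUM_GUTMET] = gut_met
        d[:, _CUM_HEP_OTHER] = hep_total - to_met
        d[:, _CUM_HEP_MET] = to_met
        d[:, _CUM_RENAL] = renal
        d[:, _CUM_FORMED] = formed

        out = np.empty(self.n_states)
        out[: n * _N_STATES] = d.ravel()
        if self.induction_on:
            amp = (self.indmax - 1.0)
            m_l = 1.0 + (amp * cu_h / (self.indc50 + cu_h)).sum()
            m_g = 1.0 + (amp * cu_ent / (self.indc50 + cu_ent)).sum()
        else:
            m_l = m_g = 1.0
        out[-2] = self.kdeg_liver * (m_l - pool_l)
        out[-1] = self.kdeg_gut * (m_g - pool_g)
        return out


@dataclass
class SimulationResult:
    """Time-stamped trajectories of one deterministic simulation."""

    time_h: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    compounds: list[str]
    dosed_umol: dict[str, float]  # absorbable (fa-scaled) amount delivered
    not_absorbed_umol: dict[str, float]  # (1 - fa) fraction, never enters lumen
    solver_stats: dict = field(default_factory=dict)
    _compiled: "_Compiled" = field(default=None, repr=False)

    def _idx(self, compound: str) -> int:
        return self.compounds.index(compound)

    def concentration(self, compound: str, compartment: str = "central") -> np.ndarray:
        """Concentration series (µmol/L) in 'central' (plasma) or 'enterocyte'."""
        i = self._idx(compound)
        if compartment == "central":
            return self.states[:, i * _N_STATES + _CENTRAL] / self._compiled.v_c[i]
        if compartment == "enterocyte":
            return self.states[:, i * _N_STATES + _ENT] / self._compiled.v_ent
        raise KeyError(f"unknown compartment {compartment!r}")

    def enzyme_pool(self, site: str = "liver") -> np.ndarray:
        """Relative CYP3A4 amount E/E0 at 'liver' or 'gut'."""
        col = {"liver": -2, "gut": -1}[site]
        return self.states[:, col]

    def amounts(self, compound: str) -> np.ndarray:
        i = self._idx(compound)
        return self.states[:, i * _N_STATES : (i + 1) * _N_STATES]

    def mass_balance_error(self, compound: str) -> float:
        """Relative mass-balance defect at the final time point.

        Input (absorbable dose + formed from parent) must equal material in
        compartments plus every cumulative elimination bucket.
        """
        a = self.amounts(compound)[-1]
        inputs = self.dosed_umol.get(compound, 0.0) + a[_CUM_FORMED]
        held = a[_LUMEN] + a[_ENT] + a[_CENTRAL] + a[_PERIPH]
        eliminated = (
            a[_CUM_TRANSIT] + a[_CUM_GUTMET] + a[_CUM_HEP_OTHER]
            + a[_CUM_HEP_MET] + a[_CUM_RENAL]
        )
        if inputs <= 0:
            return 0.0
        return abs(inputs - held - eliminated) / inputs


def simulate(
    spec: ModelSpec,
    regimens: Sequence[Regimen],
    duration_h: float,
    *,
    output_dt_h: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the coupled perpetrator-victim system.

    Doses are instantaneous additions of fa x dose to the compound's gut
    lumen at each scheduled time; integration proceeds piecewise between
    dose events with a stiff solver.
    """
    compiled = _Compiled(spec)
    name_to_i = {name: i for i, name in enumerate(compiled.names)}
    events: dict[float, list[tuple[int, float]]] = {}
    dosed = dict.fromkeys(compiled.names, 0.0)
    wasted = dict.fromkeys(compiled.names, 0.0)
    for reg in regimens:
        if reg.compound not in name_to_i:
            raise KeyError(f"regimen for unknown compound {reg.compound!r}")
        i = name_to_i[reg.compound]
        amount = reg.dose_mg * 1000.0 / compiled.mw[i]  # µmol
        for t in reg.dose_times():
            if t > duration_h:
                raise ValueError("duration does not cover all doses")
            events.setdefault(t, []).append((i, amount))

    y = np.zeros(compiled.n_states)
    y[-2] = y[-1] = 1.0  # enzyme pools start at baseline
    grid = np.arange(0.0, duration_h + output_dt_h / 2, output_dt_h)
    times_out = [np.array([0.0])]
    states_out = [y.copy()[None, :]]
    cut_points = sorted(t for t in events if t < duration_h)
    boundaries = [0.0] + [t for t in cut_points if t > 0] + [duration_h]
    nfev = 0

    for seg_start, seg_end in zip(boundaries[:-1], boundaries[1:]):
        for i, amount in events.get(seg_start, []):
            y[i * _N_STATES + _LUMEN] += compiled.fa[i] * amount
            dosed[compiled.names[i]] += compiled.fa[i] * amount
            wasted[compiled.names[i]] += (1.0 - compiled.fa[i]) * amount
        seg_grid = grid[(grid > seg_start) & (grid <= seg_end)]
        t_eval = np.unique(np.concatenate([seg_grid, [seg_end]]))
        sol = solve_ivp(
            compiled.rhs,
            (seg_start, seg_end),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(
                f"solver failed in [{seg_start}, {seg_end}]: {sol.message}", state=y
            )
        nfev += sol.nfev
        y = sol.y[:, -1].copy()
        times_out.append(sol.t)
        states_out.append(sol.y.T)

    time = np.concatenate(times_out)
    states = np.concatenate(states_out, axis=0)
    # collapse duplicated segment boundaries, keeping the post-dose state
    keep = np.ones(len(time), dtype=bool)
    keep[:-1] = np.diff(time) > 0
    result = SimulationResult(
        time_h=time[keep],
        states=states[keep],
        compounds=list(compiled.names),
        dosed_umol=dosed,
        not_absorbed_umol=wasted,
        solver_stats={"nfev": nfev, "method": method, "rtol": rtol, "atol": atol},
        _compiled=compiled,
    )
    floor = -10.0 * atol * max(1.0, float(np.max(np.abs(states))))
    if float(states[:, : compiled.n * _N_STATES].min()) < floor:
        raise SimulationError("negative state beyond tolerance", state=y)
    return result


def pk_metrics(
    result: SimulationResult,
    compound: str,
    window: tuple[float, float],
    compartment: str = "central",
) -> dict[str, float]:
    """AUC (linear trapezoid), Cmax, Tmax (parabolic refinement) and Cmin
    of a concentration series over ``window`` (hours)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    t = result.time_h
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError("window outside simulated range")
    c = result.concentration(compound, compartment)
    mask = (t >= t0) & (t <= t1)
    tt = t[mask]
    cc = c[mask]
    # interpolated window endpoints for an exact trapezoid over [t0, t1]
    if tt[0] > t0:
        tt = np.insert(tt, 0, t0)
        cc = np.insert(cc, 0, np.interp(t0, t, c))
    if tt[-1] < t1:
        tt = np.append(tt, t1)
        cc = np.append(cc, np.interp(t1, t, c))
    auc = float(np.trapezoid(cc, tt))
    k = int(np.argmax(cc))
    cmax, tmax = float(cc[k]), float(tt[k])
    if 0 < k < len(cc) - 1:
        x0, x1, x2 = tt[k - 1 : k + 2]
        y0, y1, y2 = cc[k - 1 : k + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        if denom != 0:
            a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
            b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
            if a < 0:
                tv = -b / (2 * a)
                if x0 <= tv <= x2:
                    tmax = float(tv)
                    cmax = float(a * tv**2 + b * tv + (y0 - a * x0**2 - b * x0))
    return {"auc": auc, "cmax": cmax, "tmax": tmax, "cmin": float(cc.min())}
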