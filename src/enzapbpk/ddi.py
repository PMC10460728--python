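"""DDI study designs: paired virtual-subject trials, geometric mean ratios,
P-gp sensitivity grids and the Guest et al. acceptance interval.

A study simulates each virtual subject twice with identical subject
parameters — victim alone, and victim co-dosed after a multiple-dose
perpetrator loading phase — and summarizes the paired exposure ratios as a
geometric mean ratio (GMR) with a t-based 90% confidence interval on the
log scale.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from . import datasets
from .engine import pk_metrics, simulate
from .models import (
    CompoundModel,
    InteractionSwitches,
    MetaboliteLink,
    ModelSpec,
    Regimen,
    SystemModel,
)

__all__ = [
    "PopulationSpec",
    "DDIScenario",
    "DDIResult",
    "GuestBounds",
    "run_ddi",
    "guest_bounds",
    "sensitivity_pgp",
    "gmr_ci",
    "default_victim_regimen",
    "default_perpetrator_regimen",
]

#: default single-dose victim regimens (mg)
_VICTIM_DOSES = {"digoxin": 0.25, "midazolam": 2.0, "apixaban": 10.0, "rivaroxaban": 20.0}
_LOADING_DAYS = 50
_OBS_WINDOW_H = 120.0


class PopulationSpec(BaseModel):
    n_subjects: int = Field(default=100, ge=1)
    seed: int = 0
    cv: Optional[dict[str, float]] = None  # falls back to SystemModel defaults


class DDIScenario(BaseModel):
    """One victim-perpetrator study arm specification.

    The perpetrator default is enzalutamide 160 mg once daily; the victim is
    dosed once, simultaneously with the dose on the day after
    ``loading_days`` of perpetrator dosing, and observed for
    ``observation_window_h`` while perpetrator dosing continues.
    """

    victim: str
    victim_regimen: Optional[Regimen] = None
    perpetrator_regimen: Optional[Regimen] = None
    loading_days: int = Field(default=_LOADING_DAYS, ge=0)
    observation_window_h: float = Field(default=_OBS_WINDOW_H, gt=0)
    fi_pgp: float = Field(default=1.0, gt=0)
    raf_ref_override: Optional[float] = Field(default=None, ge=0)
    oat3_inhibition: bool = True
    cyp3a_induction: bool = True
    cyp3a_inhibition: bool = True
    pgp_inhibition: bool = True
    population: PopulationSpec = Field(default_factory=PopulationSpec)


@dataclass
class DDIResult:
    auc_ratio_gmr: float
    cmax_ratio_gmr: float
    ci90: dict[str, tuple[float, float]]
    per_subject_ratios: pd.DataFrame
    n_excluded: int = 0
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GuestBounds:
    observed_ratio: float
    delta: float
    lower: float
    upper: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        return (round(self.lower, ndigits), round(self.upper, ndigits))

    def contains(self, predicted_ratio: float) -> bool:
        return self.lower <= predicted_ratio <= self.upper


def guest_bounds(observed_ratio: float, delta: float = 1.25) -> GuestBounds:
    """Observation-scaled acceptance interval for a predicted DDI ratio.

    With R the observed ratio folded to >= 1 (reciprocal if below one), the
    limit is L = (delta + 2(R - 1)) / R and the interval [R/L, R*L]; for
    observed ratios below one the interval is mapped back through the
    reciprocal. At R = 1 the interval is the classical [1/delta, delta].
    """
    if observed_ratio <= 0:
        raise ValueError("observed_ratio must be > 0")
    if delta < 1:
        raise ValueError("delta must be >= 1")
    flipped = observed_ratio < 1.0
    r = 1.0 / observed_ratio if flipped else observed_ratio
    limit = (delta + 2.0 * (r - 1.0)) / r
    lo, hi = r / limit, r * limit
    if flipped:
        lo, hi = 1.0 / hi, 1.0 / lo
    return GuestBounds(observed_ratio=observed_ratio, delta=delta, lower=lo, upper=hi)


def gmr_ci(
    ratios: Sequence[float], level: float = 0.90
) -> tuple[float, float, float]:
    """Geometric mean and two-sided t confidence interval on the log scale."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("empty ratio series")
    if np.any(arr <= 0):
        raise ValueError("all ratios must be > 0")
    logs = np.log(arr)
    gmr = float(np.exp(logs.mean()))
    n = arr.size
    if n < 2:
        return gmr, math.nan, math.nan
    se = logs.std(ddof=1) / math.sqrt(n)
    half = stats.t.ppf(0.5 + level / 2.0, df=n - 1) * se
    return gmr, float(np.exp(logs.mean() - half)), float(np.exp(logs.mean() + half))


def default_victim_regimen(victim: str, start_h: float) -> Regimen:
    dose = _VICTIM_DOSES.get(victim)
    if dose is None:
        raise KeyError(f"no default regimen for victim {victim!r}")
    return Regimen(compound=victim, dose_mg=dose, n_doses=1, start_h=start_h)


def default_perpetrator_regimen(n_days: int) -> Regimen:
    return Regimen(
        compound="enzalutamide", dose_mg=160.0, interval_h=24.0, n_doses=n_days, start_h=0.0
    )


def _apply_raf_override(victim: CompoundModel, raf: Optional[float]) -> CompoundModel:
    if raf is None:
        return victim
    if raf == 0.0 or victim.pgp_substrate is None:
        return victim.model_copy(update={"pgp_substrate": None})
    new_pgp = victim.pgp_substrate.model_copy(update={"raf_ref": raf})
    return victim.model_copy(update={"pgp_substrate": new_pgp})


def _subject_variant(
    compound: CompoundModel, mult: dict[str, float]
) -> CompoundModel:
    entries = [
        e.model_copy(update={"clint_ul_min_pmol": e.clint_ul_min_pmol * mult["clint"]})
        for e in compound.clint_entries
    ]
    return compound.model_copy(
        update={
            "clint_entries": entries,
            "clint_hlm_additional_ul_min_mg": compound.clint_hlm_additional_ul_min_mg
            * mult["clint"],
            "vss_L_kg": compound.vss_L_kg * mult["vss"],
            "ka_per_h": compound.ka_per_h * mult["ka"],
        }
    )


def _sample_multipliers(rng: np.random.Generator, cv: dict[str, float]) -> dict[str, float]:
    out = {}
    for key in ("clint", "vss", "ka"):
        sigma = math.sqrt(math.log(1.0 + cv.get(key, 0.0) ** 2))
        out[key] = float(rng.lognormal(mean=0.0, sigma=sigma))
    return out


def _identity_multipliers() -> dict[str, float]:
    return {"clint": 1.0, "vss": 1.0, "ka": 1.0}


def build_scenario_components(
    scenario: DDIScenario,
    system: Optional[SystemModel] = None,
    victim_model: Optional[CompoundModel] = None,
):
    """Resolve compound files, regimens and switches for a scenario."""
    system = system or SystemModel()
    victim = victim_model if victim_model is not None else datasets.load_packaged_compound(scenario.victim)
    victim = _apply_raf_override(victim, scenario.raf_ref_override)
    perpetrator = datasets.load_packaged_compound("enzalutamide")
    metabolite = datasets.load_packaged_compound("m2")
    victim_start = scenario.loading_days * 24.0
    victim_reg = scenario.victim_regimen or default_victim_regimen(
        victim.name, victim_start
    )
    n_perp_doses = scenario.loading_days + math.ceil(scenario.observation_window_h / 24.0)
    perp_reg = scenario.perpetrator_regimen or default_perpetrator_regimen(n_perp_doses)
    switches = InteractionSwitches(
        cyp3a_induction=scenario.cyp3a_induction,
        cyp3a_inhibition=scenario.cyp3a_inhibition,
        pgp_inhibition=scenario.pgp_inhibition,
        pgp_fold_increase=scenario.fi_pgp,
        oat3_inhibition=scenario.oat3_inhibition,
    )
    return system, victim, perpetrator, metabolite, victim_reg, perp_reg, switches


def _paired_ratios(
    system: SystemModel,
    victim: CompoundModel,
    perpetrator: CompoundModel,
    metabolite: CompoundModel,
    victim_reg: Regimen,
    perp_reg: Regimen,
    switches: InteractionSwitches,
    window: float,
    solver_opts: dict,
) -> tuple[float, float]:
    """(AUC ratio, Cmax ratio) for one subject's paired arms."""
    w0 = victim_reg.start_h
    w1 = w0 + window
    baseline_reg = victim_reg.model_copy(update={"start_h": 0.0})
    # FI models perpetrator-induced P-gp expression: baseline arm runs at 1.0
    base_switches = switches.model_copy(update={"pgp_fold_increase": 1.0})
    base_spec = ModelSpec(system=system, compounds=[victim], switches=base_switches)
    base = simulate(base_spec, [baseline_reg], duration_h=window, **solver_opts)
    base_m = pk_metrics(base, victim.name, (0.0, window))

    combo_spec = ModelSpec(
        system=system,
        compounds=[perpetrator, metabolite, victim],
        metabolite_links=[MetaboliteLink(parent=perpetrator.name, metabolite=metabolite.name)],
        switches=switches,
    )
    combo = simulate(combo_spec, [perp_reg, victim_reg], duration_h=w1, **solver_opts)
    combo_m = pk_metrics(combo, victim.name, (w0, w1))
    if base_m["auc"] <= 0 or combo_m["auc"] <= 0:
        return math.nan, math.nan
    return combo_m["auc"] / base_m["auc"], combo_m["cmax"] / base_m["cmax"]


def run_ddi(
    scenario: DDIScenario,
    system: Optional[SystemModel] = None,
    victim_model: Optional[CompoundModel] = None,
    **solver_opts,
) -> DDIResult:
    """Run the paired-design virtual trial for a scenario.

    Each subject's parameters (hepatic intrinsic clearances, Vss, ka;
    log-normal with the system CV map, median 1) are shared between the
    victim-alone and co-dosed arms, so between-subject variability widens
    the CI without biasing the GMR. Subjects with non-positive exposure in
    either arm are excluded with a warning.
    """
    (system, victim, perpetrator, metabolite, victim_reg, perp_reg, switches
     ) = build_scenario_components(scenario, system, victim_model)
    solver_opts.setdefault("output_dt_h", 0.1)
    cv = scenario.population.cv or system.population_cv
    rng = np.random.default_rng(scenario.population.seed)
    n = scenario.population.n_subjects

    rows = []
    excluded = 0
    for subject in range(n):
        mult = _sample_multipliers(rng, cv) if n > 1 else _identity_multipliers()
        compounds = {
            "victim": _subject_variant(victim, mult),
            "perp": _subject_variant(perpetrator, mult),
            "met": _subject_variant(metabolite, mult),
        }
        auc_ratio, cmax_ratio = _paired_ratios(
            system,
            compounds["victim"],
            compounds["perp"],
            compounds["met"],
            victim_reg,
            perp_reg,
            switches,
            scenario.observation_window_h,
            solver_opts,
        )
        if not (math.isfinite(auc_ratio) and auc_ratio > 0 and cmax_ratio > 0):
            excluded += 1
            continue
        rows.append({"subject": subject, "auc_ratio": auc_ratio, "cmax_ratio": cmax_ratio})
    if excluded:
        warnings.warn(f"excluded {excluded} subject(s) with non-positive exposure")
    if not rows:
        raise RuntimeError("no evaluable subjects")
    per_subject = pd.DataFrame(rows)
    auc_g, auc_lo, auc_hi = gmr_ci(per_subject["auc_ratio"])
    cmax_g, cmax_lo, cmax_hi = gmr_ci(per_subject["cmax_ratio"])
    return DDIResult(
        auc_ratio_gmr=auc_g,
        cmax_ratio_gmr=cmax_g,
        ci90={"auc": (auc_lo, auc_hi), "cmax": (cmax_lo, cmax_hi)},
        per_subject_ratios=per_subject,
        n_excluded=excluded,
        meta={
            "victim": victim.name,
            "fi_pgp": scenario.fi_pgp,
            "n_subjects": n,
            "seed": scenario.population.seed,
        },
    )


def sensitivity_pgp(
    scenario: DDIScenario,
    raf_ref_grid: Sequence[float],
    system: Optional[SystemModel] = None,
    victim_model: Optional[CompoundModel] = None,
    **solver_opts,
) -> pd.DataFrame:
    """Deterministic representative-subject DDI ratios across a grid of
    intestinal P-gp RAF/REF values for the victim."""
    grid = list(raf_ref_grid)
    if not grid:
        raise ValueError("empty RAF/REF grid")
    if any(g < 0 for g in grid):
        raise ValueError("RAF/REF values must be >= 0")
    rows = []
    for raf in grid:
        point = scenario.model_copy(
            update={
                "raf_ref_override": raf,
                "population": PopulationSpec(n_subjects=1, seed=scenario.population.seed),
            }
        )
        res = run_ddi(point, system=system, victim_model=victim_model, **solver_opts)
        rows.append(
            {"raf_ref": raf, "auc_ratio": res.auc_ratio_gmr, "cmax_ratio": res.cmax_ratio_gmr}
        )
    return pd.DataFrame(rows)
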