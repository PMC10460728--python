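"""Compound, system and scenario parameter models.

All quantities carry their units in the field name. Compound files are
YAML documents validated against :class:`CompoundModel`; the physiological
constants live in :class:`SystemModel`. Hepatic intrinsic clearances are
expressed per pmol of enzyme (µL/min/pmol) and scaled to whole-liver values
through microsomal protein per gram of liver (MPPGL), liver mass and enzyme
abundance.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

Destination = Literal["metabolite", "other"]


class ClintEntry(BaseModel):
    """One enzymatic elimination pathway: intrinsic clearance per pmol of
    enzyme, tagged with whether its flux forms the tracked metabolite."""

    enzyme: str
    clint_ul_min_pmol: float = Field(ge=0)
    destination: Destination = "other"


class PgpSubstrate(BaseModel):
    """Intestinal P-gp secretion: in vitro intrinsic clearance (µL/min)
    scaled in vivo by the relative activity/expression factor (RAF/REF)."""

    clint_pgp_ul_min: float = Field(gt=0)
    raf_ref: float = Field(gt=0)


class CompoundModel(BaseModel):
    name: str
    mw_g_mol: float = Field(gt=0)
    log_p: Optional[float] = None
    fu: float = Field(gt=0, le=1)
    fu_gut: Optional[float] = Field(default=None, gt=0, le=1)
    bp_ratio: float = Field(default=1.0, gt=0)
    vss_L_kg: float = Field(gt=0)
    kp_scalar: float = 1.0  # provenance only; distribution is lumped
    cl_r_L_h: float = Field(default=0.0, ge=0)
    oat3_fraction_of_clr: float = Field(default=0.0, ge=0, le=1)
    ka_per_h: float = Field(default=1.0, gt=0)
    fa: float = Field(default=1.0, gt=0, le=1)
    peff_man_1e4_cm_s: Optional[float] = None
    clint_entries: list[ClintEntry] = Field(default_factory=list)
    clint_hlm_additional_ul_min_mg: float = Field(default=0.0, ge=0)
    ki_cyp3a_umol_L: Optional[float] = Field(default=None, gt=0)
    ki_pgp_umol_L: Optional[float] = Field(default=None, gt=0)
    ki_oat3_umol_L: Optional[float] = Field(default=None, gt=0)
    indmax_calibrated: Optional[float] = Field(default=None, ge=1)
    indc50_umol_L: Optional[float] = Field(default=None, gt=0)
    pgp_substrate: Optional[PgpSubstrate] = None
    q_distribution_L_h: float = Field(default=25.0, ge=0)
    central_fraction_of_vss: float = Field(default=0.3, gt=0, le=1)
    notes: str = ""

    @model_validator(mode="after")
    def _defaults(self) -> "CompoundModel":
        if self.fu_gut is None:
            object.__setattr__(self, "fu_gut", self.fu)
        if self.indmax_calibrated is not None and self.indc50_umol_L is None:
            raise ValueError("indc50_umol_L required when indmax_calibrated is set")
        return self

    @property
    def oat3_substrate_flag(self) -> bool:
        return self.oat3_fraction_of_clr > 0


class SystemModel(BaseModel):
    """Physiological constants of the virtual human.

    Defaults are standard population values for a 70-kg adult; they
    reproduce the packaged enzalutamide clearance assignments (87% CYP2C8 /
    13% CYP3A4 from an oral clearance of 0.60 L/h) within 2%.
    """

    liver_mass_g: float = Field(default=1650.0, gt=0)
    mppgl_mg_per_g: float = Field(default=40.0, gt=0)
    enzyme_abundance_pmol_per_mg: dict[str, float] = Field(
        default_factory=lambda: {"CYP3A4": 137.0, "CYP2C8": 24.0}
    )
    cyp3a4_gut_abundance_pmol: float = Field(default=66100.0, gt=0)
    kdeg_per_h: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {"CYP3A4": {"liver": 0.0193, "gut": 0.029}}
    )
    hepatic_blood_flow_L_h: float = Field(default=90.0, gt=0)
    villous_blood_flow_L_h: float = Field(default=18.0, gt=0)
    enterocyte_volume_L: float = Field(default=0.5, gt=0)
    lumen_transit_per_h: float = Field(default=0.25, ge=0)
    body_weight_kg: float = Field(default=70.0, gt=0)
    indmax_reference_invivo: float = Field(default=16.0, gt=1)
    population_cv: dict[str, float] = Field(
        default_factory=lambda: {"clint": 0.35, "vss": 0.20, "ka": 0.30}
    )

    @model_validator(mode="after")
    def _positive(self) -> "SystemModel":
        for enzyme, value in self.enzyme_abundance_pmol_per_mg.items():
            if value <= 0:
                raise ValueError(f"non-positive abundance for {enzyme}")
        return self

    def microsomal_protein_mg(self) -> float:
        return self.liver_mass_g * self.mppgl_mg_per_g

    def check_abundances(self, compounds: list[CompoundModel]) -> None:
        """Every enzyme referenced by a compound must have an abundance."""
        for compound in compounds:
            for entry in compound.clint_entries:
                if entry.enzyme not in self.enzyme_abundance_pmol_per_mg:
                    raise KeyError(
                        f"{compound.name}: no abundance for enzyme {entry.enzyme}"
                    )


class Regimen(BaseModel):
    compound: str
    dose_mg: float = Field(gt=0)
    interval_h: float = Field(default=24.0, gt=0)
    n_doses: int = Field(default=1, ge=1)
    start_h: float = Field(default=0.0, ge=0)

    def dose_times(self) -> list[float]:
        return [self.start_h + i * self.interval_h for i in range(self.n_doses)]


class InteractionSwitches(BaseModel):
    """Mechanism toggles of a scenario.

    ``pgp_fold_increase`` is the static fold-increase (FI) in intestinal
    P-gp expression; 1.0 means no P-gp induction, which is the default the
    digoxin interaction supports.
    """

    cyp3a_induction: bool = True
    cyp3a_inhibition: bool = True
    pgp_inhibition: bool = True
    pgp_fold_increase: float = Field(default=1.0, gt=0)
    oat3_inhibition: bool = True

    @classmethod
    def all_off(cls) -> "InteractionSwitches":
        return cls(
            cyp3a_induction=False,
            cyp3a_inhibition=False,
            pgp_inhibition=False,
            pgp_fold_increase=1.0,
            oat3_inhibition=False,
        )


class MetaboliteLink(BaseModel):
    parent: str
    metabolite: str


class ModelSpec(BaseModel):
    system: SystemModel = Field(default_factory=SystemModel)
    compounds: list[CompoundModel]
    metabolite_links: list[MetaboliteLink] = Field(default_factory=list)
    switches: InteractionSwitches = Field(default_factory=InteractionSwitches)

    @model_validator(mode="after")
    def _consistent(self) -> "ModelSpec":
        names = {c.name for c in self.compounds}
        for link in self.metabolite_links:
            if link.parent not in names or link.metabolite not in names:
                raise ValueError(f"metabolite link references unknown compound: {link}")
        self.system.check_abundances(self.compounds)
        return self


def load_compound(path: str | Path) -> CompoundModel:
    with open(path) as fh:
        return CompoundModel.model_validate(yaml.safe_load(fh))


def load_system(path: str | Path) -> SystemModel:
    with open(path) as fh:
        return SystemModel.model_validate(yaml.safe_load(fh))


def dump_compound(compound: CompoundModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(compound.model_dump(exclude_none=True), fh, sort_keys=False)
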