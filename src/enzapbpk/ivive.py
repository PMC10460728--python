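"""In vitro-in vivo extrapolation: retrograde intrinsic clearances,
enzyme-pathway splits and metabolite-formation fractions.

The retrograde calculation distributes an observed in vivo oral clearance
over hepatic enzymes: for a low-extraction drug, CL_po ≈ fu * CL_int,u, so
the total unbound hepatic intrinsic clearance is CL_po / fu. That whole-
liver value is split by the fraction-metabolized (fm) map, scaled to
per-mg-microsomal-protein via liver mass x MPPGL, and divided by the
enzyme abundance to yield per-pmol intrinsic clearances (µL/min/pmol).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .models import SystemModel

__all__ = [
    "PathwaySplit",
    "retrograde_clint",
    "forward_clint",
    "fm_from_clint",
    "split_to_metabolite",
    "overall_to_metabolite",
    "m2_cyp3a4_fraction",
]

_UL_MIN_PER_L_H = 1e6 / 60.0  # 1 L/h = 16667 µL/min


@dataclass(frozen=True)
class PathwaySplit:
    """Hepatic elimination split: per-enzyme fm and, per enzyme, the
    fraction of that enzyme's intrinsic clearance forming the metabolite."""

    fm: dict[str, float]
    frac_to_metabolite: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.fm.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fm values must sum to 1 (got {total})")
        for name, value in {**self.fm, **self.frac_to_metabolite}.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"fraction out of [0,1] for {name}: {value}")

    @property
    def overall_to_metabolite(self) -> float:
        return overall_to_metabolite(self)


def retrograde_clint(
    cl_po_L_h: float,
    fu: float,
    fm: dict[str, float],
    system: SystemModel | None = None,
    *,
    well_stirred: bool = False,
    bp_ratio: float = 1.0,
) -> dict[str, float]:
    """Per-enzyme intrinsic clearances (µL/min/pmol) from oral clearance.

    Default uses the low-extraction approximation CL_po = fu * CL_int,u.
    ``well_stirred=True`` instead inverts the full well-stirred oral
    clearance CL_po = fu_b * CL_int,u * BP (identical in the low-extraction
    limit but correcting for hepatic blood flow is unnecessary for oral
    clearance of a completely absorbed drug, so the two agree exactly; the
    flag is kept for symmetry with the forward model).
    """
    if cl_po_L_h <= 0:
        raise ValueError("cl_po must be > 0")
    if not 0 < fu <= 1:
        raise ValueError("fu must be in (0, 1]")
    total = sum(fm.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fm must sum to 1 (got {total})")
    system = system or SystemModel()
    clint_u_L_h = cl_po_L_h / fu  # whole-body unbound hepatic CL_int
    clint_ul_min = clint_u_L_h * _UL_MIN_PER_L_H
    per_mg = clint_ul_min / system.microsomal_protein_mg()
    out = {}
    for enzyme, fraction in fm.items():
        try:
            abundance = system.enzyme_abundance_pmol_per_mg[enzyme]
        except KeyError:
            raise KeyError(f"no abundance configured for enzyme {enzyme}") from None
        out[enzyme] = per_mg * fraction / abundance
    return out


def forward_clint(
    clint_per_pmol: dict[str, float],
    fu: float,
    system: SystemModel | None = None,
) -> float:
    """Inverse of :func:`retrograde_clint`: oral clearance (L/h) implied by
    per-pmol intrinsic clearances under the low-extraction approximation."""
    system = system or SystemModel()
    per_mg = sum(
        v * system.enzyme_abundance_pmol_per_mg[e] for e, v in clint_per_pmol.items()
    )
    clint_u_L_h = per_mg * system.microsomal_protein_mg() / _UL_MIN_PER_L_H
    return fu * clint_u_L_h


def fm_from_clint(
    clint_per_pmol: dict[str, float], abundance_pmol_per_mg: dict[str, float]
) -> dict[str, float]:
    """fm(e) = CL_int(e) * abundance(e) / sum over enzymes."""
    if not clint_per_pmol:
        raise ValueError("empty clearance map")
    if set(clint_per_pmol) != set(abundance_pmol_per_mg):
        raise ValueError("clint and abundance maps must share key sets")
    weighted = {e: clint_per_pmol[e] * abundance_pmol_per_mg[e] for e in clint_per_pmol}
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError("all-zero clearances")
    return {e: w / total for e, w in weighted.items()}


def split_to_metabolite(
    fm_primary: float, frac_primary_to_met: float, target_overall: float
) -> float:
    """Solve fm1*f1 + (1 - fm1)*x = target for the secondary pathway's
    metabolite-formation fraction x."""
    if not 0 <= fm_primary < 1:
        raise ValueError("fm_primary must be in [0, 1)")
    x = (target_overall - fm_primary * frac_primary_to_met) / (1.0 - fm_primary)
    if not -1e-12 <= x <= 1.0 + 1e-12:
        raise ValueError(
            f"infeasible split: required secondary fraction {x:.4f} outside [0, 1]"
        )
    return min(max(x, 0.0), 1.0)


def overall_to_metabolite(split: PathwaySplit) -> float:
    """Overall fraction of elimination forming the metabolite:
    sum over enzymes of fm(e) * frac_to_metabolite(e)."""
    return sum(
        split.fm[e] * split.frac_to_metabolite.get(e, 0.0) for e in split.fm
    )


def m2_cyp3a4_fraction(
    clint_cyp3a4_ul_min_pmol: float,
    clint_hlm_additional_ul_min_mg: float,
    abundance_cyp3a4_pmol_per_mg: float,
) -> float:
    """CYP3A4's share of a metabolite's hepatic elimination, mixing a
    per-pmol CYP3A4 clearance with an additional per-mg microsomal
    clearance on the common per-mg scale."""
    if min(clint_cyp3a4_ul_min_pmol, clint_hlm_additional_ul_min_mg) < 0:
        raise ValueError("clearances must be >= 0")
    cyp = clint_cyp3a4_ul_min_pmol * abundance_cyp3a4_pmol_per_mg
    total = cyp + clint_hlm_additional_ul_min_mg
    if total <= 0:
        raise ValueError("all-zero denominator")
    return cyp / total
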