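"""Seeded generators for synthetic in vitro datasets and victim compounds.

Every generator is a pure function of (truth, seed): regenerating with the
same arguments is bit-identical. Generated tables pass the same schema
validation as the packaged assay transcriptions, so the fitting code is
exercised on exactly the structures it sees in production.

Noise models: hepatocyte fold-induction values are positive with lot SDs
roughly proportional to the mean, so lot-level noise is log-normal
(median 1); transwell P_app noise is normal on the measurement scale,
truncated at 3 SD to keep permeabilities positive.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assays import fold_induction_model, pct_control_model
from .datasets import validate_induction_frame, validate_transwell_frame
from .models import ClintEntry, CompoundModel, PgpSubstrate, SystemModel

__all__ = [
    "InductionTruth",
    "TranswellTruth",
    "gen_induction_dataset",
    "gen_transwell_dataset",
    "gen_victim_compound",
    "write_dataset",
]


@dataclass(frozen=True)
class InductionTruth:
    """True Emax parameters and lot-level noise of a synthetic induction assay.

    ``lot_cv`` is the between-lot coefficient of variation of the fold
    values; the default matches the spread of the hepatocyte CYP3A4 data
    (SD/mean ~ 0.35 across concentrations).
    """

    ind_max: float = 5.9
    ind_c50: float = 1.5
    lot_cv: float = 0.35


@dataclass(frozen=True)
class TranswellTruth:
    """True Hill-inhibition parameters of a synthetic transwell assay."""

    ic50: float = 1.67
    i_max: float = 1.0
    hill_c: float = 1.0
    baseline_corrected_ratio: float = 20.0
    control_ratio: float = 1.0
    papp_level_1e6: float = 2.9  # geometric mean of the MDR1 directional pair
    noise_cv: float = 0.05


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _truncnorm_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative normal noise truncated at 3 SD (keeps P_app > 0)."""
    if cv <= 0:
        return np.ones(size)
    draws = rng.normal(0.0, 1.0, size=size)
    draws = np.clip(draws, -3.0, 3.0)
    return 1.0 + cv * draws


def gen_induction_dataset(
    truth: InductionTruth,
    concentrations: Sequence[float],
    n_lots: int = 3,
    seed: int = 0,
    compound: str = "synthetic",
    gene: str = "CYP3A4",
) -> pd.DataFrame:
    """Synthetic hepatocyte induction table (mean ± SD over lots).

    Lot-level folds are the Emax model value times log-normal noise; the
    table reports their mean and SD per concentration, mirroring the
    packaged assay transcription.
    """
    if n_lots < 1:
        raise ValueError("n_lots must be >= 1")
    conc = np.asarray(list(concentrations), dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc:
        model_value = float(fold_induction_model(c, truth.ind_max, truth.ind_c50))
        lots = model_value * _lognormal_factor(rng, truth.lot_cv, n_lots)
        rows.append(
            {
                "compound": compound,
                "gene": gene,
                "concentration_umol_L": c,
                "fold_mean": float(np.mean(lots)),
                "fold_sd": float(np.std(lots, ddof=1)) if n_lots > 1 else np.nan,
                "n_lots": n_lots,
            }
        )
    return validate_induction_frame(pd.DataFrame(rows))


def gen_transwell_dataset(
    truth: TranswellTruth,
    concentrations: Sequence[float],
    seed: int = 0,
    additive: str = "synthetic",
) -> pd.DataFrame:
    """Synthetic bidirectional transwell table.

    The MDR1 efflux ratio follows the Hill inhibition curve scaled to the
    baseline corrected ratio; control-cell ratios sit at
    ``truth.control_ratio`` (≈ 1). The zero-additive baseline row is always
    included. Directional P_app values are split geometrically around
    ``papp_level_1e6``.
    """
    if truth.baseline_corrected_ratio <= 1:
        raise ValueError("baseline corrected ratio must be > 1")
    conc = sorted({0.0, *(float(c) for c in concentrations)})
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc:
        pct = float(pct_control_model(c, truth.i_max, truth.ic50, truth.hill_c))
        corrected = truth.baseline_corrected_ratio * pct / 100.0
        corrected = max(corrected, 1e-6)
        mdr1_ratio = corrected * truth.control_ratio
        values = {
            ("control", "A2B"): 1.6 / np.sqrt(truth.control_ratio),
            ("control", "B2A"): 1.6 * np.sqrt(truth.control_ratio),
            ("MDR1", "A2B"): truth.papp_level_1e6 / np.sqrt(mdr1_ratio),
            ("MDR1", "B2A"): truth.papp_level_1e6 * np.sqrt(mdr1_ratio),
        }
        for (line, direction), papp in values.items():
            noisy = papp * float(_truncnorm_factor(rng, truth.noise_cv, ()))
            rows.append(
                {
                    "additive": additive,
                    "additive_conc_umol_L": c,
                    "cell_line": line,
                    "direction": direction,
                    "papp_1e6_cm_s": noisy,
                }
            )
    return validate_transwell_frame(pd.DataFrame(rows))


_DEFAULT_RANGES = {
    "fm_cyp3a": (0.0, 0.9),
    "clint_total_L_h": (10.0, 150.0),
    "cl_r_L_h": (0.0, 5.0),
    "vss_L_kg": (0.2, 2.0),
    "ka_per_h": (0.5, 2.0),
    "fu": (0.02, 0.7),
    "raf_ref": (0.1, 30.0),
}


def gen_victim_compound(
    param_ranges: Optional[dict[str, tuple[float, float]]] = None,
    seed: int = 0,
    system: Optional[SystemModel] = None,
    name: str = "synthetic_victim",
) -> CompoundModel:
    """Random but valid victim compound for property-based engine tests.

    Samples fm,CYP3A, total hepatic intrinsic clearance, renal clearance,
    Vss, ka, fu and an intestinal P-gp RAF/REF uniformly from the given
    ranges and converts them into a schema-valid compound file.
    """
    ranges = {**_DEFAULT_RANGES, **(param_ranges or {})}
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"invalid range for {key}")
    system = system or SystemModel()
    rng = np.random.default_rng(seed)
    draw = {k: float(rng.uniform(*ranges[k])) for k in sorted(ranges)}
    mg_protein = system.microsomal_protein_mg()
    clint_total_ul_min = draw["clint_total_L_h"] * 1e6 / 60.0
    cyp3a_per_pmol = (
        draw["fm_cyp3a"]
        * clint_total_ul_min
        / mg_protein
        / system.enzyme_abundance_pmol_per_mg["CYP3A4"]
    )
    other_per_mg = (1.0 - draw["fm_cyp3a"]) * clint_total_ul_min / mg_protein
    entries = (
        [ClintEntry(enzyme="CYP3A4", clint_ul_min_pmol=cyp3a_per_pmol)]
        if cyp3a_per_pmol > 0
        else []
    )
    return CompoundModel(
        name=name,
        mw_g_mol=450.0,
        fu=draw["fu"],
        fu_gut=1.0,
        vss_L_kg=draw["vss_L_kg"],
        cl_r_L_h=draw["cl_r_L_h"],
        ka_per_h=draw["ka_per_h"],
        fa=0.9,
        clint_entries=entries,
        clint_hlm_additional_ul_min_mg=other_per_mg,
        pgp_substrate=PgpSubstrate(clint_pgp_ul_min=4000.0, raf_ref=draw["raf_ref"]),
        notes=f"synthetic victim, seed={seed}",
    )


def write_dataset(df: pd.DataFrame, truth, path: str | Path) -> Path:
    """Write a generated dataset as CSV with a truth sidecar JSON."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    record = asdict(truth) if hasattr(truth, "__dataclass_fields__") else dict(truth)
    record["generator"] = type(truth).__name__
    sidecar.write_text(json.dumps(record, indent=2))
    return sidecar
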