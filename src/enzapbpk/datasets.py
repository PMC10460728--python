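"""Packaged datasets and parameter files, plus the tidy-table schemas.

The induction table holds hepatocyte fold-increase data (mean ± SD over
lots) for enzalutamide, its metabolites and the prototypical inducers; the
transwell table holds bidirectional P_app data for digoxin transport across
control and MDR1-expressing monolayers. Both are plain CSV transcriptions
of the corresponding assay report tables.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .models import CompoundModel, SystemModel, load_compound, load_system

__all__ = [
    "load_induction_table",
    "load_transwell_table",
    "load_packaged_compound",
    "load_default_system",
    "packaged_compounds",
    "validate_induction_frame",
    "validate_transwell_frame",
]

INDUCTION_COLUMNS = [
    "compound",
    "gene",
    "concentration_umol_L",
    "fold_mean",
    "fold_sd",
    "n_lots",
]
TRANSWELL_COLUMNS = [
    "additive",
    "additive_conc_umol_L",
    "cell_line",
    "direction",
    "papp_1e6_cm_s",
]

_COMPOUND_FILES = {
    "enzalutamide": "enzalutamide.yaml",
    "m2": "m2.yaml",
    "M2": "m2.yaml",
    "digoxin": "digoxin.yaml",
    "midazolam": "midazolam.yaml",
    "apixaban": "apixaban.yaml",
    "rivaroxaban": "rivaroxaban_model1.yaml",
    "rivaroxaban_model1": "rivaroxaban_model1.yaml",
    "rivaroxaban_model2": "rivaroxaban_model2.yaml",
}


def _data_path(*parts: str) -> Path:
    return Path(resources.files("enzapbpk") / "data" / Path(*parts))


def validate_induction_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(INDUCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"induction table missing columns: {sorted(missing)}")
    if (df["concentration_umol_L"] < 0).any():
        raise ValueError("negative concentration")
    if (df["fold_mean"] <= 0).any():
        raise ValueError("non-positive fold_mean")
    if (df["n_lots"] < 1).any():
        raise ValueError("n_lots must be >= 1")
    return df


def validate_transwell_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRANSWELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transwell table missing columns: {sorted(missing)}")
    if (df["papp_1e6_cm_s"] <= 0).any():
        raise ValueError("non-positive P_app")
    if not set(df["direction"]) <= {"A2B", "B2A"}:
        raise ValueError("direction must be A2B or B2A")
    if not set(df["cell_line"]) <= {"control", "MDR1"}:
        raise ValueError("cell_line must be control or MDR1")
    return df


def load_induction_table() -> pd.DataFrame:
    """Hepatocyte CYP/P-gp mRNA fold-increase data (tidy)."""
    return validate_induction_frame(pd.read_csv(_data_path("induction_foldchange.csv")))


def load_transwell_table() -> pd.DataFrame:
    """Bidirectional digoxin P_app data across control/MDR1 monolayers (tidy)."""
    return validate_transwell_frame(pd.read_csv(_data_path("transwell_papp.csv")))


def packaged_compounds() -> list[str]:
    return sorted(set(_COMPOUND_FILES) - {"M2", "rivaroxaban"})


def load_packaged_compound(name: str) -> CompoundModel:
    try:
        fname = _COMPOUND_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown compound {name!r}; available: {packaged_compounds()}"
        ) from None
    return load_compound(_data_path("compounds", fname))


def load_default_system() -> SystemModel:
    return load_system(_data_path("system_default.yaml"))
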