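"""In vitro assay analysis: CYP/P-gp induction fits, transwell efflux
summaries, P-gp inhibition (IC50) fits, and induction-amplitude calibration.

Two concentration-response models are fitted by unweighted least squares
with a fixed multi-start strategy (deterministic: the start list does not
depend on a random seed):

* fold induction = 1 + (Ind_max - 1) * C / (IndC50 + C)
* % of control   = 100 * (1 - I_max * I**C / (I**C + IC50**C))

IC50 values fitted here are used downstream as competitive inhibition
constants (K_i).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "InductionObservation",
    "InductionFit",
    "TranswellRecord",
    "EffluxSummary",
    "InhibitionFit",
    "fit_fold_induction",
    "compute_papp",
    "summarize_efflux",
    "pct_of_control_series",
    "fit_pgp_inhibition",
    "calibrate_indmax",
    "fold_induction_model",
    "pct_control_model",
]


@dataclass(frozen=True)
class InductionObservation:
    """One mean fold-increase measurement for a compound x gene pair."""

    compound: str
    gene: str
    concentration_umol_L: float
    fold_mean: float
    fold_sd: Optional[float] = None
    n_lots: int = 3

    def __post_init__(self) -> None:
        if self.concentration_umol_L < 0:
            raise ValueError("concentration must be >= 0")
        if self.fold_mean <= 0:
            raise ValueError("fold_mean must be > 0")
        if self.n_lots < 1:
            raise ValueError("n_lots must be >= 1")


@dataclass(frozen=True)
class InductionFit:
    ind_max: float
    ind_c50: float
    sse: float
    converged: bool


@dataclass(frozen=True)
class TranswellRecord:
    cell_line: str  # "control" | "MDR1"
    additive: str
    additive_conc_umol_L: float
    direction: str  # "A2B" | "B2A"
    papp_1e6_cm_s: float

    def __post_init__(self) -> None:
        if self.papp_1e6_cm_s <= 0:
            raise ValueError("papp must be > 0")
        if self.additive_conc_umol_L < 0:
            raise ValueError("additive_conc must be >= 0")


@dataclass(frozen=True)
class EffluxSummary:
    additive_conc_umol_L: float
    papp_ratio_control: float
    papp_ratio_mdr1: float
    corrected_ratio: float
    pct_control: float


@dataclass(frozen=True)
class InhibitionFit:
    ic50: Optional[float]
    i_max: float
    hill_c: float
    sse: float
    converged: bool


def fold_induction_model(conc, ind_max: float, ind_c50: float):
    """1 + (Ind_max - 1) * C / (IndC50 + C)."""
    conc = np.asarray(conc, dtype=float)
    return 1.0 + (ind_max - 1.0) * conc / (ind_c50 + conc)


def pct_control_model(conc, i_max: float, ic50: float, hill_c: float):
    """100 * (1 - I_max * I**C / (I**C + IC50**C)); 100 at I = 0."""
    conc = np.asarray(conc, dtype=float)
    out = np.full(conc.shape, 100.0)
    pos = conc > 0
    ic = conc[pos] ** hill_c
    out[pos] = 100.0 * (1.0 - i_max * ic / (ic + ic50**hill_c))
    return out


# fixed log-spaced multi-start lists; deterministic by construction
_N_STARTS = 8


def _c50_starts(conc: np.ndarray) -> np.ndarray:
    lo = max(conc[conc > 0].min() / 10.0, 1e-6)
    hi = conc.max() * 10.0
    return np.geomspace(lo, hi, _N_STARTS)


def fit_fold_induction(
    observations: Iterable[InductionObservation] | Sequence[tuple[float, float]],
    *,
    exclude_concentrations: Sequence[float] = (),
) -> InductionFit:
    """Least-squares Emax fit of mean fold-induction data.

    Accepts either :class:`InductionObservation` records for one
    compound x gene pair, or bare ``(concentration, fold_mean)`` pairs.
    ``exclude_concentrations`` drops listed concentrations (e.g. the
    highest tested concentration, where fewer hepatocyte lots were
    available and cytotoxic fall-off is suspected).
    """
    pairs = []
    for obs in observations:
        if isinstance(obs, InductionObservation):
            pairs.append((obs.concentration_umol_L, obs.fold_mean))
        else:
            c, f = obs
            pairs.append((float(c), float(f)))
    pairs = [(c, f) for c, f in pairs if c not in set(exclude_concentrations)]
    conc = np.array([c for c, _ in pairs if c > 0])
    fold = np.array([f for c, f in pairs if c > 0])
    if len(np.unique(conc)) < 2:
        raise ValueError(
            "unidentifiable fit: need >= 2 distinct positive concentrations"
        )
    if np.all(fold <= 1.0):
        sse = float(np.sum((fold - 1.0) ** 2))
        return InductionFit(ind_max=1.0, ind_c50=math.nan, sse=sse, converged=False)

    def residuals(p):
        return fold_induction_model(conc, p[0], p[1]) - fold

    best = None
    imax0 = max(fold.max(), 1.0 + 1e-6)
    for c50 in _c50_starts(conc):
        res = least_squares(
            residuals, x0=[imax0, c50], bounds=([1.0, 1e-9], [1e4, 1e8])
        )
        if best is None or res.cost < best.cost:
            best = res
    ind_max, ind_c50 = best.x
    return InductionFit(
        ind_max=float(ind_max),
        ind_c50=float(ind_c50),
        sse=float(2.0 * best.cost),
        converged=bool(best.success),
    )


def compute_papp(dqdt_dpm_s: float, area_cm2: float, c0_dpm_ml: float) -> float:
    """Apparent permeability P_app (cm/s) = (dQ/dt) / A / C0."""
    if area_cm2 <= 0 or c0_dpm_ml <= 0:
        raise ValueError("area and C0 must be > 0")
    return dqdt_dpm_s / area_cm2 / c0_dpm_ml


def _round_1dp(x: float, decimals: Optional[int]) -> float:
    return x if decimals is None else float(np.round(x, decimals))


def summarize_efflux(
    records: pd.DataFrame | Iterable[TranswellRecord],
    *,
    round_decimals: Optional[int] = None,
) -> list[EffluxSummary]:
    """Per-concentration efflux summary of a bidirectional transwell dataset.

    For each additive concentration computes the P_app ratio (B->A over
    A->B) per cell line, the corrected ratio (MDR1 over control) and the
    % of control relative to the zero-additive row.

    ``round_decimals`` reproduces the reporting convention under which each
    intermediate ratio is rounded (to that many decimal places) before the
    next division, as assay reports typically tabulate; the default
    computes fully unrounded values.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
        df = df.rename(
            columns={
                "additive_conc_umol_L": "additive_conc_umol_L",
                "papp_1e6_cm_s": "papp_1e6_cm_s",
            }
        )
    required = {"cell_line", "additive_conc_umol_L", "direction", "papp_1e6_cm_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    grouped = df.groupby(["additive_conc_umol_L", "cell_line", "direction"])[
        "papp_1e6_cm_s"
    ].mean()
    concentrations = sorted(df["additive_conc_umol_L"].unique())
    if 0.0 not in concentrations:
        raise ValueError("missing zero-additive row: cannot compute % of control")

    summaries: dict[float, tuple[float, float, float]] = {}
    for conc in concentrations:
        try:
            ratios = {}
            for line in ("control", "MDR1"):
                b2a = grouped[(conc, line, "B2A")]
                a2b = grouped[(conc, line, "A2B")]
                ratios[line] = _round_1dp(b2a / a2b, round_decimals)
        except KeyError as err:
            raise ValueError(
                f"concentration {conc}: missing cell line x direction mean ({err})"
            ) from None
        corrected = _round_1dp(ratios["MDR1"] / ratios["control"], round_decimals)
        summaries[conc] = (ratios["control"], ratios["MDR1"], corrected)

    baseline = summaries[0.0][2]
    return [
        EffluxSummary(
            additive_conc_umol_L=conc,
            papp_ratio_control=summaries[conc][0],
            papp_ratio_mdr1=summaries[conc][1],
            corrected_ratio=summaries[conc][2],
            pct_control=100.0 * summaries[conc][2] / baseline,
        )
        for conc in concentrations
    ]


def pct_of_control_series(
    summaries: Sequence[EffluxSummary],
) -> list[tuple[float, float]]:
    """(concentration, % of control) pairs ready for the inhibition fit."""
    return [(s.additive_conc_umol_L, s.pct_control) for s in summaries]


def fit_pgp_inhibition(
    points: Sequence[tuple[float, float]],
) -> InhibitionFit:
    """Least-squares fit of the % of control inhibition model.

    ``points`` are (additive concentration, % of control) pairs including
    the 100% zero-concentration baseline. I_max (0-1], IC50 and the Hill
    coefficient are all free parameters. Data showing no inhibition
    (monotonically non-decreasing % of control) yield ``converged=False``
    with no IC50.
    """
    pts = sorted((float(c), float(p)) for c, p in points)
    conc = np.array([c for c, _ in pts])
    pct = np.array([p for _, p in pts])
    if np.sum(conc > 0) < 4:
        raise ValueError("need >= 4 positive concentrations plus the 100% baseline")
    if np.all(np.diff(pct) >= 0):
        return InhibitionFit(
            ic50=None, i_max=0.0, hill_c=math.nan, sse=math.nan, converged=False
        )

    def residuals(p):
        return pct_control_model(conc, p[0], p[1], p[2]) - pct

    best = None
    for ic50 in _c50_starts(conc):
        for hill in (0.5, 1.0, 2.0):
            res = least_squares(
                residuals,
                x0=[0.9, ic50, hill],
                bounds=([1e-6, 1e-9, 0.01], [1.0, 1e8, 10.0]),
            )
            if best is None or res.cost < best.cost:
                best = res
    i_max, ic50, hill_c = best.x
    return InhibitionFit(
        ic50=float(ic50),
        i_max=float(i_max),
        hill_c=float(hill_c),
        sse=float(2.0 * best.cost),
        converged=bool(best.success),
    )


def calibrate_indmax(
    ind_max_test: float,
    ind_max_positive_control_invitro: float,
    ind_max_reference_invivo: float,
) -> float:
    """Scale an in vitro induction amplitude to its in vivo equivalent.

    The induction amplitude (Ind_max - 1) of the test compound is
    multiplied by the ratio of the positive control's (rifampicin) in vivo
    reference amplitude to its amplitude in the same in vitro assay:

        1 + (Ind_max,test - 1) * (Ind_max,ref - 1) / (Ind_max,pc - 1)
    """
    if min(ind_max_test, ind_max_positive_control_invitro, ind_max_reference_invivo) < 1:
        raise ValueError("all Ind_max values must be >= 1")
    if ind_max_positive_control_invitro == 1.0:
        raise ZeroDivisionError("positive-control Ind_max of 1 has zero amplitude")
    scale = (ind_max_reference_invivo - 1.0) / (ind_max_positive_control_invitro - 1.0)
    return 1.0 + (ind_max_test - 1.0) * scale
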