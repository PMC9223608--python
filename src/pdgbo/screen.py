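"""Dose–response scoring for the organoid drug screen.

Per-well readouts are normalized to the vehicle (DMSO) median of their
plate, assembled into per-drug dose–response curves (DRCs), summarized as
AUC ratios over log10 concentration, standardized into panel z-scores, and
turned into hit calls:

* ``z < -1``            strong candidate (promising for personalized therapy)
* ``-1 <= z < -0.5``    predicted responder (partial/complete response expected)
* otherwise             non-hit

The z reference population is the screened drug panel of the same sample,
excluding the bortezomib positive control.  QC requires stable vehicle
wells (CV <= 0.2) and an active positive control (top-dose viability <= 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import POSITIVE_CONTROL_ID, four_pl

__all__ = [
    "DoseResponseCurve",
    "DrugScore",
    "ScreenReport",
    "FourPLFit",
    "normalize_viability",
    "build_drc",
    "auc_ratio",
    "panel_zscores",
    "call_hits",
    "qc_screen",
    "fit_4pl",
    "score_screen",
]

Z_STRONG = -1.0
Z_WEAK = -0.5
VEHICLE_CV_MAX = 0.2
POSITIVE_CONTROL_VIABILITY_MAX = 0.5
VIABILITY_FLAG_LEVEL = 1.2


@dataclass
class DoseResponseCurve:
    drug_id: str
    concentrations: np.ndarray  # molar, strictly ascending
    viability: np.ndarray  # mean normalized viability per concentration
    replicates: list[np.ndarray]  # per-concentration replicate values

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if len(self.concentrations) != len(self.viability):
            raise ValueError("concentration/viability length mismatch")
        if (np.diff(self.concentrations) <= 0).any():
            raise ValueError("concentrations must be strictly increasing")
        if (self.viability < 0).any():
            raise ValueError("viabilities must be >= 0")


@dataclass
class DrugScore:
    drug_id: str
    auc_ratio: float
    z: float
    hit_class: str
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class ScreenReport:
    sample_id: str
    scores: list[DrugScore]
    vehicle_cv: dict[str, float]  # per plate
    positive_control_viability: dict[float, float]  # top two doses
    qc_pass: bool
    qc_flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "drug_id": s.drug_id,
                    "auc_ratio": s.auc_ratio,
                    "z": s.z,
                    "hit_class": s.hit_class,
                    "flags": ";".join(s.qc_flags),
                }
                for s in self.scores
            ]
        )

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "qc_pass": self.qc_pass,
            "qc_flags": self.qc_flags,
            "vehicle_cv": self.vehicle_cv,
            "positive_control_viability": {
                f"{c:.3g}": v for c, v in self.positive_control_viability.items()
            },
            "scores": self.to_frame().to_dict(orient="records"),
        }


def normalize_viability(readouts: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Per-well viability fraction: readout / median(vehicle readouts of the plate).

    The vehicle median of each plate maps to exactly 1.0.  Wells above
    1.2x vehicle get a 'high_viability' flag (growth stimulation or artifact);
    nothing is clipped.
    """
    merged = layout.merge(readouts, on=["plate_id", "well"], how="left", validate="1:1")
    if merged["readout"].isna().any():
        missing = merged.loc[merged["readout"].isna(), ["plate_id", "well"]]
        raise ValueError(f"readouts missing for wells:\n{missing.to_string(index=False)}")
    out = []
    for plate, grp in merged.groupby("plate_id", sort=False):
        veh = grp.loc[grp["role"] == "vehicle", "readout"]
        if veh.empty:
            raise ValueError(f"plate {plate}: no vehicle wells")
        med = float(veh.median())
        if med <= 0:
            raise ValueError(f"plate {plate}: non-positive vehicle median")
        g = grp.copy()
        g["viability"] = g["readout"] / med
        out.append(g)
    result = pd.concat(out, ignore_index=True)
    result["flag"] = np.where(
        result["viability"] > VIABILITY_FLAG_LEVEL, "high_viability", ""
    )
    return result


def build_drc(normalized: pd.DataFrame, drug_id: str) -> DoseResponseCurve:
    """Assemble one drug's curve: replicates averaged, concentrations ascending."""
    rows = normalized[normalized["drug_id"] == drug_id]
    if rows.empty:
        raise ValueError(f"no wells for drug {drug_id!r}")
    grouped = rows.groupby("concentration_M")["viability"]
    concs = np.sort(rows["concentration_M"].unique())
    if len(concs) < 2:
        raise ValueError(f"drug {drug_id!r}: need >= 2 concentrations")
    counts = grouped.count()
    gaps = counts[counts < 1]
    if not gaps.empty:
        raise ValueError(f"drug {drug_id!r}: missing concentrations {list(gaps.index)}")
    means = grouped.mean().reindex(concs).to_numpy()
    reps = [grouped.get_group(c).to_numpy() for c in concs]
    return DoseResponseCurve(
        drug_id=drug_id, concentrations=concs, viability=means, replicates=reps
    )


def auc_ratio(drc: DoseResponseCurve) -> float:
    """Trapezoidal AUC of viability over log10 concentration, normalized to 1.0.

    The denominator is the AUC of the constant no-effect curve (viability 1)
    on the same grid, so a flat curve at 1 gives exactly 1.0 and complete
    kill gives 0.0.  Values above 1 (growth stimulation) are permitted.
    """
    if len(drc.concentrations) < 2:
        raise ValueError("need >= 2 points for an AUC")
    if (drc.concentrations <= 0).any():
        raise ValueError("concentrations must be positive")
    x = np.log10(drc.concentrations)
    area = np.trapezoid(drc.viability, x)
    return float(area / (x[-1] - x[0]))


def panel_zscores(
    auc_ratios: dict[str, float], exclude: tuple[str, ...] = (POSITIVE_CONTROL_ID,)
) -> dict[str, float]:
    """Standardize AUC ratios against the screened panel (sample sd, n-1).

    Excluded drugs (the positive control) do not enter the reference panel
    and receive no z-score.  A zero-variance panel yields all-zero z with a
    warning.
    """
    panel = {d: v for d, v in auc_ratios.items() if d not in exclude}
    if len(panel) < 3:
        raise ValueError("need >= 3 non-control drugs for panel z-scores")
    vals = np.array(list(panel.values()), dtype=float)
    mean = vals.mean()
    sd = vals.std(ddof=1)
    if sd == 0:
        warnings.warn("zero panel variance: all z-scores set to 0")
        return {d: 0.0 for d in panel}
    return {d: float((v - mean) / sd) for d, v in panel.items()}


def call_hits(z: float, z_strong: float = Z_STRONG, z_weak: float = Z_WEAK) -> str:
    """Map a panel z-score to a hit class (strict inequalities at both cuts)."""
    if not np.isfinite(z):
        raise ValueError("non-finite z-score")
    if z < z_strong:
        return "strong_candidate"
    if z < z_weak:
        return "predicted_responder"
    return "non_hit"


@dataclass
class FourPLFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    converged: bool
    identifiable: bool
    ci_ic50: tuple[float, float]
    rss: float


def fit_4pl(drc: DoseResponseCurve, n_starts: int = 3) -> FourPLFit:
    """Bounded least-squares 4PL fit with multi-start (validation aid).

    IC50 is searched within 100x of the tested range; a flat curve is
    flagged unidentifiable rather than raising.  Non-convergence yields a
    flagged result, never an exception.
    """
    if len(drc.concentrations) < 4:
        raise ValueError("need >= 4 points to fit a 4PL")
    c = drc.concentrations
    y = drc.viability
    lo_c, hi_c = c.min() / 100.0, c.max() * 100.0
    bounds = ([0.5, 0.0, lo_c, 1e-6], [1.5, 1.0, hi_c, 10.0])
    starts = np.geomspace(c.min(), c.max(), n_starts)
    best = None
    for s in starts:
        p0 = [min(max(y.max(), 0.5), 1.5), min(max(y.min(), 0.0), 1.0), s, 1.0]
        try:
            popt, pcov = curve_fit(
                four_pl, c, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((four_pl(c, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        return FourPLFit(
            np.nan, np.nan, np.nan, np.nan, False, False, (np.nan, np.nan), np.inf
        )
    popt, pcov, rss = best
    se = np.sqrt(np.diag(pcov))
    ci = (popt[2] - 1.96 * se[2], popt[2] + 1.96 * se[2])
    # flat curve: no dynamic range, or IC50 CI swamps the tested range
    span = abs(popt[0] - popt[1])
    identifiable = bool(
        span > 0.05 and np.isfinite(se[2]) and se[2] < 10 * popt[2]
    )
    return FourPLFit(
        top=float(popt[0]),
        bottom=float(popt[1]),
        ic50=float(popt[2]),
        hill=float(popt[3]),
        converged=True,
        identifiable=identifiable,
        ci_ic50=(float(ci[0]), float(ci[1])),
        rss=rss,
    )


def qc_screen(
    normalized: pd.DataFrame,
    positive_control: str = POSITIVE_CONTROL_ID,
) -> tuple[dict[str, float], dict[float, float], bool, list[str]]:
    """Control summaries: per-plate vehicle CV and positive-control viability
    at the top two doses; pass/fail flags.  Never drops drugs."""
    flags: list[str] = []
    vehicle_cv: dict[str, float] = {}
    for plate, grp in normalized.groupby("plate_id", sort=False):
        veh = grp.loc[grp["role"] == "vehicle", "readout"]
        if veh.empty:
            raise ValueError(f"plate {plate}: no vehicle wells")
        cv = float(veh.std(ddof=1) / veh.mean()) if len(veh) > 1 else 0.0
        vehicle_cv[plate] = cv
        if cv > VEHICLE_CV_MAX:
            flags.append("vehicle_unstable")
    pc = normalized[normalized["drug_id"] == positive_control]
    if pc.empty:
        raise ValueError(f"positive control {positive_control!r} not in layout")
    top_doses = np.sort(pc["concentration_M"].unique())[-2:]
    pc_viab = {
        float(c): float(pc.loc[pc["concentration_M"] == c, "viability"].mean())
        for c in top_doses
    }
    if pc_viab[float(top_doses[-1])] > POSITIVE_CONTROL_VIABILITY_MAX:
        flags.append("positive_control_inactive")
    return vehicle_cv, pc_viab, not flags, sorted(set(flags))


def score_screen(
    layout: pd.DataFrame,
    readouts: pd.DataFrame,
    sample_id: str = "sample",
    positive_control: str = POSITIVE_CONTROL_ID,
    z_strong: float = Z_STRONG,
    z_weak: float = Z_WEAK,
) -> ScreenReport:
    """Full scoring pass: normalize -> DRCs -> AUC ratios -> z -> hit calls + QC."""
    normalized = normalize_viability(readouts, layout)
    drug_ids = sorted(
        normalized.loc[
            normalized["role"].isin(["drug", "positive_control"]), "drug_id"
        ].unique()
    )
    aucs: dict[str, float] = {}
    well_flags: dict[str, list[str]] = {}
    for d in drug_ids:
        drc = build_drc(normalized, d)
        aucs[d] = auc_ratio(drc)
        fl = []
        if (drc.viability > VIABILITY_FLAG_LEVEL).any():
            fl.append("high_viability")
        well_flags[d] = fl
    z = panel_zscores(aucs, exclude=(positive_control,))
    vehicle_cv, pc_viab, qc_pass, qc_flags = qc_screen(
        normalized, positive_control=positive_control
    )
    scores = []
    for d in drug_ids:
        if d == positive_control:
            scores.append(
                DrugScore(d, aucs[d], np.nan, "positive_control", well_flags[d])
            )
        else:
            scores.append(
                DrugScore(
                    d, aucs[d], z[d], call_hits(z[d], z_strong, z_weak), well_flags[d]
                )
            )
    return ScreenReport(
        sample_id=sample_id,
        scores=scores,
        vehicle_cv=vehicle_cv,
        positive_control_viability=pc_viab,
        qc_pass=qc_pass,
        qc_flags=qc_flags,
    )
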