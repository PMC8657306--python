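"""Drug-screen analytics: DMSO normalisation, AUC, Z-scores, 4PL, hits.

AUC is defined here as the trapezoidal integral of viability over log10
concentration divided by the log10 range, so a constant viability v has
AUC exactly v and curves on different dose ranges stay comparable.
Z-scores across cell models use the sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

DMSO = "DMSO"

PLATE_COLUMNS = ["plate_id", "well", "compound_id", "concentration", "unit", "model_id", "signal"]


@dataclass
class PlateData:
    """Well-level screen readout; concentrations canonicalised to uM."""

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.wells.copy()
        missing = set(PLATE_COLUMNS) - set(df.columns)
        if "unit" in missing:
            df["unit"] = "uM"
            missing.discard("unit")
        if missing:
            raise ValueError(f"plate table is missing columns {sorted(missing)}")
        df["concentration"] = df["concentration"].astype(float)
        df["signal"] = df["signal"].astype(float)
        unit = df["unit"].astype(str).str.lower()
        known = {"um", "µm", "nm"}
        bad = sorted(set(unit) - known)
        if bad:
            raise ValueError(f"unknown concentration units {bad}; expected uM or nM")
        df.loc[unit == "nm", "concentration"] /= 1000.0
        df["unit"] = "uM"
        if (df["signal"] < 0).any():
            raise ValueError("luminescence signals must be non-negative")
        compounds = df["compound_id"] != DMSO
        if (df.loc[compounds, "concentration"] <= 0).any():
            raise ValueError("compound concentrations must be positive")
        self.wells = df

    @classmethod
    def from_csv(cls, path) -> "PlateData":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.wells[PLATE_COLUMNS].to_csv(path, index=False)

    @property
    def models(self) -> list[str]:
        return sorted(self.wells["model_id"].unique())

    @property
    def compounds(self) -> list[str]:
        ids = self.wells.loc[self.wells["compound_id"] != DMSO, "compound_id"]
        return sorted(ids.unique())


@dataclass
class FitResult:
    """4PL fit: v(c) = bottom + (top - bottom) / (1 + (c/ic50)^hill)."""

    top: float | None
    bottom: float | None
    ic50: float | None
    hill: float | None
    rss: float | None
    converged: bool


@dataclass
class ViabilityCurve:
    compound_id: str
    model_id: str
    points: list[tuple[float, float]]  # (uM, viability), ascending dose
    auc: float | None = None
    fit: FitResult | None = None

    def __post_init__(self) -> None:
        self.points = sorted(self.points)
        if any(v < 0 for _, v in self.points):
            raise ValueError("viability must be non-negative")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def viabilities(self) -> np.ndarray:
        return np.array([v for _, v in self.points])


def normalize_viability(plate: PlateData) -> dict[tuple[str, str], ViabilityCurve]:
    """Normalise signals to the DMSO mean of the same plate and model.

    Replicate wells at a concentration are averaged after normalisation.
    Returns curves keyed by (compound_id, model_id).
    """
    df = plate.wells
    dmso = df[df["compound_id"] == DMSO]
    dmso_mean = dmso.groupby(["plate_id", "model_id"])["signal"].mean()
    if (dmso_mean == 0).any():
        bad = dmso_mean[dmso_mean == 0].index.tolist()
        raise ValueError(f"zero mean DMSO signal on (plate, model) {bad}")

    comp = df[df["compound_id"] != DMSO].copy()
    missing = set(zip(comp["plate_id"], comp["model_id"])) - set(dmso_mean.index)
    if missing:
        raise ValueError(f"no DMSO wells for (plate, model) {sorted(missing)}")
    denom = dmso_mean.loc[
        pd.MultiIndex.from_arrays([comp["plate_id"], comp["model_id"]])
    ].to_numpy()
    comp["viability"] = comp["signal"].to_numpy() / denom

    curves: dict[tuple[str, str], ViabilityCurve] = {}
    grouped = comp.groupby(["compound_id", "model_id", "concentration"])["viability"].mean()
    for (compound, model), sub in grouped.groupby(level=[0, 1]):
        points = [(float(c), float(v)) for (_, _, c), v in sub.items()]
        curves[(compound, model)] = ViabilityCurve(compound, model, points)
    return curves


def compute_auc(curve: ViabilityCurve) -> float:
    """Range-normalised trapezoidal AUC over log10 concentration.

    Viability values are used as-is (no clipping); a constant curve at v
    yields exactly v.
    """
    conc = curve.concentrations
    via = curve.viabilities
    distinct = np.unique(conc)
    if distinct.size < 2:
        raise ValueError(
            f"curve {curve.compound_id}/{curve.model_id}: need >= 2 distinct "
            f"concentrations, got {distinct.size}"
        )
    if (conc <= 0).any():
        raise ValueError("AUC requires strictly positive concentrations")
    x = np.log10(conc)
    return float(np.trapezoid(via, x) / (x[-1] - x[0]))


@dataclass
class ZscoreResult:
    z: dict[str, float]
    degenerate: bool  # all-equal AUCs (sd == 0)


def auc_zscores(aucs: dict[str, float]) -> ZscoreResult:
    """Standardise one compound's AUCs across models: (auc - mean)/sd, ddof=1."""
    if len(aucs) < 2:
        raise ValueError(f"need AUCs for >= 2 models, got {len(aucs)}")
    models = list(aucs)
    vals = np.array([aucs[m] for m in models], dtype=float)
    sd = vals.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(vals).max())):
        return ZscoreResult({m: 0.0 for m in models}, degenerate=True)
    z = (vals - vals.mean()) / sd
    return ZscoreResult(dict(zip(models, map(float, z))), degenerate=False)


def _four_pl(c, top, bottom, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_dose_response(curve: ViabilityCurve) -> FitResult:
    """Least-squares 4PL fit; IC50 is reported missing on non-convergence.

    Zero-dose points are excluded from the residuals but anchor the top
    initialisation.  Bounds: bottom >= 0, ic50 > 0, hill in (0.1, 10].
    """
    conc = curve.concentrations
    via = curve.viabilities
    pos = conc > 0
    c, v = conc[pos], via[pos]
    if np.unique(c).size < 4:
        raise ValueError(
            f"curve {curve.compound_id}/{curve.model_id}: need >= 4 distinct "
            f"nonzero concentrations for a 4PL fit"
        )
    if np.ptp(via) < 1e-12:
        # flat curve: no dose effect, IC50 undefined
        return FitResult(None, None, None, None, None, converged=False)
    top0 = float(via.max())
    bottom0 = float(v.min())
    ic50_0 = float(np.exp(np.mean(np.log(c))))
    p0 = [top0, max(bottom0, 1e-9), ic50_0, 1.0]
    lo = [0.0, 0.0, 1e-12, 0.1 + 1e-9]
    hi = [np.inf, np.inf, np.inf, 10.0]
    p0 = np.clip(p0, lo, hi)
    try:
        popt, _ = curve_fit(
            _four_pl, c, v, p0=p0, bounds=(lo, hi),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except (RuntimeError, ValueError) as exc:
        logger.warning(
            "4PL fit failed for %s/%s: %s", curve.compound_id, curve.model_id, exc
        )
        return FitResult(None, None, None, None, None, converged=False)
    top, bottom, ic50, hill = map(float, popt)
    rss = float(np.sum((v - _four_pl(c, *popt)) ** 2))
    # An IC50 driven to the box bounds means the data carry no dose
    # information in range; treat as non-convergent rather than report it.
    if not np.isfinite(ic50) or ic50 <= 2e-12:
        return FitResult(top, bottom, None, hill, rss, converged=False)
    return FitResult(top, bottom, ic50, hill, rss, converged=True)


@dataclass
class HitFlag:
    compound_id: str
    z_ok: bool
    plasma_ok: bool | None  # None when no plasma value is available
    is_hit: bool


@dataclass
class ScreenResult:
    """Full screen analytics for one plate table."""

    curves: dict[tuple[str, str], ViabilityCurve]
    aucs: dict[tuple[str, str], float]
    zscores: dict[str, ZscoreResult]
    fits: dict[tuple[str, str], FitResult]
    focus_model: str
    hits: list[HitFlag] = field(default_factory=list)

    def z_of(self, compound: str, model: str | None = None) -> float:
        return self.zscores[compound].z[model or self.focus_model]

    def ranked_by_focus_z(self) -> list[tuple[str, float]]:
        pairs = [(c, r.z[self.focus_model]) for c, r in self.zscores.items()]
        return sorted(pairs, key=lambda item: item[1])

    def to_dict(self) -> dict:
        return {
            "focus_model": self.focus_model,
            "auc": {f"{c}/{m}": a for (c, m), a in self.aucs.items()},
            "z": {c: r.z for c, r in self.zscores.items()},
            "degenerate": sorted(c for c, r in self.zscores.items() if r.degenerate),
            "ic50_uM": {
                f"{c}/{m}": f.ic50 for (c, m), f in self.fits.items()
            },
            "hits": [
                {
                    "compound_id": h.compound_id,
                    "z_ok": h.z_ok,
                    "plasma_ok": h.plasma_ok,
                    "is_hit": h.is_hit,
                }
                for h in self.hits
            ],
        }


def analyze_screen(
    plate: PlateData, focus_model: str, fit_curves: bool = True
) -> ScreenResult:
    """Normalise, integrate and standardise a whole screen."""
    if focus_model not in plate.models:
        raise ValueError(
            f"focus model {focus_model!r} not among plate models {plate.models}"
        )
    curves = normalize_viability(plate)
    aucs = {}
    fits = {}
    for key, curve in curves.items():
        curve.auc = compute_auc(curve)
        aucs[key] = curve.auc
        if fit_curves:
            try:
                curve.fit = fit_dose_response(curve)
            except ValueError:
                curve.fit = FitResult(None, None, None, None, None, converged=False)
            fits[key] = curve.fit
    zscores = {}
    for compound in plate.compounds:
        per_model = {m: aucs[(compound, m)] for m in plate.models if (compound, m) in aucs}
        zscores[compound] = auc_zscores(per_model)
    return ScreenResult(curves, aucs, zscores, fits, focus_model)


def select_hits(
    result: ScreenResult,
    plasma_uM: dict[str, float],
    z_max: float = -0.5,
    plasma_factor: float = 2.0,
) -> list[HitFlag]:
    """Flag compounds sensitive in the focus model and clinically reachable.

    A compound is a hit iff its focus-model Z <= ``z_max`` AND its
    focus-model IC50 <= ``plasma_factor`` x plasma concentration.
    Compounds without a plasma value are evaluated on the Z criterion only
    and flagged (``plasma_ok`` is None).
    """
    hits = []
    for compound, zres in sorted(result.zscores.items()):
        z_ok = zres.z[result.focus_model] <= z_max
        fit = result.fits.get((compound, result.focus_model))
        ic50 = fit.ic50 if fit is not None else None
        plasma = plasma_uM.get(compound)
        if plasma is None:
            plasma_ok: bool | None = None
            is_hit = z_ok
        elif ic50 is None:
            plasma_ok = False
            is_hit = False
        else:
            plasma_ok = ic50 <= plasma_factor * plasma
            is_hit = z_ok and plasma_ok
        hits.append(HitFlag(compound, z_ok, plasma_ok, is_hit))
    result.hits = hits
    return hits
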