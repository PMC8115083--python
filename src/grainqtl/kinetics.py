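"""Starch hydrolysis kinetics: resistant starch percentage and predicted glycemic index.

The in-vitro digestion read-out is a glucose time-course.  Hydrolyzed starch
is glucose x 0.9; expressed as a percent of total starch it follows the
first-order model

    C(t) = Calpha * (1 - exp(-k t))

with ``Calpha`` the equilibrium percent hydrolyzed and ``k`` the kinetic
constant (per minute).  The area under C(t) over [t0, tf] has the closed
form used throughout:

    AUC = Calpha*(tf - t0) - (Calpha/k)*(1 - exp(-k*(tf - t0)))

The hydrolysis index HI is the sample AUC as a percent of a white-bread
reference AUC, and the predicted glycemic index is the affine map
PGI = 39.7 + 0.548 * HI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

GLUCOSE_TO_STARCH = 0.9
PGI_INTERCEPT = 39.7
PGI_SLOPE = 0.548
DEFAULT_TIMES = (30.0, 60.0, 90.0, 120.0, 180.0)
DEFAULT_T0 = 0.0
DEFAULT_TF = 180.0
GI_LOW_MAX = 55.0    # pgi < 55 -> low
GI_INTERMEDIATE_MAX = 70.0  # 55 <= pgi <= 70 -> intermediate; above -> high

CALPHA_BOUNDS = (0.0, 110.0)
K_BOUNDS = (1e-8, 1.0)


@dataclass
class HydrolysisCurve:
    """One sample's glucose time-course.

    ``times`` are minutes (strictly increasing; an optional leading t=0 point
    is allowed), ``glucose`` the matching readings, and ``total_starch`` the
    denominator used to express hydrolyzed starch as a percent (same units
    as glucose x 0.9).
    """

    sample: str
    times: np.ndarray
    glucose: np.ndarray
    total_starch: float = 100.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times.shape != self.glucose.shape:
            raise ValueError("times and glucose must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(self.glucose < 0):
            raise ValueError("glucose readings must be non-negative")
        if self.total_starch <= 0:
            raise ValueError("total_starch must be positive")

    def percent_hydrolyzed(self) -> np.ndarray:
        """C(t): hydrolyzed starch as percent of total starch."""
        return self.glucose * GLUCOSE_TO_STARCH / self.total_starch * 100.0


@dataclass
class KineticFit:
    sample: str
    calpha: float
    k: float
    converged: bool
    identifiable: bool
    rss: float
    auc: float = np.nan
    message: str = ""


@dataclass
class PGIResult:
    sample: str
    hi: float
    pgi: float
    gi_class: str


@dataclass
class RSAssayReadout:
    """GOPOD absorbance read-out for the resistant-starch assay.

    ``gopod_factor`` converts net absorbance to micrograms of glucose in the
    read cuvette (from the D-glucose standard); ``dilution`` scales that up
    to the whole extract.  ``sample_mass`` is mg of flour on a dry basis.
    The non-resistant fraction from the pooled supernatants uses its own
    absorbance/dilution and the same blank and factor.
    """

    sample: str
    absorbance_sample: float
    absorbance_blank: float
    gopod_factor: float
    dilution: float
    sample_mass: float
    absorbance_nonrs: float | None = None
    dilution_nonrs: float | None = None

    def __post_init__(self):
        if self.sample_mass <= 0:
            raise ValueError("sample_mass must be positive")
        if self.gopod_factor <= 0:
            raise ValueError("gopod_factor must be positive")


def starch_from_glucose(glucose):
    """Convert glucose to anhydroglucose (starch) units: multiply by 0.9."""
    glucose = np.asarray(glucose, dtype=float)
    if np.any(glucose < 0):
        raise ValueError("glucose must be non-negative")
    out = GLUCOSE_TO_STARCH * glucose
    return float(out) if out.ndim == 0 else out


def first_order_model(t, calpha, k):
    """C(t) = Calpha (1 - e^{-kt})."""
    return calpha * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def fit_first_order(curve: HydrolysisCurve, equilibrium: str = "fitted") -> KineticFit:
    """Least-squares fit of the first-order hydrolysis model to one curve.

    Bounded least squares (Calpha in [0, 110] percent, k in (0, 1] /min)
    with multi-start over k; the start Calpha is the max observed percent.
    ``equilibrium="plugin"`` instead fixes Calpha to the reading nearest
    120 min (the asymptote-as-plug-in alternative) and fits k only.

    All-zero curves return Calpha = 0 with k flagged unidentifiable.
    Fewer than 3 positive time points is an error.
    """
    mask = curve.times > 0
    t = curve.times[mask]
    c = curve.percent_hydrolyzed()[mask]
    if t.size < 3:
        raise ValueError("need at least 3 positive time points to fit")

    if np.allclose(c, 0.0):
        return KineticFit(curve.sample, calpha=0.0, k=np.nan, converged=True,
                          identifiable=False, rss=0.0, auc=0.0,
                          message="all-zero curve: k unidentifiable")

    if equilibrium not in ("fitted", "plugin"):
        raise ValueError(f"unknown equilibrium mode {equilibrium!r}")

    if equilibrium == "plugin":
        calpha0 = float(c[np.argmin(np.abs(t - 120.0))])

        def resid_k(theta):
            return first_order_model(t, calpha0, theta[0]) - c

        best = None
        for k0 in (0.002, 0.01, 0.05, 0.3):
            sol = least_squares(resid_k, x0=[k0],
                                bounds=([K_BOUNDS[0]], [K_BOUNDS[1]]))
            if best is None or sol.cost < best.cost:
                best = sol
        k_hat = float(best.x[0])
        rss = float(2 * best.cost)
        fit = KineticFit(curve.sample, calpha=calpha0, k=k_hat,
                         converged=bool(best.success), identifiable=True,
                         rss=rss)
    else:
        def resid(theta):
            return first_order_model(t, theta[0], theta[1]) - c

        ca0 = min(max(float(c.max()), 1e-3), CALPHA_BOUNDS[1])
        best = None
        for k0 in (0.002, 0.01, 0.05, 0.3):
            sol = least_squares(
                resid, x0=[ca0, k0],
                bounds=([CALPHA_BOUNDS[0], K_BOUNDS[0]],
                        [CALPHA_BOUNDS[1], K_BOUNDS[1]]))
            if best is None or sol.cost < best.cost:
                best = sol
        ca_hat, k_hat = (float(v) for v in best.x)
        rss = float(2 * best.cost)
        identifiable = k_hat > K_BOUNDS[0] * 10
        fit = KineticFit(curve.sample, calpha=ca_hat, k=k_hat,
                         converged=bool(best.success),
                         identifiable=identifiable, rss=rss,
                         message="" if best.success else best.message)
    if fit.converged and np.isfinite(fit.k):
        fit.auc = auc_first_order(fit.calpha, fit.k)
    return fit


def auc_first_order(calpha: float, k: float,
                    t0: float = DEFAULT_T0, tf: float = DEFAULT_TF) -> float:
    """Closed-form area under C(t) = Calpha(1-e^{-kt}) over [t0, tf].

    AUC = Calpha*(tf-t0) - (Calpha/k)*(1 - e^{-k(tf-t0)}).
    """
    if not tf > t0 or t0 < 0:
        raise ValueError("require tf > t0 >= 0")
    if k <= 0:
        raise ValueError("kinetic constant k must be positive")
    if calpha < 0:
        raise ValueError("Calpha must be non-negative")
    dt = tf - t0
    return calpha * dt - (calpha / k) * (1.0 - np.exp(-k * dt))


def hydrolysis_index(auc_sample: float, auc_reference: float) -> float:
    """HI: sample AUC as a percent of the white-bread reference AUC."""
    if auc_reference <= 0:
        raise ValueError("reference AUC must be positive")
    if auc_sample < 0:
        raise ValueError("sample AUC must be non-negative")
    return 100.0 * auc_sample / auc_reference


def predicted_gi(hi: float) -> float:
    """PGI = 39.7 + 0.548 * HI."""
    if hi < 0:
        raise ValueError("hydrolysis index must be non-negative")
    return PGI_INTERCEPT + PGI_SLOPE * hi


def classify_gi(pgi: float) -> str:
    """GI band: low (< 55), intermediate (55-70), high (> 70)."""
    if not np.isfinite(pgi):
        raise ValueError("pgi must be finite")
    if pgi < GI_LOW_MAX:
        return "low"
    if pgi <= GI_INTERMEDIATE_MAX:
        return "intermediate"
    return "high"


def rs_percent(readout: RSAssayReadout) -> tuple[float, float]:
    """Resistant-starch percent (and non-resistant percent) from absorbances.

    glucose = net absorbance x gopod_factor x dilution; the percent is
    glucose x 0.9 / sample_mass x 100 with glucose in ug and mass in mg.
    Negative net absorbance clamps to zero with a warning.  The non-RS
    percent is NaN when no supernatant absorbance was supplied.
    """

    def _pct(net_abs: float, dilution: float) -> float:
        if net_abs < 0:
            warnings.warn(
                f"{readout.sample}: net absorbance {net_abs:.4f} < 0, clamped to 0",
                UserWarning, stacklevel=3)
            net_abs = 0.0
        glucose_ug = net_abs * readout.gopod_factor * dilution
        mass_ug = readout.sample_mass * 1000.0
        return glucose_ug * GLUCOSE_TO_STARCH / mass_ug * 100.0

    rs = _pct(readout.absorbance_sample - readout.absorbance_blank,
              readout.dilution)
    if readout.absorbance_nonrs is None:
        non_rs = np.nan
    else:
        non_rs = _pct(readout.absorbance_nonrs - readout.absorbance_blank,
                      readout.dilution_nonrs or readout.dilution)
    return rs, non_rs


def pgi_from_curve(curve: HydrolysisCurve, auc_reference: float,
                   equilibrium: str = "fitted") -> tuple[KineticFit, PGIResult]:
    """Fit one curve and chain AUC -> HI -> PGI -> GI class."""
    fit = fit_first_order(curve, equilibrium=equilibrium)
    if not np.isfinite(fit.auc):
        res = PGIResult(curve.sample, hi=np.nan, pgi=np.nan, gi_class="")
        return fit, res
    hi = hydrolysis_index(fit.auc, auc_reference)
    pgi = predicted_gi(hi)
    return fit, PGIResult(curve.sample, hi=hi, pgi=pgi, gi_class=classify_gi(pgi))


def curves_from_frame(df: pd.DataFrame) -> list[HydrolysisCurve]:
    """Build curves from a table with ``time_<minutes>`` glucose columns.

    Expected columns: ``sample``, ``time_30 ... time_180`` (any strictly
    increasing set of minute suffixes), ``total_starch``; an optional
    boolean ``is_reference`` column marks the white-bread reference row.
    """
    time_cols = sorted(
        (c for c in df.columns if c.startswith("time_")),
        key=lambda c: float(c.split("_", 1)[1]))
    if len(time_cols) < 3:
        raise ValueError("need at least 3 time_<min> columns")
    times = np.array([float(c.split("_", 1)[1]) for c in time_cols])
    curves = []
    for _, row in df.iterrows():
        curves.append(HydrolysisCurve(
            sample=str(row["sample"]),
            times=times,
            glucose=row[time_cols].to_numpy(dtype=float),
            total_starch=float(row.get("total_starch", 100.0)),
        ))
    return curves


def pgi_table(df: pd.DataFrame, auc_reference: float | None = None,
              equilibrium: str = "fitted") -> pd.DataFrame:
    """Run the full PGI pipeline on a curve table.

    The reference AUC is either supplied or computed from the row(s) with
    ``is_reference`` truthy (their fitted AUCs are averaged).  Rows that
    fail to fit are reported with NaNs and a reason in ``note``.
    """
    curves = curves_from_frame(df)
    ref_flags = df.get("is_reference")
    if auc_reference is None:
        if ref_flags is None or not ref_flags.astype(bool).any():
            raise ValueError("no reference AUC supplied and no is_reference row")
        ref_aucs = []
        for curve, flag in zip(curves, ref_flags.astype(bool)):
            if flag:
                f = fit_first_order(curve, equilibrium=equilibrium)
                if np.isfinite(f.auc) and f.auc > 0:
                    ref_aucs.append(f.auc)
        if not ref_aucs:
            raise ValueError("reference curve(s) failed to fit")
        auc_reference = float(np.mean(ref_aucs))

    rows = []
    for curve in curves:
        note = ""
        try:
            fit, res = pgi_from_curve(curve, auc_reference, equilibrium=equilibrium)
        except ValueError as exc:
            fit = KineticFit(curve.sample, np.nan, np.nan, False, False, np.nan)
            res = PGIResult(curve.sample, np.nan, np.nan, "")
            note = str(exc)
        if not fit.converged:
            note = note or fit.message or "fit did not converge"
        elif not fit.identifiable:
            note = note or fit.message
        rows.append({
            "sample": curve.sample, "calpha": fit.calpha, "k": fit.k,
            "auc": fit.auc, "hi": res.hi, "pgi": res.pgi,
            "gi_class": res.gi_class, "note": note,
        })
    return pd.DataFrame(rows)
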