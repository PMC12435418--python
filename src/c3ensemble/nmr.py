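"""NMR observables: chemical-shift perturbations, relaxation fits, hetNOE,
and CPMG relaxation-dispersion fitting with Rex extraction.

Conventions
-----------
* CSP: combined amide perturbation ``sqrt(dH^2 + (0.14 dN)^2)`` in ppm, the
  standard 1H/15N weighting.
* CPMG: ``nu_cpmg = 1/(2*delta)`` where ``delta`` is the spacing between
  successive 180-degree pulses.  The two-site exchange model is the general
  Carver-Richards closed form (equal intrinsic R2 in both states); the
  Luz-Meiboom fast-exchange expression is available as a reduced model.
* 15N offsets: ``dw`` in ppm converts to rad/s using the 15N Larmor
  frequency, 0.1013757 times the stated 1H field in MHz.
* Rex is the model-predicted ``R2eff(nu->0) - R2eff(nu->inf)``, evaluated
  analytically from the fitted parameters, not from data endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .io import ShiftTable

__all__ = [
    "CSPProfile",
    "RelaxationSeries",
    "DispersionCurve",
    "DispersionFit",
    "compute_csp",
    "fit_exponential_rate",
    "compute_hetnoe",
    "r2eff_from_ct_cpmg",
    "carver_richards_r2eff",
    "luz_meiboom_r2eff",
    "rex_from_parameters",
    "dw_ppm_to_rad",
    "fit_dispersion",
]

GAMMA_RATIO_15N = 0.1013757  # |gamma_N/gamma_H|: 15N Larmor per 1H MHz


# ---------------------------------------------------------------------------
# chemical-shift perturbations
# ---------------------------------------------------------------------------


@dataclass
class CSPProfile:
    """Per-residue combined amide chemical-shift perturbation.

    ``profile`` columns: residue_number, delta_ppm (NaN where either state
    lacks the amide H or N assignment), plus one boolean flag column per
    threshold (``above_0.3`` etc.).
    """

    profile: pd.DataFrame
    scale: float = 0.14
    thresholds: tuple[float, ...] = (0.3, 1.0)


def compute_csp(
    apo: ShiftTable,
    holo: ShiftTable,
    scale: float = 0.14,
    thresholds: tuple[float, ...] = (0.3, 1.0),
) -> CSPProfile:
    """Combined amide CSP ``sqrt(dH^2 + (scale*dN)^2)`` per residue.

    Residues missing the amide H or N shift in either state are reported as
    absent (NaN), never as zero.  Symmetric in the two states.
    """

    def amide(table: ShiftTable) -> pd.DataFrame:
        ent = table.entries
        sub = ent[ent["atom_name"].isin(["H", "N"])]
        return sub.pivot(index="residue_number", columns="atom_name", values="shift")

    a = amide(apo)
    b = amide(holo)
    residues = sorted(set(a.index) | set(b.index))
    rows = []
    for res in residues:
        vals = {}
        for at in ("H", "N"):
            va = a[at].get(res, np.nan) if at in a.columns else np.nan
            vb = b[at].get(res, np.nan) if at in b.columns else np.nan
            vals[at] = (va, vb)
        if any(np.isnan(v) for pair in vals.values() for v in pair):
            delta = np.nan
        else:
            dh = vals["H"][1] - vals["H"][0]
            dn = vals["N"][1] - vals["N"][0]
            delta = float(np.sqrt(dh**2 + (scale * dn) ** 2))
        rows.append({"residue_number": res, "delta_ppm": delta})
    df = pd.DataFrame(rows)
    for thr in thresholds:
        df[f"above_{thr:g}"] = df["delta_ppm"] > thr
    return CSPProfile(profile=df, scale=scale, thresholds=tuple(thresholds))


# ---------------------------------------------------------------------------
# exponential relaxation
# ---------------------------------------------------------------------------


@dataclass
class RelaxationSeries:
    """An exponential relaxation decay: intensities vs delay times (s)."""

    delays: np.ndarray
    intensities: np.ndarray
    errors: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.size == 0:
            raise ValueError("delay list must be non-empty")
        if np.any(self.delays < 0):
            raise ValueError("delays must be >= 0")
        if self.intensities.shape != self.delays.shape:
            raise ValueError("intensities must match delays")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)


def fit_exponential_rate(series: RelaxationSeries) -> tuple[float, float]:
    """Fit ``I(t) = I0 exp(-R t)`` by nonlinear least squares.

    Returns ``(rate, stderr)`` in 1/s.  The initial guess comes from a
    log-linear regression on the positive intensities; if fewer than two
    are positive, a coarse rate grid seeds the fit instead.
    """
    t = series.delays
    y = series.intensities
    if len(np.unique(t)) < 3:
        raise ValueError("exponential fit requires >= 3 distinct delays")
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        r0 = max(-slope, 1e-6)
        i0 = float(np.exp(intercept))
    else:
        span = max(t.max(), 1e-9)
        r0 = 1.0 / span
        i0 = float(np.abs(y).max())

    def residual(params):
        model = params["i0"].value * np.exp(-params["rate"].value * t)
        res = y - model
        if series.errors is not None:
            res = res / series.errors
        return res

    best = None
    for rate_seed in {r0, 0.1 / max(t.max(), 1e-9), 3.0 / max(t.max(), 1e-9)}:
        params = Parameters()
        params.add("i0", value=i0, min=0)
        params.add("rate", value=rate_seed, min=1e-9)
        out = minimize(residual, params)
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not best.success:
        raise RuntimeError("exponential fit did not converge")
    rate = float(best.params["rate"].value)
    stderr = best.params["rate"].stderr
    return rate, float(stderr) if stderr is not None else float("nan")


def compute_hetnoe(
    i_sat: float,
    i_ref: float,
    err_sat: float = 0.0,
    err_ref: float = 0.0,
) -> tuple[float, float]:
    """Steady-state heteronuclear NOE ratio I_sat/I_ref with propagated error."""
    if i_ref == 0:
        raise ValueError("reference intensity must be nonzero")
    ratio = i_sat / i_ref
    rel_sat = (err_sat / i_sat) ** 2 if i_sat != 0 else 0.0
    err = abs(ratio) * np.sqrt(rel_sat + (err_ref / i_ref) ** 2)
    return float(ratio), float(err)


# ---------------------------------------------------------------------------
# CPMG relaxation dispersion
# ---------------------------------------------------------------------------


@dataclass
class DispersionCurve:
    """R2,eff as a function of nu_CPMG at a stated 1H field."""

    nu_hz: np.ndarray
    r2eff: np.ndarray
    field_mhz: float
    errors: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.nu_hz = np.asarray(self.nu_hz, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        if np.any(self.nu_hz <= 0) or np.any(np.diff(self.nu_hz) <= 0):
            raise ValueError("nu grid must be positive and strictly ascending")
        if self.r2eff.shape != self.nu_hz.shape:
            raise ValueError("r2eff must match nu grid")


@dataclass
class DispersionFit:
    """Outcome of per-residue dispersion fitting with AIC model selection."""

    model: str  # "no-exchange" | "two-site"
    r20: float
    rex: float
    kex: float | None = None
    pb: float | None = None
    dw_ppm: float | None = None
    chisqr: float = np.nan
    aic_flat: float = np.nan
    aic_exchange: float = np.nan


def dw_ppm_to_rad(dw_ppm: float, field_mhz: float) -> float:
    """Convert a 15N shift difference in ppm to rad/s at a 1H field (MHz)."""
    return 2.0 * np.pi * dw_ppm * GAMMA_RATIO_15N * field_mhz


def carver_richards_r2eff(
    nu_hz: np.ndarray, r20: float, kex: float, pb: float, dw_rad: float
) -> np.ndarray:
    """General two-site exchange R2,eff (Carver-Richards closed form).

    Equal intrinsic R2 in both states; ``nu_hz = 1/(2*delta)`` with delta
    the pi-pulse spacing.  Numerically safe for large exchange/slow pulsing
    via a log-space branch of the arccosh term.
    """
    nu = np.asarray(nu_hz, dtype=float)
    pa = 1.0 - pb
    psi = kex**2 - dw_rad**2
    zeta = -2.0 * dw_rad * kex * (pa - pb)
    s = np.sqrt(psi**2 + zeta**2)
    dplus = 0.5 * (1.0 + (psi + 2.0 * dw_rad**2) / s)
    dminus = 0.5 * (-1.0 + (psi + 2.0 * dw_rad**2) / s)
    t180 = 1.0 / (2.0 * nu)
    eta_p = (t180 / np.sqrt(2.0)) * np.sqrt(np.maximum(psi + s, 0.0))
    eta_m = (t180 / np.sqrt(2.0)) * np.sqrt(np.maximum(-psi + s, 0.0))
    out = np.empty_like(nu)
    large = eta_p > 350.0
    if np.any(~large):
        val = dplus * np.cosh(eta_p[~large]) - dminus * np.cos(eta_m[~large])
        out[~large] = np.arccosh(np.maximum(val, 1.0))
    if np.any(large):
        # arccosh(D+ cosh x - ...) ~ x + log(D+) for large x
        out[large] = eta_p[large] + np.log(max(dplus, 1e-300))
    return r20 + 0.5 * (kex - out / t180)


def luz_meiboom_r2eff(
    nu_hz: np.ndarray, r20: float, kex: float, pb: float, dw_rad: float
) -> np.ndarray:
    """Fast-exchange (Luz-Meiboom) R2,eff under the same nu convention."""
    nu = np.asarray(nu_hz, dtype=float)
    phi = pb * (1.0 - pb) * dw_rad**2
    x = kex / (4.0 * nu)
    return r20 + (phi / kex) * (1.0 - np.tanh(x) / x)


def rex_from_parameters(kex: float, pb: float, dw_rad: float) -> float:
    """Analytic Rex = R2eff(nu->0) - R2eff(nu->inf) of the two-site model."""
    pa = 1.0 - pb
    psi = kex**2 - dw_rad**2
    zeta = -2.0 * dw_rad * kex * (pa - pb)
    s = np.sqrt(psi**2 + zeta**2)
    return float(0.5 * (kex - np.sqrt(max(psi + s, 0.0) / 2.0)))


def r2eff_from_ct_cpmg(
    i_nu: np.ndarray, i0: float, t_cp: float
) -> np.ndarray:
    """Constant-time CPMG conversion ``R2eff = -ln(I_nu/I_0)/T_cp``.

    Non-positive intensities yield NaN (flagged points, excluded from fits).
    """
    if i0 <= 0:
        raise ValueError("reference intensity I_0 must be positive")
    if t_cp <= 0:
        raise ValueError("constant-time delay T_cp must be positive")
    i_nu = np.asarray(i_nu, dtype=float)
    out = np.full(i_nu.shape, np.nan)
    ok = i_nu > 0
    out[ok] = -np.log(i_nu[ok] / i0) / t_cp
    return out


def _fit_flat(nu: np.ndarray, y: np.ndarray, err: np.ndarray | None):
    if err is None:
        r20 = float(y.mean())
        rss = float(((y - r20) ** 2).sum())
    else:
        w = 1.0 / err**2
        r20 = float((y * w).sum() / w.sum())
        rss = float((((y - r20) / err) ** 2).sum())
    return r20, rss


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def fit_dispersion(
    curve: DispersionCurve,
    delta_aic: float = 2.0,
    kex_starts: tuple[float, ...] = (200.0, 1000.0, 3000.0, 10000.0),
    dw_starts_ppm: tuple[float, ...] = (0.5, 2.0, 5.0),
) -> DispersionFit:
    """Fit a dispersion curve with no-exchange and two-site models.

    The two-site (Carver-Richards) fit is multi-started over a kex/dw grid;
    the exchange model is preferred only when its AIC undercuts the flat
    model by more than ``delta_aic``.  Rex is evaluated analytically from
    the fitted parameters (0 for the flat model).
    """
    ok = np.isfinite(curve.r2eff)
    nu = curve.nu_hz[ok]
    y = curve.r2eff[ok]
    err = curve.errors[ok] if curve.errors is not None else None
    if nu.size < 5 or nu.max() / nu.min() < 10.0:
        raise ValueError(
            "dispersion fit requires >= 5 nu points spanning at least a decade"
        )
    n = nu.size
    r20_flat, rss_flat = _fit_flat(nu, y, err)
    aic_flat = _aic(rss_flat, n, 1)

    def residual(params):
        model = carver_richards_r2eff(
            nu,
            params["r20"].value,
            params["kex"].value,
            params["pb"].value,
            dw_ppm_to_rad(params["dw_ppm"].value, curve.field_mhz),
        )
        res = y - model
        return res if err is None else res / err

    best = None
    for kex0 in kex_starts:
        for dw0 in dw_starts_ppm:
            params = Parameters()
            params.add("r20", value=max(y.min(), 0.1), min=0.0)
            params.add("kex", value=kex0, min=1.0, max=1e6)
            params.add("pb", value=0.05, min=1e-6, max=0.499)
            params.add("dw_ppm", value=dw0, min=1e-4, max=50.0)
            try:
                out = minimize(residual, params, nan_policy="omit")
            except Exception:
                continue
            if best is None or out.chisqr < best.chisqr:
                best = out
    if best is None:
        raise RuntimeError("all dispersion fit starts failed")
    aic_exch = _aic(float(best.chisqr), n, 4)

    if aic_flat - aic_exch > delta_aic:
        p = best.params
        dw_rad = dw_ppm_to_rad(p["dw_ppm"].value, curve.field_mhz)
        return DispersionFit(
            model="two-site",
            r20=float(p["r20"].value),
            rex=rex_from_parameters(p["kex"].value, p["pb"].value, dw_rad),
            kex=float(p["kex"].value),
            pb=float(p["pb"].value),
            dw_ppm=float(p["dw_ppm"].value),
            chisqr=float(best.chisqr),
            aic_flat=float(aic_flat),
            aic_exchange=float(aic_exch),
        )
    return DispersionFit(
        model="no-exchange",
        r20=r20_flat,
        rex=0.0,
        chisqr=rss_flat,
        aic_flat=float(aic_flat),
        aic_exchange=float(aic_exch),
    )
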