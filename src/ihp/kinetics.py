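"""Autophosphorylation kinetics: two-component global model and saturation fits.

The central model describes the phosphorylated fraction of a large excess of
substrate (kinase-dead) holoenzymes phosphorylated by an active kinase at
concentration ``c`` (nM):

    f(t) = 1 - A1 * exp(-r1 * t) - (1 - A1) * exp(-c * k2 * t)

The first component (amplitude A1, rate r1 in 1/min) is independent of the
active-kinase concentration; the second scales linearly with ``c``
(k2 in 1/(nM min)), the signature expected of collisional inter-holoenzyme
phosphorylation.  A single (A1, r1, k2) triple is fitted globally across
all concentrations, weighting residuals by the inverse replicate SD; at
saturating concentrations the curve is reduced to the single
concentration-dependent component by fixing A1 = 0.

Simple saturation time courses are fitted with the Langmuir form
``y(t) = ymax * t / (t_half + t)``, whose half-time is ``t_half`` by
construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

TIMECOURSE_COLUMNS = ("conc_nM", "time_min", "replicate", "phospho", "total")


class FitError(RuntimeError):
    """Raised when a fit cannot converge; carries diagnostics."""

    def __init__(self, message: str, best=None, diagnostics: dict | None = None):
        super().__init__(message)
        self.best = best
        self.diagnostics = diagnostics or {}


def eval_model(
    t, a1: float, r1: float, k2: float, c: float
):
    """Two-component phosphorylation model; accepts scalar or array ``t``."""
    if not 0.0 <= a1 <= 1.0:
        raise ValueError(f"A1 must lie in [0, 1], got {a1}")
    if r1 < 0 or k2 < 0 or c < 0:
        raise ValueError("rates and concentration must be nonnegative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = 1.0 - a1 * np.exp(-r1 * t) - (1.0 - a1) * np.exp(-c * k2 * t)
    return out if out.ndim else float(out)


@dataclass
class GlobalFitResult:
    """Shared two-component fit over all concentrations."""

    a1: float
    r1: float
    k2: float
    single_component: dict[float, bool]
    covariance: np.ndarray | None
    weighted_ssr: float
    half_times: dict[float, float] = field(default_factory=dict)
    n_points: int = 0

    def model(self, t, c: float):
        a1 = 0.0 if self.single_component.get(c, False) else self.a1
        return eval_model(t, a1, self.r1, self.k2, c)


@dataclass
class LangmuirFit:
    """Saturation-isotherm fit y = ymax * t / (t_half + t)."""

    ymax: float
    t_half: float
    degenerate: bool = False


def normalize_curve(table: pd.DataFrame, fit_max: float) -> pd.DataFrame:
    """Scale phospho/total ratios by the fitted curve maximum.

    Rows with zero total signal cannot be normalized; they are excluded,
    logged, and counted in ``result.attrs['n_excluded']``.
    """
    if fit_max <= 0:
        raise ValueError(f"fit_max must be positive, got {fit_max}")
    out = table.copy()
    bad = out["total"] <= 0
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("normalize_curve: excluding %d rows with zero total signal", n_bad)
    out = out[~bad].copy()
    out["normalized"] = (out["phospho"] / out["total"]) / fit_max
    out.attrs["n_excluded"] = n_bad
    return out


def _exp_rise(t, ymax, a1, r1, r2):
    return ymax * (1.0 - a1 * np.exp(-r1 * t) - (1.0 - a1) * np.exp(-r2 * t))


def estimate_fit_max(table: pd.DataFrame, components: str = "auto") -> float:
    """Preliminary curve maximum from a one- or two-exponential rise fit.

    Fits ``ymax * (1 - A1 e^{-r1 t} - (1-A1) e^{-r2 t})`` to the
    phospho/total ratio of one dataset; with ``components='auto'`` the one-
    or two-component variant is chosen by AICc.  Returns the fitted
    asymptote ``ymax``, used to normalize the curve to its own maximum.
    """
    t = table["time_min"].to_numpy(float)
    y = (table["phospho"] / table["total"]).to_numpy(float)
    if len(t) < 3:
        raise FitError("need >=3 points for a preliminary maximum fit")
    ymax0 = max(float(np.max(y)), 1e-9)
    r0 = 1.0 / max(float(np.median(t)), 1e-9)

    def _try(n_comp: int):
        if n_comp == 1:
            f = lambda tt, ymax, r: _exp_rise(tt, ymax, 1.0, r, r)
            p0, bounds = [ymax0, r0], ([1e-12, 1e-9], [np.inf, np.inf])
        else:
            f = _exp_rise
            p0 = [ymax0, 0.5, r0 * 3, r0 / 3]
            bounds = ([1e-12, 0.0, 1e-9, 1e-9], [np.inf, 1.0, np.inf, np.inf])
        popt, _ = optimize.curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=20000)
        rss = float(np.sum((f(t, *popt) - y) ** 2))
        k = len(popt)
        n = len(t)
        aicc = n * math.log(max(rss, 1e-300) / n) + 2 * k
        if n - k - 1 > 0:
            aicc += 2 * k * (k + 1) / (n - k - 1)
        return popt[0], aicc

    if components == "one":
        return float(_try(1)[0])
    if components == "two":
        return float(_try(2)[0])
    results = []
    for n_comp in (1, 2):
        try:
            results.append(_try(n_comp))
        except RuntimeError:
            pass
    if not results:
        raise FitError("preliminary maximum fit failed for both 1- and 2-component forms")
    return float(min(results, key=lambda r: r[1])[0])


def _aggregate(table: pd.DataFrame) -> pd.DataFrame:
    g = table.groupby(["conc_nM", "time_min"])["normalized"]
    agg = g.agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan,
                n="count").reset_index()
    return agg


def _weights(agg: pd.DataFrame) -> np.ndarray:
    """Per-(concentration, time) weights 1/SD, floored at the curve median.

    Replicate SDs estimated from a handful of replicates are themselves
    noisy; an accidentally tiny SD would dominate the fit, so each SD is
    floored at the median SD of its concentration's curve.  A zero or
    unavailable SD (single replicate) likewise falls back to the median;
    if a whole curve lacks usable SDs the weight defaults to 1.
    """
    w = np.empty(len(agg))
    for c, idx in agg.groupby("conc_nM").groups.items():
        sd = agg.loc[idx, "sd"].to_numpy(float)
        usable = sd[np.isfinite(sd) & (sd > 0)]
        fallback = float(np.median(usable)) if len(usable) else np.nan
        if not np.isfinite(fallback):
            w[agg.index.get_indexer(idx)] = 1.0
        else:
            sd_eff = np.where(np.isfinite(sd) & (sd > 0), sd, fallback)
            w[agg.index.get_indexer(idx)] = 1.0 / np.maximum(sd_eff, fallback)
    return w


def fit_global(
    table: pd.DataFrame,
    saturating: set[float] | frozenset[float] = frozenset(),
    n_starts: int = 5,
) -> GlobalFitResult:
    """SD-weighted global fit of the two-component model.

    ``table`` holds normalized time courses for all concentrations
    (columns conc_nM, time_min, replicate, normalized).  Curves whose
    concentration is in ``saturating`` use the single concentration-
    dependent component (A1 fixed to 0).  Two-exponential surfaces are
    multimodal, so the bounded least-squares fit is restarted from
    ``n_starts`` spread initial points and the best weighted residual wins.
    """
    concs = sorted(table["conc_nM"].unique())
    if len(concs) < 2:
        raise FitError("global fit requires >=2 concentrations")
    for c in concs:
        if table[table["conc_nM"] == c]["time_min"].nunique() < 3:
            raise FitError(f"concentration {c} nM has <3 timepoints")
    agg = _aggregate(table)
    if len(agg) < 3:
        raise FitError("fewer aggregated points than parameters")
    w = _weights(agg)
    t = agg["time_min"].to_numpy(float)
    y = agg["mean"].to_numpy(float)
    c_arr = agg["conc_nM"].to_numpy(float)
    sat = np.isin(c_arr, sorted(saturating))

    def residual(params):
        a1 = params["a1"].value
        r1 = params["r1"].value
        k2 = params["k2"].value
        a1_eff = np.where(sat, 0.0, a1)
        model = 1.0 - a1_eff * np.exp(-r1 * t) - (1.0 - a1_eff) * np.exp(-c_arr * k2 * t)
        return w * (model - y)

    t_scale = float(np.median(t[t > 0])) if np.any(t > 0) else 1.0
    c_scale = float(np.median(c_arr))
    a1_starts = np.linspace(0.1, 0.9, n_starts)
    r1_starts = np.geomspace(0.1 / t_scale, 10.0 / t_scale, n_starts)
    k2_starts = np.geomspace(0.1 / (t_scale * c_scale), 10.0 / (t_scale * c_scale), n_starts)

    best = None
    for a1_0, r1_0, k2_0 in zip(a1_starts, r1_starts, k2_starts):
        params = lmfit.Parameters()
        params.add("a1", value=a1_0, min=0.0, max=1.0)
        params.add("r1", value=r1_0, min=1e-9)
        params.add("k2", value=k2_0, min=1e-12)
        try:
            res = lmfit.minimize(residual, params, method="leastsq", nan_policy="raise")
        except Exception:
            continue
        ssr = float(np.sum(res.residual**2))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    if best is None:
        raise FitError("global fit failed from all starts",
                       diagnostics={"n_starts": n_starts})
    ssr, res = best
    a1 = float(res.params["a1"].value)
    r1 = float(res.params["r1"].value)
    k2 = float(res.params["k2"].value)
    covar = np.asarray(res.covar) if res.covar is not None else None
    result = GlobalFitResult(
        a1=a1, r1=r1, k2=k2,
        single_component={c: bool(c in saturating) for c in concs},
        covariance=covar, weighted_ssr=ssr, n_points=len(agg),
    )
    for c in concs:
        try:
            result.half_times[c] = half_time(result, c)
        except ValueError:
            result.half_times[c] = float("nan")
    return result


def fit_langmuir(table: pd.DataFrame) -> LangmuirFit:
    """Least-squares Langmuir fit of one time course.

    Uses the ``normalized`` column when present, the phospho/total ratio
    otherwise.  A fitted half-time collapsing toward zero relative to the
    sampled times is flagged degenerate.
    """
    t = table["time_min"].to_numpy(float)
    if "normalized" in table.columns:
        y = table["normalized"].to_numpy(float)
    else:
        y = (table["phospho"] / table["total"]).to_numpy(float)
    if len(np.unique(t)) < 3:
        raise FitError("Langmuir fit requires >=3 timepoints")

    def f(tt, ymax, t_half):
        return ymax * tt / (t_half + tt)

    p0 = [max(float(np.max(y)), 1e-9), max(float(np.median(t)), 1e-9)]
    try:
        popt, _ = optimize.curve_fit(
            f, t, y, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"Langmuir fit did not converge: {exc}") from exc
    ymax, t_half = float(popt[0]), float(popt[1])
    degenerate = t_half < 1e-6 * max(float(np.max(t)), 1.0)
    if degenerate:
        logger.warning("fit_langmuir: near-zero half-time %.3g min, flagged degenerate", t_half)
    return LangmuirFit(ymax=ymax, t_half=t_half, degenerate=degenerate)


def half_time(params, c: float | None = None, tol: float = 1e-6) -> float:
    """Smallest time at which the model reaches half of its maximum.

    For a Langmuir fit this is ``t_half`` by definition.  For the
    two-component model the limits are 0 and 1, so the half-time solves
    f(t) = 1/2; when a single exponential remains (A1 = 1, or A1 = 0 at a
    saturating concentration) the closed form ln 2 / rate is returned,
    otherwise the root is bracketed and bisected to ``tol`` minutes.
    """
    if isinstance(params, LangmuirFit):
        return params.t_half
    if isinstance(params, GlobalFitResult):
        if c is None:
            raise ValueError("half_time of a global fit needs a concentration")
        a1 = 0.0 if params.single_component.get(c, False) else params.a1
        r1, k2 = params.r1, params.k2
    else:
        a1, r1, k2 = params
        if c is None:
            raise ValueError("half_time needs a concentration")
    if not 0.0 <= a1 <= 1.0:
        raise ValueError(f"A1 must lie in [0, 1], got {a1}")

    if a1 == 1.0:
        if r1 <= 0:
            raise ValueError("degenerate parameters: model never reaches 0.5")
        return math.log(2.0) / r1
    if a1 == 0.0:
        rate = c * k2
        if rate <= 0:
            raise ValueError("degenerate parameters: model never reaches 0.5")
        return math.log(2.0) / rate

    def f(t):
        return eval_model(t, a1, r1, k2, c) - 0.5

    hi = 1.0
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 2.0
    else:
        raise ValueError("degenerate parameters: model never reaches 0.5")
    return float(optimize.bisect(f, 0.0, hi, xtol=tol))
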