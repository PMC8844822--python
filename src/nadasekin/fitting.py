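"""Nonlinear least-squares estimation of NAD(P)ase kinetic parameters.

All estimation is done by unweighted least squares on untransformed initial
rates (double-reciprocal transforms are produced as diagnostics only, never
used for estimation).  Parameters are fitted on a log10 scale to enforce
positivity, with a deterministic multistart grid around data-driven initial
guesses; the best residual sum of squares wins, ties broken by start order.

Inhibition constants that run away beyond the data are *censored*: an
estimate at or above 8000 uM, or one whose profile-likelihood lower bound
exceeds the largest tested substrate concentration, is reported as "> 8000"
and treated as unbounded when converted back to a parameter object.

The module also implements the two composite analyses built on these fits:

* mixed-type inhibition fitting with Lineweaver-Burk secondary replots and a
  competitive / noncompetitive / mixed classification from the multiplier
  ``a``;
* the NMN-titration competition analysis — refitting the dual-inhibition law
  at each effector level and regressing the allosteric constant ``Kia`` and
  the curve maxima on effector concentration to decide whether the effector
  competes with substrate at the allosteric site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .models import (
    CENSOR_THRESHOLD_UM,
    UNBOUNDED,
    CatalyticInhibitionParameters,
    DualInhibitionParameters,
    Ic50Value,
    MichaelisParameters,
    MixedInhibitionParameters,
    NoInteriorMaximum,
    curve_maximum,
    fractional_activity,
    rate_mixed_inhibition,
    evaluate_rate,
    params_from_record,
)

__all__ = [
    "RateDataset",
    "FitResult",
    "FitError",
    "TrendFit",
    "CompetitionAnalysis",
    "InhibitionFit",
    "fit_rate_model",
    "select_substrate_model",
    "double_reciprocal",
    "fit_ic50",
    "fit_mixed_inhibition",
    "nmn_titration_analysis",
    "trend_regression",
]


class FitError(RuntimeError):
    """Raised when no start of a fit converges, with diagnostics attached."""


@dataclass
class RateDataset:
    """Initial-rate records: substrate, optional inhibitor/effector, rate.

    Thin wrapper over a DataFrame with columns ``S_uM``, ``rate_mU_mg`` and
    optional ``I_uM``, ``effector_uM``, ``replicate``.
    """

    data: pd.DataFrame
    enzyme: str = ""
    substrate: str = ""

    def __post_init__(self) -> None:
        df = self.data
        for col in ("S_uM", "rate_mU_mg"):
            if col not in df.columns:
                raise ValueError(f"RateDataset requires column {col!r}")
        if np.any(df["S_uM"].to_numpy() <= 0):
            raise ValueError("all substrate concentrations must be positive")

    @property
    def S(self) -> np.ndarray:
        return self.data["S_uM"].to_numpy(dtype=float)

    @property
    def rate(self) -> np.ndarray:
        return self.data["rate_mU_mg"].to_numpy(dtype=float)

    @property
    def I(self) -> np.ndarray:
        if "I_uM" in self.data.columns:
            return self.data["I_uM"].to_numpy(dtype=float)
        return np.zeros(len(self.data))

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, enzyme: str = "", substrate: str = "") -> "RateDataset":
        df = pd.read_csv(path)
        missing = {"S_uM", "rate_mU_mg"} - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        return cls(data=df, enzyme=enzyme, substrate=substrate)


@dataclass
class FitResult:
    """Point estimates with standard errors, censoring flags and diagnostics."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float | None]
    censored: dict[str, bool]
    rss: float
    aicc: float
    n_obs: int
    n_free: int
    converged: bool
    n_starts: int
    warnings: list[str] = field(default_factory=list)

    def to_record(self) -> dict:
        rec = {"model": self.model, "rss": self.rss, "aicc": self.aicc,
               "n_obs": self.n_obs, "converged": self.converged,
               "warnings": list(self.warnings)}
        for k, v in self.params.items():
            if self.censored.get(k):
                rec[k] = f"> {CENSOR_THRESHOLD_UM:g}"
            else:
                rec[k] = v
            se = self.stderr.get(k)
            if se is not None and not self.censored.get(k):
                rec[f"{k}_se"] = se
        return rec

    def to_parameters(self):
        """Typed parameter object; censored inhibition constants → unbounded."""
        p = dict(self.params)
        rec = {"model": self.model}
        for k, v in p.items():
            if k in ("Kis", "Kia") and self.censored.get(k):
                continue
            if k == "a" and self.censored.get(k):
                continue
            rec[k] = v
        if self.model == "eq5":
            rec["n"] = max(rec.get("n", 1.0), 1.0)
        return params_from_record(rec)


@dataclass(frozen=True)
class TrendFit:
    """Straight-line OLS of a quantity against effector concentration."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float

    @property
    def significant_positive(self) -> bool:
        return self.slope > 0 and self.p_value < 0.05


@dataclass
class CompetitionAnalysis:
    """Per-effector-level dual-inhibition fits and their trend regressions."""

    effector_levels: list[float]
    fits: list[FitResult]
    maxima: list[tuple[float, float]]  # (S_opt, V_opt) per level
    kia_trend: TrendFit | None
    kis_trend: TrendFit | None
    vopt_trend: TrendFit | None
    verdict: str  # "competitive-allosteric" | "non-allosteric"

    def to_record(self) -> dict:
        return {
            "effector_levels_uM": self.effector_levels,
            "fits": [f.to_record() for f in self.fits],
            "maxima": [{"S_opt_uM": s, "V_opt_mU_mg": v} for s, v in self.maxima],
            "kia_trend": None if self.kia_trend is None else vars(self.kia_trend),
            "kis_trend": None if self.kis_trend is None else vars(self.kis_trend),
            "vopt_trend": None if self.vopt_trend is None else vars(self.vopt_trend),
            "verdict": self.verdict,
        }


@dataclass
class InhibitionFit:
    """Mixed-inhibition fit plus classification and secondary replots."""

    fit: FitResult
    classification: str  # "competitive" | "noncompetitive" | "mixed"
    replot_I: np.ndarray
    replot_slopes: np.ndarray
    replot_intercepts: np.ndarray
    slopes_nonlinear: bool
    intercepts_nonlinear: bool

    def to_record(self) -> dict:
        return {
            "fit": self.fit.to_record(),
            "classification": self.classification,
            "secondary_replot": {
                "I_uM": self.replot_I.tolist(),
                "lb_slopes": self.replot_slopes.tolist(),
                "lb_intercepts": self.replot_intercepts.tolist(),
                "slopes_nonlinear": self.slopes_nonlinear,
                "intercepts_nonlinear": self.intercepts_nonlinear,
            },
        }


# ---------------------------------------------------------------------------
# Core least-squares machinery
# ---------------------------------------------------------------------------

_PARAM_NAMES = {
    "eq1": ("Km", "Vmax"),
    "eq2": ("Km", "Vmax", "Kis"),
    "eq3": ("Km", "Vmax", "Kis", "Kia"),
    "eq5": ("Km", "Vmax", "Ki", "a", "n"),
}

# log10 bounds per parameter kind
_LOG_BOUNDS = {
    "Km": (-3.0, 7.0),
    "Vmax": (-6.0, 9.0),
    "Kis": (-3.0, 9.0),
    "Kia": (-3.0, 9.0),
    "Ki": (-3.0, 9.0),
    "a": (-3.0, 6.0),
    "n": (0.0, math.log10(8.0)),
}

_MULTISTART_FACTORS = (0.3, 1.0, 3.0)


def _aicc(rss: float, n: int, p: int) -> float:
    k = p + 1  # +1 for the residual variance
    if n - k - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _initial_guesses(model: str, S: np.ndarray, rate: np.ndarray, I: np.ndarray) -> dict[str, float]:
    vmax0 = float(np.max(rate))
    if vmax0 <= 0:
        vmax0 = 1.0
    if model in ("eq2", "eq3"):
        vmax0 *= 2.0  # observed maximum underestimates Vmax under substrate inhibition
    half = np.max(rate) / 2.0
    km0 = float(S[np.argmin(np.abs(rate - half))])
    km0 = max(km0, 1e-3)
    guesses = {"Km": km0, "Vmax": vmax0}
    smax = float(np.max(S))
    if model in ("eq2", "eq3"):
        guesses["Kis"] = smax
    if model == "eq3":
        guesses["Kia"] = smax
    if model == "eq5":
        pos = I[I > 0]
        guesses["Ki"] = float(np.median(pos)) if pos.size else smax
        guesses["a"] = 1.0
        guesses["n"] = 1.0
    return guesses


_UNBOUNDED_START = 1e8  # uM; lets substrate-inhibition constants start effectively absent


def _multistart_grid(model: str, guesses: dict[str, float]) -> list[dict[str, float]]:
    varied = [k for k in _PARAM_NAMES[model] if k in ("Km", "Kis", "Kia", "Ki")]
    # Kis/Kia may genuinely be unbounded; give each an extra far-out start so
    # the optimizer can reach the reduced-model solution instead of a swapped
    # local minimum where the wrong site absorbs the inhibition.
    options = {
        k: (
            [guesses[k] * f for f in _MULTISTART_FACTORS] + [_UNBOUNDED_START]
            if k in ("Kis", "Kia")
            else [guesses[k] * f for f in _MULTISTART_FACTORS]
        )
        for k in varied
    }
    starts = []
    for combo in product(*(options[k] for k in varied)):
        g = dict(guesses)
        g.update(zip(varied, combo))
        starts.append(g)
    return starts


def _residual_fn(model: str, S: np.ndarray, rate: np.ndarray, I: np.ndarray):
    names = _PARAM_NAMES[model]

    def resid(x: np.ndarray) -> np.ndarray:
        vals = dict(zip(names, 10.0**x))
        p = params_from_record({"model": model, **vals})
        pred = evaluate_rate(model, S, p, I)
        return np.asarray(pred) - rate

    return resid


def _fit_once(resid, x0: np.ndarray, lb: np.ndarray, ub: np.ndarray):
    return least_squares(resid, np.clip(x0, lb, ub), bounds=(lb, ub),
                         method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)


def _standard_errors(sol, names: Sequence[str], n: int) -> dict[str, float | None]:
    """Delta-method standard errors on the linear scale from the log10-space fit."""
    p = len(names)
    dof = n - p
    out: dict[str, float | None] = {k: None for k in names}
    if dof <= 0:
        return out
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (2 * sol.cost) / dof
    except np.linalg.LinAlgError:
        return out
    sd_log = np.sqrt(np.clip(np.diag(cov), 0, None))
    for k, x, s in zip(names, sol.x, sd_log):
        out[k] = float(10.0**x * math.log(10) * s)
    return out


def _profile_lower_bound(model, S, rate, I, names, best_x, best_rss, target: str) -> float:
    """Coarse profile-likelihood lower bound for one parameter (linear scale).

    Refits the remaining parameters on a descending log grid of fixed values;
    the bound is the smallest fixed value whose RSS stays below the F-test
    threshold around the global minimum.
    """
    idx = names.index(target)
    n, p = len(S), len(names)
    dof = max(n - p, 1)
    fcrit = stats.f.ppf(0.95, 1, dof)
    threshold = best_rss * (1.0 + fcrit / dof) + 1e-12 * (1 + abs(best_rss))
    others = [i for i in range(p) if i != idx]
    lbs = np.array([_LOG_BOUNDS[k][0] for k in names])
    ubs = np.array([_LOG_BOUNDS[k][1] for k in names])

    def rss_fixed(log_val: float) -> float:
        def resid_red(x_red: np.ndarray) -> np.ndarray:
            full = np.empty(p)
            full[others] = x_red
            full[idx] = log_val
            vals = dict(zip(names, 10.0**full))
            pp = params_from_record({"model": model, **vals})
            return np.asarray(evaluate_rate(model, S, pp, I)) - rate

        sol = _fit_once(resid_red, best_x[others], lbs[others], ubs[others])
        return 2 * sol.cost

    lo = math.log10(max(float(np.max(S)) / 10.0, 1e-3))
    hi = best_x[idx]
    if hi <= lo:
        return 10.0**hi
    bound = 10.0**hi
    for log_val in np.linspace(hi, lo, 12):
        if rss_fixed(log_val) > threshold:
            break
        bound = 10.0**log_val
    return bound


def _canonicalize_eq3(params: dict, stderr: dict, censored: dict, warnings: list[str]) -> None:
    """Resolve the one-finite-constant degeneracy of the dual-inhibition law.

    With a single finite constant the law is non-identifiable between two
    exact representations: the allosteric form ``Vmax*S/((Km+S)(1+S/Kia))``
    equals the catalytic form with ``Kis = Km + Kia`` after rescaling Km and
    Vmax by ``Kia/(Km+Kia)``.  A lone substrate-inhibition curve cannot say
    which site is responsible, so when the fit lands in the catalytic-form
    minimum (Kia censored) and a real allosteric twin exists
    (``Kis > 4*Km``), the estimate is re-expressed in the allosteric form —
    the site whose presence motivates fitting this law in the first place.
    The catalytic twin exists only for ``Kis > 4*Km``; genuinely
    catalytic-site-inhibited data (Kis well below Km) are left untouched.
    """
    if not censored.get("Kia") or censored.get("Kis"):
        return
    km, vmax, kis = params["Km"], params["Vmax"], params["Kis"]
    disc = kis * kis - 4.0 * km * kis
    if disc <= 0:
        return
    root = math.sqrt(disc)
    km_allo = (kis - root) / 2.0
    kia_allo = (kis + root) / 2.0
    params["Km"] = km_allo
    params["Kia"] = kia_allo
    params["Vmax"] = vmax * kis / kia_allo
    params["Kis"] = 10.0 ** _LOG_BOUNDS["Kis"][1]
    censored["Kis"], censored["Kia"] = True, False
    for k in ("Km", "Vmax", "Kis", "Kia"):
        stderr[k] = None
    warnings.append("reparameterized to the allosteric canonical form")


def fit_rate_model(d: RateDataset, model: str, profile_censoring: bool = True) -> FitResult:
    """Fit one of the substrate rate laws (``eq1``/``eq2``/``eq3``/``eq5``).

    Unweighted least squares on rates, multistart over a deterministic grid of
    initial guesses, parameters constrained positive via a log10
    parameterization.  Inhibition constants are censored (reported "> 8000")
    when the estimate exceeds 8000 uM or, with ``profile_censoring``, when the
    profile-likelihood lower bound exceeds the largest tested S.
    """
    if model not in _PARAM_NAMES:
        raise ValueError(f"model must be one of {sorted(_PARAM_NAMES)}, got {model!r}")
    names = list(_PARAM_NAMES[model])
    S, rate, I = d.S, d.rate, d.I
    n, p = len(S), len(names)
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} records to fit {model}, got {n}")

    resid = _residual_fn(model, S, rate, I)
    lb = np.array([_LOG_BOUNDS[k][0] for k in names])
    ub = np.array([_LOG_BOUNDS[k][1] for k in names])

    best = None
    n_tried = 0
    failures: list[str] = []
    for start in _multistart_grid(model, _initial_guesses(model, S, rate, I)):
        x0 = np.array([math.log10(start[k]) for k in names])
        n_tried += 1
        try:
            sol = _fit_once(resid, x0, lb, ub)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if not sol.success:
            failures.append(sol.message)
            continue
        if best is None or 2 * sol.cost < 2 * best.cost - 1e-15:
            best = sol
    if best is None:
        raise FitError(
            f"no start converged for {model} ({n_tried} starts); messages: {failures[:3]}"
        )

    rss = float(2 * best.cost)
    params = {k: float(10.0**x) for k, x in zip(names, best.x)}
    stderr = _standard_errors(best, names, n)
    warnings: list[str] = []

    censored = {k: False for k in names}
    smax = float(np.max(S))
    for k in ("Kis", "Kia"):
        if k not in params:
            continue
        est = params[k]
        if est >= CENSOR_THRESHOLD_UM:
            censored[k] = True
        elif profile_censoring and est > smax:
            lb_prof = _profile_lower_bound(model, S, rate, I, names, best.x, rss, k)
            if lb_prof > smax:
                censored[k] = True
    if model == "eq5":
        if params["a"] >= 0.5 * 10.0 ** _LOG_BOUNDS["a"][1]:
            censored["a"] = True  # competitive limit: a runs to its bound
        for k in ("n", "a"):
            lo_b, hi_b = _LOG_BOUNDS[k]
            logv = math.log10(params[k])
            if logv <= lo_b + 1e-6 or logv >= hi_b - 1e-6:
                warnings.append(f"{k} pinned to its fitting bound")

    if model == "eq3":
        _canonicalize_eq3(params, stderr, censored, warnings)

    return FitResult(
        model=model, params=params, stderr=stderr, censored=censored,
        rss=rss, aicc=_aicc(rss, n, p), n_obs=n, n_free=p,
        converged=True, n_starts=n_tried, warnings=warnings,
    )


_MODEL_COMPLEXITY = ("eq1", "eq2", "eq3")


def select_substrate_model(d: RateDataset) -> tuple[str, FitResult]:
    """Fit the three substrate laws and choose by AICc.

    The simpler model wins whenever its AICc is within 2 of the minimum, so a
    hyperbola is never rejected on the basis of an ignorable improvement.
    """
    S = d.S
    if np.max(S) / np.min(S) < 30:
        raise ValueError("substrate range must span at least 30-fold for model selection")
    fits = {m: fit_rate_model(d, m, profile_censoring=False) for m in _MODEL_COMPLEXITY}
    best_aicc = min(f.aicc for f in fits.values())
    for m in _MODEL_COMPLEXITY:  # simplest adequate model first
        if fits[m].aicc <= best_aicc + 2.0:
            return m, fits[m]
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Double-reciprocal diagnostics
# ---------------------------------------------------------------------------


def _added_term_pvalue(x: np.ndarray, y: np.ndarray, term: np.ndarray) -> float:
    """F-test p-value for one extra regressor improving on a straight line."""
    n = len(x)
    if n < 4:
        return 1.0
    lin = np.polyfit(x, y, 1)
    rss1 = float(np.sum((y - np.polyval(lin, x)) ** 2))
    X = np.column_stack([np.ones(n), x, term])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss2 = float(np.sum((y - X @ coef) ** 2))
    scale = float(np.sum(y**2)) + 1e-300
    if rss1 / scale < 1e-16:  # already an exact line
        return 1.0
    dof = n - 3
    if rss2 <= 0:
        return 0.0
    f = (rss1 - rss2) / (rss2 / dof)
    return float(stats.f.sf(f, 1, dof))


def _curvature_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """F-test p-value for a quadratic term improving on a straight line."""
    return _added_term_pvalue(x, y, np.asarray(x) ** 2)


def double_reciprocal(d: RateDataset) -> pd.DataFrame:
    """Lineweaver-Burk transform with per-inhibitor-level line fits.

    Returns one row per inhibitor level with that level's OLS slope and
    intercept of 1/rate vs 1/S and a curvature flag (quadratic term
    significant at p < 0.05) marking departure from linearity, as produced by
    substrate-inhibited data.  Rates must all be positive.
    """
    if np.any(d.rate <= 0):
        raise ValueError("double-reciprocal transform requires strictly positive rates")
    rows = []
    df = d.data.assign(_I=d.I)
    for level, grp in df.groupby("_I"):
        inv_s = 1.0 / grp["S_uM"].to_numpy(dtype=float)
        inv_v = 1.0 / grp["rate_mU_mg"].to_numpy(dtype=float)
        slope, intercept = np.polyfit(inv_s, inv_v, 1)
        # substrate inhibition bends 1/v upward at high S, i.e. as 1/(1/S);
        # test both a quadratic and a reciprocal augmentation of the line
        nonlinear = (
            _curvature_pvalue(inv_s, inv_v) < 0.05
            or _added_term_pvalue(inv_s, inv_v, 1.0 / inv_s) < 0.05
        )
        rows.append({
            "I_uM": float(level),
            "slope": float(slope),
            "intercept": float(intercept),
            "n_points": len(grp),
            "nonlinear": nonlinear,
        })
    return pd.DataFrame(rows).sort_values("I_uM", ignore_index=True)


# ---------------------------------------------------------------------------
# IC50 and mixed inhibition
# ---------------------------------------------------------------------------


def fit_ic50(I: Sequence[float], activity: Sequence[float]) -> FitResult:
    """Fit the one-site dose-response law to a fractional-activity series.

    ``activity`` is already normalized to the I=0 control (which must be
    present).  A series that does not decrease overall is flagged; an IC50
    running far beyond the tested range is flagged divergent.
    """
    I = np.asarray(I, dtype=float)
    y = np.asarray(activity, dtype=float)
    if len(I) < 4:
        raise ValueError("need at least 4 inhibitor levels")
    if not np.any(I == 0):
        raise ValueError("an I=0 control is required for normalization")
    if np.any(I < 0):
        raise ValueError("inhibitor concentrations must be nonnegative")

    warnings: list[str] = []
    order = np.argsort(I)
    if y[order][-1] >= y[order][0]:
        warnings.append("activities do not decrease overall")

    imax = float(np.max(I[I > 0]))

    def resid(x: np.ndarray) -> np.ndarray:
        return fractional_activity(I, Ic50Value(ic50=float(10.0 ** x[0]))) - y

    best = None
    for start in (np.median(I[I > 0]), imax, np.min(I[I > 0])):
        sol = _fit_once(resid, np.array([math.log10(start)]), np.array([-3.0]), np.array([9.0]))
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("IC50 fit failed from all starts")
    ic50 = float(10.0 ** best.x[0])
    censored = {"ic50": False}
    if ic50 > 100.0 * imax:
        warnings.append("divergent IC50: estimate far beyond tested range")
        censored["ic50"] = True
    rss = float(2 * best.cost)
    return FitResult(
        model="eq4", params={"ic50": ic50},
        stderr=_standard_errors(best, ["ic50"], len(I)),
        censored=censored, rss=rss, aicc=_aicc(rss, len(I), 1),
        n_obs=len(I), n_free=1, converged=True, n_starts=3, warnings=warnings,
    )


def fit_mixed_inhibition(d: RateDataset) -> InhibitionFit:
    """Fit the mixed-type multi-site law over an (S, I) grid and classify it.

    Requires at least three nonzero inhibitor levels plus the I=0 control;
    substrate should be restricted to the range where substrate inhibition is
    negligible.  Classification from the fitted multiplier ``a``: competitive
    when ``a`` is censored at its upper bound, noncompetitive when ``a`` is in
    [0.8, 1.25] with ``n`` in [0.9, 1.1], mixed otherwise.  Lineweaver-Burk
    slope and intercept replots vs I are computed and flagged nonlinear when a
    quadratic term significantly improves their straight-line fit — the
    signature of multi-site binding (n > 1).
    """
    levels = np.unique(d.I)
    if 0.0 not in levels:
        raise ValueError("an I=0 series is required")
    if len(levels[levels > 0]) < 3:
        raise ValueError("need at least 3 nonzero inhibitor levels")

    fit = fit_rate_model(d, "eq5")
    a, n_hat = fit.params["a"], fit.params["n"]
    if fit.censored.get("a"):
        classification = "competitive"
    elif 0.8 <= a <= 1.25 and 0.9 <= n_hat <= 1.1:
        classification = "noncompetitive"
    else:
        classification = "mixed"

    lb = double_reciprocal(d)
    I_levels = lb["I_uM"].to_numpy()
    slopes = lb["slope"].to_numpy()
    intercepts = lb["intercept"].to_numpy()
    return InhibitionFit(
        fit=fit,
        classification=classification,
        replot_I=I_levels,
        replot_slopes=slopes,
        replot_intercepts=intercepts,
        slopes_nonlinear=_curvature_pvalue(I_levels, slopes) < 0.05,
        intercepts_nonlinear=_curvature_pvalue(I_levels, intercepts) < 0.05,
    )


# ---------------------------------------------------------------------------
# NMN-titration competition analysis
# ---------------------------------------------------------------------------


def trend_regression(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """OLS line with the two-sided t-test p-value on the slope."""
    res = stats.linregress(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return TrendFit(slope=float(res.slope), intercept=float(res.intercept),
                    r_squared=float(res.rvalue**2), p_value=float(res.pvalue))


def nmn_titration_analysis(
    datasets: Mapping[float, RateDataset] | Sequence[tuple[float, RateDataset]],
) -> CompetitionAnalysis:
    """Competition analysis across effector (NMN-type) titration levels.

    Fits the dual-site substrate-inhibition law independently at each effector
    level, extracts the allosteric constant Kia and the curve maximum, and
    regresses Kia and V_opt on effector concentration.  Verdict
    "competitive-allosteric" requires a significantly positive Kia slope
    (two-sided p < 0.05) together with monotone nondecreasing curve maxima —
    the signature of the effector competing with substrate at the allosteric
    site; anything else (including Kia censored at any level) is
    "non-allosteric".
    """
    items = sorted(datasets.items() if isinstance(datasets, Mapping) else datasets)
    if len(items) < 3:
        raise ValueError("need at least 3 effector levels")
    levels = [float(e) for e, _ in items]
    fits = [fit_rate_model(d, "eq3") for _, d in items]

    maxima: list[tuple[float, float]] = []
    for f in fits:
        try:
            maxima.append(curve_maximum(f.to_parameters()))
        except NoInteriorMaximum:
            maxima.append((math.nan, math.nan))

    kia_vals = [f.params["Kia"] for f in fits]
    kia_ok = not any(f.censored.get("Kia") for f in fits)
    kia_trend = trend_regression(levels, kia_vals) if kia_ok else None

    kis_vals = [f.params["Kis"] for f in fits]
    kis_ok = not any(f.censored.get("Kis") for f in fits)
    kis_trend = trend_regression(levels, kis_vals) if kis_ok else None

    vopts = [v for _, v in maxima]
    vopt_trend = (
        trend_regression(levels, vopts) if not any(math.isnan(v) for v in vopts) else None
    )

    monotone_maxima = all(
        not (math.isnan(a) or math.isnan(b)) and b >= a for a, b in zip(vopts, vopts[1:])
    )
    verdict = (
        "competitive-allosteric"
        if kia_trend is not None and kia_trend.significant_positive and monotone_maxima
        else "non-allosteric"
    )
    return CompetitionAnalysis(
        effector_levels=levels, fits=fits, maxima=maxima,
        kia_trend=kia_trend, kis_trend=kis_trend, vopt_trend=vopt_trend,
        verdict=verdict,
    )
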