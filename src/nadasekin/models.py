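"""Closed-form rate laws for multifunctional NAD(P)ases and derived constants.

This module is the mathematical core of the package.  It implements the five
steady-state rate laws used to describe NAD(P) glycohydrolases such as CD38,
*Aplysia* ADP-ribosyl cyclase and SARM1:

``eq1``
    the Michaelis-Menten hyperbola, adequate for CD38 and the cyclase;
``eq2``
    Michaelis-Menten with uncompetitive substrate inhibition at the catalytic
    (TIR) site, governed by ``Kis`` — the SAM-TIR fragment of SARM1;
``eq3``
    dual-site substrate inhibition: the ``eq2`` form multiplied by an
    allosteric (ARM-site) inhibition factor governed by ``Kia`` — full-length
    SARM1;
``eq4``
    the one-site fractional-activity (IC50) law for dose-response series;
``eq5``
    multi-site mixed-type inhibition with inhibition constant ``Ki``, the
    competitive/uncompetitive multiplier ``a`` and a Hill-like stoichiometry
    ``n`` counting inhibitor molecules bound.

Units are fixed package-wide: substrate/inhibitor concentrations in uM, rates
in mU per mg protein (1 U = 1 umol/min), turnover kcat in s^-1 and catalytic
efficiency kcat/Km in M^-1 s^-1.

Inhibition constants may be *unbounded* (``math.inf``): the corresponding
inhibition term is then exactly 1 and the law collapses to its simpler limit.
Fits report such constants censored as "> 8000 uM" rather than as a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.optimize import golden

__all__ = [
    "UNBOUNDED",
    "CENSOR_THRESHOLD_UM",
    "FULL_LENGTH_FLAG_KDA",
    "MichaelisParameters",
    "CatalyticInhibitionParameters",
    "DualInhibitionParameters",
    "Ic50Value",
    "MixedInhibitionParameters",
    "CatalyticConstants",
    "rate_mm",
    "rate_catalytic_inhibition",
    "rate_dual_inhibition",
    "fractional_activity",
    "rate_mixed_inhibition",
    "curve_maximum",
    "NoInteriorMaximum",
    "kcat_from_specific_activity",
    "catalytic_efficiency",
    "params_to_record",
    "params_from_record",
]

#: Sentinel for an inhibition constant too large to resolve.  ``S / UNBOUNDED``
#: is exactly 0.0, so the inhibition term it controls is exactly 1.
UNBOUNDED: float = math.inf

#: Censoring convention for fitted inhibition constants (uM): estimates at or
#: above this are reported as "> 8000" rather than as a point value.
CENSOR_THRESHOLD_UM: float = 8000.0

#: Molar mass of full-length human SARM1 carrying a C-terminal FLAG tag,
#: kg/mol: 724 residues (~79.4 kDa) plus the DYKDDDDK octapeptide (+~1.0 kDa).
FULL_LENGTH_FLAG_KDA: float = 80.4

ArrayLike = Union[float, np.ndarray]


def _check_nonnegative(x: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative, got {x!r}")
    return arr


def _is_unbounded(k: float) -> bool:
    return math.isinf(k)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MichaelisParameters:
    """Hyperbolic (``eq1``) parameters: Km (uM) and Vmax (mU/mg)."""

    Km: float
    Vmax: float

    def __post_init__(self) -> None:
        if not self.Km > 0:
            raise ValueError(f"Km must be positive, got {self.Km}")
        if not self.Vmax > 0:
            raise ValueError(f"Vmax must be positive, got {self.Vmax}")


@dataclass(frozen=True)
class CatalyticInhibitionParameters:
    """``eq2`` parameters: Michaelis base plus catalytic-site Kis (uM).

    ``Kis = UNBOUNDED`` (math.inf) marks a constant too large to resolve; the
    law then reduces exactly to ``eq1``.
    """

    base: MichaelisParameters
    Kis: float = UNBOUNDED

    def __post_init__(self) -> None:
        if not self.Kis > 0:
            raise ValueError(f"Kis must be positive or unbounded, got {self.Kis}")

    @property
    def Km(self) -> float:
        return self.base.Km

    @property
    def Vmax(self) -> float:
        return self.base.Vmax

    @property
    def kis_unbounded(self) -> bool:
        return _is_unbounded(self.Kis)


@dataclass(frozen=True)
class DualInhibitionParameters:
    """``eq3`` parameters: ``eq2`` base plus allosteric ARM-site Kia (uM)."""

    base: CatalyticInhibitionParameters
    Kia: float = UNBOUNDED

    def __post_init__(self) -> None:
        if not self.Kia > 0:
            raise ValueError(f"Kia must be positive or unbounded, got {self.Kia}")

    @property
    def Km(self) -> float:
        return self.base.Km

    @property
    def Vmax(self) -> float:
        return self.base.Vmax

    @property
    def Kis(self) -> float:
        return self.base.Kis

    @property
    def kis_unbounded(self) -> bool:
        return self.base.kis_unbounded

    @property
    def kia_unbounded(self) -> bool:
        return _is_unbounded(self.Kia)


@dataclass(frozen=True)
class Ic50Value:
    """Half-inhibitory concentration (uM) for the ``eq4`` dose-response law."""

    ic50: float

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError(f"ic50 must be positive, got {self.ic50}")


@dataclass(frozen=True)
class MixedInhibitionParameters:
    """``eq5`` parameters for mixed-type multi-site inhibition.

    ``a = UNBOUNDED`` is the competitive limit (the inhibitor never binds the
    ES complex); ``a = 1, n = 1`` is pure noncompetitive inhibition.
    """

    base: MichaelisParameters
    Ki: float
    a: float = 1.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if not self.Ki > 0:
            raise ValueError(f"Ki must be positive, got {self.Ki}")
        if not self.a > 0:
            raise ValueError(f"a must be positive or infinite, got {self.a}")
        if not self.n >= 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def Km(self) -> float:
        return self.base.Km

    @property
    def Vmax(self) -> float:
        return self.base.Vmax

    @property
    def competitive_limit(self) -> bool:
        return _is_unbounded(self.a)


@dataclass(frozen=True)
class CatalyticConstants:
    """Turnover number and catalytic efficiency derived from a fit.

    ``efficiency`` must equal ``kcat / (Km in molar)``; construction verifies
    the identity so inconsistent triples cannot circulate.
    """

    kcat: float
    Km: float
    efficiency: float = field(default=0.0)
    molar_mass: float = 0.0
    purity_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.kcat > 0:
            raise ValueError(f"kcat must be positive, got {self.kcat}")
        if not self.Km > 0:
            raise ValueError(f"Km must be positive, got {self.Km}")
        if not 0 < self.purity_fraction <= 1:
            raise ValueError(f"purity_fraction must be in (0, 1], got {self.purity_fraction}")
        expected = catalytic_efficiency(self.kcat, self.Km)
        if self.efficiency == 0.0:
            object.__setattr__(self, "efficiency", expected)
        elif not math.isclose(self.efficiency, expected, rel_tol=1e-9):
            raise ValueError(
                f"efficiency {self.efficiency} inconsistent with kcat/Km = {expected}"
            )


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------


def rate_mm(S: ArrayLike, p: MichaelisParameters) -> ArrayLike:
    """Michaelis-Menten rate (``eq1``): ``Vmax*S / (Km + S)``, mU/mg."""
    s = _check_nonnegative(S, "S")
    v = p.Vmax * s / (p.Km + s)
    return float(v) if np.isscalar(S) or np.ndim(S) == 0 else v


def rate_catalytic_inhibition(S: ArrayLike, p: CatalyticInhibitionParameters) -> ArrayLike:
    """Substrate-inhibited rate (``eq2``): ``Vmax*S / (Km + S*(1 + S/Kis))``.

    Equals :func:`rate_mm` exactly when ``Kis`` is unbounded.
    """
    s = _check_nonnegative(S, "S")
    v = p.Vmax * s / (p.Km + s * (1.0 + s / p.Kis))
    return float(v) if np.isscalar(S) or np.ndim(S) == 0 else v


def rate_dual_inhibition(S: ArrayLike, p: DualInhibitionParameters) -> ArrayLike:
    """Dual-site substrate inhibition (``eq3``).

    ``Vmax*S / ((Km + S*(1 + S/Kis)) * (1 + S/Kia))``; reduces to ``eq2`` when
    ``Kia`` is unbounded and to ``eq1`` when both constants are.
    """
    s = _check_nonnegative(S, "S")
    v = p.Vmax * s / ((p.Km + s * (1.0 + s / p.Kis)) * (1.0 + s / p.Kia))
    return float(v) if np.isscalar(S) or np.ndim(S) == 0 else v


def fractional_activity(I: ArrayLike, p: Ic50Value) -> ArrayLike:
    """Fractional remaining activity (``eq4``): ``1 / (1 + I/IC50)``.

    Strictly decreasing in I, equal to 1 at I=0 and to 0.5 at I=IC50.
    """
    i = _check_nonnegative(I, "I")
    v = 1.0 / (1.0 + i / p.ic50)
    return float(v) if np.isscalar(I) or np.ndim(I) == 0 else v


def rate_mixed_inhibition(S: ArrayLike, I: ArrayLike, p: MixedInhibitionParameters) -> ArrayLike:
    """Mixed-type multi-site inhibition rate (``eq5``), mU/mg.

    ``Vmax*S / (Km*(1 + (I/Ki)^n) + S*(1 + (I/(a*Ki))^n))``.  At I=0 this is
    exactly ``eq1``; with a=1, n=1 it is pure noncompetitive inhibition
    ``Vmax*S / ((Km+S)*(1+I/Ki))``.
    """
    s = _check_nonnegative(S, "S")
    i = _check_nonnegative(I, "I")
    slope_term = 1.0 + (i / p.Ki) ** p.n
    # a unbounded: inhibitor cannot bind ES, the S-coefficient stays 1
    icat = np.zeros_like(i) if p.competitive_limit else (i / (p.a * p.Ki)) ** p.n
    v = p.Vmax * s / (p.Km * slope_term + s * (1.0 + icat))
    scalar = (np.isscalar(S) or np.ndim(S) == 0) and (np.isscalar(I) or np.ndim(I) == 0)
    return float(v) if scalar else v


# ---------------------------------------------------------------------------
# Curve maxima of the substrate-inhibited laws
# ---------------------------------------------------------------------------


class NoInteriorMaximum(ValueError):
    """The rate law is monotone in S and has no interior maximum."""


def curve_maximum(p, model_id: str | None = None) -> tuple[float, float]:
    """Locate the substrate optimum (S_opt, V_opt) of a substrate-inhibited law.

    For ``eq2`` the closed form is ``S_opt = sqrt(Km*Kis)`` with
    ``V_opt = Vmax / (1 + 2*sqrt(Km/Kis))``.  For ``eq3`` with only the
    allosteric constant finite the same form holds with ``Kia`` in place of
    ``Kis``; with both constants finite the unique interior maximum is found
    numerically (512-point log grid bracket followed by golden-section search
    on log S over [1e-2, 1e6] uM).

    Raises :class:`NoInteriorMaximum` for a plain hyperbola (``eq1`` or all
    constants unbounded).
    """
    if isinstance(p, MichaelisParameters):
        raise NoInteriorMaximum("Michaelis-Menten rate is monotone in S")
    if isinstance(p, CatalyticInhibitionParameters):
        if p.kis_unbounded:
            raise NoInteriorMaximum("Kis unbounded: curve is monotone")
        s_opt = math.sqrt(p.Km * p.Kis)
        v_opt = p.Vmax / (1.0 + 2.0 * math.sqrt(p.Km / p.Kis))
        return s_opt, v_opt
    if isinstance(p, DualInhibitionParameters):
        if p.kis_unbounded and p.kia_unbounded:
            raise NoInteriorMaximum("both inhibition constants unbounded: curve is monotone")
        if p.kia_unbounded:
            return curve_maximum(p.base)
        if p.kis_unbounded:
            # eq3 degenerates to the eq2 form with Kia as the single constant
            s_opt = math.sqrt(p.Km * p.Kia)
            v_opt = float(rate_dual_inhibition(s_opt, p))
            return s_opt, v_opt
        return _numeric_maximum(lambda s: rate_dual_inhibition(s, p))
    raise TypeError(f"unsupported parameter object {type(p).__name__}")


def _numeric_maximum(rate, lo: float = 1e-2, hi: float = 1e6, ngrid: int = 512) -> tuple[float, float]:
    logs = np.linspace(math.log(lo), math.log(hi), ngrid)
    vals = np.array([rate(math.exp(x)) for x in logs])
    k = int(np.argmax(vals))
    if k == 0 or k == ngrid - 1:
        raise NoInteriorMaximum("no interior maximum on the search interval")
    bracket = (logs[k - 1], logs[k], logs[k + 1])
    x_opt = golden(lambda x: -rate(math.exp(x)), brack=bracket, tol=1e-12)
    s_opt = float(math.exp(x_opt))
    return s_opt, float(rate(s_opt))


# ---------------------------------------------------------------------------
# Derived catalytic constants
# ---------------------------------------------------------------------------


def kcat_from_specific_activity(
    Vmax: float, molar_mass: float, purity_fraction: float = 1.0
) -> float:
    """Turnover number (s^-1) from a crude-preparation specific activity.

    ``Vmax`` is in mU/mg of total protein (= nmol product min^-1 mg^-1),
    ``molar_mass`` in kg/mol (kDa) and ``purity_fraction`` the mass fraction
    of the preparation that is the enzyme.  Then

        kcat = Vmax * molar_mass * 1e-3 / (60 * purity_fraction)

    since 1 mg of preparation holds ``purity/molar_mass`` umol of enzyme.
    """
    if not (Vmax > 0 and molar_mass > 0):
        raise ValueError("Vmax and molar_mass must be positive")
    if not 0 < purity_fraction <= 1:
        raise ValueError(f"purity_fraction must be in (0, 1], got {purity_fraction}")
    return Vmax * molar_mass * 1e-3 / (60.0 * purity_fraction)


def catalytic_efficiency(kcat: float, Km: float) -> float:
    """Catalytic efficiency kcat/Km in M^-1 s^-1 from kcat (s^-1), Km (uM)."""
    if not (kcat > 0 and Km > 0):
        raise ValueError("kcat and Km must be positive")
    return kcat / (Km * 1e-6)


# ---------------------------------------------------------------------------
# Flat-record (JSON dialect) serialization
# ---------------------------------------------------------------------------

_MODEL_IDS = ("eq1", "eq2", "eq3", "eq4", "eq5")


def params_to_record(p) -> dict:
    """Serialize any parameter object to a flat key-value record.

    Unbounded constants are simply omitted, matching the convention that an
    absent key means unbounded / not applicable.
    """
    if isinstance(p, MichaelisParameters):
        return {"model": "eq1", "Km": p.Km, "Vmax": p.Vmax}
    if isinstance(p, DualInhibitionParameters):
        rec = {"model": "eq3", "Km": p.Km, "Vmax": p.Vmax}
        if not p.kis_unbounded:
            rec["Kis"] = p.Kis
        if not p.kia_unbounded:
            rec["Kia"] = p.Kia
        return rec
    if isinstance(p, CatalyticInhibitionParameters):
        rec = {"model": "eq2", "Km": p.Km, "Vmax": p.Vmax}
        if not p.kis_unbounded:
            rec["Kis"] = p.Kis
        return rec
    if isinstance(p, Ic50Value):
        return {"model": "eq4", "ic50": p.ic50}
    if isinstance(p, MixedInhibitionParameters):
        rec = {"model": "eq5", "Km": p.Km, "Vmax": p.Vmax, "Ki": p.Ki, "n": p.n}
        if not p.competitive_limit:
            rec["a"] = p.a
        return rec
    raise TypeError(f"unsupported parameter object {type(p).__name__}")


def params_from_record(rec: dict):
    """Inverse of :func:`params_to_record`."""
    model = rec.get("model")
    if model not in _MODEL_IDS:
        raise ValueError(f"unknown model id {model!r}; expected one of {_MODEL_IDS}")
    if model == "eq4":
        return Ic50Value(ic50=float(rec["ic50"]))
    base = MichaelisParameters(Km=float(rec["Km"]), Vmax=float(rec["Vmax"]))
    if model == "eq1":
        return base
    if model == "eq2":
        return CatalyticInhibitionParameters(base=base, Kis=float(rec.get("Kis", UNBOUNDED)))
    if model == "eq3":
        inner = CatalyticInhibitionParameters(base=base, Kis=float(rec.get("Kis", UNBOUNDED)))
        return DualInhibitionParameters(base=inner, Kia=float(rec.get("Kia", UNBOUNDED)))
    return MixedInhibitionParameters(
        base=base,
        Ki=float(rec["Ki"]),
        a=float(rec.get("a", UNBOUNDED)),
        n=float(rec.get("n", 1.0)),
    )


def evaluate_rate(model: str, S: ArrayLike, p, I: ArrayLike = 0.0) -> ArrayLike:
    """Dispatch a rate evaluation by model id (``eq1``/``eq2``/``eq3``/``eq5``)."""
    if model == "eq1":
        return rate_mm(S, p)
    if model == "eq2":
        return rate_catalytic_inhibition(S, p)
    if model == "eq3":
        return rate_dual_inhibition(S, p)
    if model == "eq5":
        return rate_mixed_inhibition(S, I, p)
    raise ValueError(f"cannot evaluate rate for model {model!r}")
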