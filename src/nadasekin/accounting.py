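"""Multi-product activity accounting for NAD(P) glycohydrolase time courses.

The branching Uni-Bi mechanism of these enzymes releases the pyridine base
first and then resolves a common ADP-ribosyl intermediate three ways:
hydrolysis (ADPR-type product), intramolecular cyclization (cADPR-type), or
exchange with a supplied free base (a new dinucleotide analog, e.g. AcPyrAD
from AcPyr + NAD).  Every consumed substrate molecule therefore yields exactly
one counted product molecule plus one released base — the mass-balance
identity this module checks.

Given timestamped HPLC-style concentration series, this module selects the
initial-rate window (consumption capped at 20% of starting substrate and
products still accumulating linearly), estimates per-product initial rates by
ordinary least squares, partitions total activity into hydrolysis /
cyclization / base-exchange fractions, and converts to specific activity in
mU per mg protein (1 U = 1 umol total products per min).

It also carries the small normalization utilities used around the assays:
profile normalization to curve maxima, immunoblot standard-curve protein
quantification, and internal-standard (cAMP) recovery correction of
metabolite levels per mg protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourse",
    "ActivityPartition",
    "MassBalanceReport",
    "MetaboliteMeasurement",
    "InsufficientLinearRange",
    "select_initial_window",
    "estimate_rates",
    "partition_activities",
    "check_mass_balance",
    "normalize_profile",
    "protein_from_standard_curve",
    "normalize_metabolite",
]

DEFAULT_MAX_CONSUMED_FRACTION = 0.20
DEFAULT_R2_MIN = 0.98
DEFAULT_MASS_BALANCE_TOL = 0.05
DEFAULT_RECOVERY_FLOOR = 0.5


class InsufficientLinearRange(ValueError):
    """No prefix of >= 3 points satisfies the initial-rate window criteria."""


@dataclass
class TimeCourse:
    """Concentration time course of a substrate and all its products (uM).

    ``exchange_products`` maps a base-exchange product name (e.g. "AcPyrAD")
    to its concentration series; ``free_base_supplied`` maps the same names to
    the free-base amount present at t=0 (the stoichiometric cap on exchange).
    ``released_base`` is the Nam-type base released on every catalytic event.
    """

    times: np.ndarray
    substrate: np.ndarray
    adpr_product: np.ndarray
    cyclic_product: np.ndarray
    released_base: np.ndarray
    exchange_products: dict[str, np.ndarray] = field(default_factory=dict)
    free_base_supplied: dict[str, float] = field(default_factory=dict)
    protein_conc: float = 1.0  # ug/mL in the assay

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.adpr_product = np.asarray(self.adpr_product, dtype=float)
        self.cyclic_product = np.asarray(self.cyclic_product, dtype=float)
        self.released_base = np.asarray(self.released_base, dtype=float)
        self.exchange_products = {
            k: np.asarray(v, dtype=float) for k, v in self.exchange_products.items()
        }
        n = len(self.times)
        if n < 2:
            raise ValueError("a time course needs at least two time points")
        if self.times[0] != 0:
            raise ValueError("time course must start at t=0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, series in self._all_series().items():
            if len(series) != n:
                raise ValueError(f"series {name!r} length {len(series)} != {n} time points")
            if np.any(series < -1e-9):
                raise ValueError(f"series {name!r} has negative concentrations")
        for name, series in self._product_series().items():
            if abs(series[0]) > 1e-9:
                raise ValueError(f"product series {name!r} must start at 0")
        # substrate nonincreasing within a small tolerance relative to S0
        tol = 1e-6 * max(self.substrate[0], 1.0)
        if np.any(np.diff(self.substrate) > tol):
            raise ValueError("substrate series must be nonincreasing")
        if not self.protein_conc > 0:
            raise ValueError("protein_conc must be positive")

    def _product_series(self) -> dict[str, np.ndarray]:
        out = {"adpr": self.adpr_product, "cyclic": self.cyclic_product}
        out.update(self.exchange_products)
        return out

    def _all_series(self) -> dict[str, np.ndarray]:
        out = {"substrate": self.substrate, "base": self.released_base}
        out.update(self._product_series())
        return out

    @property
    def S0(self) -> float:
        return float(self.substrate[0])

    def total_products(self) -> np.ndarray:
        """Sum of all counted product series at each time point (uM)."""
        return sum(self._product_series().values())

    # -- delimited-text round trip ------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the course as CSV with '#'-prefixed metadata header lines."""
        path = Path(path)
        cols = {"time_min": self.times, "substrate_uM": self.substrate,
                "adpr_uM": self.adpr_product, "cyclic_uM": self.cyclic_product}
        for name, series in self.exchange_products.items():
            cols[f"x_{name}_uM"] = series
        cols["base_uM"] = self.released_base
        meta = {"protein_conc_ug_ml": self.protein_conc, "S0": self.S0,
                "free_base_supplied": self.free_base_supplied}
        with path.open("w") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            pd.DataFrame(cols).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeCourse":
        path = Path(path)
        meta: dict = {}
        with path.open() as fh:
            first = fh.readline()
            if first.startswith("#"):
                meta = json.loads(first.lstrip("#").strip())
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        exch = {
            c[len("x_"):-len("_uM")]: df[c].to_numpy()
            for c in df.columns
            if c.startswith("x_") and c.endswith("_uM")
        }
        return cls(
            times=df["time_min"].to_numpy(),
            substrate=df["substrate_uM"].to_numpy(),
            adpr_product=df["adpr_uM"].to_numpy(),
            cyclic_product=df["cyclic_uM"].to_numpy(),
            released_base=df["base_uM"].to_numpy(),
            exchange_products=exch,
            free_base_supplied=dict(meta.get("free_base_supplied", {})),
            protein_conc=float(meta.get("protein_conc_ug_ml", 1.0)),
        )


@dataclass(frozen=True)
class ActivityPartition:
    """Initial rates (uM/min) split into the three catalytic branches."""

    rate_hydrolysis: float
    rate_cyclization: float
    rate_base_exchange: dict[str, float]
    total_rate: float
    fraction_hydrolysis: float
    fraction_cyclization: float
    fraction_base_exchange: float
    specific_activity: float  # mU per mg protein

    @property
    def rate_base_exchange_total(self) -> float:
        return sum(self.rate_base_exchange.values())

    def to_record(self) -> dict:
        return {
            "rate_hydrolysis_uM_min": self.rate_hydrolysis,
            "rate_cyclization_uM_min": self.rate_cyclization,
            "rate_base_exchange_uM_min": dict(self.rate_base_exchange),
            "total_rate_uM_min": self.total_rate,
            "fraction_hydrolysis": self.fraction_hydrolysis,
            "fraction_cyclization": self.fraction_cyclization,
            "fraction_base_exchange": self.fraction_base_exchange,
            "specific_activity_mU_mg": self.specific_activity,
        }


@dataclass(frozen=True)
class MassBalanceReport:
    """Pointwise comparison of consumed substrate, product sum and base."""

    substrate_consumed: float
    products_sum: float
    base_released: float
    discrepancy_products: float  # max relative |consumed - products| over points
    discrepancy_base: float
    tolerance: float
    passed: bool

    def to_record(self) -> dict:
        return {
            "substrate_consumed_uM": self.substrate_consumed,
            "products_sum_uM": self.products_sum,
            "base_released_uM": self.base_released,
            "relative_discrepancy_products": self.discrepancy_products,
            "relative_discrepancy_base": self.discrepancy_base,
            "tolerance": self.tolerance,
            "pass": self.passed,
        }


@dataclass(frozen=True)
class MetaboliteMeasurement:
    """A metabolite amount with its internal-standard recovery bookkeeping."""

    analyte: str
    measured_amount: float  # nmol
    internal_standard_spiked: float  # nmol (cAMP role)
    internal_standard_recovered: float  # nmol
    protein_mass: float  # mg

    def __post_init__(self) -> None:
        for name in ("measured_amount", "internal_standard_spiked",
                     "internal_standard_recovered", "protein_mass"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.internal_standard_recovered > self.internal_standard_spiked:
            raise ValueError("recovered internal standard exceeds spiked amount")


# ---------------------------------------------------------------------------
# Initial-rate window and rate estimation
# ---------------------------------------------------------------------------


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of a straight-line OLS fit; 1.0 for a flat response (zero variance)."""
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 1.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return 1.0 - float(np.sum(resid**2)) / sst


def select_initial_window(
    tc: TimeCourse,
    max_consumed_fraction: float = DEFAULT_MAX_CONSUMED_FRACTION,
    r2_min: float = DEFAULT_R2_MIN,
) -> slice:
    """Select the initial-rate window of a progress curve.

    Returns the longest prefix (as a slice from t=0) over which cumulative
    substrate consumption stays at or below ``max_consumed_fraction`` of S0
    and the total-product-vs-time straight-line fit has R^2 >= ``r2_min``.
    At least 3 points are required; otherwise
    :class:`InsufficientLinearRange` is raised.
    """
    n = len(tc.times)
    if n < 3:
        raise InsufficientLinearRange("need at least 3 time points")
    consumed = tc.S0 - tc.substrate
    budget = max_consumed_fraction * tc.S0
    total = tc.total_products()
    best = 0
    for m in range(3, n + 1):
        if consumed[m - 1] > budget:
            break
        if _ols_r2(tc.times[:m], total[:m]) < r2_min:
            continue
        best = m
    if best < 3:
        raise InsufficientLinearRange(
            f"no 3-point prefix with consumption <= {max_consumed_fraction:.0%} "
            f"of S0 and product linearity R^2 >= {r2_min}"
        )
    return slice(0, best)


def estimate_rates(tc: TimeCourse, window: slice) -> dict[str, float]:
    """OLS slopes (uM/min) of every product, plus substrate consumption rate.

    Keys: ``hydrolysis`` (ADPR-type slope), ``cyclization``, one key per
    exchange product name, ``base`` and ``substrate_consumption``.
    """
    t = tc.times[window]
    if len(t) < 2 or np.ptp(t) == 0:
        raise ValueError("degenerate window: need spread in time")

    def slope(y: np.ndarray) -> float:
        return float(np.polyfit(t, y[window], 1)[0])

    rates = {"hydrolysis": slope(tc.adpr_product), "cyclization": slope(tc.cyclic_product)}
    for name, series in tc.exchange_products.items():
        rates[name] = slope(series)
    rates["base"] = slope(tc.released_base)
    rates["substrate_consumption"] = -slope(tc.substrate)
    return rates


def partition_activities(rates: Mapping[str, float], protein_conc: float) -> ActivityPartition:
    """Partition branch rates into fractions and a specific activity.

    ``rates`` uses the key convention of :func:`estimate_rates`; negative
    slopes from noise are clipped to zero before partitioning.  Specific
    activity counts total products formed: uM/min (= nmol mL^-1 min^-1)
    divided by protein (ug/mL) times 1000 gives mU/mg.
    """
    hyd = max(float(rates.get("hydrolysis", 0.0)), 0.0)
    cyc = max(float(rates.get("cyclization", 0.0)), 0.0)
    exch = {
        k: max(float(v), 0.0)
        for k, v in rates.items()
        if k not in ("hydrolysis", "cyclization", "base", "substrate_consumption")
    }
    total = hyd + cyc + sum(exch.values())
    if total <= 0:
        raise ValueError("no activity: total product formation rate is zero")
    if not protein_conc > 0:
        raise ValueError("protein_conc must be positive")
    return ActivityPartition(
        rate_hydrolysis=hyd,
        rate_cyclization=cyc,
        rate_base_exchange=exch,
        total_rate=total,
        fraction_hydrolysis=hyd / total,
        fraction_cyclization=cyc / total,
        fraction_base_exchange=sum(exch.values()) / total,
        specific_activity=total / protein_conc * 1000.0,
    )


def check_mass_balance(tc: TimeCourse, tolerance: float = DEFAULT_MASS_BALANCE_TOL) -> MassBalanceReport:
    """Check consumed substrate == sum of products == released base pointwise.

    Discrepancies are maximum absolute relative deviations over all time
    points with meaningful consumption (> 1e-12 * S0); the report passes iff
    both stay within ``tolerance``.
    """
    consumed = tc.S0 - tc.substrate
    products = tc.total_products()
    base = tc.released_base
    scale = np.maximum(np.abs(consumed), 1e-12 * max(tc.S0, 1.0))
    mask = consumed > 1e-12 * max(tc.S0, 1.0)
    if np.any(mask):
        d_prod = float(np.max(np.abs(products - consumed)[mask] / scale[mask]))
        d_base = float(np.max(np.abs(base - consumed)[mask] / scale[mask]))
    else:
        d_prod = d_base = 0.0
    return MassBalanceReport(
        substrate_consumed=float(consumed[-1]),
        products_sum=float(products[-1]),
        base_released=float(base[-1]),
        discrepancy_products=d_prod,
        discrepancy_base=d_base,
        tolerance=tolerance,
        passed=bool(d_prod <= tolerance and d_base <= tolerance),
    )


# ---------------------------------------------------------------------------
# Normalizations and protein quantification
# ---------------------------------------------------------------------------


def normalize_profile(values: Sequence[float]) -> np.ndarray:
    """Normalize a rate profile to its maximum (curve maximum maps to 1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or np.all(arr <= 0):
        raise ValueError("profile needs at least one positive value")
    return arr / arr.max()


def protein_from_standard_curve(
    sample_intensity: float,
    standards: Sequence[tuple[float, float]],
) -> tuple[float, bool]:
    """Protein mass (ng) from an immunoblot dilution-series standard curve.

    ``standards`` are (band intensity, mass ng) pairs; a straight line with
    free intercept is fit by least squares and the sample mass obtained by
    inverse prediction.  Returns ``(mass_ng, extrapolated)`` where the flag is
    True when the sample intensity lies outside the standard range (the value
    is still returned).
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 standards")
    intensity = np.array([s[0] for s in standards], dtype=float)
    mass = np.array([s[1] for s in standards], dtype=float)
    slope, intercept = np.polyfit(mass, intensity, 1)
    if slope == 0:
        raise ValueError("degenerate standard curve: zero slope")
    estimate = (sample_intensity - intercept) / slope
    extrapolated = not (intensity.min() <= sample_intensity <= intensity.max())
    return float(estimate), bool(extrapolated)


def normalize_metabolite(
    m: MetaboliteMeasurement, recovery_floor: float = DEFAULT_RECOVERY_FLOOR
) -> float:
    """Internal-standard-corrected metabolite level, nmol per mg protein.

    The measured amount is divided by the internal-standard recovery
    (recovered/spiked, cAMP in the reference protocol) and then by the
    protein mass extracted in parallel.  A recovery below ``recovery_floor``
    signals extraction failure.
    """
    recovery = m.internal_standard_recovered / m.internal_standard_spiked
    if recovery < recovery_floor:
        raise ValueError(
            f"extraction failure: internal-standard recovery {recovery:.2f} "
            f"below floor {recovery_floor}"
        )
    return m.measured_amount / recovery / m.protein_mass
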