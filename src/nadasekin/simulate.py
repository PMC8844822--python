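"""Synthetic data generation for the NAD(P)ase kinetic pipeline.

No raw bench measurements are deposited for these assays, so every input the
pipeline consumes is generated here: noisy initial-rate datasets drawn from
any of the rate laws, inhibition series, branching Uni-Bi progress curves and
metabolite fixtures.  The generators are seeded and deterministic, and every
output embeds the ground-truth parameters used to produce it so fits can be
audited against truth.

The progress-curve simulator follows the ordered Uni-Bi mechanism: substrate
is consumed at the rate given by the chosen rate law (converted from specific
activity to uM/min through the protein concentration in the assay), the
pyridine base is released on every catalytic event, and the common
ADP-ribosyl intermediate is resolved into hydrolysis / cyclization /
base-exchange products by fixed branch fractions.  Branch fractions are
configured constants independent of substrate concentration, mirroring the
observation that varying substrate does not change the product proportions.
Exchange products are capped by the free base supplied; once a base is
exhausted its branch flow is reassigned (ultimately to hydrolysis — water is
always available as the acceptor) and the event is logged.

The noise model for initial rates is a single multiplicative mean-one
Gaussian term, ``rate = v * (1 + eps)``, ``eps ~ N(0, CV)``, truncated so
rates stay nonnegative.

Reference ground truths from the fitted kinetic constants of the three
enzymes (hCD38, *Aplysia* cyclase, full-length hSARM1, and its SAM-TIR
fragment, each with NAD and NADP) are bundled as :data:`TABLE1_TRUTHS` and
:data:`NMN_TITRATION_TRUTHS` so fixtures and recovery studies can be
regenerated from a single source.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .accounting import TimeCourse
from .fitting import RateDataset
from .models import UNBOUNDED, evaluate_rate, params_from_record

__all__ = [
    "SimulationConfig",
    "BranchingScheme",
    "TABLE1_TRUTHS",
    "NMN_TITRATION_TRUTHS",
    "generate_initial_rates",
    "generate_ic50_series",
    "generate_inhibition_grid",
    "simulate_time_course",
    "make_fixture_suite",
]


# Fitted kinetic constants per enzyme/substrate (uM, mU/mg); absent Kis/Kia
# keys mean the constant was unbounded (censored "> 8000") in the fit.
TABLE1_TRUTHS: dict[tuple[str, str], dict] = {
    ("hCD38", "NAD"): {"model": "eq1", "Km": 10.4, "Vmax": 6649.0},
    ("hCD38", "NADP"): {"model": "eq1", "Km": 11.7, "Vmax": 4376.0},
    ("AplysiaCyclase", "NAD"): {"model": "eq1", "Km": 212.0, "Vmax": 51353.0},
    ("AplysiaCyclase", "NADP"): {"model": "eq1", "Km": 384.0, "Vmax": 20043.0},
    ("hSARM1-FL", "NAD"): {"model": "eq3", "Km": 30.3, "Vmax": 22.4, "Kia": 324.0},
    ("hSARM1-FL", "NADP"): {"model": "eq3", "Km": 66.9, "Vmax": 14.3, "Kis": 132.0},
    ("SAM-TIR", "NAD"): {"model": "eq2", "Km": 69.5, "Vmax": 723.0},
    ("SAM-TIR", "NADP"): {"model": "eq2", "Km": 83.5, "Vmax": 582.0, "Kis": 151.0},
}

# Full-length enzyme refit at fixed effector (NMN) levels, per substrate:
# effector uM -> rate-law record.
NMN_TITRATION_TRUTHS: dict[str, dict[float, dict]] = {
    "NAD": {
        5.0: {"model": "eq3", "Km": 44.1, "Vmax": 39.7, "Kia": 385.1},
        10.0: {"model": "eq3", "Km": 34.2, "Vmax": 54.1, "Kia": 414.9},
        20.0: {"model": "eq3", "Km": 44.6, "Vmax": 88.2, "Kia": 787.0},
        50.0: {"model": "eq3", "Km": 56.1, "Vmax": 161.0, "Kia": 1201.7},
    },
    "NADP": {
        5.0: {"model": "eq3", "Km": 129.3, "Vmax": 15.7, "Kis": 52.7},
        10.0: {"model": "eq3", "Km": 145.9, "Vmax": 29.9, "Kis": 57.4},
        20.0: {"model": "eq3", "Km": 145.0, "Vmax": 52.2, "Kis": 60.0},
        50.0: {"model": "eq3", "Km": 191.7, "Vmax": 98.1, "Kis": 48.0},
    },
}


@dataclass
class SimulationConfig:
    """Configuration of one initial-rate simulation.

    Defaults mirror the reference assay design: 12 log-spaced substrate points
    from 15 uM to 4 mM, 8 inhibitor points from 10 to 300 uM, multiplicative
    noise CV 0.05, one replicate.
    """

    model: str
    params: dict
    s_points: int = 12
    s_min: float = 15.0
    s_max: float = 4000.0
    log_spacing: bool = True
    i_levels: tuple[float, ...] = ()
    cv: float = 0.05
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_points < 2 or self.s_min <= 0 or self.s_max <= self.s_min:
            raise ValueError("substrate grid must be positive with s_max > s_min")
        if any(i < 0 for i in self.i_levels):
            raise ValueError("inhibitor levels must be nonnegative")
        if self.cv < 0:
            raise ValueError("noise CV must be nonnegative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def substrate_grid(self) -> np.ndarray:
        if self.log_spacing:
            return np.geomspace(self.s_min, self.s_max, self.s_points)
        return np.linspace(self.s_min, self.s_max, self.s_points)

    def to_record(self) -> dict:
        return {
            "model": self.model, "params": dict(self.params),
            "s_points": self.s_points, "s_min": self.s_min, "s_max": self.s_max,
            "log_spacing": self.log_spacing, "i_levels": list(self.i_levels),
            "cv": self.cv, "replicates": self.replicates, "seed": self.seed,
        }


@dataclass
class BranchingScheme:
    """Branching Uni-Bi consumption scheme for progress-curve simulation.

    ``model``/``params`` give the substrate consumption law (specific rate in
    mU/mg, converted to uM/min via ``protein_conc`` ug/mL).  Branch fractions
    must be nonnegative and sum to 1; an exchange fraction requires the
    corresponding free base to be supplied at simulation time.
    """

    model: str
    params: dict
    f_hydrolysis: float
    f_cyclization: float
    f_exchange: dict[str, float] = field(default_factory=dict)
    protein_conc: float = 1.0  # ug/mL

    def __post_init__(self) -> None:
        fracs = [self.f_hydrolysis, self.f_cyclization, *self.f_exchange.values()]
        if any(f < 0 for f in fracs):
            raise ValueError("branch fractions must be nonnegative")
        if not math.isclose(sum(fracs), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"branch fractions must sum to 1, got {sum(fracs)}")
        if not self.protein_conc > 0:
            raise ValueError("protein_conc must be positive")

    def consumption_rate(self, S: float) -> float:
        """Substrate consumption rate in uM/min at concentration S (uM)."""
        p = params_from_record({"model": self.model, **self.params})
        v = evaluate_rate(self.model, max(S, 0.0), p)
        return float(v) * self.protein_conc / 1000.0


# ---------------------------------------------------------------------------
# Initial-rate and inhibition-series generators
# ---------------------------------------------------------------------------


def _noisy(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return values.copy()
    eps = rng.normal(0.0, cv, size=values.shape)
    return np.clip(values * (1.0 + eps), 0.0, None)


def generate_initial_rates(cfg: SimulationConfig, enzyme: str = "", substrate: str = "") -> RateDataset:
    """Noisy initial-rate dataset from a rate law over the configured grids.

    Deterministic given ``cfg.seed``; the truth record travels in
    ``dataset.data.attrs['truth']``.
    """
    rng = np.random.default_rng(cfg.seed)
    p = params_from_record({"model": cfg.model, **cfg.params})
    S = cfg.substrate_grid()
    i_levels = cfg.i_levels or (0.0,)
    rows = []
    for rep in range(cfg.replicates):
        for i in i_levels:
            v = np.asarray(evaluate_rate(cfg.model, S, p, np.full_like(S, i)))
            noisy = _noisy(rng, v, cfg.cv)
            for s, r in zip(S, noisy):
                rows.append({"S_uM": s, "I_uM": i, "rate_mU_mg": r, "replicate": rep})
    df = pd.DataFrame(rows)
    if not any(i_levels):
        df = df.drop(columns=["I_uM"])
    df.attrs["truth"] = cfg.to_record()
    return RateDataset(data=df, enzyme=enzyme, substrate=substrate)


def generate_ic50_series(
    ic50: float,
    i_levels: tuple[float, ...] = (0.0, 10.0, 25.0, 50.0, 80.0, 120.0, 200.0, 300.0),
    cv: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy fractional-activity series from the dose-response law.

    Noise is applied to the underlying rates; the series is then renormalized
    by its measured I=0 value, as bench fractional activities are.  The I=0
    level is always included.
    """
    if 0.0 not in i_levels:
        i_levels = (0.0, *i_levels)
    rng = np.random.default_rng(seed)
    I = np.asarray(sorted(i_levels), dtype=float)
    truth = 1.0 / (1.0 + I / ic50)
    noisy = _noisy(rng, truth, cv)
    ref = noisy[I == 0.0][0]
    if ref <= 0:
        ref = 1.0
    df = pd.DataFrame({"I_uM": I, "activity": noisy / ref})
    df.attrs["truth"] = {"model": "eq4", "ic50": ic50, "cv": cv, "seed": seed}
    return df


def generate_inhibition_grid(cfg: SimulationConfig, enzyme: str = "", substrate: str = "") -> RateDataset:
    """Noisy (S, I) grid dataset from the mixed-inhibition law (``eq5``)."""
    if cfg.model != "eq5":
        raise ValueError("inhibition grids are generated from the eq5 law")
    if 0.0 not in cfg.i_levels:
        raise ValueError("the I=0 control level is required")
    return generate_initial_rates(cfg, enzyme=enzyme, substrate=substrate)


# ---------------------------------------------------------------------------
# Branching Uni-Bi progress-curve simulation
# ---------------------------------------------------------------------------


def _allocate_products(
    C: np.ndarray,
    scheme: BranchingScheme,
    bases: Mapping[str, float],
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, list[str]]:
    """Allocate cumulative consumption C(t) to branches with base caps.

    Builds the piecewise-linear cumulative product of each branch as a
    function of total consumption: within a segment the active branch
    fractions are constant; when an exchange branch exhausts its free base the
    flow is renormalized over the remaining branches (falling back entirely to
    hydrolysis if no branch with positive fraction remains).  Exact
    conservation: the per-branch cumulative products sum to C at every point.
    """
    names = list(scheme.f_exchange)
    for b, f in scheme.f_exchange.items():
        if f > 0 and bases.get(b, 0.0) <= 0:
            raise ValueError(f"exchange fraction for base {b!r} requires the free base")
    c_max = float(C[-1])
    events: list[str] = []

    # breakpoints in consumption space
    bp_c = [0.0]
    bp_products: dict[str, list[float]] = {b: [0.0] for b in ("hydrolysis", "cyclization", *names)}
    frac = {"hydrolysis": scheme.f_hydrolysis, "cyclization": scheme.f_cyclization}
    frac.update(scheme.f_exchange)
    active_exchange = {b for b in names if frac[b] > 0}
    c_now = 0.0
    while c_now < c_max:
        # next exhaustion among active exchange branches
        next_dc = math.inf
        next_base = None
        for b in active_exchange:
            room = bases.get(b, 0.0) - bp_products[b][-1]
            dc = room / frac[b] if frac[b] > 0 else math.inf
            if dc < next_dc:
                next_dc, next_base = dc, b
        dc = min(next_dc, c_max - c_now)
        c_now += dc
        bp_c.append(c_now)
        for b in bp_products:
            bp_products[b].append(bp_products[b][-1] + frac[b] * dc)
        if next_base is not None and next_dc <= c_max - (c_now - dc) and math.isclose(dc, next_dc):
            # base exhausted: reassign its flow to the remaining branches
            lost = frac[next_base]
            frac[next_base] = 0.0
            active_exchange.discard(next_base)
            remaining = frac["hydrolysis"] + frac["cyclization"] + sum(frac[b] for b in active_exchange)
            if remaining > 0:
                for k in frac:
                    frac[k] += frac[k] / remaining * lost
            else:
                frac["hydrolysis"] += lost  # water is always available
            events.append(
                f"free base {next_base!r} exhausted at consumption {c_now:.6g} uM; "
                "exchange branch renormalized"
            )

    bp_c_arr = np.asarray(bp_c)
    out = {b: np.interp(C, bp_c_arr, np.asarray(v)) for b, v in bp_products.items()}
    hyde = out.pop("hydrolysis")
    cyc = out.pop("cyclization")
    return out, hyde, cyc, events


def simulate_time_course(
    scheme: BranchingScheme,
    S0: float,
    bases: Mapping[str, float] | None = None,
    duration: float = 30.0,
    n_points: int = 13,
    tolerance: float = 1e-6,
) -> tuple[TimeCourse, list[str]]:
    """Integrate a branching Uni-Bi progress curve.

    Substrate follows ``dS/dt = -v(S)`` (adaptive Runge-Kutta, tolerances two
    orders tighter than the requested conservation ``tolerance``); products
    are allocated from cumulative consumption by the branch fractions, with
    exchange capped by the supplied free base, and the released base equals
    total consumption — so |S0 - S - sum(products)|/S0 stays below
    ``tolerance`` at every output point by construction plus integration
    accuracy.

    Returns the noiseless :class:`~nadasekin.accounting.TimeCourse` and a log
    of base-exhaustion events (empty when none occurred).
    """
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    bases = dict(bases or {})
    times = np.linspace(0.0, duration, n_points)
    rtol = min(1e-9, tolerance * 1e-2)
    sol = solve_ivp(
        lambda _, y: [-scheme.consumption_rate(y[0])],
        (0.0, duration),
        [S0],
        t_eval=times,
        method="RK45",
        rtol=rtol,
        atol=rtol * S0,
    )
    if not sol.success:
        raise RuntimeError(f"progress-curve integration failed: {sol.message}")
    S = np.clip(sol.y[0], 0.0, S0)
    S = np.minimum.accumulate(S)  # guard monotonicity against roundoff
    C = S0 - S
    exch, hyd, cyc, events = _allocate_products(C, scheme, bases)
    tc = TimeCourse(
        times=times,
        substrate=S,
        adpr_product=hyd,
        cyclic_product=cyc,
        released_base=C,
        exchange_products=exch,
        free_base_supplied=dict(bases),
        protein_conc=scheme.protein_conc,
    )
    return tc, events


# ---------------------------------------------------------------------------
# Canonical fixture suite
# ---------------------------------------------------------------------------


def make_fixture_suite(outdir: str | Path, seed: int = 0, cv: float = 0.05) -> dict:
    """Write the canonical fixture files used by tests and docs.

    Produces one noisy initial-rate CSV per reference enzyme/substrate truth,
    the NMN-titration series, an IC50 series and a mixed-inhibition grid, a
    90:10 hydrolysis:cyclization time course and a DRG-style metabolite
    record, plus ``manifest.json`` mapping every file to its generating truth
    and seed.  Regenerating with the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    k = 0
    for (enzyme, substrate), truth in TABLE1_TRUTHS.items():
        params = {key: v for key, v in truth.items() if key != "model"}
        cfg = SimulationConfig(model=truth["model"], params=params, cv=cv, seed=seed + k)
        ds = generate_initial_rates(cfg, enzyme=enzyme, substrate=substrate)
        name = f"rates_{enzyme}_{substrate}.csv"
        ds.to_csv(outdir / name)
        manifest[name] = {"kind": "initial_rates", **cfg.to_record(),
                          "enzyme": enzyme, "substrate": substrate}
        k += 1

    for substrate, series in NMN_TITRATION_TRUTHS.items():
        for level, truth in series.items():
            params = {key: v for key, v in truth.items() if key != "model"}
            cfg = SimulationConfig(model=truth["model"], params=params, cv=cv, seed=seed + k)
            ds = generate_initial_rates(cfg, enzyme="hSARM1-FL", substrate=substrate)
            name = f"rates_hSARM1-FL_{substrate}_NMN{level:g}.csv"
            ds.to_csv(outdir / name)
            manifest[name] = {"kind": "initial_rates", **cfg.to_record(),
                              "enzyme": "hSARM1-FL", "substrate": substrate,
                              "effector_uM": level}
            k += 1

    ic50_truth = 87.0  # full-length NaR
    df = generate_ic50_series(ic50_truth, cv=0.03, seed=seed + k)
    df.to_csv(outdir / "ic50_FL_NaR.csv", index=False)
    manifest["ic50_FL_NaR.csv"] = {"kind": "ic50_series", **df.attrs["truth"]}
    k += 1

    ki_cfg = SimulationConfig(
        model="eq5",
        params={"Km": 69.5, "Vmax": 723.0, "Ki": 15.0, "a": 0.5, "n": 2.0},
        s_points=8, s_min=15.0, s_max=600.0,
        i_levels=(0.0, 25.0, 50.0, 80.0, 120.0), cv=cv, seed=seed + k,
    )
    ds = generate_inhibition_grid(ki_cfg, enzyme="SAM-TIR", substrate="NAD")
    ds.to_csv(outdir / "inhibition_SAMTIR_NaR.csv")
    manifest["inhibition_SAMTIR_NaR.csv"] = {"kind": "inhibition_grid", **ki_cfg.to_record()}
    k += 1

    scheme = BranchingScheme(
        model="eq3", params={"Km": 30.3, "Vmax": 22.4, "Kia": 324.0},
        f_hydrolysis=0.9, f_cyclization=0.1, protein_conc=300.0,
    )
    tc, _ = simulate_time_course(scheme, S0=250.0, duration=30.0)
    tc.to_csv(outdir / "timecourse_90_10.csv")
    manifest["timecourse_90_10.csv"] = {
        "kind": "time_course", "model": scheme.model, "params": scheme.params,
        "f_hydrolysis": 0.9, "f_cyclization": 0.1,
        "protein_conc_ug_ml": scheme.protein_conc, "S0": 250.0, "duration_min": 30.0,
    }

    drg = {"analyte": "AcPyrAD", "measured_amount_nmol": 0.4282,
           "internal_standard_spiked_nmol": 10.0,
           "internal_standard_recovered_nmol": 9.6, "protein_mass_mg": 1.0}
    (outdir / "drg_metabolite.json").write_text(json.dumps(drg, indent=1) + "\n")
    manifest["drg_metabolite.json"] = {"kind": "metabolite_record", **drg}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
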