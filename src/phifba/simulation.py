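"""FBA/FVA simulation of pH-constrained models.

Proliferation is the maximal flux through the biomass reaction of the
constrained model (standard FBA).  Exchange readouts are computed with the
biomass flux held at a fraction of its optimum (80% by default) while each
role reaction is pushed to its flux-variability extreme — uptakes to their
most negative value, secretions to their maximum — "taking its maximal flux
as a proxy for its catalytic activity".  Total ATP/NADPH production is the
flux-sum of all producing stoichiometric terms for the metabolite across
compartments.  The anti-Warburg ratio is |OCR| / lactate secretion, the
in-silico analogue of OCR/ECAR.

Fluxes below |1e-7| are reported as exact zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from cobra.exceptions import OptimizationError

from .constraints import ConstrainedState, DEFAULT_PH_GRID, constrain_model
from .model_io import MetabolicModel

__all__ = [
    "ZERO_TOL",
    "SOLVER_TOL",
    "FluxReadout",
    "SweepCurve",
    "SimulationError",
    "apply_state",
    "optimize_biomass",
    "fva_readouts",
    "anti_warburg_ratio",
    "ph_sweep",
]

#: Reporting threshold: any |flux| below this is an exact 0 in outputs.
ZERO_TOL = 1e-7

#: Internal LP feasibility tolerance.
SOLVER_TOL = 1e-9

#: Readout roles whose FVA extreme is the minimum (most negative = uptake).
UPTAKE_ROLES = ("oxygen", "glucose")
#: Readout roles whose FVA extreme is the maximum (secretion).
SECRETION_ROLES = ("lactate", "ros")
#: Metabolite id stems whose producing flux-sum is reported.
FLUX_SUM_ROLES = {"atp_total": "atp", "nadph_total": "nadph"}

READOUT_ROLES = UPTAKE_ROLES + SECRETION_ROLES + tuple(FLUX_SUM_ROLES)


class SimulationError(RuntimeError):
    """Solver failure that is not plain infeasibility."""


def _zeroed(value: float) -> float:
    return 0.0 if abs(value) < ZERO_TOL else float(value)


class apply_state:
    """Context manager: impose a :class:`ConstrainedState`'s bounds on the
    wrapped cobra model, restoring everything on exit."""

    def __init__(self, model: MetabolicModel, state: ConstrainedState | None):
        self.model = model
        self.state = state

    def __enter__(self):
        cm = self.model.cobra
        self._ctx = cm.__enter__()
        cm.tolerance = SOLVER_TOL
        if self.state is not None:
            for c in self.state:
                cm.reactions.get_by_id(c.reaction_id).bounds = (c.lb, c.ub)
        return cm

    def __exit__(self, *exc):
        return self.model.cobra.__exit__(*exc)


def _solve_max(cm) -> float | None:
    """Maximize the current objective; None on infeasibility."""
    value = cm.slim_optimize(error_value=None)
    status = cm.solver.status
    if value is None or status != "optimal":
        if status in ("infeasible", "undefined") or value is None:
            return None
        raise SimulationError(f"solver returned status {status!r}")
    return float(value)


def optimize_biomass(model: MetabolicModel, state: ConstrainedState | None = None) -> float:
    """Maximal biomass flux of the (optionally constrained) model.

    Infeasibility reports a biomass of 0 (acidic extremes legitimately kill
    the model); genuine solver failures raise :class:`SimulationError`.
    Values below the |1e-7| zeroing threshold are exact zeros.
    """
    with apply_state(model, state) as cm:
        cm.objective = model.biomass_reaction_id
        value = _solve_max(cm)
    return 0.0 if value is None else _zeroed(value)


@dataclass
class FluxReadout:
    """Biomass plus signed exchange readouts of one model at one pH.

    ``rates`` maps the roles oxygen / glucose / lactate / atp_total /
    nadph_total / ros to signed fluxes (uptakes negative, secretions
    positive); roles absent from the model are NaN.
    """

    ph: float
    biomass: float
    rates: dict = field(default_factory=dict)
    anti_warburg: float = math.nan
    feasible: bool = True

    def as_row(self) -> dict:
        return {
            "ph": self.ph,
            "biomass": self.biomass,
            "o2": self.rates.get("oxygen", math.nan),
            "glc": self.rates.get("glucose", math.nan),
            "lac": self.rates.get("lactate", math.nan),
            "atp": self.rates.get("atp_total", math.nan),
            "nadph": self.rates.get("nadph_total", math.nan),
            "ros": self.rates.get("ros", math.nan),
            "anti_warburg": self.anti_warburg,
        }


def anti_warburg_ratio(readout) -> float:
    """|oxygen uptake| / lactate secretion (OCR over the ECAR proxy).

    Zero lactate with positive OCR is the fully oxidative limit (+inf);
    zero/zero is undefined (NaN).  Accepts a :class:`FluxReadout` or a
    rates mapping.
    """
    rates = readout.rates if isinstance(readout, FluxReadout) else readout
    ocr = abs(rates.get("oxygen", 0.0) or 0.0)
    lac = rates.get("lactate", 0.0) or 0.0
    if lac <= 0.0:
        return math.inf if ocr > 0.0 else math.nan
    return ocr / lac


def _flux_sum_expression(cm, stem: str):
    """Linear expression summing the producing terms of a metabolite family.

    ``stem`` matches metabolite ids equal to it or prefixed ``stem_`` (i.e.
    the metabolite across compartments).  Producing terms are the positive
    stoichiometric coefficients times the reaction flux.
    """
    terms = 0
    found = False
    for met in cm.metabolites:
        if met.id != stem and not met.id.startswith(stem + "_"):
            continue
        for rxn in met.reactions:
            coef = rxn.metabolites[met]
            if coef > 0:
                terms = terms + coef * rxn.flux_expression
                found = True
    return terms if found else None


def fva_readouts(
    model: MetabolicModel,
    state: ConstrainedState | None = None,
    biomass_fraction: float = 0.8,
    ph: float | None = None,
) -> FluxReadout:
    """Exchange-rate readouts with biomass held at >= fraction x optimum.

    Each uptake role reports its FVA minimum (strongest uptake), each
    secretion role its maximum; atp_total / nadph_total are the maximal
    producing flux-sums of the metabolite across compartments.  The
    anti-Warburg ratio is attached.  The fraction defaults to 0.8 and is
    supported across the 0.7-0.9 robustness range (any value in (0, 1] is
    accepted).
    """
    if not (0.0 < biomass_fraction <= 1.0):
        raise ValueError(f"biomass_fraction must be in (0, 1], got {biomass_fraction!r}")
    ph_out = ph if ph is not None else (state.ph if state is not None else math.nan)
    biomass = optimize_biomass(model, state)
    if biomass == 0.0:
        return FluxReadout(
            ph=ph_out, biomass=0.0,
            rates={r: 0.0 for r in READOUT_ROLES},
            anti_warburg=math.nan, feasible=False,
        )
    rates: dict = {}
    with apply_state(model, state) as cm:
        bio = cm.reactions.get_by_id(model.biomass_reaction_id)
        bio.lower_bound = biomass_fraction * biomass
        for role in UPTAKE_ROLES + SECRETION_ROLES:
            rid = model.exchange_ids.get(role)
            if rid is None:
                rates[role] = math.nan
                continue
            rxn = cm.reactions.get_by_id(rid)
            sense = "min" if role in UPTAKE_ROLES else "max"
            cm.objective = rxn.flux_expression
            cm.objective.direction = sense
            value = _solve_max(cm) if sense == "max" else _solve_min(cm)
            if value is None:
                raise SimulationError(
                    f"infeasible after fixing biomass >= {biomass_fraction:g} x optimum"
                )
            rates[role] = _zeroed(value)
        for role, stem in FLUX_SUM_ROLES.items():
            expr = _flux_sum_expression(cm, stem)
            if expr is None:
                rates[role] = math.nan
                continue
            cm.objective = expr
            cm.objective.direction = "max"
            value = _solve_max(cm)
            if value is None:
                raise SimulationError(
                    f"infeasible after fixing biomass >= {biomass_fraction:g} x optimum"
                )
            rates[role] = _zeroed(value)
    out = FluxReadout(ph=ph_out, biomass=biomass, rates=rates)
    out.anti_warburg = anti_warburg_ratio(out)
    return out


def _solve_min(cm) -> float | None:
    value = cm.slim_optimize(error_value=None)
    if value is None or cm.solver.status != "optimal":
        if cm.solver.status in ("infeasible", "undefined") or value is None:
            return None
        raise SimulationError(f"solver returned status {cm.solver.status!r}")
    return float(value)


@dataclass
class SweepCurve:
    """Biomass and readouts across an ordered pHi grid for one model."""

    cell_id: str
    points: list = field(default_factory=list)  # FluxReadout, ordered by ph

    @property
    def ph_grid(self) -> list:
        return [p.ph for p in self.points]

    @property
    def biomass(self) -> list:
        return [p.biomass for p in self.points]

    @property
    def normalized_biomass(self) -> list:
        """Biomass normalized by the maximum across the sweep (max = 1)."""
        peak = max(self.biomass, default=0.0)
        if peak <= 0.0:
            return [0.0 for _ in self.points]
        return [b / peak for b in self.biomass]

    @property
    def argmax_ph(self) -> float:
        return self.points[max(range(len(self.points)), key=lambda i: self.points[i].biomass)].ph

    def to_frame(self) -> pd.DataFrame:
        rows = [p.as_row() for p in self.points]
        frame = pd.DataFrame(
            rows, columns=["ph", "biomass", "o2", "glc", "lac", "atp", "nadph",
                           "ros", "anti_warburg"]
        )
        frame.insert(2, "norm_biomass", self.normalized_biomass)
        return frame

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def ph_sweep(
    model: MetabolicModel,
    profiles: dict,
    grid=None,
    biomass_fraction: float = 0.8,
    cytosol_only: bool = True,
    with_readouts: bool = True,
    cell_id: str | None = None,
) -> SweepCurve:
    """Constrain, optimize and read out the model at every grid pH.

    Per-point failures are recorded as infeasible readouts (biomass 0,
    ``feasible=False``) and the sweep continues.
    """
    if grid is None:
        grid = DEFAULT_PH_GRID()
    grid = list(grid)
    if grid != sorted(grid):
        raise ValueError("ph grid must be ordered")
    curve = SweepCurve(cell_id=cell_id or model.cobra.id)
    for ph in grid:
        state = constrain_model(model, profiles, ph, cytosol_only=cytosol_only)
        try:
            if with_readouts:
                point = fva_readouts(model, state, biomass_fraction=biomass_fraction, ph=ph)
            else:
                point = FluxReadout(ph=ph, biomass=optimize_biomass(model, state))
        except SimulationError:
            point = FluxReadout(ph=ph, biomass=0.0, feasible=False)
        curve.points.append(point)
    return curve
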