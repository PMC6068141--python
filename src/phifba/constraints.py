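"""pH-dependent gene weights, reaction weights and flux-bound scaling.

At a given intracellular pH, each profiled gene gets a fractional activity
``W_G = activity(pH) / 100`` in [0, 1]; genes without a profile are
conservatively fully active (``W_G = 1``).  Reaction weights ``W_R`` follow
from the gene-association logic — an AND (complex) takes the minimum of its
genes' weights, an OR (isozymes) the maximum — and scale the reaction's flux
bounds in a direction-aware way that never produces an invalid range.

Organelles are assumed well buffered, so by default only reactions touching
the cytosol are rescaled; knockout overrides (setting a specific gene's
weight directly) apply regardless of compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model_io import CYTOSOL, GPRTree, MetabolicModel
from .profiles import activity_at

__all__ = [
    "GeneWeightMap",
    "ReactionConstraint",
    "ConstrainedState",
    "gene_weights",
    "reaction_weight",
    "scale_bounds",
    "constrain_model",
    "DEFAULT_PH_GRID",
]


def DEFAULT_PH_GRID(start: float = 6.5, stop: float = 8.5, step: float = 0.1) -> list:
    """The default pHi grid: 6.5 to 8.5 in steps of 0.1 (inclusive)."""
    n = int(round((stop - start) / step))
    return [round(start + i * step, 10) for i in range(n + 1)]


@dataclass(frozen=True)
class GeneWeightMap:
    """pH-specific fractional activities, gene -> W_G in [0, 1]."""

    ph: float
    weights: dict

    def __post_init__(self) -> None:
        bad = {g: w for g, w in self.weights.items() if not (0.0 <= w <= 1.0)}
        if bad:
            raise ValueError(f"gene weights outside [0, 1]: {bad}")

    def __getitem__(self, gene: str) -> float:
        return self.weights[gene]


def gene_weights(profiles: dict, genes, ph: float) -> GeneWeightMap:
    """W_G for every gene at a pH: interpolated activity / 100 for profiled
    genes, 1.0 (no constraint) for unprofiled ones."""
    if not (0.0 < ph < 14.0):
        raise ValueError(f"ph must be in (0, 14), got {ph!r}")
    weights = {}
    for g in genes:
        prof = profiles.get(g)
        weights[g] = 1.0 if prof is None else activity_at(prof, ph) / 100.0
    return GeneWeightMap(ph=ph, weights=weights)


def reaction_weight(gpr: GPRTree | None, weights) -> float:
    """Evaluate a GPR tree into W_R: AND -> min, OR -> max of the children.

    ``weights`` may be a :class:`GeneWeightMap` or a plain dict.  A reaction
    without a gene association gets weight 1 (never constrained).
    """
    if gpr is None:
        return 1.0
    wmap = weights.weights if isinstance(weights, GeneWeightMap) else weights
    return float(gpr.evaluate(wmap, and_op=min, or_op=max))


def scale_bounds(v_min: float, v_max: float, w_r: float) -> tuple:
    """Scale a reaction's flux bounds by W_R without creating invalid ranges.

    - bidirectional (``v_min <= 0 <= v_max``): both bounds are scaled,
      ``(W_R * v_min, W_R * v_max)``;
    - forward (``0 <= v_min``): only the upper bound is scaled, and is kept
      at least ``v_min`` so the range stays valid;
    - reverse (``v_max <= 0``): symmetrically, only the lower bound is
      scaled and kept at most ``v_max``.
    """
    if not (0.0 <= w_r <= 1.0):
        raise ValueError(f"W_R must be in [0, 1], got {w_r!r}")
    if v_min > v_max:
        raise ValueError(f"invalid bounds ({v_min}, {v_max})")
    if v_min <= 0.0 <= v_max:
        return (w_r * v_min, w_r * v_max)
    if v_min >= 0.0:
        return (v_min, max(w_r * v_max, v_min))
    return (min(w_r * v_min, v_max), v_max)


@dataclass(frozen=True)
class ReactionConstraint:
    """One reaction's weight and scaled bounds at a given pH."""

    reaction_id: str
    w_r: float
    lb: float
    ub: float
    flag: str  # scaled | untouched-noncytosolic | untouched-noprofile

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(
                f"reaction {self.reaction_id!r}: LB {self.lb} > UB {self.ub}"
            )


@dataclass
class ConstrainedState:
    """Per-reaction weights and bounds of a model at one pH."""

    ph: float
    constraints: dict = field(default_factory=dict)  # reaction_id -> ReactionConstraint

    def __getitem__(self, reaction_id: str) -> ReactionConstraint:
        return self.constraints[reaction_id]

    def __iter__(self):
        return iter(self.constraints.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction_id": c.reaction_id, "W_R": c.w_r, "LB": c.lb, "UB": c.ub,
             "flag": c.flag}
            for c in self.constraints.values()
        ]
        return pd.DataFrame(rows, columns=["reaction_id", "W_R", "LB", "UB", "flag"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def constrain_model(
    model: MetabolicModel,
    profiles: dict,
    ph: float,
    cytosol_only: bool = True,
    gene_overrides: dict | None = None,
) -> ConstrainedState:
    """Compute the pH-constrained state of every reaction in a model.

    Reactions without a gene association keep their base bounds
    (``untouched-noprofile``).  With ``cytosol_only=True`` (the default,
    reflecting well-buffered organelles) pH scaling applies only to
    reactions touching a cytosolic metabolite; others keep their bounds
    (``untouched-noncytosolic``) unless a ``gene_overrides`` entry (a
    knockout/inhibition, gene -> weight) reaches them — overrides are not
    a pH effect and apply in every compartment.  W_R is evaluated over all
    genes of the rule; the compartment test gates the reaction, not the
    individual leaves.  With ``cytosol_only=False`` every compartment is
    constrained (the buffering robustness mode).
    """
    overrides = gene_overrides or {}
    wmap = gene_weights(profiles, model.gene_ids, ph)
    state = ConstrainedState(ph=ph)
    for rd in model.reactions:
        if rd.gpr is None:
            state.constraints[rd.id] = ReactionConstraint(
                rd.id, 1.0, rd.v_min, rd.v_max, "untouched-noprofile"
            )
            continue
        gated = (not cytosol_only) or (CYTOSOL in rd.compartments)
        rule_genes = rd.gpr.genes
        if not gated and not (rule_genes & set(overrides)):
            state.constraints[rd.id] = ReactionConstraint(
                rd.id, 1.0, rd.v_min, rd.v_max, "untouched-noncytosolic"
            )
            continue
        local = {}
        for g in rule_genes:
            if g in overrides:
                local[g] = overrides[g]
            elif gated:
                local[g] = wmap[g]
            else:
                local[g] = 1.0
        w_r = reaction_weight(rd.gpr, local)
        lb, ub = scale_bounds(rd.v_min, rd.v_max, w_r)
        state.constraints[rd.id] = ReactionConstraint(rd.id, w_r, lb, ub, "scaled")
    return state
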