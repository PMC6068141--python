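"""Metabolic model IO and gene-association (GPR) logic.

Models are held as thin wrappers around :class:`cobra.Model` (which supplies
SBML Level-3 fbc and COBRA-toolbox MATLAB readers plus the LP machinery),
augmented with the two pieces of bookkeeping the pH pipeline needs: a map
from exchange *roles* (oxygen, glucose, lactate, ...) to reaction ids, and
per-reaction boolean gene-association trees evaluated later with min/max
semantics.

A minimal JSON dialect is supported for programmatic fixtures::

    {"reactions": [{"id", "mets": {met: coef}, "lb", "ub", "gpr"}],
     "metabolites": [{"id", "compartment"}],
     "biomass": "...", "exchanges": {role: reaction_id}, "genes": [...]}
"""

from __future__ import annotations

import json
import re
from ast import BoolOp, Name, And, Or
from dataclasses import dataclass

import numpy as np
import pandas as pd
import cobra
from cobra.core.gene import GPR
from cobra.util.array import create_stoichiometric_matrix

__all__ = [
    "EXCHANGE_ROLES",
    "DEFAULT_ROLE_PATTERNS",
    "GPRTree",
    "GPRParseError",
    "ModelIOError",
    "parse_gpr",
    "MetabolicModel",
    "ReactionDef",
    "load_model",
    "model_from_json",
    "model_to_json",
    "gene_compartments",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

#: Exchange roles the simulation readouts refer to.
EXCHANGE_ROLES = ("oxygen", "glucose", "lactate", "atp_drain", "nadph_drain", "ros")

#: Default id regexes used to resolve roles in models that do not declare
#: them (common BiGG-style exchange naming); all configurable.
DEFAULT_ROLE_PATTERNS = {
    "oxygen": r"^EX_o2(_.+)?$",
    "glucose": r"^EX_glc(__D)?(_.+)?$",
    "lactate": r"^EX_lac(__L|__D)?(_.+)?$",
    "atp_drain": r"^(DM|EX)_atp(_.+)?$",
    "nadph_drain": r"^(DM|EX)_nadph(_.+)?$",
    "ros": r"^EX_ros(_.+)?$",
}

#: Compartment code treated as cytosol throughout the pipeline.
CYTOSOL = "c"


class ModelIOError(ValueError):
    """Raised for malformed model files or unresolvable configuration."""


class GPRParseError(ModelIOError):
    """Raised when a gene-association rule cannot be parsed."""


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRTree:
    """Boolean gene-association expression: a gene leaf or an AND/OR node.

    ``kind`` is one of ``"gene"``, ``"and"``, ``"or"``; AND/OR nodes carry
    at least two children.
    """

    kind: str
    gene: str | None = None
    children: tuple = ()

    def __post_init__(self) -> None:
        if self.kind == "gene":
            if not self.gene:
                raise GPRParseError("gene leaf without a gene id")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise GPRParseError(f"{self.kind!r} node needs >= 2 children")
        else:
            raise GPRParseError(f"unknown GPR node kind {self.kind!r}")

    @property
    def genes(self) -> frozenset:
        if self.kind == "gene":
            return frozenset([self.gene])
        return frozenset().union(*(c.genes for c in self.children))

    def evaluate(self, weights: dict, and_op=min, or_op=max) -> float:
        """Fold the tree with the given connective operators.

        With ``and_op=min`` / ``or_op=max`` (the defaults) this is exactly
        the reaction-weight semantics: an enzyme complex (AND) is as active
        as its least active subunit, isozymes (OR) as active as the best one.
        """
        if self.kind == "gene":
            try:
                return weights[self.gene]
            except KeyError:
                raise KeyError(f"no weight for gene {self.gene!r}") from None
        op = and_op if self.kind == "and" else or_op
        return op(c.evaluate(weights, and_op, or_op) for c in self.children)

    def to_string(self) -> str:
        if self.kind == "gene":
            return self.gene
        sep = f" {self.kind} "
        parts = []
        for child in self.children:
            s = child.to_string()
            # parenthesize AND below OR is unnecessary; OR below AND is required
            if self.kind == "and" and child.kind == "or":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


def _from_ast(node, known_genes=None) -> GPRTree:
    if isinstance(node, Name):
        if known_genes is not None and node.id not in known_genes:
            raise ModelIOError(f"gene-association references undeclared gene {node.id!r}")
        return GPRTree(kind="gene", gene=node.id)
    if isinstance(node, BoolOp):
        kind = "and" if isinstance(node.op, And) else "or"
        children = tuple(_from_ast(v, known_genes) for v in node.values)
        return GPRTree(kind=kind, children=children)
    raise GPRParseError(f"unsupported GPR construct {type(node).__name__}")


def parse_gpr(rule: str, known_genes=None) -> GPRTree | None:
    """Parse a gene-association rule string into a :class:`GPRTree`.

    Standard boolean precedence applies (parentheses > and > or) and the
    connectives are case-insensitive.  Empty rules give ``None``.  When
    ``known_genes`` is provided, leaves must be members of it.
    """
    if rule is None or not rule.strip():
        return None
    rule = re.sub(r"\b[Aa][Nn][Dd]\b", "and", rule)
    rule = re.sub(r"\b[Oo][Rr]\b", "or", rule)
    try:
        gpr = GPR.from_string(rule)
    except (SyntaxError, TypeError) as exc:  # cobra re-raises python syntax errors
        raise GPRParseError(f"cannot parse GPR {rule!r}: {exc}") from exc
    if gpr.body is None:
        raise GPRParseError(f"cannot parse GPR {rule!r}")
    return _from_ast(gpr.body, known_genes)


# ---------------------------------------------------------------------------
# Model wrapper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionDef:
    """Static view of one reaction: bounds, GPR tree, touched compartments."""

    id: str
    v_min: float
    v_max: float
    gpr: GPRTree | None
    compartments: frozenset

    def __post_init__(self) -> None:
        if self.v_min > self.v_max:
            raise ModelIOError(
                f"reaction {self.id!r} has v_min {self.v_min} > v_max {self.v_max}"
            )


class MetabolicModel:
    """A stoichiometric model plus the pH pipeline's bookkeeping.

    Wraps a :class:`cobra.Model`; exposes the stoichiometric matrix,
    per-reaction :class:`ReactionDef` views, the biomass reaction id and the
    exchange-role map.  The underlying cobra model is the single source of
    truth for bounds and the LP solves.
    """

    def __init__(
        self,
        cobra_model: cobra.Model,
        biomass_reaction_id: str,
        exchange_ids: dict | None = None,
        role_patterns: dict | None = None,
    ):
        if biomass_reaction_id not in {r.id for r in cobra_model.reactions}:
            raise ModelIOError(f"biomass reaction {biomass_reaction_id!r} not in model")
        cobra_model.solver = "glpk"  # deterministic, single-threaded
        self.cobra = cobra_model
        self.biomass_reaction_id = biomass_reaction_id
        self.exchange_ids = self._resolve_roles(exchange_ids, role_patterns)
        self._gpr_cache: dict = {}
        self.cobra.objective = biomass_reaction_id

    def _resolve_roles(self, explicit, patterns) -> dict:
        roles = dict(explicit or {})
        for role, rid in roles.items():
            if role not in EXCHANGE_ROLES:
                raise ModelIOError(f"unknown exchange role {role!r}")
            if rid not in {r.id for r in self.cobra.reactions}:
                raise ModelIOError(f"exchange role {role!r} maps to missing reaction {rid!r}")
        pats = dict(DEFAULT_ROLE_PATTERNS)
        pats.update(patterns or {})
        for role in EXCHANGE_ROLES:
            if role in roles:
                continue
            rx = re.compile(pats[role])
            hits = [r.id for r in self.cobra.reactions if rx.match(r.id)]
            if len(hits) == 1:
                roles[role] = hits[0]
            elif len(hits) > 1:
                raise ModelIOError(f"role {role!r} pattern matches several reactions: {hits}")
            # zero hits: the role is simply absent from this model
        return roles

    # -- static views ------------------------------------------------------

    @property
    def gene_ids(self) -> list:
        return [g.id for g in self.cobra.genes]

    @property
    def reaction_ids(self) -> list:
        return [r.id for r in self.cobra.reactions]

    @property
    def metabolites(self) -> list:
        return [(m.id, m.compartment) for m in self.cobra.metabolites]

    @property
    def S(self) -> np.ndarray:
        return create_stoichiometric_matrix(self.cobra)

    def gpr_tree(self, reaction_id: str) -> GPRTree | None:
        if reaction_id not in self._gpr_cache:
            rule = self.cobra.reactions.get_by_id(reaction_id).gene_reaction_rule
            self._gpr_cache[reaction_id] = parse_gpr(rule)
        return self._gpr_cache[reaction_id]

    def reaction_compartments(self, reaction_id: str) -> frozenset:
        rxn = self.cobra.reactions.get_by_id(reaction_id)
        return frozenset(m.compartment for m in rxn.metabolites if m.compartment)

    def reaction_def(self, reaction_id: str) -> ReactionDef:
        rxn = self.cobra.reactions.get_by_id(reaction_id)
        return ReactionDef(
            id=rxn.id,
            v_min=rxn.lower_bound,
            v_max=rxn.upper_bound,
            gpr=self.gpr_tree(rxn.id),
            compartments=self.reaction_compartments(rxn.id),
        )

    @property
    def reactions(self) -> list:
        return [self.reaction_def(rid) for rid in self.reaction_ids]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            self.cobra.copy(),
            self.biomass_reaction_id,
            exchange_ids=dict(self.exchange_ids),
        )


def gene_compartments(model: MetabolicModel) -> dict:
    """Map each gene to the union of compartments of its reactions.

    A gene referenced by no reaction maps to the empty set.  Downstream,
    a gene (and its reactions) counts as cytosolic if any of its reactions
    touches a cytosolic metabolite — a conservative superset.
    """
    out = {g: set() for g in model.gene_ids}
    for rd in model.reactions:
        if rd.gpr is None:
            continue
        comps = rd.compartments
        for g in rd.gpr.genes:
            out.setdefault(g, set()).update(comps)
    return {g: frozenset(c) for g, c in out.items()}


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def model_from_json(data, exchange_ids=None, role_patterns=None) -> MetabolicModel:
    """Build a model from the fixture JSON dialect (dict or JSON string)."""
    if isinstance(data, str):
        data = json.loads(data)
    cm = cobra.Model(data.get("id", "model"))
    mets = {}
    for m in data.get("metabolites", []):
        met = cobra.Metabolite(m["id"], compartment=m.get("compartment", CYTOSOL))
        mets[m["id"]] = met
    cm.add_metabolites(list(mets.values()))
    declared_genes = set(data["genes"]) if "genes" in data else None
    rxns = []
    for r in data["reactions"]:
        rxn = cobra.Reaction(r["id"], lower_bound=float(r["lb"]), upper_bound=float(r["ub"]))
        rxns.append(rxn)
    cm.add_reactions(rxns)
    for r, rxn in zip(data["reactions"], rxns):
        rxn.add_metabolites({mets[mid]: coef for mid, coef in r.get("mets", {}).items()})
        rule = r.get("gpr", "") or ""
        if rule:
            parse_gpr(rule, known_genes=declared_genes)  # validates against declared genes
            rxn.gene_reaction_rule = rule
    if "biomass" not in data:
        raise ModelIOError("JSON model lacks a biomass reaction id")
    return MetabolicModel(
        cm,
        biomass_reaction_id=data["biomass"],
        exchange_ids=data.get("exchanges") or exchange_ids,
        role_patterns=role_patterns,
    )


def model_to_json(model: MetabolicModel) -> dict:
    """Serialize a model back into the fixture JSON dialect."""
    return {
        "id": model.cobra.id,
        "metabolites": [
            {"id": mid, "compartment": comp} for mid, comp in model.metabolites
        ],
        "reactions": [
            {
                "id": rxn.id,
                "mets": {m.id: coef for m, coef in sorted(
                    rxn.metabolites.items(), key=lambda kv: kv[0].id)},
                "lb": rxn.lower_bound,
                "ub": rxn.upper_bound,
                "gpr": rxn.gene_reaction_rule,
            }
            for rxn in model.cobra.reactions
        ],
        "genes": sorted(model.gene_ids),
        "biomass": model.biomass_reaction_id,
        "exchanges": dict(model.exchange_ids),
    }


def load_model(
    path,
    format: str | None = None,
    biomass_reaction_id: str | None = None,
    exchange_ids: dict | None = None,
    role_patterns: dict | None = None,
) -> MetabolicModel:
    """Load a model from SBML L3(+fbc), the JSON fixture dialect, or a
    COBRA-toolbox MATLAB file (``format="mat"``, the deposited-cell-model
    adapter).

    For SBML/MAT, ``biomass_reaction_id`` may be omitted if exactly one
    reaction id contains "biomass" (case-insensitive).
    """
    path = str(path)
    if format is None:
        format = {"xml": "sbml", "sbml": "sbml", "json": "json", "mat": "mat"}.get(
            path.rsplit(".", 1)[-1].lower(), "sbml"
        )
    if format == "json":
        with open(path) as fh:
            data = json.load(fh)
        return model_from_json(data, exchange_ids=exchange_ids, role_patterns=role_patterns)
    if format == "sbml":
        try:
            cm = cobra.io.read_sbml_model(path)
        except Exception as exc:
            raise ModelIOError(f"malformed SBML file {path}: {exc}") from exc
    elif format == "mat":
        try:
            cm = cobra.io.load_matlab_model(path)
        except Exception as exc:
            raise ModelIOError(f"cannot read MATLAB model {path}: {exc}") from exc
    else:
        raise ModelIOError(f"unknown model format {format!r}")
    if biomass_reaction_id is None:
        candidates = [r.id for r in cm.reactions if "biomass" in r.id.lower()]
        if len(candidates) != 1:
            raise ModelIOError(
                f"cannot infer the biomass reaction (candidates: {candidates}); "
                "pass biomass_reaction_id explicitly"
            )
        biomass_reaction_id = candidates[0]
    return MetabolicModel(
        cm, biomass_reaction_id, exchange_ids=exchange_ids, role_patterns=role_patterns
    )


# ---------------------------------------------------------------------------
# Screen result IO
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "target", "level", "SEL", "PHS", "sel_recurrence", "phs_recurrence",
    "quadrant", "dOCR", "dGlc", "dLac", "dATP", "dNADPH", "dROS",
    "anti_warburg_low", "anti_warburg_phys",
]


def write_results(scores, path) -> None:
    """Write knockout scores as a TSV, sorted by PHS then SEL (descending),
    ties broken by target id; deterministic column order; lossless
    round-trip via :func:`read_results`."""
    rows = []
    for s in scores:
        rows.append({col: getattr(s, _attr_for(col)) for col in RESULT_COLUMNS})
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(frame):
        frame = frame.sort_values(
            by=["PHS", "SEL", "target"], ascending=[False, False, True]
        ).reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _attr_for(column: str) -> str:
    return {"target": "target_id"}.get(column, column)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
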