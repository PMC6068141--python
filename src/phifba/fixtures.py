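"""Synthetic toy cells, profile databases and activity records.

The toy metabolic network is a hand-verifiable caricature of central carbon
metabolism: glucose uptake feeds a lumped glycolytic chain ending in a
pyruvate-kinase-like junction (optionally split into a major and a minor
isozyme, and optionally OR-gated by a paralog pair), pyruvate is either
secreted as lactate or imported into a mitochondrial compartment and
respired, and biomass is drawn from ATP (plus NADPH via a lumped pentose
shunt).  Stoichiometry uses round numbers — fermentation yields 2 ATP per
glucose, the lumped respiratory path 14 ATP per pyruvate (30 per glucose)
at a cost of 3 O2 — so LP optima can be checked by hand or by exhaustive
vertex enumeration.

Profile generators emulate the cancer/normal dichotomy at toy scale:
``cancer_like`` gives the glycolytic genes alkaline-shifted activity
plateaus and the mitochondrial pyruvate importer a neutral profile that
falls off at alkaline pH, so proliferation peaks above pH 7.3 and collapses
under intracellular acidification; ``normal_like`` gives every gene a broad
plateau covering the physiological range, so proliferation is
pH-insensitive.  Inert, gene-bearing "padding" reactions emulate the bulk
of a genome-scale model that never limits growth; they are what makes
random profile-to-enzyme reassignment destroy, rather than relocate, the
engineered pH response.

Quantitative thresholds asserted on these fixtures in the test suite are
reference-run values committed with their seeds (regression tests), not
biological claims.

Also here: the ratiometric SNARF-1 calibration that converts a 580/640
fluorescence ratio into an intracellular pH.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .model_io import MetabolicModel, model_from_json
from .profiles import (
    CRITICAL_POINTS,
    POINT_LEVELS,
    ActivityRecord,
    PHProfile,
)

__all__ = [
    "ToySpec",
    "make_toy_model",
    "make_profiles",
    "make_screen_panel",
    "make_activity_records",
    "CalibrationConstants",
    "MCF7_CALIBRATION",
    "snarf_ph",
]


# ---------------------------------------------------------------------------
# Toy model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToySpec:
    """Parameters of the synthetic toy cell.

    ``aux_uptake`` opens an auxiliary oxidisable substrate (amino-acid-like)
    that bypasses glycolysis; normal-like cells get a generous allowance,
    cancer-like cells none, mirroring the lower glycolytic dependence of
    normal cells.  ``n_padding_genes`` adds inert gene-bearing reactions.
    """

    n_glycolysis_steps: int = 1
    include_oxphos: bool = True
    include_lactate_exchange: bool = True
    include_ppp: bool = True
    include_ros: bool = True
    split_junction: bool = True
    paralog_pairs: tuple = ()
    glucose_uptake: float = 20.0
    o2_uptake: float = 6.0
    aux_uptake: float = 0.0
    n_padding_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glycolysis_steps < 1:
            raise ValueError("need at least one glycolytic step")
        if not self.include_oxphos and not self.include_lactate_exchange:
            raise ValueError(
                "contradictory spec: pyruvate needs a sink "
                "(oxphos and lactate exchange both disabled)"
            )
        if self.aux_uptake and not self.include_oxphos:
            raise ValueError("the auxiliary substrate is oxidised; needs oxphos")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ToySpec":
        data = json.loads(text)
        data["paralog_pairs"] = tuple(tuple(p) for p in data.get("paralog_pairs", []))
        return cls(**data)

    # gene-name helpers used by the profile generators
    @property
    def chain_genes(self) -> tuple:
        return tuple(f"gly{i}" for i in range(1, self.n_glycolysis_steps + 1))

    @property
    def glycolytic_genes(self) -> tuple:
        """Genes whose profiles are alkaline-shifted in the cancer phenotype."""
        genes = list(self.chain_genes)
        genes.append("gjxB" if self.split_junction else "gjx")
        if self.include_lactate_exchange:
            genes.append("ldh")
        if self.include_ppp:
            genes.append("ppp")
        return tuple(genes)


def make_toy_model(spec: ToySpec) -> MetabolicModel:
    """Build the deterministic toy model described by a :class:`ToySpec`."""
    mets: list = []
    rxns: list = []

    def met(mid: str, comp: str) -> str:
        mets.append({"id": mid, "compartment": comp})
        return mid

    def rxn(rid, stoich, lb, ub, gpr=""):
        rxns.append({"id": rid, "mets": stoich, "lb": lb, "ub": ub, "gpr": gpr})

    g_up = spec.glucose_uptake
    met("glc_c", "c")
    rxn("EX_glc", {"glc_c": -1}, -g_up, 0.0)

    # glycolytic chain: glc -> ... -> junction substrate, one gene per step;
    # the first paralog pair OR-gates the junction, extras decorate the chain
    prev = "glc_c"
    pairs = list(spec.paralog_pairs)
    junction_pair = pairs.pop(0) if pairs else None
    for i, gene in enumerate(spec.chain_genes, start=1):
        nxt = met(f"gint{i}_c", "c")
        rule = gene
        if i > 1 and pairs:
            a, b = pairs.pop(0)
            rule = f"{a} or {b}"
        rxn(f"GLY{i}", {prev: -1, nxt: 1}, 0.0, g_up, rule)
        prev = nxt

    met("pyr_c", "c")
    met("atp_c", "c")
    junction = {prev: -1, "pyr_c": 2, "atp_c": 2}
    pair_rule = f"{junction_pair[0]} or {junction_pair[1]}" if junction_pair else None
    if spec.split_junction:
        rxn("JXA", dict(junction), 0.0, 12.0, pair_rule or "gjxA")
        rxn("JXB", dict(junction), 0.0, g_up, "gjxB")
    else:
        rxn("JX", dict(junction), 0.0, g_up, pair_rule or "gjx")

    exchanges = {"glucose": "EX_glc", "atp_drain": "DM_atp"}
    rxn("DM_atp", {"atp_c": -1}, 0.0, 1000.0)

    if spec.include_lactate_exchange:
        met("lac_c", "c")
        rxn("LDH", {"pyr_c": -1, "lac_c": 1}, 0.0, 3.0 * g_up, "ldh")
        rxn("EX_lac", {"lac_c": -1}, 0.0, 1000.0)
        exchanges["lactate"] = "EX_lac"

    if spec.include_oxphos:
        met("o2_c", "c")
        met("o2_m", "m")
        met("pyr_m", "m")
        met("atp_m", "m")
        rxn("EX_o2", {"o2_c": -1}, -spec.o2_uptake, 0.0)
        rxn("O2T", {"o2_c": -1, "o2_m": 1}, 0.0, 1000.0)
        rxn("MPC", {"pyr_c": -1, "pyr_m": 1}, 0.0, 1.0, "mpc")
        oxphos = {"pyr_m": -1, "o2_m": -3, "atp_m": 14}
        if spec.include_ros:
            met("ros_m", "m")
            met("ros_c", "c")
            oxphos["ros_m"] = 1
            rxn("ROST", {"ros_m": -1, "ros_c": 1}, 0.0, 1000.0)
            rxn("EX_ros", {"ros_c": -1}, 0.0, 1000.0)
            exchanges["ros"] = "EX_ros"
        rxn("OXPHOS", oxphos, 0.0, 1000.0, "oxp")
        rxn("ATPT", {"atp_m": -1, "atp_c": 1}, 0.0, 1000.0)
        exchanges["oxygen"] = "EX_o2"
        if spec.aux_uptake > 0:
            met("aa_c", "c")
            rxn("EX_aa", {"aa_c": -1}, -spec.aux_uptake, 0.0)
            rxn("AAOX", {"aa_c": -1, "o2_c": -2, "atp_c": 8}, 0.0, 1000.0, "aaox")

    biomass = {"atp_c": -20}
    if spec.include_ppp:
        met("nadph_c", "c")
        met("co2_c", "c")
        rxn("PPP", {"glc_c": -1, "nadph_c": 2, "co2_c": 6}, 0.0, g_up, "ppp")
        rxn("EX_co2", {"co2_c": -1}, 0.0, 1000.0)
        rxn("DM_nadph", {"nadph_c": -1}, 0.0, 1000.0)
        exchanges["nadph_drain"] = "DM_nadph"
        biomass["nadph_c"] = -2
    rxn("BIOMASS", biomass, 0.0, 1000.0)

    for i in range(1, spec.n_padding_genes + 1):
        met(f"pad{i}_c", "c")
        met(f"pad{i}_m", "m")
        rxn(f"PAD{i}", {f"pad{i}_c": -1, f"pad{i}_m": 1}, -1000.0, 1000.0, f"pad{i}")

    data = {
        "id": f"toy-{spec.seed}",
        "metabolites": mets,
        "reactions": rxns,
        "biomass": "BIOMASS",
        "exchanges": exchanges,
    }
    return model_from_json(data)


# ---------------------------------------------------------------------------
# Profile databases
# ---------------------------------------------------------------------------

# Template six-point profiles (A0, A50, A100, B100, B50, B0)
ALKALINE_SHIFTED = (6.6, 7.0, 7.3, 7.6, 7.9, 8.2)   # cancer-like glycolysis
NEUTRAL_NARROW = (6.0, 6.3, 6.6, 7.3, 7.8, 8.3)     # respiratory gateway
BROAD_FLAT = (5.5, 6.0, 6.4, 8.0, 8.4, 8.8)         # effectively unregulated
NORMAL_BROAD = (5.6, 6.0, 6.5, 7.9, 8.3, 8.7)       # normal-like everything


def _profile(gene: str, template, shift: float = 0.0) -> PHProfile:
    prof = PHProfile(enzyme_id=gene)
    for name, value in zip(CRITICAL_POINTS, template):
        prof.set_point(name, round(value + shift, 6), "experimental")
    return prof


def make_profiles(model: MetabolicModel, phenotype: str, seed: int = 0,
                  jitter: float = 0.03) -> dict:
    """Generate a profile db for every gene of a toy model.

    ``cancer_like``: glycolytic genes (chain, minor junction isozyme,
    lactate and pentose branches) get alkaline-shifted plateaus, the
    mitochondrial pyruvate importer a neutral profile declining above
    pH 7.3, everything else broad flat plateaus.  ``normal_like``: every
    gene gets a broad plateau covering 6.5-7.9, so the model is
    pH-insensitive across the physiological range.  Each gene's template is
    rigidly shifted by a seeded uniform jitter (+/- ``jitter`` pH units), so
    ordering always holds and output is byte-reproducible for a seed.
    """
    if phenotype not in ("cancer_like", "normal_like"):
        raise ValueError(f"unknown phenotype {phenotype!r}")
    rng = np.random.default_rng(seed)
    db: dict = {}
    for gene in sorted(model.gene_ids):
        shift = float(rng.uniform(-jitter, jitter))
        if phenotype == "normal_like":
            template = NORMAL_BROAD
        elif gene.startswith(("gly", "ldh", "ppp")) or gene in ("gjxB", "gjx"):
            template = ALKALINE_SHIFTED
        elif gene == "mpc":
            template = NEUTRAL_NARROW
            shift = 0.0  # the respiratory gate anchors the OCR response
        else:
            template = BROAD_FLAT
        db[gene] = _profile(gene, template, shift)
    return db


def make_screen_panel(n_cancer: int = 2, n_normal: int = 3, seed: int = 0):
    """Toy cancer/normal panels plus one shared profile db for KO screens.

    Cancer members lack the auxiliary oxidisable substrate (fully
    glycolysis-dependent); normal members carry a generous allowance and
    more oxygen.  Per-cell glucose allowances are jittered so pair scores
    vary.  In the shared db the minor junction isozyme ("gjxB") is the only
    alkaline-shifted gene: knocking out the major isozyme ("gjxA") forces
    flux through it, which fails at acidic pH — the engineered selective
    and pH-specific target.
    """
    rng = np.random.default_rng(seed)

    def build(kind: str, idx: int) -> MetabolicModel:
        glc = 20.0 * (1.0 + 0.05 * float(rng.uniform(-1, 1)))
        if kind == "cancer":
            spec = ToySpec(glucose_uptake=glc, o2_uptake=6.0, aux_uptake=0.0,
                           seed=seed * 101 + idx)
        else:
            spec = ToySpec(glucose_uptake=glc, o2_uptake=20.0, aux_uptake=5.0,
                           seed=seed * 101 + 50 + idx)
        model = make_toy_model(spec)
        model.cobra.id = f"{kind}{idx}"
        return model

    cancer = [build("cancer", i) for i in range(n_cancer)]
    normal = [build("normal", i) for i in range(n_normal)]
    genes = sorted(set().union(*(m.gene_ids for m in cancer + normal)))
    db = {}
    for gene in genes:
        template = ALKALINE_SHIFTED if gene == "gjxB" else BROAD_FLAT
        db[gene] = _profile(gene, template)
    return cancer, normal, db


# ---------------------------------------------------------------------------
# Activity records (inverse of curation, for round-trip testing)
# ---------------------------------------------------------------------------

def make_activity_records(
    db: dict,
    records_per_point: int = 1,
    noise: float = 0.0,
    seed: int = 0,
) -> list:
    """Emit noisy activity records around each critical point of each profile.

    100%-level points yield "optimum" records, the others "range" records
    with a representative activity inside their bin (10% for the zero
    level, 50% for half-activity).  Gaussian pH noise of s.d. ``noise`` is
    added per record.  Curating the output with
    :func:`phifba.profiles.build_profiles` recovers each critical point to
    within about ``2 * noise / sqrt(records_per_point)`` on average.
    """
    rng = np.random.default_rng(seed)
    level_activity = {0: 10.0, 50: 50.0, 100: 100.0}
    records: list = []
    for enzyme_id in sorted(db):
        prof = db[enzyme_id]
        prof.validate()
        for name in CRITICAL_POINTS:
            level = POINT_LEVELS[name]
            for _ in range(records_per_point):
                ph = prof.point(name) + (float(rng.normal(0.0, noise)) if noise else 0.0)
                ph = min(max(ph, 0.01), 13.99)
                records.append(
                    ActivityRecord(
                        enzyme_id=enzyme_id,
                        ec="0.0.0.0",
                        taxon="synthetic",
                        ph=ph,
                        activity_pct=level_activity[level],
                        record_kind="optimum" if level == 100 else "range",
                    )
                )
    return records


# ---------------------------------------------------------------------------
# SNARF-1 ratiometric pH calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationConstants:
    """In-situ SNARF-1 calibration constants for one cell line.

    ``r_min`` and ``r_max`` are the asymptotic 580/640 fluorescence ratios
    at the acidic and basic ends of the calibration curve.
    """

    pKa: float
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if self.r_min == self.r_max:
            raise ValueError("degenerate calibration: R_min == R_max")


#: In-situ calibration constants measured for MCF7 breast cancer cells.
MCF7_CALIBRATION = CalibrationConstants(pKa=7.30, r_min=2.54, r_max=0.56)


def snarf_ph(R: float, constants: CalibrationConstants = MCF7_CALIBRATION) -> float:
    """Intracellular pH from a 580/640 SNARF-1 fluorescence ratio.

    ``pH = pKa - log10((R - R_max) / (R_min - R))`` — the base-10 log
    follows the Henderson-Hasselbalch convention.  ``R`` must lie strictly
    between the two asymptotic ratios; at the arithmetic midpoint the log
    term vanishes and the pH equals the pKa.
    """
    lo, hi = sorted((constants.r_min, constants.r_max))
    if not (lo < R < hi):
        raise ValueError(
            f"ratio {R!r} outside the open calibration interval ({lo}, {hi})"
        )
    return constants.pKa - math.log10((R - constants.r_max) / (constants.r_min - R))
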