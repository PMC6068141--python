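"""Gene- and reaction-level knockout screening across cell panels.

A knockout (KO) of gene G is simulated by overriding its weight to
``W_G = 0-0.1`` (0 = full KO, up to 0.1 = 90% inhibition) inside the same
constraint machinery used for the pH profiles; a reaction KO forces the
reaction's bounds to zero.  The effect on proliferation is the normalized
biomass ``nB = B_KO / B_WT`` at a given pH, from which two ranking scores
are built:

- selectivity ``SEL = nB^normal - nB^cancer`` at low pH, evaluated over all
  cancer x normal pairs — positive means the KO impairs cancer cells more;
- pH-specificity ``PHS = nB(pH 7.3) - nB(pH 6.7)`` per cancer cell —
  positive means the KO bites harder under intracellular acidification.

Targets must exceed a strict |1e-7| zero threshold and recur in at least
12.5% of the comparisons (12/96 pairs for selectivity, 1/8 cells for
pH-specificity, on a full 8 x 12 cell panel).  Targets are classified into
quadrants by which of the two criteria they pass, and re-evaluated for
their anti-Warburg (OCR/ECAR) consequences.

The module also houses the divide-and-conquer modulator search (which gene
subsets carry the pH response) and the robustness suite (profile
perturbation and random profile reassignment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats

from .constraints import constrain_model, ReactionConstraint
from .model_io import MetabolicModel
from .profiles import CRITICAL_POINTS, PHProfile
from .simulation import ZERO_TOL, fva_readouts, optimize_biomass

__all__ = [
    "KOScore",
    "PanelConfig",
    "knockout_gene",
    "knockout_reaction",
    "normalized_biomass",
    "sel_score",
    "phs_score",
    "recurrence_filter",
    "classify_target",
    "run_screen",
    "divide_and_conquer",
    "perturb_db",
    "robustness_suite",
]

QUADRANTS = (
    "selective_and_ph_specific",
    "selective_only",
    "ph_specific_only",
    "neither",
)


@dataclass
class PanelConfig:
    """Screen configuration: model panels, pH regimes and thresholds."""

    cancer_models: list
    normal_models: list
    ph_low: float = 6.7
    ph_phys: float = 7.3
    inhibition: float = 0.0          # residual W_G of a "knocked-out" gene
    zero_tol: float = ZERO_TOL
    recurrence_min: float = 0.125
    biomass_fraction: float = 0.8
    cytosol_only: bool = True

    def __post_init__(self) -> None:
        if self.ph_low > self.ph_phys:
            # equality is allowed as a degenerate diagnostic (PHS == 0)
            raise ValueError("ph_low must not exceed ph_phys")
        if not (0.0 <= self.inhibition <= 0.1):
            raise ValueError("inhibition (residual W_G) must be in [0, 0.1]")


@dataclass
class KOScore:
    """Scores of one knockout target across the panel."""

    target_id: str
    level: str                              # "gene" | "reaction"
    nB: dict = field(default_factory=dict)  # (cell_id, ph) -> normalized biomass
    SEL: float = math.nan
    PHS: float = math.nan
    sel_pairs: list = field(default_factory=list)
    phs_values: list = field(default_factory=list)
    sel_recurrence: float = 0.0
    phs_recurrence: float = 0.0
    quadrant: str = "neither"
    dOCR: float = math.nan
    dGlc: float = math.nan
    dLac: float = math.nan
    dATP: float = math.nan
    dNADPH: float = math.nan
    dROS: float = math.nan
    anti_warburg_low: float = math.nan
    anti_warburg_phys: float = math.nan


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def knockout_gene(
    model: MetabolicModel,
    profiles: dict,
    gene: str,
    ph: float,
    w_ko: float = 0.0,
    cytosol_only: bool = True,
) -> float:
    """Biomass after overriding one gene's weight to ``w_ko`` (0-0.1).

    The override applies in every compartment (a knockout is not a pH
    effect); pH profiles still apply under the usual cytosol gate.
    """
    if gene not in model.gene_ids:
        raise KeyError(f"unknown gene {gene!r}")
    if not (0.0 <= w_ko <= 0.1):
        raise ValueError(f"w_ko must be in [0, 0.1], got {w_ko!r}")
    state = constrain_model(
        model, profiles, ph, cytosol_only=cytosol_only, gene_overrides={gene: w_ko}
    )
    return optimize_biomass(model, state)


def knockout_reaction(
    model: MetabolicModel,
    profiles: dict,
    reaction: str,
    ph: float,
    cytosol_only: bool = True,
) -> float:
    """Biomass after forcing one reaction's bounds to (0, 0)."""
    if reaction not in model.reaction_ids:
        raise KeyError(f"unknown reaction {reaction!r}")
    state = constrain_model(model, profiles, ph, cytosol_only=cytosol_only)
    state.constraints[reaction] = ReactionConstraint(reaction, 0.0, 0.0, 0.0, "knockout")
    return optimize_biomass(model, state)


def normalized_biomass(b_ko: float, b_wt: float, zero_tol: float = ZERO_TOL) -> float:
    """``nB = B_KO / B_WT``; a dead wild type gives 1 if the KO is equally
    dead, NaN (flagged undefined) otherwise."""
    if b_wt < 0:
        raise ValueError("wild-type biomass must be >= 0")
    if b_wt < zero_tol:
        return 1.0 if b_ko < zero_tol else math.nan
    return b_ko / b_wt


def sel_score(nb_normal: float, nb_cancer: float) -> float:
    """Selectivity of a KO for one cancer-normal pair (larger = more
    selective against the cancer cell)."""
    return nb_normal - nb_cancer


def phs_score(nb_at_phys: float, nb_at_low: float) -> float:
    """pH-specificity of a KO for one cancer cell (larger = the KO bites
    harder at low pH)."""
    return nb_at_phys - nb_at_low


def recurrence_filter(pair_scores, min_freq: float = 0.125,
                      zero_tol: float = ZERO_TOL) -> tuple:
    """(passes, frequency) of strictly-positive scores above the zero
    threshold.  The minimal passing count on n scores is ceil(min_freq*n)
    (12 of 96 pairs; 1 of 8 cells)."""
    scores = [s for s in pair_scores if not math.isnan(s)]
    if not scores:
        raise ValueError("empty score list")
    freq = sum(1 for s in scores if s > zero_tol) / len(scores)
    return freq >= min_freq, freq


def classify_target(score: KOScore, min_freq: float = 0.125,
                    zero_tol: float = ZERO_TOL) -> str:
    """Quadrant of a target from its mean scores and recurrence passes."""
    selective = (
        not math.isnan(score.SEL) and score.SEL > zero_tol
        and score.sel_recurrence >= min_freq
    )
    ph_specific = (
        not math.isnan(score.PHS) and score.PHS > zero_tol
        and score.phs_recurrence >= min_freq
    )
    if selective and ph_specific:
        return "selective_and_ph_specific"
    if selective:
        return "selective_only"
    if ph_specific:
        return "ph_specific_only"
    return "neither"


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------

def _ko_biomass(model, profiles, target, level, ph, panel: PanelConfig) -> float:
    if level == "gene":
        if target not in model.gene_ids:
            return optimize_biomass(
                model, constrain_model(model, profiles, ph,
                                       cytosol_only=panel.cytosol_only)
            )
        return knockout_gene(model, profiles, target, ph,
                             w_ko=panel.inhibition, cytosol_only=panel.cytosol_only)
    return knockout_reaction(model, profiles, target, ph,
                             cytosol_only=panel.cytosol_only)


def _ko_readout(model, profiles, target, level, ph, panel: PanelConfig):
    if level == "gene" and target in model.gene_ids:
        state = constrain_model(model, profiles, ph, cytosol_only=panel.cytosol_only,
                                gene_overrides={target: panel.inhibition})
    else:
        state = constrain_model(model, profiles, ph, cytosol_only=panel.cytosol_only)
        if level == "reaction":
            state.constraints[target] = ReactionConstraint(target, 0.0, 0.0, 0.0,
                                                           "knockout")
    return fva_readouts(model, state, biomass_fraction=panel.biomass_fraction, ph=ph)


def run_screen(
    panel: PanelConfig,
    profiles: dict,
    level: str = "gene",
    targets=None,
    readouts_for: str = "hits",
) -> list:
    """Score every target's KO across the panel; sorted by PHS then SEL.

    ``targets`` defaults to all genes (or all reactions) present in any
    panel model.  ``readouts_for`` controls the anti-Warburg re-evaluation:
    "hits" (targets outside the "neither" quadrant, the default), "all", or
    "none".  Exchange-rate deltas are KO minus wild type at low pH,
    averaged over the cancer cells; the KO anti-Warburg ratios are reported
    at both pH regimes.  Per-target failures yield NaN scores and the
    screen continues.
    """
    if level not in ("gene", "reaction"):
        raise ValueError(f"level must be 'gene' or 'reaction', got {level!r}")
    cells = [("cancer", m) for m in panel.cancer_models] + [
        ("normal", m) for m in panel.normal_models
    ]
    if targets is None:
        pool: set = set()
        for _, m in cells:
            pool.update(m.gene_ids if level == "gene" else m.reaction_ids)
        targets = sorted(pool)

    phs_grid = (panel.ph_low, panel.ph_phys)
    b_wt = {
        (m.cobra.id, ph): optimize_biomass(
            m, constrain_model(m, profiles, ph, cytosol_only=panel.cytosol_only)
        )
        for _, m in cells
        for ph in phs_grid
    }

    scores: list = []
    for target in targets:
        score = KOScore(target_id=target, level=level)
        try:
            for kind, m in cells:
                for ph in phs_grid:
                    b_ko = _ko_biomass(m, profiles, target, level, ph, panel)
                    score.nB[(m.cobra.id, ph)] = normalized_biomass(
                        b_ko, b_wt[(m.cobra.id, ph)], panel.zero_tol
                    )
        except Exception:  # per-target failure: record and continue
            scores.append(score)
            continue

        score.sel_pairs = [
            sel_score(score.nB[(n.cobra.id, panel.ph_low)],
                      score.nB[(c.cobra.id, panel.ph_low)])
            for c in panel.cancer_models
            for n in panel.normal_models
        ]
        score.phs_values = [
            phs_score(score.nB[(c.cobra.id, panel.ph_phys)],
                      score.nB[(c.cobra.id, panel.ph_low)])
            for c in panel.cancer_models
        ]
        valid_sel = [s for s in score.sel_pairs if not math.isnan(s)]
        valid_phs = [s for s in score.phs_values if not math.isnan(s)]
        score.SEL = float(np.mean(valid_sel)) if valid_sel else math.nan
        score.PHS = float(np.mean(valid_phs)) if valid_phs else math.nan
        if valid_sel:
            _, score.sel_recurrence = recurrence_filter(
                valid_sel, panel.recurrence_min, panel.zero_tol)
        if valid_phs:
            _, score.phs_recurrence = recurrence_filter(
                valid_phs, panel.recurrence_min, panel.zero_tol)
        score.quadrant = classify_target(score, panel.recurrence_min, panel.zero_tol)
        scores.append(score)

    if readouts_for != "none":
        for score in scores:
            if readouts_for == "hits" and score.quadrant == "neither":
                continue
            _attach_readouts(score, panel, profiles, level)

    scores.sort(key=lambda s: (-_nan_low(s.PHS), -_nan_low(s.SEL), s.target_id))
    return scores


def _nan_low(x: float) -> float:
    return -math.inf if math.isnan(x) else x


def _attach_readouts(score: KOScore, panel: PanelConfig, profiles, level) -> None:
    deltas = {k: [] for k in ("oxygen", "glucose", "lactate",
                              "atp_total", "nadph_total", "ros")}
    aw_low, aw_phys = [], []
    for m in panel.cancer_models:
        try:
            wt_low = fva_readouts(
                m, constrain_model(m, profiles, panel.ph_low,
                                   cytosol_only=panel.cytosol_only),
                biomass_fraction=panel.biomass_fraction, ph=panel.ph_low)
            ko_low = _ko_readout(m, profiles, score.target_id, level,
                                 panel.ph_low, panel)
            ko_phys = _ko_readout(m, profiles, score.target_id, level,
                                  panel.ph_phys, panel)
        except Exception:
            continue
        for k in deltas:
            deltas[k].append(ko_low.rates.get(k, math.nan)
                             - wt_low.rates.get(k, math.nan))
        aw_low.append(ko_low.anti_warburg)
        aw_phys.append(ko_phys.anti_warburg)
    def _mean(vals):
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan
    score.dOCR = _mean(deltas["oxygen"])
    score.dGlc = _mean(deltas["glucose"])
    score.dLac = _mean(deltas["lactate"])
    score.dATP = _mean(deltas["atp_total"])
    score.dNADPH = _mean(deltas["nadph_total"])
    score.dROS = _mean(deltas["ros"])
    score.anti_warburg_low = _mean(aw_low)
    score.anti_warburg_phys = _mean(aw_phys)


# ---------------------------------------------------------------------------
# Divide and conquer
# ---------------------------------------------------------------------------

def divide_and_conquer(
    model: MetabolicModel,
    profiles: dict,
    criterion=None,
    theta: float = 0.8,
    ph: float = 6.7,
    cytosol_only: bool = True,
    zero_tol: float = ZERO_TOL,
) -> list:
    """Minimal gene subset whose profiles carry the pH phenotype.

    The default criterion is the biomass gap between the unconstrained and
    the profile-constrained model at low pH, as a function of the gene
    subset whose profiles are applied (genes outside the subset stay at
    weight 1).  The profiled gene set is recursively bisected in model gene
    order, descending into any half preserving at least ``theta`` of the
    full effect; when neither half does (redundant drivers), the current
    set is greedily pruned one gene at a time instead.  A zero full-set
    effect returns the empty list.
    """
    profiled = [g for g in model.gene_ids if g in profiles]

    if criterion is None:
        base = optimize_biomass(model)

        def criterion(subset) -> float:
            sub = {g: profiles[g] for g in subset}
            state = constrain_model(model, sub, ph, cytosol_only=cytosol_only)
            return base - optimize_biomass(model, state)

    full_effect = criterion(profiled)
    if full_effect <= zero_tol:
        return []
    target = theta * full_effect

    def recurse(genes: list) -> list:
        if len(genes) == 1:
            return list(genes)
        mid = len(genes) // 2
        left, right = genes[:mid], genes[mid:]
        if criterion(left) >= target:
            return recurse(left)
        if criterion(right) >= target:
            return recurse(right)
        current = list(genes)
        for g in list(current):  # deterministic greedy pruning
            if len(current) > 1:
                trial = [x for x in current if x != g]
                if criterion(trial) >= target:
                    current = trial
        return current

    return sorted(recurse(profiled))


# ---------------------------------------------------------------------------
# Robustness
# ---------------------------------------------------------------------------

def perturb_db(db: dict, sigma: float, rng) -> tuple:
    """Gaussian-shift every critical point; re-sort violating profiles.

    Returns (new_db, n_resorted).  Re-sorting (rather than rejecting) keeps
    Monte-Carlo runs alive; the count of re-sorted profiles is reported.
    """
    out: dict = {}
    n_resorted = 0
    for gene in sorted(db):
        prof = db[gene]
        vals = [prof.point(p) + float(rng.normal(0.0, sigma)) for p in CRITICAL_POINTS]
        ordered = sorted(vals)
        if vals != ordered:
            n_resorted += 1
        new = PHProfile(enzyme_id=gene)
        for name, v in zip(CRITICAL_POINTS, ordered):
            new.set_point(name, v, prof.source_per_point.get(name, "experimental"))
        out[gene] = new
    return out, n_resorted


def robustness_suite(
    mode: str,
    profiles: dict,
    panel: PanelConfig | None = None,
    model: MetabolicModel | None = None,
    reference_profiles: dict | None = None,
    targets=None,
    sigma: float = 0.1,
    n: int = 50,
    probe_ph: float = 7.8,
    seed: int = 0,
) -> dict:
    """Robustness checks of the engineered pH response.

    ``mode="perturb"``: re-run the KO screen ``n`` times with profiles
    whose critical points are Gaussian-shifted by ``sigma`` pH units;
    report how often the top-PHS target is preserved and the mean Spearman
    rank correlation of PHS scores against baseline.  Requires ``panel``.

    ``mode="randomize"``: permute the profile-to-gene assignment ``n``
    times and compare the biomass gap at ``probe_ph`` between the model
    under ``reference_profiles`` (e.g. a pH-insensitive normal-like db) and
    under the (permuted) engineered db.  A wrong assignment should collapse
    the engineered gap.  Requires ``model`` and ``reference_profiles``.
    """
    rng = np.random.default_rng(seed)
    if mode == "perturb":
        if panel is None:
            raise ValueError("perturb mode requires a panel")
        baseline = run_screen(panel, profiles, targets=targets, readouts_for="none")
        base_order = [s.target_id for s in baseline]
        base_phs = {s.target_id: s.PHS for s in baseline}
        top = base_order[0]
        preserved = 0
        rank_corrs = []
        n_resorted_total = 0
        for _ in range(n):
            db, n_resorted = perturb_db(profiles, sigma, rng)
            n_resorted_total += n_resorted
            trial = run_screen(panel, db, targets=targets, readouts_for="none")
            if trial[0].target_id == top:
                preserved += 1
            t_phs = {s.target_id: s.PHS for s in trial}
            ids = sorted(base_phs)
            if len(ids) > 1 and sigma > 0:
                rho = _scipy_stats.spearmanr(
                    [base_phs[i] for i in ids], [t_phs[i] for i in ids]
                ).statistic
                if not math.isnan(rho):
                    rank_corrs.append(float(rho))
            elif sigma == 0:
                rank_corrs.append(1.0)
        return {
            "mode": "perturb",
            "sigma": sigma,
            "n": n,
            "baseline_top": top,
            "top_preserved_fraction": preserved / n if n else math.nan,
            "mean_rank_correlation": float(np.mean(rank_corrs)) if rank_corrs else math.nan,
            "profiles_resorted": n_resorted_total,
        }
    if mode == "randomize":
        if model is None or reference_profiles is None:
            raise ValueError("randomize mode requires model and reference_profiles")

        def gap(db) -> float:
            b_ref = optimize_biomass(
                model, constrain_model(model, reference_profiles, probe_ph))
            b_db = optimize_biomass(model, constrain_model(model, db, probe_ph))
            return b_ref - b_db

        baseline_gap = gap(profiles)
        genes = sorted(profiles)
        gaps = []
        for _ in range(n):
            perm = rng.permutation(len(genes))
            shuffled = {
                genes[i]: _reassigned(profiles[genes[j]], genes[i])
                for i, j in enumerate(perm)
            }
            gaps.append(gap(shuffled))
        mean_gap = float(np.mean(gaps)) if gaps else math.nan
        return {
            "mode": "randomize",
            "n": n,
            "probe_ph": probe_ph,
            "baseline_gap": baseline_gap,
            "mean_permuted_gap": mean_gap,
            "gap_ratio": mean_gap / baseline_gap if baseline_gap else math.nan,
        }
    raise ValueError(f"unknown robustness mode {mode!r}")


def _reassigned(prof: PHProfile, gene: str) -> PHProfile:
    new = prof.copy()
    new.enzyme_id = gene
    return new
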