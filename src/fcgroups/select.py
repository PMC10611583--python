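"""Optimization-based selection of an overlapping bicluster family.

The selected family should jointly maximize specificity, sensitivity and
coverage of subjects and features. We realize this as a quality-weighted
facility-location objective:

    q(B)   = spec_excess(B)^w_spec * sensitivity(B)^w_sens * strength gate
    C(Sel) = w_subj * mean over patients of max_{B in Sel covering s} q(B)
           + w_feat * mean over candidate-union features of max q(B)

where spec_excess = max(0, 2*(specificity - 1/2)) centres specificity at
its chance level and the strength gate zeroes the quality of biclusters
whose deviations sit within control sampling noise — together these make
selection on structure-free data terminate empty. Greedy forward selection
adds the candidate with the largest marginal gain w_cov * dC, pruning
near-duplicate views (subject Jaccard >= tau_dup against any selected
bicluster), and stops when the best gain falls below epsilon_gain; a
deterministic local search (swap/drop/add) then refines the family on the
penalized objective O = w_cov * C - epsilon * |Sel|. C is monotone
submodular; an exhaustive mode maximizing O serves as an oracle on small
candidate lists.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biclusters import Bicluster

logger = logging.getLogger(__name__)


@dataclass
class SelectionWeights:
    """Exponents of the quality terms and weights of the coverage facets.

    Subject coverage drives the selection gain by default; feature coverage
    is tracked and reported but, with ``feat = 0``, does not add gain —
    candidate biclusters blending two groups carry bloated feature sets
    that would otherwise buy them selection without adding any subject
    information.
    """

    spec: float = 1.0
    sens: float = 1.0
    cov: float = 1.0
    subj: float = 1.0
    feat: float = 0.0


@dataclass
class SelectionResult:
    selected: list[Bicluster]
    gains: list[float]
    objective: float
    subject_coverage: float  # percent of patients covered
    feature_coverage: float  # percent of candidate-union features covered
    duplicates: list[tuple[tuple[int, int], tuple[int, int]]]  # (skipped, kept)
    n_patients: int

    @property
    def n_selected(self) -> int:
        return len(self.selected)


@dataclass
class GroupAccounting:
    """Per-group accounting in the style of a study summary table."""

    name: str
    connections: int
    n_subjects: int
    n_sz: int
    n_bp: int
    n_controls: int
    risk: float
    sz_percent: int
    bp_percent: int


def quality(bc: Bicluster, weights: SelectionWeights = SelectionWeights()) -> float:
    """Chance-centred composite quality in [0, 1].

    Specificity is re-centred at its chance level of 1/2 and multiplied by
    sensitivity (the weights act as exponents). The product is gated by the
    bicluster's deviation strength: deviations at or below one control
    sampling SD (strength <= 1) describe noise and contribute nothing.
    """
    spec_excess = max(0.0, 2.0 * (bc.specificity - 0.5))
    q = (spec_excess ** weights.spec) * (bc.sensitivity ** weights.sens)
    if np.isfinite(bc.strength):
        q *= max(0.0, 1.0 - 1.0 / bc.strength) if bc.strength > 0 else 0.0
    return q


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


class _CoverageState:
    """Incremental quality-weighted coverage over subjects and features."""

    def __init__(self, candidates: list[Bicluster], patient_ids: list[str],
                 weights: SelectionWeights):
        self.weights = weights
        self.subjects = list(patient_ids)
        self.s_pos = {s: i for i, s in enumerate(self.subjects)}
        universe = sorted({f for bc in candidates for f in bc.features})
        self.f_pos = {f: i for i, f in enumerate(universe)}
        self.s_cover = np.zeros(len(self.subjects))
        self.f_cover = np.zeros(max(len(universe), 1))

    def value(self) -> float:
        w = self.weights
        sv = self.s_cover.mean() if self.s_cover.size else 0.0
        fv = self.f_cover.mean() if self.f_cover.size else 0.0
        return w.subj * sv + w.feat * fv

    def gain(self, bc: Bicluster, q: float) -> float:
        w = self.weights
        si = [self.s_pos[s] for s in bc.subjects if s in self.s_pos]
        fi = [self.f_pos[f] for f in bc.features]
        ds = np.maximum(q - self.s_cover[si], 0.0).sum() / max(self.s_cover.size, 1)
        df = np.maximum(q - self.f_cover[fi], 0.0).sum() / max(self.f_cover.size, 1)
        return w.subj * ds + w.feat * df

    def add(self, bc: Bicluster, q: float) -> None:
        si = [self.s_pos[s] for s in bc.subjects if s in self.s_pos]
        fi = [self.f_pos[f] for f in bc.features]
        self.s_cover[si] = np.maximum(self.s_cover[si], q)
        self.f_cover[fi] = np.maximum(self.f_cover[fi], q)


def _objective(
    sel: list[Bicluster],
    candidates: list[Bicluster],
    patient_ids: list[str],
    weights: SelectionWeights,
    qs: dict,
    epsilon_gain: float,
) -> float:
    """Penalized set objective w_cov * C(Sel) - epsilon * |Sel|."""
    state = _CoverageState(candidates, patient_ids, weights)
    for bc in sel:
        state.add(bc, qs[bc.provenance])
    return weights.cov * state.value() - epsilon_gain * len(sel)


def select(
    candidates: list[Bicluster],
    patient_ids: list[str],
    weights: SelectionWeights = SelectionWeights(),
    epsilon_gain: float = 0.02,
    tau_dup: float = 0.6,
) -> SelectionResult:
    """Select a bicluster family maximizing quality-weighted coverage.

    Near-duplicate views from different ranks are first consolidated (best
    view per group); greedy forward selection over the representatives
    (stop when the marginal gain drops below ``epsilon_gain``) is then
    refined by deterministic local search — swap, drop and add moves that
    improve the penalized objective — correcting the greedy habit of
    grabbing broad, lower-quality candidates before sharper ones. Ties are
    broken by higher specificity, then smaller subject set, then
    provenance (rank, factor). An empty candidate list yields an empty
    result.
    """
    state = _CoverageState(candidates, patient_ids, weights)
    qs = {bc.provenance: quality(bc, weights) for bc in candidates}
    selected: list[Bicluster] = []
    gains: list[float] = []
    duplicates: list[tuple[tuple[int, int], tuple[int, int]]] = []
    remaining = list(candidates)

    while remaining:
        best = None
        best_key = None
        for bc in remaining:
            g = weights.cov * state.gain(bc, qs[bc.provenance])
            key = (g, bc.specificity, -len(bc.subjects),
                   tuple(-x for x in bc.provenance))
            if best_key is None or key > best_key:
                best, best_key = bc, key
        g_best = best_key[0]
        if g_best < epsilon_gain:
            break
        remaining.remove(best)
        selected.append(best)
        gains.append(g_best)
        state.add(best, qs[best.provenance])
        # prune near-duplicate views of the newly selected bicluster
        for bc in list(remaining):
            if _jaccard(bc.subject_set, best.subject_set) >= tau_dup:
                remaining.remove(bc)
                duplicates.append((bc.provenance, best.provenance))
                logger.info(
                    "skipping near-duplicate bicluster %s of %s (subject Jaccard >= %.2f)",
                    bc.provenance, best.provenance, tau_dup,
                )

    # local search on the penalized objective O = w_cov*C - eps*|Sel|
    def obj(sel: list[Bicluster]) -> float:
        return _objective(sel, candidates, patient_ids, weights, qs, epsilon_gain)

    def dup_free(sel: list[Bicluster]) -> bool:
        return all(
            _jaccard(a.subject_set, b.subject_set) < tau_dup
            for a, b in itertools.combinations(sel, 2)
        )

    current = obj(selected)
    for _ in range(20):  # deterministic passes to a local optimum
        improved = False
        # drop
        for bc in list(selected):
            trial = [b for b in selected if b is not bc]
            v = obj(trial)
            if v > current + 1e-12:
                selected, current, improved = trial, v, True
        # swap
        for i, bc in enumerate(list(selected)):
            best_v, best_alt = current, None
            for alt in candidates:
                if any(alt is s for s in selected):
                    continue
                trial = selected[:i] + [alt] + selected[i + 1 :]
                if not dup_free(trial):
                    continue
                v = obj(trial)
                if v > best_v + 1e-12:
                    best_v, best_alt = v, alt
            if best_alt is not None:
                selected = selected[:i] + [best_alt] + selected[i + 1 :]
                current, improved = best_v, True
        # add
        for alt in candidates:
            if any(alt is s for s in selected):
                continue
            trial = selected + [alt]
            if not dup_free(trial):
                continue
            v = obj(trial)
            if v > current + 1e-12:
                selected, current, improved = trial, v, True
        if not improved:
            break

    # re-derive the marginal-gain decomposition in final selection order
    state = _CoverageState(candidates, patient_ids, weights)
    gains = []
    for bc in selected:
        gains.append(weights.cov * state.gain(bc, qs[bc.provenance]))
        state.add(bc, qs[bc.provenance])

    covered_s = set().union(*(b.subject_set for b in selected)) if selected else set()
    covered_s &= set(patient_ids)
    universe = {f for bc in candidates for f in bc.features}
    covered_f = {f for b in selected for f in b.features}
    return SelectionResult(
        selected=selected,
        gains=gains,
        objective=float(sum(gains)),
        subject_coverage=100.0 * len(covered_s) / max(len(patient_ids), 1),
        feature_coverage=100.0 * len(covered_f) / max(len(universe), 1),
        duplicates=duplicates,
        n_patients=len(patient_ids),
    )


def exhaustive_select(
    candidates: list[Bicluster],
    patient_ids: list[str],
    weights: SelectionWeights = SelectionWeights(),
    epsilon_gain: float = 0.02,
    tau_dup: float = 0.6,
) -> tuple[list[Bicluster], float]:
    """Exact maximization of w_cov * C(Sel) - epsilon_gain * |Sel| over all
    duplicate-free subsets. Oracle for testing; limited to 15 candidates."""
    if len(candidates) > 15:
        raise ValueError("exhaustive mode is limited to 15 candidates")
    qs = {bc.provenance: quality(bc, weights) for bc in candidates}
    best_sel: list[Bicluster] = []
    best_obj = 0.0
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            if any(
                _jaccard(a.subject_set, b.subject_set) >= tau_dup
                for a, b in itertools.combinations(combo, 2)
            ):
                continue
            state = _CoverageState(candidates, patient_ids, weights)
            for bc in combo:
                state.add(bc, qs[bc.provenance])
            obj = weights.cov * state.value() - epsilon_gain * r
            if obj > best_obj + 1e-12:
                best_obj = obj
                best_sel = list(combo)
    return best_sel, best_obj


# ---------------------------------------------------------------------------
# accounting


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def compute_risk(bc: Bicluster, cohort: pd.DataFrame) -> GroupAccounting:
    """Diagnosis accounting for one bicluster's subject set.

    Risk is the fraction of members with a patient diagnosis; SZ%/BP% are
    computed among patients only and rounded half away from zero.
    """
    if not bc.subjects:
        raise ValueError("cannot account an empty bicluster")
    status = cohort.set_index("subject_id")["status"]
    missing = [s for s in bc.subjects if s not in status.index]
    if missing:
        raise KeyError(f"subjects missing from cohort: {missing}")
    st = status.loc[list(bc.subjects)]
    n_sz = int((st == "SZ").sum())
    n_bp = int((st == "BP").sum())
    n_ctrl = int((st == "control").sum())
    n = len(bc.subjects)
    n_pat = n_sz + n_bp
    return GroupAccounting(
        name=bc.name or f"rank{bc.rank}-factor{bc.factor}",
        connections=len({f for f in bc.features}),
        n_subjects=n,
        n_sz=n_sz,
        n_bp=n_bp,
        n_controls=n_ctrl,
        risk=n_pat / n,
        sz_percent=_round_half_away(100.0 * n_sz / n_pat) if n_pat else 0,
        bp_percent=_round_half_away(100.0 * n_bp / n_pat) if n_pat else 0,
    )


def compute_coverage(result: SelectionResult, cohort: pd.DataFrame) -> tuple[int, float]:
    """Percent of patients in at least one selected bicluster.

    Returns (nearest-integer percent, full-precision percent)."""
    patients = set(cohort.loc[cohort["status"] != "control", "subject_id"])
    covered = set()
    for bc in result.selected:
        covered |= bc.subject_set
    pct = 100.0 * len(covered & patients) / max(len(patients), 1)
    return _round_half_away(pct), pct


def accounting_table(
    result: SelectionResult, cohort: pd.DataFrame
) -> pd.DataFrame:
    rows = [compute_risk(bc, cohort) for bc in result.selected]
    return pd.DataFrame(
        {
            "group": [r.name for r in rows],
            "connections": [r.connections for r in rows],
            "subjects": [r.n_subjects for r in rows],
            "SZ": [r.n_sz for r in rows],
            "BP": [r.n_bp for r in rows],
            "controls": [r.n_controls for r in rows],
            "risk": [round(r.risk, 2) for r in rows],
            "SZ_percent": [r.sz_percent for r in rows],
            "BP_percent": [r.bp_percent for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# persistence


def write_selection(result: SelectionResult, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "objective": result.objective,
        "subject_coverage": result.subject_coverage,
        "feature_coverage": result.feature_coverage,
        "n_patients": result.n_patients,
        "duplicates_skipped": [list(map(list, d)) for d in result.duplicates],
        "biclusters": [
            {
                "name": bc.name,
                "rank": bc.rank,
                "factor": bc.factor,
                "subjects": list(bc.subjects),
                "features": list(bc.features),
                "block_signs": bc.block_signs,
                "sensitivity": bc.sensitivity,
                "specificity": bc.specificity,
                "strength": bc.strength,
                "gain": g,
            }
            for bc, g in zip(result.selected, result.gains)
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_selection(path: str | Path) -> SelectionResult:
    data = json.loads(Path(path).read_text())
    selected = [
        Bicluster(
            subjects=tuple(b["subjects"]),
            features=tuple(b["features"]),
            block_signs=b["block_signs"],
            rank=b["rank"],
            factor=b["factor"],
            sensitivity=b["sensitivity"],
            specificity=b["specificity"],
            strength=b.get("strength", float("nan")),
            name=b.get("name"),
        )
        for b in data["biclusters"]
    ]
    return SelectionResult(
        selected=selected,
        gains=[b["gain"] for b in data["biclusters"]],
        objective=data["objective"],
        subject_coverage=data["subject_coverage"],
        feature_coverage=data["feature_coverage"],
        duplicates=[tuple(map(tuple, d)) for d in data["duplicates_skipped"]],
        n_patients=data["n_patients"],
    )
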