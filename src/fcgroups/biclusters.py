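"""Dissecting NMF factors into fuzzy, overlapping biclusters.

Each factor j of a rank-k model induces a candidate bicluster: the subjects
whose loading on j is within a factor ``alpha`` of their own best loading
(fuzzy — one subject may qualify for several factors) and the features
whose loading is within ``beta`` of the factor's best feature loading.

Candidates carry two quality scores:

* sensitivity — coherence of the submatrix: the mean of V[s, f] normalized
  by the column maximum, over the bicluster's cells;
* specificity — how sharply the bicluster's features separate its members
  from the remaining patients: Cohen's d of the feature-mean profile,
  reported through a logistic squashing so that chance level is 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import DeviationFeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class Bicluster:
    """A subject set x feature set with provenance and quality scores."""

    subjects: tuple[str, ...]
    features: tuple[int, ...]  # column indices into the 2F deviation matrix
    block_signs: dict[str, int]  # network block -> majority channel sign
    rank: int
    factor: int
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    #: mean member deviation on the bicluster's features, in units of the
    #: per-feature control sampling SD (~1 for noise, >> 1 for real effects)
    strength: float = float("nan")
    risk: float | None = None
    name: str | None = None

    @property
    def provenance(self) -> tuple[int, int]:
        return (self.rank, self.factor)

    @property
    def subject_set(self) -> frozenset[str]:
        return frozenset(self.subjects)


def extract_biclusters(
    model, fm: DeviationFeatureMatrix, alpha: float = 0.5, beta: float = 0.5,
    membership_rule: str = "hybrid",
) -> list[Bicluster]:
    """Threshold a fitted NMF model's factors into candidate biclusters.

    ``alpha``, ``beta`` in (0, 1]: relative-to-maximum membership
    thresholds for subjects and features. Factors with an empty subject or
    feature set are dropped.

    Membership rules (the fuzziness construction): ``factor_max`` admits
    subject s to factor j when its loading reaches ``alpha`` times the
    factor's top subject loading — membership measures how strongly s
    expresses *this* pattern, independent of what else s expresses.
    ``subject_max`` compares against the subject's own best factor instead
    (s joins every factor within ``alpha`` of its dominant one), which
    suits broad factors with graded expression. The default ``hybrid``
    admits a subject under either criterion, the permissive union that
    fits overlapping groups of very different breadths.
    """
    if not (0 < alpha <= 1 and 0 < beta <= 1):
        raise ValueError("alpha and beta must lie in (0, 1]")
    if membership_rule not in ("hybrid", "factor_max", "subject_max"):
        raise ValueError(f"unknown membership_rule: {membership_rule!r}")
    W, H = model.W, model.H
    ids = np.asarray(fm.patient_ids)
    # balance the scale ambiguity of NMF (W D)(D^-1 H): rescale each subject
    # loading by its factor's feature-loading norm so loadings are comparable
    # across factors
    h_norm = np.linalg.norm(H, axis=1)
    W = W * h_norm[None, :]
    row_max = W.max(axis=1)
    col_max = W.max(axis=0)
    out: list[Bicluster] = []
    for j in range(model.rank):
        if membership_rule == "factor_max":
            ref = col_max[j]
        elif membership_rule == "subject_max":
            ref = row_max
        else:
            ref = np.minimum(row_max, col_max[j])
        s_mask = (W[:, j] >= alpha * ref) & (W[:, j] > 0)
        h = H[j]
        h_max = h.max()
        f_mask = (h >= beta * h_max) & (h > 0)
        if not s_mask.any() or not f_mask.any():
            continue
        feats = tuple(int(c) for c in np.flatnonzero(f_mask))
        out.append(
            Bicluster(
                subjects=tuple(ids[s_mask]),
                features=feats,
                block_signs=_block_signs(feats, fm),
                rank=model.rank,
                factor=j,
            )
        )
    return out


def _block_signs(features: tuple[int, ...], fm: DeviationFeatureMatrix) -> dict[str, int]:
    """Majority channel (+1 pos-dominant / -1 neg-dominant) per network block."""
    votes: dict[str, int] = {}
    for col in features:
        feat, sign = fm.channel_of(col)
        block = fm.feature_map.iloc[feat]["block"]
        votes[block] = votes.get(block, 0) + sign
    return {b: (1 if v > 0 else -1 if v < 0 else 0) for b, v in votes.items()}


def logistic(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def score_bicluster(
    bc: Bicluster, fm: DeviationFeatureMatrix,
) -> tuple[float, float]:
    """Compute (sensitivity, specificity) for a bicluster; both in [0, 1].

    Sensitivity is the mean column-max-normalized signal of the submatrix.
    Specificity is logistic(d) where d is the pooled-SD Cohen's d of the
    bicluster-feature mean between members and non-member patients; if the
    pooled SD degenerates, a rank-biserial fallback is used (logged).
    Deterministic.
    """
    if not bc.subjects or not bc.features:
        raise ValueError("bicluster must be nonempty")
    V = fm.values
    ids = list(fm.patient_ids)
    s_idx = np.asarray([ids.index(s) for s in bc.subjects])
    f_idx = np.asarray(bc.features)

    col_max = V[:, f_idx].max(axis=0)
    safe = np.where(col_max > 0, col_max, 1.0)
    sensitivity = float((V[np.ix_(s_idx, f_idx)] / safe).mean())

    row_means = V[:, f_idx].mean(axis=1)
    in_mask = np.zeros(len(ids), dtype=bool)
    in_mask[s_idx] = True
    x, y = row_means[in_mask], row_means[~in_mask]
    if y.size == 0:
        logger.warning("bicluster spans all patients; specificity set to chance")
        return sensitivity, 0.5
    d = _cohens_d(x, y)
    if d is None:
        logger.warning(
            "degenerate pooled SD for bicluster (k=%d, j=%d); rank-based fallback",
            bc.rank, bc.factor,
        )
        u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        r_rb = 2.0 * u / (x.size * y.size) - 1.0  # rank-biserial in [-1, 1]
        return sensitivity, float((r_rb + 1.0) / 2.0)
    return sensitivity, logistic(d)


def _cohens_d(x: np.ndarray, y: np.ndarray) -> float | None:
    nx, ny = x.size, y.size
    vx = x.var(ddof=1) if nx > 1 else 0.0
    vy = y.var(ddof=1) if ny > 1 else 0.0
    dof = max(nx + ny - 2, 1)
    pooled = np.sqrt(((nx - 1) * vx + (ny - 1) * vy) / dof)
    if not np.isfinite(pooled) or pooled <= 0:
        return None
    return float((x.mean() - y.mean()) / pooled)


def deviation_strength(bc: Bicluster, fm: DeviationFeatureMatrix) -> float:
    """Mean member deviation over the bicluster's cells, standardized by the
    per-feature control SD.

    Healthy-control connectivity estimates fluctuate by about one control
    SD purely through sampling, so a bicluster whose deviations sit at or
    below 1 on this scale describes noise; planted effects land well above.
    """
    if not bc.subjects or not bc.features:
        raise ValueError("bicluster must be nonempty")
    ids = list(fm.patient_ids)
    s_idx = [ids.index(s) for s in bc.subjects]
    sd = np.concatenate([fm.control_sd, fm.control_sd])
    cols = np.asarray(bc.features)
    per_feature = fm.values[np.ix_(s_idx, cols)].mean(axis=0)
    return float(np.mean(per_feature / np.maximum(sd[cols], 1e-12)))


def score_all(candidates: list[Bicluster], fm: DeviationFeatureMatrix) -> list[Bicluster]:
    """Score candidates in place and return them."""
    for bc in candidates:
        bc.sensitivity, bc.specificity = score_bicluster(bc, fm)
        bc.strength = deviation_strength(bc, fm)
    return candidates
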