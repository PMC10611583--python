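"""Connectivity features: correlation matrices, control-referenced deviations,
and the two-channel nonnegative encoding consumed by the factorization.

Feature ordering is deterministic: row-major upper triangle (i < j, 0-based
node indices). Signed deviations ``d`` are split into complementary
nonnegative channels ``pos = max(d, 0)`` and ``neg = max(-d, 0)``; the
concatenated [pos | neg] matrix is the factorization input, and
``pos - neg`` reconstructs the signed deviation exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_Z_CLIP = 0.999999


@dataclass
class ConnectivityStack:
    """Per-subject symmetric correlation (or Fisher-z) matrices."""

    subject_ids: list[str]
    matrices: np.ndarray  # (n_subjects, N, N)
    node_networks: list[str]
    fisher_z: bool = False

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]


@dataclass
class DeviationFeatureMatrix:
    """Patients x 2F nonnegative matrix of control-referenced deviations.

    Column layout: first the F positive-channel features, then the F
    negative-channel features, in the same feature order. ``feature_map``
    has one row per feature: (node_i, node_j, network_i, network_j) for
    node-pair features or the network pair for block-mean features.
    """

    patient_ids: list[str]
    values: np.ndarray  # (n_patients, 2F), >= 0
    feature_map: pd.DataFrame
    control_mean: np.ndarray  # (F,)
    control_sd: np.ndarray  # (F,)
    mode: str = "node_pair"  # or "network_block"

    @property
    def n_features(self) -> int:
        return self.feature_map.shape[0]

    def signed(self) -> np.ndarray:
        """Reconstruct the signed deviation matrix (patients x F)."""
        f = self.n_features
        return self.values[:, :f] - self.values[:, f:]

    def channel_of(self, column: int) -> tuple[int, int]:
        """Map a column of ``values`` to (feature index, sign)."""
        f = self.n_features
        return (column, +1) if column < f else (column - f, -1)


# ---------------------------------------------------------------------------


def correlation_matrix(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation of every node pair from a T x N timeseries.

    Constant columns yield undefined correlations: the affected rows and
    columns are set to NaN (diagonal kept at 1) and a warning is logged so
    downstream feature construction can drop them.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("timeseries must be T x N with T >= 3")
    sd = ts.std(axis=0)
    constant = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(ts, rowvar=False)
    if constant.any():
        idx = np.flatnonzero(constant)
        logger.warning("constant node columns %s: correlations set to NaN", idx.tolist())
        corr[idx, :] = np.nan
        corr[:, idx] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing z = atanh(r); |r| >= 1 is clipped with a warning."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        logger.warning("|r| >= 1 encountered; clipping to +/-%g", _Z_CLIP)
        arr = np.clip(arr, -_Z_CLIP, _Z_CLIP)
    out = np.arctanh(arr)
    return out if np.ndim(r) else float(out)


def build_stack(
    timeseries: dict[str, np.ndarray],
    node_networks: list[str],
    apply_fisher_z: bool = True,
) -> ConnectivityStack:
    """Correlate each subject's timeseries into a connectivity stack."""
    ids = list(timeseries)
    mats = []
    for sid in ids:
        c = correlation_matrix(timeseries[sid])
        if apply_fisher_z:
            off = ~np.eye(c.shape[0], dtype=bool)
            z = c.copy()
            z[off] = fisher_z(c[off])
            c = z
        mats.append(c)
    return ConnectivityStack(
        subject_ids=ids, matrices=np.stack(mats),
        node_networks=list(node_networks), fisher_z=apply_fisher_z,
    )


def _upper_triangle_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def control_reference(
    stack: ConnectivityStack,
    control_ids: list[str],
    patient_ids: list[str],
    standardize: bool = False,
    mode: str = "node_pair",
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, np.ndarray, list[str]]:
    """Signed deviations of each patient from the control mean, per feature.

    Features are upper-triangle node pairs (default) or network-pair block
    means (``mode="network_block"``). Features undefined (NaN) for any
    subject are dropped listwise and logged. Returns (deviations, feature
    map, control mean, control SD, kept patient ids).
    """
    if len(control_ids) < 2:
        raise ValueError("need at least 2 controls to reference against")
    pos = {s: i for i, s in enumerate(stack.subject_ids)}
    missing = [s for s in list(control_ids) + list(patient_ids) if s not in pos]
    if missing:
        raise KeyError(f"subjects not in stack: {missing}")

    iu, ju = _upper_triangle_index(stack.n_nodes)
    feats = stack.matrices[:, iu, ju]  # (n_subjects, n_pairs)
    nets = np.asarray(stack.node_networks)
    fmap = pd.DataFrame(
        {
            "node_i": iu, "node_j": ju,
            "network_i": nets[iu], "network_j": nets[ju],
        }
    )
    # unordered network pair label
    pair = np.where(
        fmap["network_i"] <= fmap["network_j"],
        fmap["network_i"] + "-" + fmap["network_j"],
        fmap["network_j"] + "-" + fmap["network_i"],
    )
    fmap["block"] = pair

    if mode == "network_block":
        blocks = sorted(set(pair))
        agg = np.stack(
            [np.nanmean(feats[:, pair == b], axis=1) for b in blocks], axis=1
        )
        feats = agg
        fmap = pd.DataFrame(
            {
                "node_i": -1, "node_j": -1,
                "network_i": [b.split("-")[0] for b in blocks],
                "network_j": [b.split("-")[1] for b in blocks],
                "block": blocks,
            }
        )
    elif mode != "node_pair":
        raise ValueError(f"unknown feature mode: {mode!r}")

    keep = ~np.isnan(feats).any(axis=0)
    if not keep.all():
        logger.warning("dropping %d features undefined for some subject", (~keep).sum())
        feats = feats[:, keep]
        fmap = fmap.loc[keep].reset_index(drop=True)

    c_idx = [pos[s] for s in control_ids]
    p_idx = [pos[s] for s in patient_ids]
    mu = feats[c_idx].mean(axis=0)
    sd = feats[c_idx].std(axis=0, ddof=1)
    dev = feats[p_idx] - mu
    if standardize:
        safe = np.where(sd > 0, sd, 1.0)
        dev = dev / safe
    return dev, fmap, mu, sd, list(patient_ids)


def encode_nonnegative(
    deviations: np.ndarray,
    patient_ids: list[str],
    feature_map: pd.DataFrame,
    control_mean: np.ndarray,
    control_sd: np.ndarray,
    tau_noise: float = 0.0,
    mode: str = "node_pair",
) -> DeviationFeatureMatrix:
    """Split signed deviations into complementary nonnegative channels.

    Deviations with |d| < tau_noise are zeroed in both channels (noise
    floor, default off).
    """
    d = np.asarray(deviations, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("deviations must be finite")
    if tau_noise > 0:
        d = np.where(np.abs(d) < tau_noise, 0.0, d)
    values = np.concatenate([np.maximum(d, 0.0), np.maximum(-d, 0.0)], axis=1)
    return DeviationFeatureMatrix(
        patient_ids=list(patient_ids), values=values,
        feature_map=feature_map.reset_index(drop=True),
        control_mean=np.asarray(control_mean), control_sd=np.asarray(control_sd),
        mode=mode,
    )


def aggregate_network_blocks(
    per_feature_values: np.ndarray, feature_map: pd.DataFrame,
) -> pd.DataFrame:
    """Mean value and contributing-pair count per unordered network block.

    ``per_feature_values`` is one value per feature row of ``feature_map``.
    """
    if len(per_feature_values) != len(feature_map):
        raise ValueError("one value per feature required")
    df = pd.DataFrame(
        {"block": feature_map["block"], "value": np.asarray(per_feature_values)}
    )
    out = df.groupby("block", sort=True).agg(mean=("value", "mean"), count=("value", "size"))
    return out.reset_index()


# ---------------------------------------------------------------------------
# persistence


def write_feature_matrix(fm: DeviationFeatureMatrix, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    f = fm.n_features
    cols = [f"pos_{i}" for i in range(f)] + [f"neg_{i}" for i in range(f)]
    mat_path = outdir / "deviation_matrix.csv"
    pd.DataFrame(fm.values, index=fm.patient_ids, columns=cols).to_csv(
        mat_path, index_label="subject_id", float_format="%.6g"
    )
    map_path = outdir / "feature_map.csv"
    fm.feature_map.to_csv(map_path, index_label="feature")
    side_path = outdir / "feature_layout.json"
    side_path.write_text(
        json.dumps(
            {
                "mode": fm.mode,
                "n_features": int(f),
                "channel_layout": "columns [0, F) positive channel, [F, 2F) negative channel",
                "control_mean": fm.control_mean.tolist(),
                "control_sd": fm.control_sd.tolist(),
            }
        )
    )
    return {"matrix": mat_path, "feature_map": map_path, "layout": side_path}


def read_feature_matrix(outdir: str | Path) -> DeviationFeatureMatrix:
    outdir = Path(outdir)
    mat = pd.read_csv(outdir / "deviation_matrix.csv", index_col="subject_id")
    fmap = pd.read_csv(outdir / "feature_map.csv", index_col="feature")
    side = json.loads((outdir / "feature_layout.json").read_text())
    return DeviationFeatureMatrix(
        patient_ids=list(mat.index), values=mat.to_numpy(float),
        feature_map=fmap.reset_index(drop=True),
        control_mean=np.asarray(side["control_mean"]),
        control_sd=np.asarray(side["control_sd"]),
        mode=side["mode"],
    )
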