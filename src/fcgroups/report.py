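"""Presentation artifacts: block matrices and BrainNet Viewer export.

These render nothing — they write the data files behind the standard
presentations: a 16x16 network-block table of signed edge counts per group,
and BrainNet Viewer ``.node`` / ``.edge`` inputs for graph display.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import NETWORKS
from .biclusters import Bicluster
from .features import DeviationFeatureMatrix

logger = logging.getLogger(__name__)


def block_matrix_table(bc: Bicluster, fm: DeviationFeatureMatrix) -> pd.DataFrame:
    """16x16 signed edge-count table for one bicluster.

    Cell (A, B) holds the number of the bicluster's connections in that
    network block, signed by the majority channel (+ = greater than
    controls, - = less). Symmetric; the counts over the upper triangle plus
    diagonal sum to the bicluster's connection count.
    """
    counts = pd.DataFrame(0, index=list(NETWORKS), columns=list(NETWORKS))
    votes = pd.DataFrame(0, index=list(NETWORKS), columns=list(NETWORKS))
    seen: set[int] = set()
    for col in bc.features:
        feat, sign = fm.channel_of(col)
        row = fm.feature_map.iloc[feat]
        a, b = row["network_i"], row["network_j"]
        if feat not in seen:
            counts.loc[a, b] += 1
            if a != b:
                counts.loc[b, a] += 1
            seen.add(feat)
        votes.loc[a, b] += sign
        if a != b:
            votes.loc[b, a] += sign
    # tied votes keep the count with positive sign so that cell counts
    # always sum to the bicluster's connection count
    signs = np.where(votes.to_numpy() < 0, -1, 1)
    return counts * signs


def export_brainnet(
    bc: Bicluster,
    fm: DeviationFeatureMatrix,
    node_table: pd.DataFrame,
    outdir: str | Path,
    stem: str,
) -> tuple[Path, Path]:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files for a bicluster.

    ``.node``: whitespace-delimited x, y, z, color index (network id), size
    (node degree within the bicluster), label. ``.edge``: N x N signed
    weight matrix (+1/-1 per connection), zero diagonal.
    """
    for c in ("x", "y", "z"):
        if c not in node_table.columns or node_table[c].isna().any():
            missing = (
                list(node_table.loc[node_table[c].isna(), "node_id"])
                if c in node_table.columns else "all"
            )
            raise ValueError(f"missing node coordinates ({c}): {missing}")
    n = len(node_table)
    edge = np.zeros((n, n))
    for col in bc.features:
        feat, sign = fm.channel_of(col)
        row = fm.feature_map.iloc[feat]
        i, j = int(row["node_i"]), int(row["node_j"])
        if i < 0 or j < 0:
            continue  # network-block features carry no node pair
        edge[i, j] = sign
        edge[j, i] = sign

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edge_path = outdir / f"{stem}.edge"
    np.savetxt(edge_path, edge, fmt="%d", delimiter="\t")

    degree = (edge != 0).sum(axis=1)
    color = node_table["network"].map({net: i + 1 for i, net in enumerate(NETWORKS)})
    node_path = outdir / f"{stem}.node"
    with open(node_path, "w") as fh:
        for i, row in node_table.iterrows():
            fh.write(
                f"{row['x']:.1f}\t{row['y']:.1f}\t{row['z']:.1f}\t"
                f"{int(color.iloc[i])}\t{int(degree[i])}\t{row['node_id']}\n"
            )
    return node_path, edge_path


# ---------------------------------------------------------------------------
# run manifest


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config, seed, stages, output digests."""

    config: dict
    master_seed: int
    package_version: str
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def log_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
                            **info})

    def register(self, path: str | Path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "config": self.config,
                    "master_seed": self.master_seed,
                    "package_version": self.package_version,
                    "stages": self.stages,
                    "outputs": self.outputs,
                },
                indent=1,
                default=str,
            )
        )
        return path
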