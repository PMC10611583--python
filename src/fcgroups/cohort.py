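"""Synthetic cohort generator with planted connectivity groups.

Emulates a case-control resting-state fMRI study: healthy controls plus
schizophrenia (SZ) and bipolar (BP) patients, where overlapping patient
groups are *planted* as network-block shifts of an otherwise common
correlation structure. Each subject's node timeseries are drawn from a
zero-mean multivariate normal whose correlation matrix is

    baseline(A, B) = rho_within  if A == B else rho_between
    cov_block(A, B) = baseline(A, B) + sum over the subject's groups of
                      sign(A, B) * (delta_bold if bold else delta)

clipped to [-0.95, 0.95] and repaired to the nearest valid correlation
matrix by eigenvalue flooring. Personality (TCI) and symptom composites are
shifted for group members according to each group's profile; demographics
are drawn independently of membership so that confounder tests are null by
construction.

The planted membership table is ground truth for evaluation only — the
analysis pipeline never reads it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import (
    CLINICAL_COMPOSITES,
    GROUP_TEMPLATES,
    NETWORKS,
    TCI_DIMENSIONS,
    GroupTemplate,
    block_sign,
    default_node_network_map,
)

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class PlantedGroup:
    """A planted patient group: members, block signs, and phenotype profile."""

    name: str
    member_ids: tuple[str, ...]
    network_signs: dict[str, tuple[int, bool]]
    tci_profile: dict[str, int]
    clinical_profile: dict[str, int]

    def block(self, net_a: str, net_b: str) -> tuple[int, bool]:
        tmpl = GroupTemplate(
            name=self.name, network_signs=self.network_signs,
            tci_profile=self.tci_profile, clinical_profile=self.clinical_profile,
            n_sz=0, n_bp=0,
        )
        return block_sign(tmpl, net_a, net_b)


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Correlation deltas are in correlation units; ``tci_effect`` is in SD
    units of the (unit-variance) phenotype scores.
    """

    n_controls: int = 30
    n_sz: int = 27
    n_bp: int = 35
    n_nodes: int = 160
    n_timepoints: int = 400
    rho_within: float = 0.35
    rho_between: float = 0.10
    delta: float = 0.12
    delta_bold: float = 0.20
    tci_effect: float = 1.5
    noise_sd: float = 1.0
    seed: int = 0
    node_network_map: list[str] | None = None

    def resolve_node_map(self) -> list[str]:
        if self.node_network_map is not None:
            bad = sorted(set(self.node_network_map) - set(NETWORKS))
            if bad:
                raise ValueError(f"unknown network labels in node map: {bad}")
            return list(self.node_network_map)
        return default_node_network_map(self.n_nodes)

    @property
    def n_patients(self) -> int:
        return self.n_sz + self.n_bp


@dataclass
class SyntheticCohort:
    """A generated cohort: roster, timeseries, node table, ground truth."""

    cohort: pd.DataFrame
    timeseries: dict[str, np.ndarray]
    node_networks: list[str]
    node_table: pd.DataFrame
    memberships: dict[str, list[str]]
    config: SimConfig

    @property
    def subject_ids(self) -> list[str]:
        return list(self.cohort["subject_id"])

    @property
    def control_ids(self) -> list[str]:
        m = self.cohort["status"] == "control"
        return list(self.cohort.loc[m, "subject_id"])

    @property
    def patient_ids(self) -> list[str]:
        m = self.cohort["status"] != "control"
        return list(self.cohort.loc[m, "subject_id"])


# ---------------------------------------------------------------------------
# membership assignment


def assign_members(
    ids: list[str], sizes: list[int], affinity: np.ndarray | None = None
) -> list[list[str]]:
    """Deterministically assign subjects to overlapping groups of given sizes.

    Every subject lands in at least one group (groups' unique "cores"
    partition the id list, sized proportionally to the group sizes by
    largest remainder); remaining slots are filled by cycling over a
    sharable half of each core, producing overlap while each group keeps a
    protected set of members unique to it.

    When ``affinity`` (group x group similarity of connectivity signatures)
    is given, each group's overlap members are drawn preferentially from
    the cores of its most compatible groups: a subject expressing two
    signatures is only biologically plausible when those signatures do not
    prescribe opposite deviations for the same networks.
    """
    n, m = len(ids), len(sizes)
    total = sum(sizes)
    if any(s < 0 for s in sizes):
        raise ValueError("group sizes must be nonnegative")
    if total < n:
        raise ValueError(f"group sizes sum to {total} < {n} subjects; cannot cover everyone")
    if max(sizes, default=0) > n:
        raise ValueError("a group cannot exceed the subject pool")

    quotas = [s * n / total for s in sizes]
    cores_n = [int(q) for q in quotas]
    order = sorted(range(m), key=lambda g: (-(quotas[g] - cores_n[g]), g))
    for g in order[: n - sum(cores_n)]:
        cores_n[g] += 1
    # keep cores within group sizes
    for g in range(m):
        while cores_n[g] > sizes[g]:
            cores_n[g] -= 1
            recipient = min(
                (h for h in range(m) if cores_n[h] < sizes[h]),
                key=lambda h: cores_n[h] / max(sizes[h], 1),
            )
            cores_n[recipient] += 1

    cores: list[list[str]] = []
    pos = 0
    for g in range(m):
        cores.append(list(ids[pos : pos + cores_n[g]]))
        pos += cores_n[g]

    def _fill(pool: list[tuple[str, int]]) -> list[list[str]]:
        members = [list(c) for c in cores]
        member_sets = [set(c) for c in cores]
        taken = {s: 0 for s, _ in pool}
        for g in range(m):
            need = sizes[g] - len(members[g])
            if need <= 0:
                continue

            # prefer subjects whose *every* current group is sign-compatible
            # with g (least compatible current membership decides), then
            # least-shared subjects
            def _pref(i: int) -> tuple:
                if affinity is None:
                    return (0, taken[pool[i][0]], i)
                sid = pool[i][0]
                worst = min(
                    affinity[h, g] for h in range(m) if sid in member_sets[h]
                )
                return (-worst, taken[sid], i)

            guard = 0
            while need > 0:
                placed = False
                for i in sorted(range(len(pool)), key=_pref):
                    cand = pool[i][0]
                    if cand in member_sets[g]:
                        continue
                    members[g].append(cand)
                    member_sets[g].add(cand)
                    taken[cand] += 1
                    need -= 1
                    placed = True
                    break
                guard += 1
                if not placed or guard > sum(sizes):
                    raise ValueError(
                        "cannot satisfy group sizes with available overlap pool"
                    )
        return members

    # sharable pool: each core minus a protected leading third (at least one
    # member stays unique to its group); tiny cohorts fall back to sharing
    # whole cores, giving up the per-group uniqueness guarantee (warned)
    strict_pool: list[tuple[str, int]] = []
    for g, c in enumerate(cores):
        protect = max(1, len(c) // 3) if c else 0
        strict_pool.extend((s, g) for s in c[protect:])
    try:
        return _fill(strict_pool)
    except ValueError:
        logger.warning(
            "overlap infeasible with protected cores; sharing all core members"
        )
        return _fill([(s, g) for g, c in enumerate(cores) for s in c])


def template_affinity(templates: tuple[GroupTemplate, ...]) -> np.ndarray:
    """Cosine similarity between the groups' planted block-sign patterns."""
    vecs = []
    for t in templates:
        v = np.zeros(len(NETWORKS) * len(NETWORKS))
        for i, a in enumerate(NETWORKS):
            for j, b in enumerate(NETWORKS):
                s, bold = block_sign(t, a, b)
                v[i * len(NETWORKS) + j] = s * (5.0 / 3.0 if bold else 1.0)
        vecs.append(v)
    V = np.stack(vecs)
    norms = np.linalg.norm(V, axis=1)
    norms[norms == 0] = 1.0
    return (V @ V.T) / np.outer(norms, norms)


def default_planted_groups(
    sz_ids: list[str], bp_ids: list[str],
    templates: tuple[GroupTemplate, ...] = GROUP_TEMPLATES,
) -> list[PlantedGroup]:
    """Build the five default planted groups over the given patient ids.

    SZ and BP members are assigned separately so each group hits its
    per-diagnosis target count; overlap between groups is deliberate and
    drawn preferentially between sign-compatible groups.
    """
    sz_sizes = [t.n_sz for t in templates]
    bp_sizes = [t.n_bp for t in templates]
    aff = template_affinity(templates)
    if len(sz_ids) and sum(sz_sizes):
        sz_members = assign_members(sz_ids, _rescale_sizes(sz_sizes, len(sz_ids)), aff)
    else:
        sz_members = [[] for _ in templates]
    if len(bp_ids) and sum(bp_sizes):
        bp_members = assign_members(bp_ids, _rescale_sizes(bp_sizes, len(bp_ids)), aff)
    else:
        bp_members = [[] for _ in templates]
    groups = []
    for t, sm, bm in zip(templates, sz_members, bp_members):
        groups.append(
            PlantedGroup(
                name=t.name,
                member_ids=tuple(sm + bm),
                network_signs=dict(t.network_signs),
                tci_profile=dict(t.tci_profile),
                clinical_profile=dict(t.clinical_profile),
            )
        )
    return groups


#: pool sizes the default templates were sized for
_TEMPLATE_POOLS = {"SZ": 27, "BP": 35}


def _rescale_sizes(sizes: list[int], n: int) -> list[int]:
    """Rescale template group sizes to a pool of ``n`` subjects.

    The default template sizes assume 27 SZ / 35 BP patients; for other pool
    sizes the per-group counts are scaled proportionally (minimum 1, capped
    at the pool) so that overlap structure is preserved."""
    ref = {44: _TEMPLATE_POOLS["SZ"], 55: _TEMPLATE_POOLS["BP"]}.get(sum(sizes), n)
    if ref == n:
        return list(sizes)
    scaled = [min(n, max(1, round(s * n / ref))) for s in sizes]
    i = 0
    while sum(scaled) < n:  # every subject must be coverable by some group
        scaled[i % len(scaled)] = min(n, scaled[i % len(scaled)] + 1)
        i += 1
    return scaled


# ---------------------------------------------------------------------------
# covariance construction


def build_covariance(
    config: SimConfig, subject_groups: list[PlantedGroup],
    node_map: list[str] | None = None,
) -> np.ndarray:
    """Node-level correlation matrix implied by a subject's group memberships.

    Returns a symmetric PSD matrix with unit diagonal. Block edits can break
    positive semidefiniteness; repaired by flooring eigenvalues at 1e-6 and
    rescaling to unit diagonal (logged).
    """
    nets = node_map if node_map is not None else config.resolve_node_map()
    n = len(nets)
    net_idx = np.array([NETWORKS.index(x) for x in nets])

    # network-pair shift table (16x16)
    shift = np.zeros((len(NETWORKS), len(NETWORKS)))
    for g in subject_groups:
        for key in g.network_signs:
            if key not in NETWORKS:
                raise ValueError(f"invalid network label in signs: {key!r}")
        for a_i, a in enumerate(NETWORKS):
            for b_i, b in enumerate(NETWORKS):
                s, bold = g.block(a, b)
                if s:
                    shift[a_i, b_i] += s * (config.delta_bold if bold else config.delta)

    same = net_idx[:, None] == net_idx[None, :]
    cov = np.where(same, config.rho_within, config.rho_between)
    cov = cov + shift[np.ix_(net_idx, net_idx)]
    cov = np.clip(cov, -0.95, 0.95)
    np.fill_diagonal(cov, 1.0)
    cov = (cov + cov.T) / 2.0
    return _repair_psd(cov)


def _repair_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if vals[0] < _EIG_FLOOR:
        logger.info("PSD repair applied: min eigenvalue %.3e floored", vals[0])
        vals = np.maximum(vals, _EIG_FLOOR)
        cov = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        cov = (cov + cov.T) / 2.0
        np.fill_diagonal(cov, 1.0)
    return cov


def simulate_timeseries(cov: np.ndarray, n_timepoints: int, seed: int,
                        scale: float = 1.0) -> np.ndarray:
    """Draw ``n_timepoints`` i.i.d. rows from N(0, cov). Deterministic per seed."""
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance is not positive definite; apply PSD repair "
            "(eigenvalue flooring) before simulating"
        ) from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, cov.shape[0]))
    return scale * (z @ chol.T)


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    cohort: pd.DataFrame, groups: list[PlantedGroup], config: SimConfig, seed: int,
) -> pd.DataFrame:
    """Fill TCI, symptom and demographic columns.

    Group members' TCI/clinical scores are shifted by ``tci_effect`` times
    the *mean* profile over their memberships (so stacked memberships do not
    inflate effect sizes) plus unit-variance noise; controls are centred at
    zero. Demographics are independent of membership, so demographic
    confounder tests are null by design.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    membership = {g.name: set(g.member_ids) for g in groups}

    profiles = np.zeros((n, len(TCI_DIMENSIONS)))
    clin = np.zeros((n, len(CLINICAL_COMPOSITES)))
    for i, sid in enumerate(out["subject_id"]):
        gs = [g for g in groups if sid in membership[g.name]]
        if gs:
            profiles[i] = np.mean(
                [[g.tci_profile.get(d, 0) for d in TCI_DIMENSIONS] for g in gs], axis=0
            )
            clin[i] = np.mean(
                [[g.clinical_profile.get(c, 0) for c in CLINICAL_COMPOSITES] for g in gs],
                axis=0,
            )
    tci = config.tci_effect * profiles + rng.standard_normal((n, len(TCI_DIMENSIONS)))
    clinical = config.tci_effect * clin + rng.standard_normal((n, len(CLINICAL_COMPOSITES)))
    for j, d in enumerate(TCI_DIMENSIONS):
        out[d] = tci[:, j]
    for j, c in enumerate(CLINICAL_COMPOSITES):
        out[c] = clinical[:, j]

    is_patient = (out["status"] != "control").to_numpy()
    out["age"] = np.clip(rng.normal(35.0, 10.0, n), 18, 65).round(1)
    out["sex"] = rng.choice(["F", "M"], n)
    out["ethnicity"] = rng.choice(["A", "B", "C"], n, p=[0.55, 0.3, 0.15])
    out["handedness"] = rng.choice(["R", "L"], n, p=[0.9, 0.1])
    out["illness_duration"] = np.where(
        is_patient, rng.gamma(2.0, 40.0, n).round(0), 0.0
    )
    out["antipsychotic"] = np.where(is_patient, rng.random(n) < 0.7, False)
    out["mood_stabilizer"] = np.where(is_patient, rng.random(n) < 0.4, False)
    return out


# ---------------------------------------------------------------------------
# cohort generation


def _node_coordinates(node_map: list[str]) -> np.ndarray:
    """Deterministic MNI-like coordinates: a centroid per network plus a
    regular offset per node (synthetic layout, for graph export only)."""
    centroids = {
        "DMN": (0, -52, 26), "CON": (0, 15, 40), "FPN": (-40, 30, 30),
        "DAN": (-28, -60, 52), "VAN": (50, 10, 2), "SAL": (36, 20, -2),
        "VIS": (0, -85, 5), "AUD": (-55, -25, 10), "THA": (0, -15, 8),
        "STR": (12, 10, -5), "CTX": (-30, -40, -12), "PER": (20, -65, -30),
        "SMH": (-38, -22, 55), "SMM": (-50, -10, 35), "AMY": (24, -2, -20),
        "ENT": (-25, -20, -28),
    }
    seen: dict[str, int] = {}
    coords = []
    for net in node_map:
        k = seen.get(net, 0)
        seen[net] = k + 1
        cx, cy, cz = centroids[net]
        coords.append((cx + 6 * (k % 3) - 6, cy + 6 * ((k // 3) % 3) - 6, cz + 6 * (k // 9)))
    return np.asarray(coords, dtype=float)


def generate_cohort(config: SimConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    All randomness flows from one master seed through fixed per-stage
    offsets (timeseries per subject, phenotypes).
    """
    master = config.seed if seed is None else seed
    node_map = config.resolve_node_map()

    ids = (
        [f"C{i+1:03d}" for i in range(config.n_controls)]
        + [f"SZ{i+1:03d}" for i in range(config.n_sz)]
        + [f"BP{i+1:03d}" for i in range(config.n_bp)]
    )
    status = (
        ["control"] * config.n_controls + ["SZ"] * config.n_sz + ["BP"] * config.n_bp
    )
    cohort = pd.DataFrame({"subject_id": ids, "status": status})

    sz_ids = [s for s, st in zip(ids, status) if st == "SZ"]
    bp_ids = [s for s, st in zip(ids, status) if st == "BP"]
    groups = default_planted_groups(sz_ids, bp_ids)
    patient_set = set(sz_ids) | set(bp_ids)
    for g in groups:
        if not set(g.member_ids) <= patient_set:
            raise ValueError(f"group {g.name} contains non-patient members")

    memberships = {g.name: sorted(g.member_ids) for g in groups}
    cohort["planted_memberships"] = [
        ";".join(g.name for g in groups if sid in set(g.member_ids)) for sid in ids
    ]

    cohort = simulate_phenotypes(cohort, groups, config, seed=master * 2 + 1)

    # one covariance per distinct membership combination
    cov_cache: dict[frozenset, np.ndarray] = {}
    timeseries: dict[str, np.ndarray] = {}
    for i, sid in enumerate(ids):
        gs = [g for g in groups if sid in set(g.member_ids)]
        key = frozenset(g.name for g in gs)
        if key not in cov_cache:
            cov_cache[key] = build_covariance(config, gs, node_map)
        timeseries[sid] = simulate_timeseries(
            cov_cache[key], config.n_timepoints,
            seed=(master * 100003 + i) % (2**31), scale=config.noise_sd,
        )

    coords = _node_coordinates(node_map)
    node_table = pd.DataFrame(
        {
            "node_id": [f"n{i:04d}" for i in range(len(node_map))],
            "network": node_map,
            "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        }
    )
    return SyntheticCohort(
        cohort=cohort, timeseries=timeseries, node_networks=node_map,
        node_table=node_table, memberships=memberships, config=config,
    )


# ---------------------------------------------------------------------------
# writers


def write_cohort(sim: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write timeseries TSVs, cohort CSV, node table CSV and the withheld
    ground-truth membership JSON. Returns the paths written."""
    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    node_ids = list(sim.node_table["node_id"])
    for sid, ts in sim.timeseries.items():
        pd.DataFrame(ts, columns=node_ids).to_csv(
            ts_dir / f"{sid}.tsv", sep="\t", index=False, float_format="%.6f"
        )
    cohort_path = outdir / "cohort.csv"
    # planted memberships are withheld from the pipeline-facing roster
    sim.cohort.drop(columns=["planted_memberships"]).to_csv(cohort_path, index=False)
    nodes_path = outdir / "nodes.csv"
    sim.node_table.to_csv(nodes_path, index=False)
    truth_path = outdir / "ground_truth_memberships.json"
    truth_path.write_text(json.dumps(sim.memberships, indent=1))
    return {
        "timeseries_dir": ts_dir, "cohort": cohort_path,
        "nodes": nodes_path, "ground_truth": truth_path,
    }
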