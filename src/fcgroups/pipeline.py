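"""End-to-end pipeline: simulate -> features -> fit -> select -> validate -> report.

All randomness flows from one master seed through fixed per-stage offsets;
re-running with the same configuration and seed reproduces identical
outputs. Each stage can also be run individually from the CLI against the
files a previous stage wrote.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import NETWORKS
from .biclusters import Bicluster, extract_biclusters, score_all
from .cohort import SimConfig, SyntheticCohort, generate_cohort, write_cohort
from .features import (
    ConnectivityStack,
    DeviationFeatureMatrix,
    build_stack,
    control_reference,
    encode_nonnegative,
    write_feature_matrix,
)
from .nmf import multilevel_factorize
from .report import RunManifest, block_matrix_table, export_brainnet
from .select import (
    SelectionResult,
    SelectionWeights,
    accounting_table,
    compute_coverage,
    select,
    write_selection,
)
from .stats import (
    classify_directions,
    confounder_tests,
    diagnosis_within_group,
    network_test_table,
    tci_explanatory_power,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline, YAML-serializable."""

    sim: SimConfig = field(default_factory=SimConfig)
    # features
    feature_mode: str = "node_pair"  # or "network_block"
    apply_fisher_z: bool = True
    standardize: bool = False
    tau_noise: float = 0.0
    # factorization
    k_min: int = 2
    k_max: int = 10
    restarts: int = 5
    init_mode: str = "random-uniform"
    nmf_tol: float = 1e-6
    nmf_max_iter: int = 500
    alpha: float = 0.5
    beta: float = 0.5
    # selection
    weights: SelectionWeights = field(default_factory=SelectionWeights)
    epsilon_gain: float = 0.02
    tau_dup: float = 0.6
    # validation
    p_sig: float = 0.05
    p_bold: float = 0.001
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = SimConfig(**d.pop("sim", {}))
        weights = SelectionWeights(**d.pop("weights", {}))
        return cls(sim=sim, weights=weights, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


def desk_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Desk-scale default configuration used by the analysis scripts.

    48 nodes (3 per network) keeps the node-pair feature matrix small
    enough for multi-seed runs on one CPU while preserving within- and
    between-network pair structure; all cohort sizes, deviation magnitudes
    and algorithm parameters are the standard defaults.
    """
    sim_kwargs: dict = {"n_nodes": 48, "seed": seed}
    sim_kwargs.update(overrides.pop("sim", {}))
    return PipelineConfig(sim=SimConfig(**sim_kwargs), seed=seed, **overrides)


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: SyntheticCohort
    stack: ConnectivityStack
    fm: DeviationFeatureMatrix
    candidates: list[Bicluster]
    selection: SelectionResult
    accounting: pd.DataFrame | None
    validation: dict | None
    manifest: RunManifest


def network_block_values(
    stack: ConnectivityStack, control_ids: list[str]
) -> pd.DataFrame:
    """Per-subject within-network mean deviation from the control mean.

    Used by the validation stage; computed for every subject (controls
    included) so members can be contrasted with controls.
    """
    dev, fmap, _, _, ids = control_reference(
        stack, control_ids, stack.subject_ids, mode="node_pair"
    )
    cols = {}
    for net in NETWORKS:
        mask = ((fmap["network_i"] == net) & (fmap["network_j"] == net)).to_numpy()
        if mask.any():
            cols[net] = dev[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=ids)


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    cohort: SyntheticCohort | None = None,
) -> PipelineResult:
    """Execute the full pipeline; optionally persist all stage outputs.

    A pre-generated cohort may be passed to skip the simulate stage (e.g.
    when analysing user data loaded into a :class:`SyntheticCohort`-shaped
    container).
    """
    manifest = RunManifest(
        config=config.to_dict(), master_seed=config.seed, package_version=__version__
    )
    out = Path(outdir) if outdir is not None else None

    # -- simulate
    if cohort is None:
        cohort = generate_cohort(config.sim, seed=config.seed)
    manifest.log_stage("simulate", subjects=len(cohort.subject_ids))
    if out is not None:
        paths = write_cohort(cohort, out / "simulate")
        for p in paths.values():
            if p.is_file():
                manifest.register(p)

    # -- features
    stack = build_stack(
        cohort.timeseries, cohort.node_networks, apply_fisher_z=config.apply_fisher_z
    )
    dev, fmap, mu, sd, pids = control_reference(
        stack, cohort.control_ids, cohort.patient_ids,
        standardize=config.standardize, mode=config.feature_mode,
    )
    fm = encode_nonnegative(
        dev, pids, fmap, mu, sd, tau_noise=config.tau_noise, mode=config.feature_mode
    )
    manifest.log_stage("features", n_features=fm.n_features, mode=fm.mode)
    if out is not None:
        for p in write_feature_matrix(fm, out / "features").values():
            manifest.register(p)

    # -- fit
    family = multilevel_factorize(
        fm.values, k_min=config.k_min, k_max=config.k_max,
        restarts=config.restarts, seed=config.seed, init_mode=config.init_mode,
        tol=config.nmf_tol, max_iter=config.nmf_max_iter,
    )
    candidates: list[Bicluster] = []
    for model in family:
        candidates.extend(
            extract_biclusters(model, fm, alpha=config.alpha, beta=config.beta)
        )
    score_all(candidates, fm)
    manifest.log_stage(
        "fit", ranks=[m.rank for m in family], n_candidates=len(candidates)
    )
    if out is not None:
        _persist_fit(family, candidates, fm, out / "fit", manifest)

    # -- select
    selection = select(
        candidates, fm.patient_ids, weights=config.weights,
        epsilon_gain=config.epsilon_gain, tau_dup=config.tau_dup,
    )
    for i, bc in enumerate(selection.selected):
        bc.name = f"Group {i + 1}"
        bc.risk = None
    accounting = accounting_table(selection, cohort.cohort) if selection.selected else None
    if accounting is not None:
        for bc, risk in zip(selection.selected, accounting["risk"]):
            bc.risk = float(risk)
    manifest.log_stage(
        "select", n_selected=selection.n_selected,
        subject_coverage=selection.subject_coverage,
    )
    if out is not None:
        _persist_selection(selection, accounting, out / "select", manifest)

    # -- validate
    if not selection.selected:
        logger.warning("selection is empty: validation skipped")
        manifest.log_stage("validate", skipped=True, reason="empty selection")
        validation = None
    else:
        validation = validate_groups(config, cohort, stack, fm, selection)
        manifest.log_stage("validate", groups=[b.name for b in selection.selected])
        if out is not None:
            _persist_validation(validation, out / "validate", manifest)

    # -- report
    if out is not None and selection.selected:
        _persist_report(selection, fm, cohort.node_table, out / "report", manifest)
        manifest.log_stage("report", n_groups=len(selection.selected))

    if out is not None:
        manifest.write(out / "manifest.json")

    return PipelineResult(
        config=config, cohort=cohort, stack=stack, fm=fm,
        candidates=candidates, selection=selection,
        accounting=accounting, validation=validation, manifest=manifest,
    )


def validate_groups(
    config: PipelineConfig,
    cohort: SyntheticCohort,
    stack: ConnectivityStack,
    fm: DeviationFeatureMatrix,
    selection: SelectionResult,
) -> dict:
    """Statistical validation of the selected groups against data the
    clustering never saw (TCI, symptoms, demographics) plus direction
    classification of their connectivity deviations."""
    blocks = network_block_values(stack, cohort.control_ids)
    roster = cohort.cohort
    patients = cohort.patient_ids
    status = roster.set_index("subject_id")["status"]
    tci = roster.set_index("subject_id").loc[patients]

    direction_tables = {}
    tci_results = {}
    diagnosis = {}
    signed = fm.signed()
    for bc in selection.selected:
        table = network_test_table(
            blocks, list(bc.subjects), cohort.control_ids, patients
        )
        direction_tables[bc.name] = classify_directions(
            table, p_sig=config.p_sig, p_bold=config.p_bold
        )
        member_mask = np.isin(patients, list(bc.subjects))
        try:
            res = tci_explanatory_power(tci, member_mask.astype(float), group_name=bc.name)
            tci_results[bc.name] = {
                "predictors": res.predictors, "r2_percent": res.r2_percent,
                "F": res.f_stat, "p": res.p_value, "rmse": res.rmse,
                "ridge_fallback": res.used_ridge_fallback,
            }
        except ValueError as exc:
            logger.warning("TCI regression not applicable for %s: %s", bc.name, exc)
            tci_results[bc.name] = {"applicable": False, "reason": str(exc)}
        feat_idx = sorted({fm.channel_of(c)[0] for c in bc.features})
        member_rows = np.flatnonzero(member_mask)
        is_sz = (status.loc[np.asarray(patients)[member_rows]] == "SZ").to_numpy()
        diagnosis[bc.name] = diagnosis_within_group(
            signed[np.ix_(member_rows, feat_idx)], is_sz
        )

    confounders = confounder_tests(
        roster, {bc.name: list(bc.subjects) for bc in selection.selected}
    )
    cov_round, cov_full = compute_coverage(selection, roster)
    return {
        "direction_tables": direction_tables,
        "tci": tci_results,
        "diagnosis": diagnosis,
        "confounders": confounders,
        "coverage_percent": cov_full,
        "coverage_percent_rounded": cov_round,
    }


def _persist_fit(family, candidates, fm, fit_dir: Path, manifest: RunManifest | None) -> None:
    fit_dir.mkdir(parents=True, exist_ok=True)
    for model in family:
        pd.DataFrame(model.W, index=fm.patient_ids).to_csv(
            fit_dir / f"W_rank{model.rank}.csv", float_format="%.6g"
        )
        pd.DataFrame(model.H).to_csv(
            fit_dir / f"H_rank{model.rank}.csv", float_format="%.6g"
        )
    cand_path = fit_dir / "candidates.json"
    _write_candidates(candidates, cand_path)
    if manifest is not None:
        manifest.register(cand_path)


def _persist_selection(selection, accounting, sel_dir: Path,
                       manifest: RunManifest | None) -> None:
    sel_dir.mkdir(parents=True, exist_ok=True)
    p = write_selection(selection, sel_dir / "selection.json")
    if manifest is not None:
        manifest.register(p)
    if accounting is not None:
        acc_path = sel_dir / "groups_table.csv"
        accounting.to_csv(acc_path, index=False)
        if manifest is not None:
            manifest.register(acc_path)


def _persist_validation(validation: dict, val_dir: Path,
                        manifest: RunManifest | None) -> None:
    val_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in validation["direction_tables"].items():
        p = val_dir / f"directions_{name.replace(' ', '_')}.csv"
        table.to_csv(p, index=False)
        paths.append(p)
    tci_path = val_dir / "tci_regressions.json"
    tci_path.write_text(json.dumps(validation["tci"], indent=1))
    paths.append(tci_path)
    conf_path = val_dir / "confounders.csv"
    validation["confounders"].to_csv(conf_path, index=False)
    paths.append(conf_path)
    diag_path = val_dir / "diagnosis_contrasts.json"
    diag_path.write_text(json.dumps(validation["diagnosis"], indent=1))
    paths.append(diag_path)
    if manifest is not None:
        for p in paths:
            manifest.register(p)


def _persist_report(selection, fm, node_table, rep_dir: Path,
                    manifest: RunManifest | None) -> None:
    rep_dir.mkdir(parents=True, exist_ok=True)
    for bc in selection.selected:
        stem = (bc.name or f"rank{bc.rank}_factor{bc.factor}").replace(" ", "_").lower()
        bm = block_matrix_table(bc, fm)
        p = rep_dir / f"block_matrix_{stem}.csv"
        bm.to_csv(p)
        if manifest is not None:
            manifest.register(p)
        if fm.mode == "node_pair":
            for p2 in export_brainnet(bc, fm, node_table, rep_dir, stem):
                if manifest is not None:
                    manifest.register(p2)


def load_cohort_dir(simdir: str | Path) -> SyntheticCohort:
    """Reload a cohort written by the simulate stage (or user data laid out
    the same way: timeseries/*.tsv, cohort.csv, nodes.csv)."""
    simdir = Path(simdir)
    roster = pd.read_csv(simdir / "cohort.csv")
    nodes = pd.read_csv(simdir / "nodes.csv")
    ts = {}
    for sid in roster["subject_id"]:
        ts[sid] = pd.read_csv(simdir / "timeseries" / f"{sid}.tsv", sep="\t").to_numpy(float)
    truth_path = simdir / "ground_truth_memberships.json"
    memberships = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    if "planted_memberships" not in roster.columns:
        roster["planted_memberships"] = ""
    return SyntheticCohort(
        cohort=roster, timeseries=ts, node_networks=list(nodes["network"]),
        node_table=nodes, memberships=memberships, config=SimConfig(),
    )


def _write_candidates(candidates: list[Bicluster], path: Path) -> None:
    path.write_text(
        json.dumps(
            [
                {
                    "rank": bc.rank, "factor": bc.factor,
                    "subjects": list(bc.subjects), "features": list(bc.features),
                    "block_signs": bc.block_signs,
                    "sensitivity": bc.sensitivity, "specificity": bc.specificity,
                    "strength": bc.strength,
                }
                for bc in candidates
            ],
            indent=1,
        )
    )


def read_candidates(path: str | Path) -> list[Bicluster]:
    data = json.loads(Path(path).read_text())
    return [
        Bicluster(
            subjects=tuple(b["subjects"]), features=tuple(b["features"]),
            block_signs=b["block_signs"], rank=b["rank"], factor=b["factor"],
            sensitivity=b["sensitivity"], specificity=b["specificity"],
            strength=b.get("strength", float("nan")),
        )
        for b in data
    ]
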