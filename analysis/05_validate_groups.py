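#!/usr/bin/env python
"""Validate the selected groups with data the clustering never saw:
per-network direction classification vs controls, TCI explanatory power
(stepwise logistic), SZ-vs-BP contrasts within groups, and demographic
confounder tests.

Writes all validation tables under results/05_validation/.
"""

from pathlib import Path

from fcgroups.features import build_stack, read_feature_matrix
from fcgroups.pipeline import (
    PipelineConfig,
    _persist_validation,
    load_cohort_dir,
    validate_groups,
)
from fcgroups.select import read_selection

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "analysis_run"


def main() -> None:
    cfg = PipelineConfig.from_yaml(RUN / "config.yaml")
    cohort = load_cohort_dir(RUN / "simulate")
    fm = read_feature_matrix(RUN / "features")
    selection = read_selection(ROOT / "results" / "04_selection.json")
    if not selection.selected:
        print("selection is empty: nothing to validate")
        return
    stack = build_stack(cohort.timeseries, cohort.node_networks,
                        apply_fisher_z=cfg.apply_fisher_z)
    validation = validate_groups(cfg, cohort, stack, fm, selection)
    outdir = ROOT / "results" / "05_validation"
    _persist_validation(validation, outdir, None)

    for bc in selection.selected:
        table = validation["direction_tables"][bc.name]
        sig = table[table["direction"] != "--"]
        dirs = ", ".join(
            f"{row['network']} {row['direction']}"
            + (" (bold)" if row["bold"] else "")
            for _, row in sig.iterrows()
        )
        tci = validation["tci"][bc.name]
        if tci.get("applicable", True):
            tci_txt = (f"TCI R^2 = {tci['r2_percent']:.1f}% "
                       f"(F = {tci['F']:.1f}, p = {tci['p']:.2g}, "
                       f"RMSE = {tci['rmse']:.2f}; "
                       f"predictors {', '.join(tci['predictors']) or 'none'})")
        else:
            tci_txt = "TCI regression not applicable (group too small)"
        diag = validation["diagnosis"][bc.name]
        print(f"{bc.name} (n = {len(bc.subjects)}):")
        print(f"  networks vs controls: {dirs or 'none significant'}")
        print(f"  {tci_txt}")
        if diag["applicable"]:
            print(f"  SZ vs BP within group: {diag['strong']} features p<0.01, "
                  f"{diag['weak']} in 0.01<p<0.05 of {diag['n_features']}")
    conf = validation["confounders"]
    n_sig = (conf["p"] < 0.05).sum()
    print(f"confounder screen: {n_sig}/{len(conf)} tests at p < 0.05 "
          f"(demographics are group-balanced by design)")


if __name__ == "__main__":
    main()
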