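#!/usr/bin/env python
"""Export presentation artifacts: 16x16 signed block matrices per group and
BrainNet Viewer .node/.edge graph inputs.

Writes everything under results/06_report/.
"""

from pathlib import Path

from fcgroups.features import read_feature_matrix
from fcgroups.pipeline import _persist_report, load_cohort_dir
from fcgroups.report import block_matrix_table
from fcgroups.select import read_selection

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "analysis_run"


def main() -> None:
    cohort = load_cohort_dir(RUN / "simulate")
    fm = read_feature_matrix(RUN / "features")
    selection = read_selection(ROOT / "results" / "04_selection.json")
    if not selection.selected:
        print("selection is empty: nothing to report")
        return
    outdir = ROOT / "results" / "06_report"
    _persist_report(selection, fm, cohort.node_table, outdir, None)
    for bc in selection.selected:
        table = block_matrix_table(bc, fm)
        pos = int((table.to_numpy() > 0).sum())
        neg = int((table.to_numpy() < 0).sum())
        print(f"{bc.name}: {len(bc.features)} channel features over "
              f"{pos} positive and {neg} negative network blocks")
    print(f"wrote block matrices and BrainNet .node/.edge files to {outdir}")


if __name__ == "__main__":
    main()
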