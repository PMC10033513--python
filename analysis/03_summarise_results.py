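#!/usr/bin/env python
"""Digest the pipeline run into a Markdown report.

States, per fossil, where its median reconstructed CC_CoM falls relative
to the extant hindlimb- and forelimb-dominated ranges, lists the
allometry classifications, and scores the fossil reconstructions against
the generator's withheld ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hullcom.pipeline import summarise

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    run_dir = STUDY / "run"
    text = summarise(run_dir)
    print(text)

    # score reconstructions against the withheld answers
    answers = pd.read_csv(STUDY / "fossil_answers.csv", index_col="taxon")
    grid = pd.read_csv(run_dir / "fossil_grid.csv")
    std = grid[grid["iteration_tag"] == "mean_ratio:all_taxa|standard"]
    merged = std.set_index("taxon").join(answers)
    mass_err = (
        (merged["body_mass"] - merged["true_body_mass"]).abs()
        / merged["true_body_mass"]
    )
    cc_err = (merged["cc_com_norm"] - merged["true_cc_com_norm"]).abs()
    lines = [
        "",
        "## Recovery vs withheld ground truth (mean-ratio / standard iteration)",
        f"- median relative body-mass error: {mass_err.median():.2e}",
        f"- median |CC_CoM_norm error|: {cc_err.median():.2e} m kg^-1/3",
    ]
    report = "\n".join(lines) + "\n"
    with open(run_dir / "summary.md", "a") as fh:
        fh.write(report)
    print(report)


if __name__ == "__main__":
    main()
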