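#!/usr/bin/env python
"""Dendritic morphometry of 30 reconstructed neurons per cohort.

Sholl profiles on 20-µm shells (split-plot ANOVA on log10(count+1)),
cumulative dendritic length, branch-point counts and soma area (Welch t).
The treated cohort grows ~15 % shorter branches, so the Sholl treatment
effect and the length difference are the panels to watch.
"""

from pathlib import Path

from matcare.pipeline import ExperimentConfig, run_experiment

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rep = run_experiment(ExperimentConfig(seed=1), stages=("morphology",))
    rep.tables["morpho_metrics"].to_csv(RESULTS / "morpho_metrics.csv",
                                        index=False)
    rep.tables["sholl_long"].to_csv(RESULTS / "sholl_long.csv", index=False)
    rep.summary.to_csv(RESULTS / "morpho_tests.csv", index=False)
    print(rep.summary.to_string(index=False))


if __name__ == "__main__":
    main()
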