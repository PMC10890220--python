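#!/usr/bin/env python
"""Quantify how well parsimony recovers a known simulated ancestor.

Simulates karyotype evolution from the 2n = 48 all-acrocentric state down
random 8-tip trees (Poisson events per branch, fusion-dominated draw
probabilities), reconstructs from the tips alone, and asks how often the
true root lies in the co-optimal root set — as a function of the event
density. Recovery decays steeply with events per branch: parsimony can
only recover a root that some lineage still witnesses. Writes
results/ancestor_recovery.tsv.
"""

from pathlib import Path

import pandas as pd

from karyokit.experiments import ancestor_recovery_rate

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    rows = []
    for mean_events in (0.1, 0.25, 0.5, 1.0, 2.0):
        res = ancestor_recovery_rate(
            n_replicates=200, n_tips=8, events_per_branch=mean_events, seed=7
        )
        rows.append(
            {
                "events_per_branch": mean_events,
                "replicates": res.n_replicates,
                "recovered": res.n_recovered,
                "recovery_rate": res.recovery_rate,
                "mean_root_set_size": round(res.mean_root_set_size, 2),
            }
        )
        print(
            f"Poisson({mean_events}) events/branch: root recovered in "
            f"{res.n_recovered}/200 ({res.recovery_rate:.0%}), "
            f"mean co-optimal set size {res.mean_root_set_size:.2f}"
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "ancestor_recovery.tsv", sep="\t", index=False)
    print(f"\nwrote {OUT / 'ancestor_recovery.tsv'}")
    print(
        "\nRecovery is near-certain only when most branches are quiet; at one "
        "expected event per branch the true root is usually erased from every "
        "lineage and no parsimony method can place it in the co-optimal set."
    )


if __name__ == "__main__":
    main()
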