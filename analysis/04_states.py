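#!/usr/bin/env python
"""Community-state typing and the state transition map.

Computes sqrt Jensen-Shannon distances between all samples, clusters them
with PAM across K = 2..10, picks K by the Calinski-Harabasz index, and
folds the per-mouse state trajectories into a transition map (who moves
where between consecutive timepoints). With the default simulated design
the expected outcome is four states: pre-diet baseline, mildly and
markedly antibiotic-perturbed, and post-diet.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from patmb.io import align, read_metadata, read_otu_table
from patmb.states import (
    choose_k,
    distance_matrix,
    relative_abundance,
    transition_map,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--kmin", type=int, default=2)
    ap.add_argument("--kmax", type=int, default=10)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_otu_table(args.data_dir / "otu_table.tsv")
    meta = read_metadata(args.data_dir / "metadata.tsv")
    view = align(table, meta)

    D = distance_matrix(relative_abundance(view.table))
    sol = choose_k(D, range(args.kmin, args.kmax + 1))
    print(f"Calinski-Harabasz selects K = {sol.k}")
    print("CH by K:", {k: round(v, 1) for k, v in sorted(sol.ch_by_k.items())})

    args.out_dir.mkdir(parents=True, exist_ok=True)
    out = pd.DataFrame({
        "state": sol.labels,
        "is_medoid": [s in set(sol.medoid_ids) for s in sol.labels.index],
    }).join(view.metadata.frame[["mouse_id", "group", "day_of_life",
                                 "timepoint_index"]])
    out.reset_index().to_csv(args.out_dir / "states.tsv", sep="\t",
                             index=False)
    with open(args.out_dir / "ch_by_k.json", "w") as fh:
        json.dump({str(k): v for k, v in sol.ch_by_k.items()}, fh, indent=2)

    tm = transition_map(sol.labels, view.metadata)
    rows = []
    for (t1, t2), mat_ in tm.counts.items():
        for i, s1 in enumerate(tm.states):
            for j, s2 in enumerate(tm.states):
                if mat_[i, j]:
                    rows.append({"from_timepoint": t1, "to_timepoint": t2,
                                 "from_state": s1, "to_state": s2,
                                 "n_mice": int(mat_[i, j])})
    pd.DataFrame(rows).to_csv(args.out_dir / "transitions.tsv", sep="\t",
                              index=False)
    tm.occupancy.reset_index().to_csv(args.out_dir / "occupancy.tsv",
                                      sep="\t", index=False)

    final = out[out["timepoint_index"] == out["timepoint_index"].max()]
    print("final-timepoint state by group:")
    print(final.groupby(["group", "state"]).size().unstack(fill_value=0)
          .to_string())


if __name__ == "__main__":
    main()
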