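"""Call hits and rank prime candidates.

From the Z-score table: (i) the broad candidate-regulator list — the union
over both age groups and both parameters of targets with |average Z| > 1;
(ii) the prime candidate set — the union of the top-5 and bottom-5 targets
by all-replicate average Z for each parameter.
"""

from pathlib import Path

import pandas as pd

from flowscreen.io import read_table, write_table
from flowscreen.screen import call_hits, hits_union_over_groups, rank_candidates

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ztable = read_table(OUT / "zscore_table.tsv")

    union = hits_union_over_groups(ztable, t=1.0)
    write_table(
        pd.DataFrame(dict(target_gene=union.members)),
        OUT / "hits_union.tsv",
    )
    down = call_hits(ztable, t=1.0, direction="below",
                     parameter_rule="union", scope="all")
    write_table(
        pd.DataFrame(dict(target_gene=down.members)),
        OUT / "hits_down.tsv",
    )
    candidates = rank_candidates(ztable, k=5)
    write_table(
        pd.DataFrame(
            dict(
                target_gene=candidates.members,
                provenance=[",".join(candidates.provenance[g])
                            for g in candidates.members],
            )
        ),
        OUT / "candidates.tsv",
    )
    print(f"{len(union)} targets with |avg Z| > 1 on either parameter in "
          f"either age group (broad candidate-regulator list)")
    print(f"{len(down)} targets with all-replicate avg Z < -1 "
          f"(reduced stem-cell readout)")
    print(f"{len(candidates)} prime candidates from the four top/bottom-5 "
          f"lists: {', '.join(candidates.members)}")
    print(f"wrote hits_union.tsv, hits_down.tsv, candidates.tsv -> {OUT}")


if __name__ == "__main__":
    main()
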