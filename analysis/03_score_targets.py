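"""Score every target: plate normalization, per-replicate Z, average Z.

Reads the gated well summaries and the plate map, normalizes each target
well to its plate's nontargeted controls, Z-scores each replicate
library-wide, and averages Z per target over the pup, adult and combined
replicate groups for both parameters (%Bright, MFI).
"""

from pathlib import Path

from flowscreen.io import read_plate_map, read_table, write_table
from flowscreen.screen import build_zscore_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summaries = read_table(OUT / "well_summaries.tsv")
    plate_map = read_plate_map(OUT / "plate_map.csv")
    ztable = build_zscore_table(summaries, plate_map)
    write_table(ztable, OUT / "zscore_table.tsv")
    for p in ("bright_pct", "mfi"):
        part = ztable[ztable["parameter"] == p]
        print(
            f"{p}: {len(part)} targets; avg Z over all six replicates in "
            f"[{part['avg_z_all'].min():.2f}, {part['avg_z_all'].max():.2f}]"
        )
    print(f"wrote zscore_table.tsv -> {OUT}")


if __name__ == "__main__":
    main()
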