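"""Compare pup versus adult knockdown responses (ΔZ).

ΔZ = |average Z (pup) - average Z (adult)| per target and parameter.
Small ΔZ means the knockdown acted similarly at both ages; ΔZ > 2 flags
strongly age-differential responders.
"""

from pathlib import Path

from flowscreen.io import read_table, write_table
from flowscreen.screen import delta_z

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ztable = read_table(OUT / "zscore_table.tsv")
    dz = delta_z(ztable)
    write_table(dz, OUT / "delta_z.tsv")

    print(f"mean ΔZ over both parameters: {dz['delta_z'].mean():.2f}")
    print(f"{100 * (dz['delta_z'] < 1).mean():.0f}% of target/parameter "
          f"responses were similar at both ages (ΔZ < 1)")
    for p in ("bright_pct", "mfi"):
        part = dz[dz["parameter"] == p]
        n2 = int((part["delta_z"] > 2).sum())
        print(f"{p}: {n2} targets with strongly age-differential "
              f"response (ΔZ > 2)")
    print(f"wrote delta_z.tsv -> {OUT}")


if __name__ == "__main__":
    main()
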