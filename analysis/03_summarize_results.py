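"""Summarize the pipeline outputs.

Reads the CSV tables written by 02_run_pipeline.py and prints: the
Table-2-style counts of subjects showing SR per source, the group-level SR
flags (2-SE and Dunnett) per condition, mean normalized power-ratio curves,
and the red/blue/gray classification of every (pair, band, window) cell.
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    counts = pd.read_csv(args.run / "sr_counts.csv", index_col=0)
    print("subjects showing SR (peak power ratio at an added-noise level):")
    print(counts.to_string(), "\n")

    group = pd.read_csv(args.run / "sr_group.csv")
    print("group SR criteria per source x condition:")
    print(group.pivot_table(index="condition", columns="source", values="mean",
                            sort=False).round(3).to_string())
    flagged = group[group["flag_2se"] | group["flag_dunnett"]]
    if len(flagged):
        print("\nflagged conditions (departing from no-noise):")
        print(flagged[["source", "condition", "mean", "se",
                       "flag_2se", "flag_dunnett"]].to_string(index=False))

    cls = pd.read_csv(args.run / "classification.csv")
    cells = cls.drop_duplicates(subset=["pair", "band", "window"])
    print("\nphase-locking SR classification (red = noise-induced locking,")
    print("blue = tonic locking modulated by noise, gray = no reliable effect):")
    print(cells[["pair", "band", "window", "category"]].to_string(index=False))


if __name__ == "__main__":
    main()
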