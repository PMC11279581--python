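"""Cyclization impact on potency over the paired MIC corpus.

Reads results/mic_pairs.tsv, computes the signed log2 MIC ratio per pair and
summarizes by bond set and gram class.  With the planted -2 dilution effect
the median ΔMIC should recover -2 in every group despite the one-dilution
noise.  Writes results/delta_mic_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from cyclopep import GramClass, MICPair, summarize_pairs


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.out_dir / "mic_pairs.tsv", sep="\t")
    pairs = [
        MICPair(
            id=str(r["id"]), sequence=str(r["sequence"]),
            mic_linear=float(r["mic_linear"]), mic_cyclic=float(r["mic_cyclic"]),
            unit=str(r["unit"]), bond_set=str(r["bond_set"]),
            strain=str(r["strain"]), gram=GramClass(r["gram"]),
        )
        for r in df.to_dict("records")
    ]
    summary = summarize_pairs(pairs, ("bond_set", "gram"))
    summary.to_csv(args.out_dir / "delta_mic_summary.tsv", sep="\t",
                   index=False, float_format="%.6g")
    print(summary.to_string(index=False))
    overall = summarize_pairs(pairs, ())
    print(f"\noverall median ΔMIC: {overall['median_delta_mic'].iloc[0]:+.0f} "
          f"dilutions over {overall['n'].iloc[0]} pairs (planted: -2)")


if __name__ == "__main__":
    main()
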