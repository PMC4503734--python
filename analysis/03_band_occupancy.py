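#!/usr/bin/env python
"""Do loud-calls follow group movement?  Classify each eligible caller's
calls (and deduplicated calling locations) into territory bands and test
the pooled counts against the movement-proportional expectation of
50% / 25% / 20% for the three inner bands (three categories, df = 2)."""

import argparse
from pathlib import Path

from babblercalls import AnalysisConfig, read_dataset, run_all
from babblercalls.pipeline import band_table

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

report = run_all(read_dataset(args.data), AnalysisConfig())
table = band_table(report)
args.out.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out / "band_counts.csv", index=False)

pooled = (
    table.groupby(["unit", "band"])[["observed", "expected"]].sum().reset_index()
)
print("pooled band occupancy (all eligible callers):")
print(pooled.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print()
print(f"calls:     {report.band_test_calls}")
print(f"locations: {report.band_test_locations}")
outside = pooled.query("band == 'outside95'")["observed"].sum()
if report.band_test_calls.p < 0.05:
    print(
        "\ncalling does NOT follow group movement: the outer band holds more "
        "calls than expected (planted border bias recovered)."
    )
else:
    print("\nno significant deviation from movement-proportional calling.")
print(f"({int(outside)} calls fell outside the 95% isopleth; reported, not tested)")
print(f"wrote {args.out / 'band_counts.csv'}")
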