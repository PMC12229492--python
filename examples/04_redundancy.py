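"""Quantify how much two inversion callsets share, stringently and loosely.

Builds a 'long-read' style callset and a 'short-read' style callset that
re-detects 60% of the events with slightly shifted breakpoints, then
compares exact-coordinate matching with 50%-of-length fractional matching.
"""

from invkit import redundancy_matrix
from invkit.model import Callset, InversionCall

long_read = []
short_read = []
for i in range(50):
    start = 100_000 + 40_000 * i
    length = 5_000 + 700 * i
    long_read.append(InversionCall(f"lr{i}", "chr1", start, start + length, "longread"))
    if i % 5 < 3:  # 60% re-detected, breakpoints off by ~300 bp
        short_read.append(
            InversionCall(f"sr{i}", "chr1", start + 300, start + length - 250, "shortread")
        )

a = Callset("longread", long_read)
b = Callset("shortread", short_read)

for criterion in ("exact", "fraction"):
    m = redundancy_matrix([a, b], criterion, f=0.5)
    print(f"criterion = {m.criterion}")
    print(m.percent.round(1).to_string(), "\n")

m = redundancy_matrix([a, b], "fraction", 0.5)
spec = m.membership[m.membership["dataset_specific"]]
print(
    f"{len(spec)} inversions are dataset-specific under the 50% criterion."
    "\nExact coordinate matching finds nothing (every breakpoint pair differs"
    "\nby a few hundred bp), while fractional matching recovers the shared"
    "\nevents - the same resolution effect that makes cross-technology"
    "\ncallset comparisons look artificially disjoint."
)
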