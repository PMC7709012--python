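"""Screen for Siliplant1-like silicification proteins and grade them.

The screen keeps secreted, basic proteins (pI >= 7 with a cleavable signal
peptide).  Kept records are graded by compositional architecture:
ACCUMULATOR (H/D-, P/K/E- and P/T/Y-rich tracts all present, as in strong
silicon accumulators), MODERATE (P/K/E tract only) or LOW.
"""

from collections import Counter

from siliscan import batch_screen
from siliscan.synthetic import SyntheticSpec, make_batch

positives, pos_meta = make_batch(SyntheticSpec(mode="slp1", n=20, seed=5))
negatives, neg_meta = make_batch(SyntheticSpec(mode="negative", screen="slp1", n=20, seed=1005))

calls, summary = batch_screen(positives + negatives, "slp1")

print(f"{summary['passed']}/{summary['input']} records pass the pI + signal filters")
print("failures by rule:", summary["failed_by_reason"])
classes = Counter(c.accumulator_class for c in calls if c.passes)
print("architecture classes among passing records:", dict(classes))
example = next(c for c in calls if c.accumulator_class == "ACCUMULATOR")
print(f"example accumulator {example.record_id}: pI={example.pi:.2f}, "
      f"cleavage after {example.signal.cleavage_pos}, "
      f"{example.architecture.cassette_count} HD->PKE->PTY cassette(s), "
      f"{len(example.repeats)} tandem repeat block(s)")
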