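"""Screen for efflux-type (Lsi2-like) Si transporters.

Efflux transporters are polytopic membrane proteins; the screen keeps
records with at least nine predicted transmembrane helices and annotates
the degenerate monocot signature XXTKHXWFXXCXXXXRX (planted, in half the
positives, in the loop right before the sixth helix).
"""

from siliscan import batch_screen
from siliscan.synthetic import SyntheticSpec, make_batch

positives, pos_meta = make_batch(SyntheticSpec(mode="lsi2", n=15, seed=3))
negatives, neg_meta = make_batch(SyntheticSpec(mode="negative", screen="lsi2", n=15, seed=1003))

calls, summary = batch_screen(positives + negatives, "lsi2")

print(f"{summary['passed']}/{summary['input']} records have >= 9 predicted helices")
with_sig = [c for c in calls if c.monocot_signature]
print(f"{len(with_sig)} records carry the monocot signature "
      f"(annotation only -- it does not gate the screen)")
for call in calls[:3]:
    print(f"  {call.record_id}: {call.tmd_count} TMDs, "
          f"signature={'yes' if call.monocot_signature else 'no'}, "
          f"passes={call.passes}")
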