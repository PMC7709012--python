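# siliscan

Rule-based, fully offline screens for the three protein families behind
silicon movement and deposition in plants:

* **channel-type influx Si transporters** (Lsi1-like NIP-III aquaporins) —
  two NPA boxes with 108–109 residues between them, a Gly-Ser-Gly-Arg
  (GSGR) or Ser-Thr-Ala-Arg (STAR) aromatic/arginine selectivity filter,
  and 5–6 transmembrane helices;
* **efflux Si transporters** (Lsi2-like anion-transporter relatives) — at
  least 9 transmembrane helices, with the degenerate monocot signature
  `XXTKHXWFXXCXXXXRX` annotated;
* **Siliplant1-like silicification proteins** — secreted (cleavable signal
  peptide), basic (pI ≥ 7), graded by their H/D-rich → P/K/E-rich →
  P/T/Y-rich cassette architecture into accumulator classes.

It is aimed at plant genomicists who want to triage proteome FASTA files
for silicon-transport candidates without depending on web servers: every
step — Kyte–Doolittle hydropathy segmentation, a von-Heijne-style
signal-peptide test, Needleman–Wunsch (BLOSUM62) filter mapping,
Bjellqvist-pKa isoelectric points, compositional-bias segmentation,
periodicity-based tandem-repeat detection, and Poisson-corrected distances
d = −ln(1 − p) — runs locally from sequence alone. A seeded synthetic-data
generator produces labelled positives and single-defect negatives for
every screen, which is how the pipeline verifies itself end to end.

## Worked example

```python
from siliscan import batch_screen, load_reference
from siliscan.synthetic import SyntheticSpec, make_batch

profile = load_reference()
positives, _ = make_batch(SyntheticSpec(mode="lsi1", n=20, seed=7))
negatives, _ = make_batch(SyntheticSpec(mode="negative", screen="lsi1", n=20, seed=1007))
calls, summary = batch_screen(positives + negatives, "lsi1", profile=profile)
print(summary["passed"], summary["failed_by_reason"])
```

Running `python examples/screen_channel_transporters.py` (the same
computation with reporting) prints:

```
screened 40 records: 20 passed, 20 failed
failures by rule: {'npa': 6, 'selectivity_filter': 8, 'spacing': 11, 'tmd_count': 5}
example pass: lsi1_positive_7_0000  spacing=108  SF=GSGR  TMDs=6
decisions matching planted labels: 40/40
```

All 20 planted transporters clear the four rules; each planted negative is
rejected by exactly the rule its defect violates (a 100/116-residue
spacing, a FAAR filter, a missing second NPA box, or too few helices).
`examples/` contains one script per capability — the efflux and Slp1
screens, the published silica-precipitating peptides, and divergence
estimation; `siliscan --help` exposes the same pipeline as `scan-lsi1`,
`scan-lsi2`, `scan-slp1`, `simulate`, `distance` and `physchem`
subcommands writing TSV reports and JSON summaries.

Another one-liner, on the published silica-precipitating signature
(`python examples/printed_peptides.py`):

```
signature KEKPVKPPKKHPPP
  positive-charge density: 0.4286  (6/14 residues are K/R/H)
  K->A scan: AEAPVAPPAAHPPP  density 0.4286 -> 0.0714
  pI: 10.18 (strongly basic, as expected for a silica-precipitating peptide)
tandem array of the printed unit: 8 copies of KPPIYKPPVYTPPVYKPPVEKPP spanning 1-184 (identity 1.00)
```

The 6/14 → 1/14 density collapse is the sequence-level counterpart of the
K→A ablation experiments on this peptide.

## Reference profile

The selectivity filter is read by aligning each candidate to a packaged
reference profile (`siliscan/data/lsi1_reference_synthetic.fasta` +
`.json`). The shipped profile is a *synthetic* scaffold with the canonical
channel-type layout (six helices, NPA boxes 108 apart, GSGR at four mapped
positions); to type filters against a real reference, replace the FASTA
and the sidecar's `sf_positions`. Screen thresholds, hydropathy windows
and gap penalties live in one config object and can be overridden from a
`section.key = value` file (`--config`).

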