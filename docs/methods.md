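# Methods

`siliscan` classifies plant protein sequences into three families involved
in silicon uptake and deposition, using explicit sequence rules rather than
external prediction servers. This note records the models behind each
module, the tunable constants and why they hold their defaults, what the
synthetic data emulate (and do not), and the numerical choices made where
the design was genuinely open.

## The screening rules

**Channel-type influx transporters (Lsi1-like).** These are NIP-III
aquaporins. A record passes when all four rules hold: (i) at least two
N-P-[A/V] boxes (the NPV variant is tolerated and flagged); (ii) the
selected box pair has 108 or 109 residues strictly between the last residue
of the first box and the first residue of the second; (iii) the four
aromatic/arginine (ar/R) selectivity-filter residues, read by alignment to
the packaged reference, spell GSGR or STAR (FAAR and other spellings are
non-permissive); (iv) five or six predicted membrane helices. When more
than two boxes are present, the first N-to-C ordered pair with accepted
spacing is selected; otherwise the first two boxes are reported and the
spacing rule fails with an explicit reason. Helix counts of 4 or 7 are
tolerated with a warning by default because window-based hydropathy
calling is accurate only to about one helix at segment boundaries; a
`strict_tmd` flag makes {5,6} a hard requirement, and `strict_spacing_108`
restricts the spacing set.

**Efflux transporters (Lsi2-like).** A single hard rule: at least nine
predicted membrane helices. The degenerate monocot signature
`XXTKHXWFXXCXXXXRX` is searched and reported but never gates the decision,
since it is absent from several functionally confirmed efflux transporters
and its functional significance is doubtful.

**Siliplant1-like silicification proteins.** A record passes when its
isoelectric point is at least 7 and it carries a cleavable N-terminal
secretion signal. Passing records are graded by compositional
architecture: `ACCUMULATOR` when H/D-rich, P/K/E-rich and P/T/Y-rich
tracts are all present; `MODERATE` when only the P/K/E tract is present
(the essential domain); `LOW` otherwise, including records with H/D or
P/T/Y tracts but no P/K/E tract.

## Physico-chemical quantities

Molecular weight is the sum of average residue masses plus one water
(through Biopython's mass tables, the same convention as the common web
calculators); masked residues (X) make the mass undefined and raise an
error. The isoelectric point solves net charge = 0 by bisection on pH
0–14 with a Henderson–Hasselbalch charge model over the N/C termini and
D, E, C, Y, H, K, R, using one Bjellqvist-style pKa table declared in
`physchem.py`; bisection terminates at |charge| < 1e-4, well inside the
0.01-pH agreement the tests demand of a dense grid search. Positive-charge
density (fraction of K/R/H) is the package's transparent proxy for
silica-precipitation potential: published work attributes precipitation to
the density of positively charged residues rather than to exact sequence,
and the in-silico alanine scan (replace a residue type with A, report the
density before and after) reproduces the direction of the published K→A
ablation. No attempt is made to model interaction energies or
precipitation rates; those require proprietary structure-based tooling and
unpublished parameters.

## Topology heuristics

Membrane helices are maximal runs of Kyte–Doolittle hydropathy, smoothed
with a centered 19-residue window (truncated at the ends), at or above
1.6. Runs separated by fewer than 5 residues are merged before length
filtering — a short dip inside one helix is not two helices — and runs
shorter than 10 residues are then dropped. The merge-then-filter order and
the minimum length of 10 (rather than the classic 15) were calibrated so
that planted 21-residue helices of realistic composition (L/I/V/F/A mixes,
including weak draws dominated by A and F) are recovered exactly, while
400-residue hydrophilic sequences yield zero calls; a 19-window run of 10
still requires roughly 15 consecutive membrane-like residues, so the
effective minimum helix length is conventional. X scores 0 (neutral).

The signal-peptide call is a von-Heijne-style three-rule test, not a
re-implementation of any HMM server: (i) n-region (positions 1–5) with at
least one K/R and non-negative net charge; (ii) an h-region — seven
consecutive residues with mean raw hydropathy ≥ 1.6 starting at or before
position 15; (iii) a cleavage position c ≤ 40, after the h-core, with
small residues (A,G,S,C,T,V) at c and c−2 (the (−3,−1) rule, counting the
cleaved bond after c). The h-core is defined as the *earliest minimal*
qualifying 7-mer so that adding hydrophobicity can only move it earlier:
this makes the present/absent call monotone under hydrophobic
strengthening, a property the tests check. The heuristic deliberately
trades sensitivity on real proteomes for transparency and offline
reproducibility; it is not expected to reproduce any server's exact
accept/reject counts.

## Alignment, filter extraction and divergence

Selectivity-filter residues are read through a *pairwise* global alignment
to a packaged reference profile rather than a multiple alignment: filter
typing only needs a coordinate map onto the four reference positions, and
pairwise Needleman–Wunsch (BLOSUM62, gap open 10, extend 0.5, through
Biopython's `PairwiseAligner`; the first optimal traceback is the
tie-break) is deterministic and dependency-light. A filter position mapped
onto a gap yields `UNDETERMINED` rather than a guess. The packaged
reference is a **synthetic** scaffold (`data/lsi1_reference_synthetic.*`):
298 residues, six helices, two NPA boxes 108 apart, GSGR at positions
60/165/185/191, built deterministically by `siliscan._scaffold`. A real
database sequence would serve the same role and can be swapped in by
replacing the FASTA + JSON sidecar; the four filter positions are data,
never hard-coded in logic.

Divergence is the observed proportion *p* of differing sites over aligned
columns, excluding any column with a gap or an X on either side (pairwise
deletion; whether published estimates used complete or pairwise deletion
is rarely stated, and pairwise deletion wastes no sites), corrected for
multiple hits by the Poisson formula d = −ln(1 − p), undefined at p ≥ 1.

## Compositional domains and repeats

"Rich" tracts are found by seeding on every window (default 10) whose
in-set residue fraction reaches 0.6, merging overlapping or adjacent
seeds, trimming the merged span to in-set edge residues, and shrinking
from the poorer edge until the whole span itself clears the threshold;
spans shorter than 8 are dropped, so every reported domain has enrichment
≥ 0.6 by construction. The literature never quantifies "rich"; these
defaults segment the published cassette architectures cleanly and all live
in `DomainConfig`. Because proline belongs to both the P/K/E and P/T/Y
sets, a sufficiently proline-heavy stretch legitimately reports both
labels; consequently a proline-rich P/K/E tract can occasionally carry a
spurious P/T/Y label, which can demote a borderline `MODERATE` record to
`LOW` (it can never inflate a record to `ACCUMULATOR`, which requires an
H/D tract as well). This is a documented property of windowed set
semantics, not an implementation accident.

Tandem repeats are found by a self-periodicity scan — for each unit length
u, stretches where `seq[i] == seq[i+u]` at density ≥ the identity
threshold — scored against a per-column majority consensus, with
overlapping candidates collapsed to the highest-identity, then longest,
then smallest-unit block; one trailing partial copy is tolerated but not
counted. Defaults: unit 4–30, ≥ 3 copies, identity ≥ 0.9. This is a
presence/unit/copy-number detector, sufficient for the screen; it is not a
gapped repeat aligner and will miss arrays whose copies drift by indels.

## Synthetic data

The generator produces labelled records per screen plus matched
single-defect negatives; each record draws from an RNG stream seeded by
(seed, index), so datasets are byte-reproducible and insertion-order
independent. Channel-type records are point-mutated copies of the
reference scaffold (mutations avoid the planted NPA boxes and filter
residues; spacing edits are split across the two inter-box loops so a
deletion cannot fuse helices). Efflux records plant 9–11 helices
(negatives 6–8) separated by hydrophilic linkers — inter-helix loops are
hydrophilic-biased as real topology is, while soluble-region filler is
uniform over the 20 residues so compositional domains cannot arise by
construction bias. Slp1 records assemble a constructed signal peptide,
2–3 HD→PKE→PTY cassettes (or K/E-weighted P/K/E tracts only, for the
moderate-accumulator variant), a proline/lysine-heavy tandem array, and a
lysine/acid adjustment loop that walks the isoelectric point above 7.3
(positives) or below 6.5 (negatives) — the generator tunes composition the
way the screens assume nature did. Default lengths (channel 280–320,
efflux 450–550, Slp1 200–400) match the real protein scales.

What the generator does **not** emulate: indel evolution, phylogenetic
correlation, database annotation noise, or realistic amino-acid background
frequencies (a Robinson-style background would change false-positive rates
of the compositional detectors). Perfect label recovery on these data
therefore demonstrates that the rules are implemented and composed
correctly under their own assumptions — it is not a sensitivity claim for
real proteomes, where helix prediction and the signal-peptide heuristic
are the weak links.

## Problem sizes and degenerate inputs

The shipped verification runs use 200 records per screen per seed (three
seeds) for label recovery, 1,000 random cases for the degenerate-matcher
oracle, 100 random 12-mer pairs for the alignment-score recursion oracle,
and sequences up to 60 residues for the exhaustive repeat oracle — sizes
chosen so the whole suite completes in well under a minute per component
on one CPU. Degenerate inputs are defined throughout: empty sequences and
unknown letters are rejected at parse time with 1-based positions; X never
matches a literal motif letter but matches pattern wildcards; sequences
shorter than the smoothing window have zero helices; sequences shorter
than 25 residues raise on the signal-peptide call and are reported as
signal-absent by the Slp1 screen; p = 0 gives distance 0 and p ≥ 1 is an
error rather than infinity.
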