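"""Sequence-intrinsic physico-chemical quantities used as screen filters.

Molecular weight uses average (isotope-abundance weighted) residue masses,
matching the convention of the usual proteomics web calculators.  The
isoelectric point solves for the zero of the Henderson-Hasselbalch net
charge under the Bjellqvist pKa set by bisection on pH 0-14.
"""

from __future__ import annotations

from Bio.SeqUtils import molecular_weight as _bio_mw

from .io import CANONICAL

# Bjellqvist / ExPASy-style pKa values.  One table, used by both the charge
# model and (in tests) the grid-search oracle.
PKA_POSITIVE = {
    "Nterm": 7.5,
    "K": 10.0,
    "R": 12.0,
    "H": 5.98,
}
PKA_NEGATIVE = {
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
}

POSITIVE_RESIDUES = frozenset("KRH")


def _check(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")


def molecular_weight(seq: str) -> float:
    """Average molecular mass in daltons, rounded to 2 decimals.

    ``X`` is rejected: the mass of a masked residue is undefined.
    """
    _check(seq)
    if "X" in seq:
        raise ValueError("mass undefined for X")
    return round(_bio_mw(seq, seq_type="protein", monoisotopic=False), 2)


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at ``ph`` (X residues are neutral)."""
    _check(seq)
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["Cterm"] - ph))
    for residue in seq:
        if residue in ("K", "R", "H"):
            charge += 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE[residue]))
        elif residue in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[residue] - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    net_charge is strictly decreasing in pH (every term is), so bisection
    converges to the unique root; |charge| < ``tol`` at the returned pH.
    """
    _check(seq)
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        charge = net_charge(seq, mid)
        if abs(charge) < tol:
            break
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return mid


def aa_frequencies(seq: str) -> dict[str, float]:
    """Residue fractions over sequence length.

    All 20 canonical residues are present as keys (zero allowed); an ``X``
    key appears only when masked residues occur.  Values sum to 1.
    """
    _check(seq)
    n = len(seq)
    freqs = {residue: 0.0 for residue in CANONICAL}
    for residue in seq:
        freqs[residue] = freqs.get(residue, 0.0) + 1.0
    return {residue: count / n for residue, count in freqs.items()}


def positive_charge_density(seq: str) -> float:
    """Fraction of residues that are K, R or H."""
    _check(seq)
    return sum(residue in POSITIVE_RESIDUES for residue in seq) / len(seq)


def alanine_scan(seq: str, target: str) -> tuple[str, float, float]:
    """Replace every ``target`` residue with alanine.

    Returns (mutant, positive-charge density before, density after).  When
    the target is itself positively charged the density can only drop, which
    is the in-silico analogue of charge-ablation scans on silica-precipitating
    peptides.
    """
    _check(seq)
    if len(target) != 1 or target not in CANONICAL:
        raise ValueError(f"target must be one canonical residue, got {target!r}")
    mutant = seq.replace(target, "A")
    return mutant, positive_charge_density(seq), positive_charge_density(mutant)
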