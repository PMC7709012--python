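"""Synthetic channel-type reference scaffold.

A constructed ~300-residue protein with the hallmark layout of a rice-type
influx silicon transporter (a NIP-III aquaporin): six membrane-spanning
hydrophobic helices, two NPA boxes with 108 residues strictly between them,
and a GSGR aromatic/arginine selectivity filter at four mapped positions.
It is *synthetic* — deterministic, built from fixed residue pools — and
serves as (a) the packaged reference profile for selectivity-filter
coordinate mapping and (b) the template the data generator mutates.

The loop pool deliberately excludes proline so the only N-P-[A/V]
tripeptides in the scaffold are the two planted boxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Residue pools (membrane helices vs. solvent-exposed loops).  Loops are
# hydrophilic-biased, as real inter-helix loops are; no P (see module doc),
# and no N to keep planted NPA boxes unique even at pool boundaries.
TMD_POOL = list("LIVFA")
TMD_WEIGHTS = [0.30, 0.25, 0.25, 0.10, 0.10]
LOOP_POOL = list("DEQKRSTGHY")
LOOP_WEIGHTS = [0.12, 0.12, 0.12, 0.14, 0.10, 0.14, 0.10, 0.08, 0.04, 0.04]

SCAFFOLD_SEED = 202011  # fixed: the scaffold is a constant, not a sample


@dataclass(frozen=True)
class Scaffold:
    """The reference sequence plus 1-based feature coordinates."""

    seq: str
    npa1: tuple[int, int]  # inclusive span of the first NPA box
    npa2: tuple[int, int]
    sf_positions: tuple[int, int, int, int]
    tmd_spans: tuple[tuple[int, int], ...]

    @property
    def spacing(self) -> int:
        return self.npa2[0] - self.npa1[1] - 1


# Layout (1-based, length 298): loops / six 21-residue helices / planted
# features.  NPA1 ends at 72 and NPA2 starts at 181 -> 108 between.
_TMD_SPANS = ((10, 30), (46, 66), (80, 100), (116, 136), (151, 171), (195, 215))
_NPA1 = (70, 72)
_NPA2 = (181, 183)
_SF_POSITIONS = (60, 165, 185, 191)
_SF_RESIDUES = "GSGR"
_LENGTH = 298


def sample_tmd(rng: np.random.Generator, length: int = 21, strength: float = 1.0) -> str:
    """A membrane-helix-like stretch; ``strength`` < 1 dilutes hydrophobicity."""
    strong = rng.choice(TMD_POOL, size=length, p=TMD_WEIGHTS)
    if strength >= 1.0:
        return "".join(strong)
    weak = rng.choice(list("AGST"), size=length)
    use_strong = rng.random(length) < strength
    return "".join(s if flag else w for s, w, flag in zip(strong, weak, use_strong))


def sample_loop(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(LOOP_POOL, size=length, p=LOOP_WEIGHTS))


def build_scaffold() -> Scaffold:
    rng = np.random.default_rng(SCAFFOLD_SEED)
    seq = list(sample_loop(rng, _LENGTH))
    for start, end in _TMD_SPANS:
        seq[start - 1 : end] = list(sample_tmd(rng, end - start + 1))
    for (start, end), box in ((_NPA1, "NPA"), (_NPA2, "NPA")):
        seq[start - 1 : end] = list(box)
    for pos, residue in zip(_SF_POSITIONS, _SF_RESIDUES):
        seq[pos - 1] = residue
    seq[0] = "M"
    return Scaffold(
        seq="".join(seq),
        npa1=_NPA1,
        npa2=_NPA2,
        sf_positions=_SF_POSITIONS,
        tmd_spans=_TMD_SPANS,
    )


SCAFFOLD = build_scaffold()
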