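"""Global pairwise alignment, selectivity-filter extraction, divergence.

The aromatic/arginine (ar/R) selectivity filter of an aquaporin is four
pore-lining residues scattered along the chain; the influx silicon
transporters carry GSGR or STAR there.  Rather than a multiple alignment,
each candidate is globally aligned to a packaged reference profile and the
residues mapped onto the four reference positions are read off.

Divergence is the classic Poisson-corrected amino-acid distance
``d = -ln(1 - p)`` with ``p`` the proportion of differing sites over
gap-free (pairwise-deletion) columns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices

from .config import DEFAULT, AlignConfig


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment of ``a`` and ``b`` with a b->a coordinate map.

    ``coordinate_map`` maps 1-based positions of ``b`` to 1-based positions
    of ``a``; positions of ``b`` opposite a gap are absent.
    """

    aligned_a: str
    aligned_b: str
    score: float
    coordinate_map: dict[int, int]


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference sequence plus the four 1-based selectivity-filter positions."""

    ref_id: str
    ref_seq: str
    sf_positions: tuple[int, int, int, int]
    sf_expected: str

    def __post_init__(self) -> None:
        spelled = "".join(self.ref_seq[p - 1] for p in self.sf_positions)
        if spelled != self.sf_expected:
            raise ValueError(
                f"reference {self.ref_id!r}: residues at sf_positions spell "
                f"{spelled!r}, expected {self.sf_expected!r}"
            )


@dataclass(frozen=True)
class SelectivityFilter:
    """Four extracted filter residues and their class."""

    residues: str
    klass: str  # GSGR | STAR | OTHER | UNDETERMINED


@lru_cache(maxsize=4)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(a: str, b: str, config: AlignConfig = DEFAULT.align) -> AlignmentResult:
    """Needleman-Wunsch with BLOSUM62 and affine gaps (defaults 10/0.5).

    The first optimal alignment of the traceback is used, which is a fixed,
    reproducible tie-break.
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    aligner = _aligner(config.matrix, config.gap_open, config.gap_extend)
    alignment = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    coordinate_map: dict[int, int] = {}
    pos_a = pos_b = 0
    for res_a, res_b in zip(aligned_a, aligned_b):
        if res_a != "-":
            pos_a += 1
        if res_b != "-":
            pos_b += 1
            if res_a != "-":
                coordinate_map[pos_b] = pos_a
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        coordinate_map=coordinate_map,
    )


def extract_selectivity_filter(
    seq: str, profile: ReferenceProfile, config: AlignConfig = DEFAULT.align
) -> SelectivityFilter:
    """Read the residues of ``seq`` mapped onto the reference filter positions.

    Any filter position falling in a gap yields class UNDETERMINED.
    """
    result = global_align(seq, profile.ref_seq, config)
    residues = []
    for pos in profile.sf_positions:
        mapped = result.coordinate_map.get(pos)
        if mapped is None:
            return SelectivityFilter(residues="", klass="UNDETERMINED")
        residues.append(seq[mapped - 1])
    spelled = "".join(residues)
    if spelled == "GSGR":
        klass = "GSGR"
    elif spelled == "STAR":
        klass = "STAR"
    else:
        klass = "OTHER"
    return SelectivityFilter(residues=spelled, klass=klass)


def p_distance(a: str, b: str, config: AlignConfig = DEFAULT.align) -> float:
    """Proportion of differing sites under pairwise deletion.

    The two sequences are globally aligned; columns containing a gap or a
    masked residue (X) on either side are excluded from the denominator.
    """
    result = global_align(a, b, config)
    comparable = differing = 0
    for res_a, res_b in zip(result.aligned_a, result.aligned_b):
        if "-" in (res_a, res_b) or "X" in (res_a, res_b):
            continue
        comparable += 1
        differing += res_a != res_b
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns")
    return differing / comparable


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p), substitutions per site."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must be in [0, 1), got {p} (saturated or invalid)")
    return -math.log1p(-p)


def load_reference() -> ReferenceProfile:
    """Load the packaged synthetic channel-type reference profile.

    The profile is a constructed scaffold (see ``siliscan._scaffold``) with
    the hallmark layout of the rice influx transporter: two NPA boxes
    spaced 108 residues apart, GSGR at the four filter positions, and six
    membrane helices.  It is synthetic — built for coordinate mapping and
    calibration, not a database sequence.
    """
    data = resources.files("siliscan") / "data"
    fasta_text = (data / "lsi1_reference_synthetic.fasta").read_text()
    lines = [line.strip() for line in fasta_text.splitlines() if line.strip()]
    ref_id = lines[0].lstrip(">").split()[0]
    ref_seq = "".join(lines[1:])
    sidecar = json.loads((data / "lsi1_reference_synthetic.json").read_text())
    return ReferenceProfile(
        ref_id=ref_id,
        ref_seq=ref_seq,
        sf_positions=tuple(sidecar["sf_positions"]),
        sf_expected=sidecar["sf_expected"],
    )
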