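"""Literal and degenerate motif detection.

Covers the aquaporin NPA boxes (with the tolerated NPV variant), the
degenerate monocot efflux-transporter signature ``XXTKHXWFXXCXXXXRX``, the
Slp1 consensus ``KKPXPXKPKPXPKPXPXPX`` and the literal silica-precipitating
signature ``KEKPVKPPKKHPPP``.  In patterns ``X`` is a wildcard; in subject
sequences ``X`` is a masked residue that matches *only* a pattern wildcard,
never a literal — masked positions must not fabricate matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .config import DEFAULT, ScreenConfig
from .io import ALPHABET

# Patterns shipped with the package (id -> pattern).
DEFAULT_PATTERNS: dict[str, str] = {
    "npa": "NPA",  # find_npa_motifs also accepts the NPV variant
    "lsi2_monocot_signature": "XXTKHXWFXXCXXXXRX",
    "slp1_consensus": "KKPXPXKPKPXPKPXPXPX",
    "slp1_signature": "KEKPVKPPKKHPPP",
}


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, 1-based inclusive coordinates."""

    pattern_id: str
    start: int
    end: int
    matched: str
    variant: bool = False


@dataclass(frozen=True)
class NPAArchitecture:
    """The NPA-box layout of one sequence.

    ``spacing`` counts residues strictly between the two selected boxes
    (last residue of the first to first residue of the second, exclusive),
    the convention under which the canonical rice influx transporter spaces
    its boxes 108 residues apart.
    """

    hits: tuple[MotifHit, ...]
    pair: tuple[MotifHit, MotifHit] | None
    spacing: int | None


def find_npa_motifs(seq: str) -> list[MotifHit]:
    """All N-P-[A/V] tripeptides in N-to-C order (NPV flagged as variant)."""
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] == "P" and seq[i + 2] in "AV":
            hits.append(
                MotifHit(
                    pattern_id="npa",
                    start=i + 1,
                    end=i + 3,
                    matched=seq[i : i + 3],
                    variant=seq[i + 2] == "V",
                )
            )
    return hits


def _spacing(first: MotifHit, second: MotifHit) -> int:
    return second.start - first.end - 1


def npa_architecture(seq: str, config: ScreenConfig = DEFAULT.screen) -> NPAArchitecture:
    """Select the biologically relevant NPA pair and its spacing.

    With exactly two boxes they are the pair.  With more, the first ordered
    pair (N-to-C) whose spacing falls in the accepted set wins; failing
    that, the first two boxes are reported and the classifier will reject
    the spacing with an explicit reason.
    """
    hits = tuple(find_npa_motifs(seq))
    if len(hits) < 2:
        return NPAArchitecture(hits=hits, pair=None, spacing=None)
    if len(hits) == 2:
        pair = (hits[0], hits[1])
        return NPAArchitecture(hits=hits, pair=pair, spacing=_spacing(*pair))
    accepted = set(config.spacing_set)
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            if _spacing(hits[i], hits[j]) in accepted:
                pair = (hits[i], hits[j])
                return NPAArchitecture(hits=hits, pair=pair, spacing=_spacing(*pair))
    pair = (hits[0], hits[1])
    return NPAArchitecture(hits=hits, pair=pair, spacing=_spacing(*pair))


def match_degenerate(seq: str, pattern: str, pattern_id: str | None = None) -> list[MotifHit]:
    """Every window where all non-X pattern positions match literally.

    ``X`` in the pattern matches any subject letter (including subject X);
    a literal pattern letter never matches subject ``X``.
    """
    if not pattern:
        raise ValueError("empty pattern")
    for letter in pattern:
        if letter not in ALPHABET:
            raise ValueError(f"illegal pattern letter {letter!r}")
    pid = pattern_id if pattern_id is not None else pattern
    m = len(pattern)
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        # p == s with p != "X" implies s != "X", so a literal pattern letter
        # can never match a masked subject residue.
        if all(p == "X" or p == s for p, s in zip(pattern, window)):
            hits.append(MotifHit(pattern_id=pid, start=i + 1, end=i + m, matched=window))
    return hits


def load_patterns(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>pattern`` file (one pattern per line, # comments)."""
    patterns: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            pid, pattern = line.split("\t")
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>pattern'") from exc
        patterns[pid.strip()] = pattern.strip()
    return patterns
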