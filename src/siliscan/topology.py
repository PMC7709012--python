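"""Hydropathy-based membrane topology and signal-peptide heuristics.

These are transparent, offline stand-ins for the HMM-based web services
normally used for transmembrane-segment counting and secretion calls:

* membrane segments are maximal runs of Kyte-Doolittle smoothed hydropathy
  at or above a threshold (TopPred-style), merged across short dips and
  length-filtered;
* the signal-peptide call is a von-Heijne-style three-rule test (charged
  n-region, hydrophobic h-region, (-3,-1) small-residue cleavage site).

Both are calibrated on the packaged synthetic reference scaffolds and make
no claim to reproduce any particular web server's output on real proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT, SignalPeptideConfig, TopologyConfig

# Kyte & Doolittle hydropathy; X (masked) is a neutral 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass(frozen=True)
class TMDSegment:
    """One predicted membrane-spanning segment (1-based inclusive)."""

    start: int
    end: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SignalPeptideCall:
    present: bool
    cleavage_pos: int | None
    reasons: tuple[str, ...]


def raw_hydropathy(seq: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE[residue] for residue in seq], dtype=float)


def hydropathy_profile(seq: str, window: int = DEFAULT.topology.window) -> np.ndarray:
    """Centered sliding-window mean of Kyte-Doolittle values.

    Output has one value per residue; near the ends the window is truncated
    to what fits inside the sequence.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > len(seq):
        raise ValueError(f"window {window} longer than sequence ({len(seq)})")
    values = raw_hydropathy(seq)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as 0-based half-open (start, stop)."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def predict_tmds(seq: str, config: TopologyConfig = DEFAULT.topology) -> list[TMDSegment]:
    """Predict membrane-spanning segments from smoothed hydropathy.

    Runs at/above ``config.threshold`` separated by fewer than
    ``config.min_gap`` residues are merged first (a short dip inside one
    helix is not two helices), then runs shorter than ``config.min_tmd_len``
    are discarded.  ``mean_hydropathy`` is the raw (unsmoothed) mean over
    the reported span.
    """
    if len(seq) < config.window:
        return []
    profile = hydropathy_profile(seq, config.window)
    runs = _runs_above(profile >= config.threshold)
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < config.min_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    values = raw_hydropathy(seq)
    segments = [
        TMDSegment(start + 1, stop, float(values[start:stop].mean()))
        for start, stop in merged
        if stop - start >= config.min_tmd_len
    ]
    return segments


def predict_signal_peptide(
    seq: str, config: SignalPeptideConfig = DEFAULT.signal
) -> SignalPeptideCall:
    """Three-rule secretion-signal test on the N-terminus.

    (i)  n-region (positions 1..5): net charge (K/R minus D/E) >= 0 and at
         least one K or R;
    (ii) h-region: a ``h_core_len``-residue stretch with mean raw
         hydropathy >= ``h_threshold`` starting at or before position
         ``h_max_start`` (the earliest such start defines the h-core);
    (iii) cleavage: smallest position c in [h-core end + 1, 40] whose
         residues at c and c-2 are small (A,G,S,C,T,V).

    The h-core is deliberately the *earliest minimal* qualifying stretch, so
    making the neighbourhood more hydrophobic can only move it earlier and
    can never shrink the cleavage search range (a monotonicity the tests
    rely on).
    """
    if len(seq) < 25:
        raise ValueError(f"sequence too short for a signal-peptide call ({len(seq)} < 25)")
    window = seq[: config.search_window]
    reasons: list[str] = []

    n_region = window[: config.n_region_len]
    basic = sum(residue in "KR" for residue in n_region)
    acidic = sum(residue in "DE" for residue in n_region)
    n_ok = basic >= 1 and basic - acidic >= 0
    reasons.append("n-region ok" if n_ok else "n-region lacks net positive charge")

    values = raw_hydropathy(window)
    h_end = None  # 1-based end of the h-core
    core = config.h_core_len
    for start in range(0, min(config.h_max_start, len(window) - core + 1)):
        if values[start : start + core].mean() >= config.h_threshold:
            h_end = start + core
            break
    reasons.append("h-region ok" if h_end else "no h-region")

    cleavage = None
    if h_end is not None:
        for c in range(h_end + 1, min(config.cleavage_max_pos, len(window)) + 1):
            if c - 2 >= 1 and window[c - 1] in config.small_residues and \
                    window[c - 3] in config.small_residues:
                cleavage = c
                break
        reasons.append("cleavage site ok" if cleavage else "no cleavage site")

    present = n_ok and h_end is not None and cleavage is not None
    return SignalPeptideCall(
        present=present,
        cleavage_pos=cleavage if present else None,
        reasons=tuple(reasons),
    )
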