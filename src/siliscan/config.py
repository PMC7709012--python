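"""Tunable constants for every screen, collected in one auditable place.

All thresholds that decide a screen outcome live in these dataclasses so a
run can be reproduced from a plain ``key=value`` config file or CLI flags.
Defaults are calibrated so that the packaged synthetic reference scaffolds
segment into their designed architecture (six membrane helices for the
channel-type reference, 108-residue inter-NPA spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class TopologyConfig:
    """Hydropathy smoothing and segment-calling parameters.

    window:        odd Kyte-Doolittle smoothing window (residues)
    threshold:     smoothed hydropathy at or above which a residue is
                   membrane-like (dimensionless, KD units)
    min_tmd_len:   shortest accepted membrane segment (residues)
    min_gap:       above-threshold runs separated by fewer residues than
                   this are merged before length filtering
    """

    window: int = 19
    threshold: float = 1.6
    min_tmd_len: int = 10
    min_gap: int = 5


@dataclass(frozen=True)
class SignalPeptideConfig:
    """von-Heijne-style signal peptide rules.

    The n-region is positions 1..n_region_len; the h-region is a stretch of
    ``h_core_len`` residues with mean raw hydropathy >= h_threshold starting
    at or before ``h_max_start``; cleavage obeys the (-3,-1) small-residue
    rule at a position no later than ``cleavage_max_pos``.
    """

    n_region_len: int = 5
    h_core_len: int = 7
    h_threshold: float = 1.6
    h_max_start: int = 15
    cleavage_max_pos: int = 40
    search_window: int = 45
    small_residues: str = "AGSCTV"


@dataclass(frozen=True)
class AlignConfig:
    """Global alignment scoring (substitution matrix + affine gaps)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass(frozen=True)
class DomainConfig:
    """Compositional-bias segmentation and tandem-repeat parameters."""

    window: int = 10
    enrichment: float = 0.6
    min_len: int = 8
    repeat_min_unit: int = 4
    repeat_max_unit: int = 30
    repeat_min_copies: int = 3
    repeat_min_identity: float = 0.9


@dataclass(frozen=True)
class ScreenConfig:
    """Decision thresholds for the three screens."""

    # channel-type (Lsi1-like): accepted inter-NPA spacings; TMD band
    spacing_set: tuple[int, ...] = (108, 109)
    strict_spacing_108: bool = False
    tmd_pass_counts: tuple[int, ...] = (5, 6)
    tmd_warn_counts: tuple[int, ...] = (4, 7)
    strict_tmd: bool = False
    # efflux (Lsi2-like)
    lsi2_min_tmds: int = 9
    # Slp1-like
    min_pi: float = 7.0


@dataclass(frozen=True)
class PipelineConfig:
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    signal: SignalPeptideConfig = field(default_factory=SignalPeptideConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    domains: DomainConfig = field(default_factory=DomainConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)


DEFAULT = PipelineConfig()


def _coerce(value: str, target_type: type):
    if target_type is bool:
        return value.strip().lower() in {"1", "true", "yes", "on"}
    if target_type in (int, float):
        return target_type(value)
    if target_type is str:
        return value.strip()
    # tuple of ints, e.g. "108,109"
    return tuple(int(v) for v in value.replace("(", "").replace(")", "").split(","))


def load_config(path: str | Path, base: PipelineConfig = DEFAULT) -> PipelineConfig:
    """Read a plain ``section.key = value`` file and override ``base``.

    Example line: ``topology.window = 19``.  Unknown keys raise ValueError so
    silently misspelt calibration constants cannot slip through.
    """
    sections = {f.name: getattr(base, f.name) for f in fields(base)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line or "." not in line.split("=", 1)[0]:
            raise ValueError(f"{path}:{lineno}: expected 'section.key = value'")
        dotted, value = (part.strip() for part in line.split("=", 1))
        section_name, key = dotted.split(".", 1)
        if section_name not in sections:
            raise ValueError(f"{path}:{lineno}: unknown section {section_name!r}")
        section = sections[section_name]
        matching = {f.name: f.type for f in fields(section)}
        if key not in matching:
            raise ValueError(f"{path}:{lineno}: unknown key {dotted!r}")
        current = getattr(section, key)
        sections[section_name] = replace(section, **{key: _coerce(value, type(current))})
    return PipelineConfig(**sections)
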