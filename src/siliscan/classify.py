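"""The three screening funnels, composed from the analysis modules.

Each screen evaluates *every* rule and reports machine-readable reasons for
each failed criterion (no short-circuiting), so the reason histogram of a
batch explains exactly where candidates fell out of the funnel:

* channel-type (Lsi1-like): two NPA boxes, 108/109 residues between them,
  GSGR or STAR selectivity filter, five or six membrane helices;
* efflux-type (Lsi2-like): at least nine membrane helices; the degenerate
  monocot signature is annotated but not required;
* Slp1-like: isoelectric point >= 7, a cleavable secretion signal; the
  compositional architecture grades the record into accumulator classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Any, Iterable

from .align import ReferenceProfile, SelectivityFilter, extract_selectivity_filter, load_reference
from .config import DEFAULT, PipelineConfig
from .domains import ArchitectureCall, RepeatBlock, domain_architecture, find_tandem_repeats
from .io import ProteinRecord
from .motifs import DEFAULT_PATTERNS, MotifHit, NPAArchitecture, match_degenerate, npa_architecture
from .physchem import isoelectric_point
from .topology import SignalPeptideCall, predict_signal_peptide, predict_tmds

MODES = ("lsi1", "lsi2", "slp1")


def _fmt(value: Any) -> Any:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return f"{value:.4f}"
    return value


@dataclass(frozen=True)
class ChannelSITCall:
    """Channel-type screen outcome for one record."""

    record_id: str
    npa: NPAArchitecture
    sf: SelectivityFilter
    tmd_count: int
    passes: bool
    reasons: tuple[str, ...]
    warnings: tuple[str, ...] = ()

    REPORT_COLUMNS = (
        "id", "n_npa", "npa_positions", "npa_variant", "spacing",
        "sf_residues", "sf_class", "tmd_count", "passes", "reasons",
    )

    def as_row(self) -> dict[str, Any]:
        hits = self.npa.hits
        return {
            "id": self.record_id,
            "n_npa": len(hits),
            "npa_positions": ";".join(f"{h.start}-{h.end}" for h in hits),
            "npa_variant": ";".join(str(h.variant).lower() for h in hits),
            "spacing": _fmt(self.npa.spacing),
            "sf_residues": self.sf.residues,
            "sf_class": self.sf.klass,
            "tmd_count": self.tmd_count,
            "passes": _fmt(self.passes),
            "reasons": ";".join(self.reasons),
        }


@dataclass(frozen=True)
class Lsi2Call:
    """Efflux-type screen outcome for one record."""

    record_id: str
    tmd_count: int
    motif_hits: tuple[MotifHit, ...]
    monocot_signature: bool
    passes: bool
    reasons: tuple[str, ...]

    REPORT_COLUMNS = (
        "id", "tmd_count", "monocot_signature", "signature_positions",
        "passes", "reasons",
    )

    def as_row(self) -> dict[str, Any]:
        return {
            "id": self.record_id,
            "tmd_count": self.tmd_count,
            "monocot_signature": _fmt(self.monocot_signature),
            "signature_positions": ";".join(
                f"{h.start}-{h.end}" for h in self.motif_hits
            ),
            "passes": _fmt(self.passes),
            "reasons": ";".join(self.reasons),
        }


@dataclass(frozen=True)
class Slp1Call:
    """Slp1-like screen outcome plus accumulator-architecture class."""

    record_id: str
    pi: float
    signal: SignalPeptideCall
    repeats: tuple[RepeatBlock, ...]
    architecture: ArchitectureCall
    accumulator_class: str  # ACCUMULATOR | MODERATE | LOW
    passes: bool
    reasons: tuple[str, ...]

    REPORT_COLUMNS = (
        "id", "pi", "signal_present", "cleavage_pos", "n_repeats",
        "repeat_units", "domains", "cassette_count", "g_runs_after_pke",
        "accumulator_class", "passes", "reasons",
    )

    def as_row(self) -> dict[str, Any]:
        return {
            "id": self.record_id,
            "pi": f"{self.pi:.2f}",
            "signal_present": _fmt(self.signal.present),
            "cleavage_pos": _fmt(self.signal.cleavage_pos),
            "n_repeats": len(self.repeats),
            "repeat_units": ";".join(
                f"{b.unit}x{b.copies}@{b.start}-{b.end}" for b in self.repeats
            ),
            "domains": ";".join(
                f"{d.label}@{d.start}-{d.end}" for d in self.architecture.domains
            ),
            "cassette_count": self.architecture.cassette_count,
            "g_runs_after_pke": self.architecture.g_runs_after_pke,
            "accumulator_class": self.accumulator_class,
            "passes": _fmt(self.passes),
            "reasons": ";".join(self.reasons),
        }


def screen_channel_sit(
    record: ProteinRecord,
    profile: ReferenceProfile | None = None,
    config: PipelineConfig = DEFAULT,
) -> ChannelSITCall:
    """Apply the channel-type rules: NPA pair, spacing, filter, helix count."""
    profile = profile if profile is not None else load_reference()
    npa = npa_architecture(record.seq, config.screen)
    sf = extract_selectivity_filter(record.seq, profile, config.align)
    tmds = predict_tmds(record.seq, config.topology)
    reasons: list[str] = []
    warnings: list[str] = []

    if len(npa.hits) < 2:
        reasons.append(f"npa: two NPA motifs required, found {len(npa.hits)}")
    accepted = (108,) if config.screen.strict_spacing_108 else config.screen.spacing_set
    if npa.spacing is None or npa.spacing not in accepted:
        reasons.append(f"spacing: {npa.spacing} not in {sorted(accepted)}")
    if sf.klass not in ("GSGR", "STAR"):
        reasons.append(f"selectivity_filter: {sf.residues or 'unmapped'} not GSGR/STAR")
    count = len(tmds)
    if count in config.screen.tmd_pass_counts:
        pass
    elif not config.screen.strict_tmd and count in config.screen.tmd_warn_counts:
        warnings.append(f"tmd count {count} outside {config.screen.tmd_pass_counts} (tolerated)")
    else:
        reasons.append(f"tmd_count: {count} not in {config.screen.tmd_pass_counts}")

    return ChannelSITCall(
        record_id=record.id,
        npa=npa,
        sf=sf,
        tmd_count=count,
        passes=not reasons,
        reasons=tuple(reasons),
        warnings=tuple(warnings),
    )


def screen_lsi2(
    record: ProteinRecord, config: PipelineConfig = DEFAULT
) -> Lsi2Call:
    """Apply the efflux-type rule (>= 9 helices); annotate the signature."""
    tmds = predict_tmds(record.seq, config.topology)
    hits = tuple(
        match_degenerate(
            record.seq,
            DEFAULT_PATTERNS["lsi2_monocot_signature"],
            pattern_id="lsi2_monocot_signature",
        )
    )
    reasons = []
    if len(tmds) < config.screen.lsi2_min_tmds:
        reasons.append(
            f"tmd_count: {len(tmds)} below minimum {config.screen.lsi2_min_tmds}"
        )
    return Lsi2Call(
        record_id=record.id,
        tmd_count=len(tmds),
        motif_hits=hits,
        monocot_signature=bool(hits),
        passes=not reasons,
        reasons=tuple(reasons),
    )


def _accumulator_class(architecture: ArchitectureCall) -> str:
    present = set(architecture.labels)
    if {"HD", "PKE", "PTY"} <= present:
        return "ACCUMULATOR"
    if "PKE" in present and "HD" not in present and "PTY" not in present:
        return "MODERATE"
    return "LOW"


def screen_slp1(
    record: ProteinRecord, config: PipelineConfig = DEFAULT
) -> Slp1Call:
    """Apply the Slp1 rules (pI, secretion signal) and grade the architecture."""
    pi = isoelectric_point(record.seq)
    try:
        signal = predict_signal_peptide(record.seq, config.signal)
    except ValueError:
        signal = SignalPeptideCall(False, None, ("sequence too short",))
    repeats = tuple(
        find_tandem_repeats(
            record.seq,
            min_unit=config.domains.repeat_min_unit,
            max_unit=config.domains.repeat_max_unit,
            min_copies=config.domains.repeat_min_copies,
            min_identity=config.domains.repeat_min_identity,
        )
    )
    architecture = domain_architecture(record.seq, config.domains)
    reasons = []
    if pi < config.screen.min_pi:
        reasons.append(f"pi: {pi:.2f} < {config.screen.min_pi:g}")
    if not signal.present:
        reasons.append("signal_peptide: absent (" + "; ".join(signal.reasons) + ")")
    return Slp1Call(
        record_id=record.id,
        pi=pi,
        signal=signal,
        repeats=repeats,
        architecture=architecture,
        accumulator_class=_accumulator_class(architecture),
        passes=not reasons,
        reasons=tuple(reasons),
    )


def batch_screen(
    records: Iterable[ProteinRecord],
    mode: str,
    config: PipelineConfig = DEFAULT,
    profile: ReferenceProfile | None = None,
) -> tuple[list, dict[str, Any]]:
    """Screen every record (order preserved) and summarise.

    Returns (calls, summary) with summary = input/passed/failed counts and
    a histogram of failure reasons (first clause of each reason).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "lsi1" and profile is None:
        profile = load_reference()
    calls = []
    for record in records:
        if mode == "lsi1":
            calls.append(screen_channel_sit(record, profile, config))
        elif mode == "lsi2":
            calls.append(screen_lsi2(record, config))
        else:
            calls.append(screen_slp1(record, config))
    passed = sum(call.passes for call in calls)
    histogram: Counter[str] = Counter()
    for call in calls:
        for reason in call.reasons:
            histogram[reason.split(":", 1)[0]] += 1
    summary = {
        "mode": mode,
        "input": len(calls),
        "passed": passed,
        "failed": len(calls) - passed,
        "failed_by_reason": dict(sorted(histogram.items())),
    }
    return calls, summary
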