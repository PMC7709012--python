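"""Compositional-bias domain segmentation and tandem-repeat discovery.

Siliplant-like silicification proteins carry a hallmark architecture of
histidine/aspartate-rich, proline/lysine/glutamate-rich and
proline/threonine/tyrosine-rich tracts arranged in repeated cassettes.
"Rich" is operationalised as windows whose in-set residue fraction reaches
a threshold, merged and trimmed to in-set edges.  Repeats are found by a
self-periodicity scan (does position i match position i+u?), which is all
the screens need: presence/absence, unit, and copy number.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

from .config import DEFAULT, DomainConfig

# The three hallmark residue sets, in cassette order.
RESIDUE_SETS: dict[str, frozenset[str]] = {
    "HD": frozenset("HD"),
    "PKE": frozenset("PKE"),
    "PTY": frozenset("PTY"),
}
CASSETTE_ORDER = ("HD", "PKE", "PTY")


@dataclass(frozen=True)
class CompositionalDomain:
    """A residue-set-enriched span, 1-based inclusive."""

    residue_set: frozenset[str]
    start: int
    end: int
    enrichment: float
    label: str = ""

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RepeatBlock:
    """A tandem array: consensus unit, copy count, span, mean copy identity."""

    unit: str
    copies: int
    start: int
    end: int
    identity: float


@dataclass(frozen=True)
class ArchitectureCall:
    """Ordered compositional domains plus cassette and G-run annotations."""

    domains: tuple[CompositionalDomain, ...]
    labels: tuple[str, ...]
    cassette_count: int  # HD -> PKE -> PTY ordered triples
    g_runs_after_pke: int  # report-only annotation: GG+ runs downstream of a PKE tract


def find_rich_domains(
    seq: str,
    residue_set: frozenset[str] | set[str] | str,
    window: int = DEFAULT.domains.window,
    threshold: float = DEFAULT.domains.enrichment,
    min_len: int = DEFAULT.domains.min_len,
) -> list[CompositionalDomain]:
    """Maximal spans enriched for ``residue_set``.

    Windows with in-set fraction >= ``threshold`` seed domains; overlapping
    or adjacent seed windows are merged; merged spans are trimmed so both
    edges are in-set residues, then greedily shrunk from the poorer edge
    until the whole span satisfies the enrichment threshold.  Spans shorter
    than ``min_len`` are dropped.  Reported enrichment is recomputed on the
    final span, so it is always >= ``threshold``.
    """
    residue_set = frozenset(residue_set)
    if not residue_set:
        raise ValueError("empty residue set")
    if window < 5:
        raise ValueError(f"window must be >= 5, got {window}")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    n = len(seq)
    if n < window:
        return []
    in_set = [residue in residue_set for residue in seq]
    prefix = [0]
    for flag in in_set:
        prefix.append(prefix[-1] + flag)

    def frac(i: int, j: int) -> float:  # 0-based half-open
        return (prefix[j] - prefix[i]) / (j - i)

    # seed windows, merged on the fly (overlap or adjacency)
    spans: list[list[int]] = []
    for i in range(n - window + 1):
        if frac(i, i + window) >= threshold:
            if spans and i <= spans[-1][1]:
                spans[-1][1] = i + window
            else:
                spans.append([i, i + window])

    domains = []
    for lo, hi in spans:
        # trim to in-set edges
        while lo < hi and not in_set[lo]:
            lo += 1
        while hi > lo and not in_set[hi - 1]:
            hi -= 1
        # shrink from the poorer edge until the span itself is enriched
        while hi - lo >= min_len and frac(lo, hi) < threshold:
            left_gain = frac(lo + 1, hi) if hi - lo > 1 else 0.0
            right_gain = frac(lo, hi - 1) if hi - lo > 1 else 0.0
            if left_gain >= right_gain:
                lo += 1
            else:
                hi -= 1
            while lo < hi and not in_set[lo]:
                lo += 1
            while hi > lo and not in_set[hi - 1]:
                hi -= 1
        if hi - lo >= min_len and frac(lo, hi) >= threshold:
            domains.append(
                CompositionalDomain(
                    residue_set=residue_set,
                    start=lo + 1,
                    end=hi,
                    enrichment=frac(lo, hi),
                )
            )
    return domains


def _consensus(copies: list[str]) -> str:
    out = []
    for column in zip(*copies):
        out.append(Counter(column).most_common(1)[0][0])
    return "".join(out)


def _identity(copies: list[str], unit: str) -> float:
    per_copy = [
        sum(a == b for a, b in zip(copy, unit)) / len(unit) for copy in copies
    ]
    return sum(per_copy) / len(per_copy)


def find_tandem_repeats(
    seq: str,
    min_unit: int = DEFAULT.domains.repeat_min_unit,
    max_unit: int = DEFAULT.domains.repeat_max_unit,
    min_copies: int = DEFAULT.domains.repeat_min_copies,
    min_identity: float = DEFAULT.domains.repeat_min_identity,
) -> list[RepeatBlock]:
    """Tandem arrays by self-periodicity.

    For each unit length u, positions where ``seq[i] == seq[i+u]`` are
    periodicity matches; maximal stretches whose match density stays at or
    above ``min_identity`` delimit candidate arrays.  Candidates are scored
    by a per-column majority consensus; overlapping candidates of different
    u collapse to the highest-identity, then longest, then smallest-unit
    block.  A trailing partial copy is allowed but not counted.
    """
    if min_unit < 4:
        raise ValueError(f"min_unit must be >= 4, got {min_unit}")
    if max_unit > 50:
        raise ValueError(f"max_unit must be <= 50, got {max_unit}")
    n = len(seq)
    candidates: list[RepeatBlock] = []
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        match = [seq[i] == seq[i + u] for i in range(n - u)]
        i = 0
        while i < len(match):
            if not match[i]:
                i += 1
                continue
            # greedily extend while the running match density holds up
            j = i
            good = 0
            best_j = i
            total = 0
            k = i
            while k < len(match):
                total += 1
                good += match[k]
                if good / total >= min_identity:
                    best_j = k
                elif good / total < min_identity * 0.8:
                    break
                k += 1
            j = best_j
            run_len = j - i + 1
            span_len = run_len + u
            copies = span_len // u
            if copies >= min_copies:
                copy_strings = [
                    seq[i + c * u : i + (c + 1) * u] for c in range(copies)
                ]
                unit = _consensus(copy_strings)
                identity = _identity(copy_strings, unit)
                if identity >= min_identity:
                    candidates.append(
                        RepeatBlock(
                            unit=unit,
                            copies=copies,
                            start=i + 1,
                            end=i + span_len,
                            identity=identity,
                        )
                    )
            i = j + 1
    # collapse overlaps: best identity, then longest span, then smallest unit
    candidates.sort(
        key=lambda b: (-b.identity, -(b.end - b.start + 1), len(b.unit), b.start)
    )
    kept: list[RepeatBlock] = []
    for block in candidates:
        if all(block.end < other.start or block.start > other.end for other in kept):
            kept.append(block)
    kept.sort(key=lambda b: b.start)
    return kept


def domain_architecture(
    seq: str, config: DomainConfig = DEFAULT.domains
) -> ArchitectureCall:
    """All three hallmark domain types, in sequence order, plus cassette count.

    Domains of different residue sets may overlap (P is shared between the
    PKE and PTY sets).  The cassette count is the number of disjoint
    HD -> PKE -> PTY triples found by a left-to-right greedy scan on domain
    start positions.  G-runs (>= 2 consecutive G) downstream of the last
    PKE tract are counted as a report-only annotation.
    """
    domains: list[CompositionalDomain] = []
    for label in CASSETTE_ORDER:
        for dom in find_rich_domains(
            seq,
            RESIDUE_SETS[label],
            window=config.window,
            threshold=config.enrichment,
            min_len=config.min_len,
        ):
            domains.append(
                CompositionalDomain(
                    residue_set=dom.residue_set,
                    start=dom.start,
                    end=dom.end,
                    enrichment=dom.enrichment,
                    label=label,
                )
            )
    domains.sort(key=lambda d: (d.start, d.end))
    labels = tuple(d.label for d in domains)

    cassette_count = 0
    want = 0  # index into CASSETTE_ORDER
    last_start = -1
    for dom in domains:
        if dom.label == CASSETTE_ORDER[want] and dom.start > last_start:
            last_start = dom.start
            want += 1
            if want == len(CASSETTE_ORDER):
                cassette_count += 1
                want = 0
    g_runs = 0
    pke_domains = [d for d in domains if d.label == "PKE"]
    if pke_domains:
        tail_start = max(d.end for d in pke_domains)  # 1-based end
        tail = seq[tail_start:]
        run = 0
        for residue in tail + "$":
            if residue == "G":
                run += 1
            else:
                if run >= 2:
                    g_runs += 1
                run = 0
    return ArchitectureCall(
        domains=tuple(domains),
        labels=labels,
        cassette_count=cassette_count,
        g_runs_after_pke=g_runs,
    )
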