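"""Seeded generator of labelled positive/negative proteins for every screen.

The generator emulates the statistical structure the screens assume — not
evolution.  Channel-type records are point-mutated copies of the packaged
reference scaffold with the selectivity filter, NPA spacing and helix count
under explicit control; efflux-type records plant 9-11 (or, for negatives,
6-8) hydrophobic helices; Slp1-like records assemble a secretion signal,
H/D- P/K/E- P/T/Y-rich cassettes and a tandem-repeat array on a uniform
background, with the lysine load adjusted until the isoelectric point
clears (positives) or stays below (negatives) the screening cut of 7.

Every record draws from its own RNG stream seeded by (seed, index), so
output is byte-reproducible and independent of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from ._scaffold import SCAFFOLD, sample_loop, sample_tmd
from .io import CANONICAL, ProteinRecord, write_fasta
from .physchem import isoelectric_point

MODES = ("lsi1", "lsi2", "slp1", "negative")
SCREENS = ("lsi1", "lsi2", "slp1")

# default target length ranges per scaffold family (residues)
LENGTH_RANGES = {"lsi1": (280, 320), "lsi2": (450, 550), "slp1": (200, 400)}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one batch of synthetic records.

    mode:            lsi1 | lsi2 | slp1 for positives, or "negative"
    screen:          which screen a "negative" batch is a negative for
                     (ignored for positive modes)
    n:               number of records
    seed:            RNG seed; records use streams (seed, index)
    length_range:    target length band (residues); per-mode default if None
    mutation_rate:   per-site substitution probability applied outside the
                     protected planted features (0 <= rate < 0.5)
    tmd_strength:    1.0 = full-contrast hydrophobic helices; lower values
                     dilute them with small/polar residues
    domain_enrichment: probability a cassette-tract residue is drawn from
                     its defining set rather than background
    repeat_copies:   copies in the planted tandem array (slp1)
    """

    mode: str
    n: int = 1
    seed: int = 0
    screen: str | None = None
    length_range: tuple[int, int] | None = None
    mutation_rate: float = 0.0
    tmd_strength: float = 1.0
    domain_enrichment: float = 0.95
    repeat_copies: int = 5

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "negative" and self.screen not in SCREENS:
            raise ValueError("negative specs need screen in " + str(SCREENS))
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.mutation_rate < 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5)")

    @property
    def target_screen(self) -> str:
        return self.screen if self.mode == "negative" else self.mode

    @property
    def positive(self) -> bool:
        return self.mode != "negative"


def _rng_for(spec: SyntheticSpec, index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, index])


def _mutate(
    seq: list[str],
    rate: float,
    protected: set[int],
    rng: np.random.Generator,
) -> None:
    """Point-substitute unprotected 0-based positions in place."""
    if rate <= 0:
        return
    letters = list(CANONICAL)
    for i in range(len(seq)):
        if i in protected:
            continue
        if rng.random() < rate:
            seq[i] = letters[rng.integers(len(letters))]


# --- channel-type (Lsi1-like) --------------------------------------------

_LSI1_DEFECTS = ("spacing", "sf", "single_npa", "tmd")


def make_channel_sit(
    spec: SyntheticSpec, index: int = 0
) -> tuple[ProteinRecord, dict[str, Any]]:
    """One channel-type record built on the reference scaffold.

    Positives plant a GSGR or STAR filter, spacing from the accepted
    {108, 109} set and 5-6 helices; negatives carry exactly one defect
    (off spacing, FAAR-like filter, a single NPA box, or too few helices).
    """
    rng = _rng_for(spec, index)
    scaffold = SCAFFOLD
    seq = list(scaffold.seq)
    sf_positions = list(scaffold.sf_positions)
    npa1, npa2 = list(scaffold.npa1), list(scaffold.npa2)
    tmd_spans = [list(s) for s in scaffold.tmd_spans]

    meta: dict[str, Any] = {"screen": "lsi1", "label": "positive" if spec.positive else "negative"}

    defect = None
    if spec.positive:
        sf = "GSGR" if rng.random() < 0.8 else "STAR"
        spacing = 108 if rng.random() < 0.9 else 109
        n_tmds = 6 if rng.random() < 0.8 else 5
    else:
        defect = _LSI1_DEFECTS[rng.integers(len(_LSI1_DEFECTS))]
        sf = "FAAR" if defect == "sf" else "GSGR"
        spacing = int(rng.choice([100, 116])) if defect == "spacing" else 108
        n_tmds = 3 if defect == "tmd" else 6
    meta.update(sf=sf, spacing=spacing, n_tmds=n_tmds, defect=defect)

    if n_tmds < 6:
        # ablate leading helices (before NPA1: no coordinate shifts)
        for span in tmd_spans[: 6 - n_tmds]:
            start, end = span
            seq[start - 1 : end] = list(sample_loop(rng, end - start + 1))
        tmd_spans = tmd_spans[6 - n_tmds :]

    if defect == "single_npa":
        seq[npa2[0] - 1 : npa2[1]] = list(sample_loop(rng, 3))
        npa2 = None

    # adjust spacing by inserting/deleting loop residues between the boxes;
    # edits are split across the two inter-NPA loops (around 105 and 140)
    # so a deletion never shortens one loop enough to fuse two helices
    delta = spacing - scaffold.spacing
    if delta and npa2 is not None:
        first = delta // 2
        for at, d in ((140, delta - first), (105, first)):  # right edit first
            if d == 0:
                continue
            if d > 0:
                seq[at - 1 : at - 1] = list(sample_loop(rng, d))
            else:
                del seq[at - 1 : at - 1 - d]
            shift = lambda p, at=at, d=d: p + d if p >= at else p  # noqa: E731
            sf_positions = [shift(p) for p in sf_positions]
            npa2 = [shift(p) for p in npa2]
            tmd_spans = [[shift(a), shift(b)] for a, b in tmd_spans]

    for pos, residue in zip(sf_positions, sf):
        seq[pos - 1] = residue

    protected = {p - 1 for p in sf_positions}
    protected.update(range(npa1[0] - 1, npa1[1]))
    if npa2 is not None:
        protected.update(range(npa2[0] - 1, npa2[1]))
    _mutate(seq, spec.mutation_rate, protected, rng)

    lo, hi = spec.length_range or LENGTH_RANGES["lsi1"]
    tail = int(rng.integers(0, max(hi - len(seq), 0) + 1))
    seq.extend(sample_loop(rng, tail))

    record = ProteinRecord(
        id=f"lsi1_{meta['label']}_{spec.seed}_{index:04d}",
        seq="".join(seq),
        description="synthetic channel-type scaffold",
    )
    meta["sf_positions"] = tuple(sf_positions)
    return record, meta


# --- efflux-type (Lsi2-like) ---------------------------------------------

# a realisation of the degenerate monocot signature XXTKHXWFXXCXXXXRX with
# hydrophilic fill so it cannot fake a membrane helix
MONOCOT_SIGNATURE = "DETKHSWFENCDQKSRT"


def make_lsi2(
    spec: SyntheticSpec, index: int = 0
) -> tuple[ProteinRecord, dict[str, Any]]:
    """One efflux-type record: k planted helices (9-11 pos / 6-8 neg).

    Half of the positives carry the monocot signature in the loop
    immediately before the sixth helix, mirroring its placement in the
    rice efflux transporters.
    """
    rng = _rng_for(spec, index)
    k = int(rng.integers(9, 12)) if spec.positive else int(rng.integers(6, 9))
    with_signature = bool(spec.positive and k >= 6 and rng.random() < 0.5)

    parts: list[str] = [sample_loop(rng, int(rng.integers(18, 28)))]
    protected_spans: list[tuple[int, int]] = []  # 0-based half-open
    length = len(parts[0])
    for t in range(k):
        if with_signature and t == 5:  # loop right before the 6th helix
            insert_at = length - 8
            loop = parts[-1]
            offset = len(loop) - 8
            parts[-1] = loop[:offset] + MONOCOT_SIGNATURE + loop[offset:]
            protected_spans.append((insert_at, insert_at + len(MONOCOT_SIGNATURE)))
            length += len(MONOCOT_SIGNATURE)
        helix = sample_tmd(rng, 21, strength=spec.tmd_strength)
        parts.append(helix)
        length += 21
        linker = sample_loop(rng, int(rng.integers(26, 34)))
        parts.append(linker)
        length += len(linker)

    lo, hi = spec.length_range or LENGTH_RANGES["lsi2"]
    if length < hi:
        parts.append(sample_loop(rng, int(rng.integers(0, hi - length + 1))))
    seq = list("".join(parts))
    seq[0] = "M"

    protected = set()
    for a, b in protected_spans:
        protected.update(range(a, b))
    _mutate(seq, spec.mutation_rate, protected, rng)

    label = "positive" if spec.positive else "negative"
    record = ProteinRecord(
        id=f"lsi2_{label}_{spec.seed}_{index:04d}",
        seq="".join(seq),
        description="synthetic efflux-type scaffold",
    )
    meta = {
        "screen": "lsi2",
        "label": label,
        "n_tmds": k,
        "signature": with_signature,
        "defect": None if spec.positive else "too_few_tmds",
    }
    return record, meta


# --- Slp1-like ------------------------------------------------------------

_SLP1_DEFECTS = ("acidic", "no_signal", "no_cleavage")

_SIGNAL = "MKRNQ" + "LLIFLILFIL" + "QASA"  # n-region / h-region / (-3,-1) site


def _tract(rng: np.random.Generator, pool: str, weights, length: int, enrichment: float) -> str:
    """A residue_set-enriched tract: in-set with prob ``enrichment``."""
    out = []
    pool = list(pool)
    for _ in range(length):
        if rng.random() < enrichment:
            out.append(pool[rng.choice(len(pool), p=weights)] if weights is not None
                       else pool[rng.integers(len(pool))])
        else:
            out.append(CANONICAL[rng.integers(20)])
    return "".join(out)


def _background(rng: np.random.Generator, length: int) -> str:
    return "".join(CANONICAL[i] for i in rng.integers(0, 20, size=length))


def make_slp1(
    spec: SyntheticSpec, index: int = 0
) -> tuple[ProteinRecord, dict[str, Any]]:
    """One Slp1-like record.

    Positives: secretion signal + 2-3 HD->PKE->PTY cassettes + a KPP-style
    tandem array, lysine-adjusted to pI >= 7 (class ACCUMULATOR), or a
    P,K,E-only moderate-accumulator variant without HD/PTY tracts and
    without the proline-heavy array (class MODERATE).  Negatives fail
    exactly one screening rule: acidified below pI 7, no hydrophobic
    h-region, or no (-3,-1) cleavage site.
    """
    rng = _rng_for(spec, index)
    label = "positive" if spec.positive else "negative"
    expected_class = None
    defect = None

    if spec.positive:
        moderate = rng.random() < 0.25
        expected_class = "MODERATE" if moderate else "ACCUMULATOR"
        signal = _SIGNAL
    else:
        defect = _SLP1_DEFECTS[rng.integers(len(_SLP1_DEFECTS))]
        moderate = False
        if defect == "no_signal":
            # poly-acidic N-terminus: no h-region can form
            signal = "M" + "".join(rng.choice(list("DE"), size=18))
        elif defect == "no_cleavage":
            # intact n/h-regions but no small residue up to position 40
            signal = "MKRNQ" + "LLIFLILFIL"
        else:
            signal = _SIGNAL

    parts = [signal]
    if defect == "no_cleavage":
        parts.append("".join(rng.choice(list("KRDEQNHY"), size=30)))

    e = spec.domain_enrichment
    n_cassettes = int(rng.integers(2, 4))
    for _ in range(n_cassettes):
        if not moderate:
            parts.append(_tract(rng, "HD", None, int(rng.integers(10, 15)), e))
            parts.append(_background(rng, 4))
            parts.append(_tract(rng, "PKE", [0.40, 0.35, 0.25], int(rng.integers(12, 17)), e))
            parts.append(_background(rng, 4))
            parts.append(_tract(rng, "PTY", [0.40, 0.30, 0.30], int(rng.integers(10, 15)), e))
        else:
            # moderate accumulators: P,K,E tract only, low proline so the
            # shared P cannot mimic a P,T,Y tract
            parts.append(_tract(rng, "PKE", [0.15, 0.50, 0.35], int(rng.integers(12, 17)), e))
        parts.append(_background(rng, int(rng.integers(4, 9))))

    repeat_meta = 0
    if not moderate:
        unit_len = int(rng.integers(20, 25))
        unit = _tract(rng, "PKVYTE", [0.42, 0.20, 0.12, 0.12, 0.07, 0.07], unit_len, 1.0)
        parts.append(unit * spec.repeat_copies)
        repeat_meta = spec.repeat_copies

    lo, hi = spec.length_range or LENGTH_RANGES["slp1"]
    body = "".join(parts)
    if len(body) < lo:
        parts.append(_background(rng, lo - len(body)))
    seq = list("".join(parts))

    protected = set(range(len(signal)))
    _mutate(seq, spec.mutation_rate, protected, rng)

    # tune the charge balance: positives must clear the pI >= 7 screen with
    # margin, acidified negatives must stay clearly below it
    mutable = [i for i in range(len(signal) + 1, len(seq))]
    rng.shuffle(mutable)
    cursor = 0
    if defect == "acidic":
        while isoelectric_point("".join(seq)) >= 6.5 and cursor < len(mutable):
            i = mutable[cursor]
            cursor += 1
            if seq[i] in "KRH":
                seq[i] = "DE"[int(rng.integers(2))]
        meta_pi = isoelectric_point("".join(seq))
    else:
        while isoelectric_point("".join(seq)) < 7.3 and cursor < len(mutable):
            i = mutable[cursor]
            cursor += 1
            if seq[i] not in "KR":
                seq[i] = "K"
        meta_pi = isoelectric_point("".join(seq))

    record = ProteinRecord(
        id=f"slp1_{label}_{spec.seed}_{index:04d}",
        seq="".join(seq),
        description="synthetic siliplant-like scaffold",
    )
    meta = {
        "screen": "slp1",
        "label": label,
        "defect": defect,
        "expected_class": expected_class,
        "n_cassettes": 0 if moderate else n_cassettes,
        "repeat_copies": repeat_meta,
        "pi": round(meta_pi, 2),
    }
    return record, meta


# --- batch assembly -------------------------------------------------------

_MAKERS = {"lsi1": make_channel_sit, "lsi2": make_lsi2, "slp1": make_slp1}


def make_batch(spec: SyntheticSpec) -> tuple[list[ProteinRecord], list[dict[str, Any]]]:
    maker = _MAKERS[spec.target_screen]
    records, metas = [], []
    for index in range(spec.n):
        record, meta = maker(spec, index)
        records.append(record)
        metas.append(meta)
    return records, metas


LABEL_COLUMNS = [
    "id", "screen", "label", "defect", "expected_class",
    "sf", "spacing", "n_tmds", "signature", "n_cassettes", "repeat_copies", "pi",
]


def generate_dataset(
    specs: list[SyntheticSpec],
    fasta_path: str | Path,
    labels_path: str | Path | None = None,
    shuffle: bool = False,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Concatenate batches, write FASTA plus an id-keyed labels TSV."""
    records: list[ProteinRecord] = []
    rows: list[dict[str, Any]] = []
    for spec in specs:
        batch_records, batch_metas = make_batch(spec)
        for record, meta in zip(batch_records, batch_metas):
            rows.append({"id": record.id, **meta})
        records.extend(batch_records)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"record id collision: {dupes[:3]}")
    if shuffle:
        order = np.random.default_rng([specs[0].seed, 987654321]).permutation(len(records))
        records = [records[i] for i in order]
        rows = [rows[i] for i in order]
    fasta_path = Path(fasta_path)
    write_fasta(records, fasta_path)
    labels = pd.DataFrame(rows).reindex(columns=LABEL_COLUMNS)
    if labels_path is None:
        labels_path = fasta_path.with_suffix(".labels.tsv")
    labels.to_csv(labels_path, sep="\t", index=False)
    return records, labels


def spec_to_json(spec: SyntheticSpec) -> dict[str, Any]:
    return dataclasses.asdict(spec)


def spec_from_json(payload: dict[str, Any]) -> SyntheticSpec:
    if payload.get("length_range") is not None:
        payload = {**payload, "length_range": tuple(payload["length_range"])}
    return SyntheticSpec(**payload)
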