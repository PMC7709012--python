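"""Compositional-bias segmentation and tandem-repeat discovery."""

from collections import Counter

import pytest

from conftest import random_peptide
from siliscan.domains import (
    domain_architecture,
    find_rich_domains,
    find_tandem_repeats,
)

SLP1_UNIT = "KPPIYKPPVYTPPVYKPPVEKPP"  # the printed soybean-homolog repeat unit


class TestRichDomains:
    def test_planted_hd_tract(self):
        domains = find_rich_domains(
            "AAAAHDHDHDHDAAAA", "HD", window=8, threshold=0.6, min_len=6
        )
        assert len(domains) == 1
        dom = domains[0]
        assert (dom.start, dom.end) == (5, 12)
        assert dom.enrichment == 1.0

    def test_uniform_sequence_has_none(self):
        assert find_rich_domains("A" * 50, "HD") == []

    def test_signature_peptide_is_pke_rich(self):
        domains = find_rich_domains(
            "KEKPVKPPKKHPPP", "PKE", window=8, threshold=0.6, min_len=6
        )
        assert len(domains) == 1
        dom = domains[0]
        # 12 of 14 residues are P/K/E; the tract spans essentially the whole
        # peptide (edges trimmed to in-set residues)
        assert dom.start == 1 and dom.end >= 10

    def test_enrichment_never_below_threshold(self, rng):
        for _ in range(50):
            seq = random_peptide(rng, 120, alphabet="HDAKPE")
            for dom in find_rich_domains(seq, "HD"):
                assert dom.enrichment >= 0.6
                assert len(dom) >= 8
                assert seq[dom.start - 1] in "HD" and seq[dom.end - 1] in "HD"

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            find_rich_domains("A" * 20, "")
        with pytest.raises(ValueError):
            find_rich_domains("A" * 20, "HD", window=3)
        with pytest.raises(ValueError):
            find_rich_domains("A" * 20, "HD", threshold=0.0)


def oracle_repeats(seq, min_unit=4, max_unit=30, min_copies=3, min_identity=0.9):
    """Exhaustive all-substrings oracle: every (start, unit, copies) array."""
    found = []
    for u in range(min_unit, min(max_unit, len(seq) // min_copies) + 1):
        for start in range(len(seq) - u * min_copies + 1):
            for copies in range(min_copies, (len(seq) - start) // u + 1):
                blocks = [seq[start + c * u : start + (c + 1) * u] for c in range(copies)]
                consensus = "".join(
                    Counter(col).most_common(1)[0][0] for col in zip(*blocks)
                )
                identity = sum(
                    sum(x == y for x, y in zip(blk, consensus)) / u for blk in blocks
                ) / copies
                if identity >= min_identity:
                    found.append((start + 1, u, copies, identity))
    return found


class TestTandemRepeats:
    def test_printed_unit_times_eight(self):
        blocks = find_tandem_repeats(SLP1_UNIT * 8)
        assert len(blocks) == 1
        block = blocks[0]
        assert block.copies == 8
        assert block.unit == SLP1_UNIT
        assert (block.start, block.end) == (1, 8 * len(SLP1_UNIT))
        assert block.identity == 1.0

    def test_short_unit_filtered(self):
        # a 2-mer period is below min_unit; the 4-mer harmonic has only 2
        # copies of the 8-residue span, below min_copies
        assert find_tandem_repeats("ARARARAR") == []

    def test_random_sequence_typically_clean(self, rng):
        seq = random_peptide(rng, 200)
        assert find_tandem_repeats(seq, min_unit=8, min_copies=3, min_identity=0.9) == []

    def test_detector_blocks_are_confirmed_by_oracle(self, rng):
        # every reported block corresponds to an array the exhaustive oracle
        # also finds at the same unit length and at least as many copies
        for _ in range(30):
            seq = random_peptide(rng, int(rng.integers(20, 61)), alphabet="KPVY")
            for block in find_tandem_repeats(seq):
                matches = [
                    (s, u, c)
                    for (s, u, c, _i) in oracle_repeats(seq)
                    if u == len(block.unit) and abs(s - block.start) < u
                ]
                assert matches, (seq, block)

    def test_perfect_planted_arrays_always_found(self, rng):
        # generator sweep: a perfect array planted in random background is
        # recovered with the exact copy number for 50 seeds
        for seed in range(50):
            import numpy as np

            srng = np.random.default_rng(seed)
            u = int(srng.integers(4, 13))
            copies = int(srng.integers(3, 7))
            unit = random_peptide(srng, u)
            # background avoids accidental extension of the planted array
            left = random_peptide(srng, int(srng.integers(0, 15)), alphabet="GHW")
            right = random_peptide(srng, int(srng.integers(0, 15)), alphabet="GHW")
            seq = left + unit * copies + right
            blocks = find_tandem_repeats(seq)
            matching = [b for b in blocks if b.copies >= copies]
            assert matching, (seed, seq)

    def test_oracle_confirms_absence(self, rng):
        for _ in range(20):
            seq = random_peptide(rng, int(rng.integers(20, 61)))
            if not oracle_repeats(seq):
                assert find_tandem_repeats(seq) == []

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("A" * 30, min_unit=3)
        with pytest.raises(ValueError):
            find_tandem_repeats("A" * 30, max_unit=60)


HD = "HDHDHDHDHDHD"
PKE = "KPEKPEKPEKPEKE"
PTY = "PTYPTYPTYPTY"
SPACER = "WGWG"


class TestArchitecture:
    def cassette(self, n):
        return "MW" + (HD + SPACER + PKE + SPACER + PTY + SPACER) * n + "WW"

    def test_two_cassettes_counted(self):
        arch = domain_architecture(self.cassette(2))
        assert arch.cassette_count == 2
        assert set(arch.labels) == {"HD", "PKE", "PTY"}

    def test_single_pke_tract(self):
        arch = domain_architecture("W" * 10 + PKE + "W" * 10)
        assert set(arch.labels) == {"PKE"}
        assert arch.cassette_count == 0

    def test_domains_sorted_by_start(self):
        arch = domain_architecture(self.cassette(3))
        starts = [d.start for d in arch.domains]
        assert starts == sorted(starts)

    def test_g_runs_annotated_downstream_of_pke(self):
        arch = domain_architecture("W" * 10 + PKE + "WGGW" + "GGG" + "WW")
        assert arch.g_runs_after_pke == 2
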