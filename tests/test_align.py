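"""Global alignment, selectivity-filter mapping, Poisson divergence."""

import math
from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from conftest import random_peptide
from siliscan.align import (
    extract_selectivity_filter,
    global_align,
    p_distance,
    poisson_distance,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 10.0, 0.5


def nw_affine_score(a, b):
    """Un-optimized affine-gap global alignment recursion (the oracle).

    Gap of length L costs GAP_OPEN + (L-1) * GAP_EXTEND, matching the
    production scorer's convention.
    """
    neg = float("-inf")

    @lru_cache(maxsize=None)
    def score(i, j, state):
        # best score of aligning a[:i] / b[:j] where the last alignment
        # column was: 0 = substitution, 1 = gap in b (consumed a[i]),
        # 2 = gap in a (consumed b[j])
        if i == 0 and j == 0:
            return 0.0 if state == 0 else neg
        if state == 0:
            if i == 0 or j == 0:
                return neg
            prev = max(score(i - 1, j - 1, s) for s in (0, 1, 2))
            return prev + BLOSUM62[a[i - 1], b[j - 1]]
        if state == 1:
            if i == 0:
                return neg
            return max(
                score(i - 1, j, 0) - GAP_OPEN,
                score(i - 1, j, 1) - GAP_EXTEND,
                score(i - 1, j, 2) - GAP_OPEN,
            )
        if j == 0:
            return neg
        return max(
            score(i, j - 1, 0) - GAP_OPEN,
            score(i, j - 1, 2) - GAP_EXTEND,
            score(i, j - 1, 1) - GAP_OPEN,
        )

    return max(score(len(a), len(b), s) for s in (0, 1, 2))


class TestGlobalAlign:
    def test_identity_score_is_diagonal_sum(self):
        result = global_align("MKV", "MKV")
        expected = sum(BLOSUM62[c, c] for c in "MKV")
        assert result.score == expected
        assert "-" not in result.aligned_a + result.aligned_b
        assert result.coordinate_map == {1: 1, 2: 2, 3: 3}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("A", "")

    def test_score_symmetry(self, rng):
        for _ in range(10):
            a = random_peptide(rng, 20)
            b = random_peptide(rng, 25)
            assert global_align(a, b).score == global_align(b, a).score

    def test_alignment_degaps_to_inputs(self, rng):
        a, b = random_peptide(rng, 30), random_peptide(rng, 24)
        result = global_align(a, b)
        assert result.aligned_a.replace("-", "") == a
        assert result.aligned_b.replace("-", "") == b
        assert len(result.aligned_a) == len(result.aligned_b)

    def test_score_matches_recursion_oracle_on_100_random_pairs(self, rng):
        for _ in range(100):
            a = random_peptide(rng, 12)
            b = random_peptide(rng, 12)
            assert global_align(a, b).score == pytest.approx(nw_affine_score(a, b))


class TestSelectivityFilter:
    def test_reference_maps_to_itself(self, profile):
        sf = extract_selectivity_filter(profile.ref_seq, profile)
        assert sf.residues == "GSGR" and sf.klass == "GSGR"

    def test_star_mutant(self, profile):
        seq = list(profile.ref_seq)
        for pos, res in zip(profile.sf_positions, "STAR"):
            seq[pos - 1] = res
        sf = extract_selectivity_filter("".join(seq), profile)
        assert sf.klass == "STAR"

    def test_faar_like_mutant_is_other(self, profile):
        seq = list(profile.ref_seq)
        for pos, res in zip(profile.sf_positions, "FAAR"):
            seq[pos - 1] = res
        assert extract_selectivity_filter("".join(seq), profile).klass == "OTHER"

    def test_deletion_over_filter_position_is_undetermined(self, profile):
        pos = profile.sf_positions[0]
        seq = profile.ref_seq[: pos - 6] + profile.ref_seq[pos + 5 :]
        assert extract_selectivity_filter(seq, profile).klass == "UNDETERMINED"

    def test_recovery_under_background_divergence(self, profile, rng):
        # point-mutate 10% of non-filter positions; mapping must still read
        # the planted residues (alignment is collinear without indels)
        for _ in range(20):
            seq = list(profile.ref_seq)
            protected = set(profile.sf_positions)
            for i in range(len(seq)):
                if (i + 1) not in protected and rng.random() < 0.10:
                    seq[i] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            assert extract_selectivity_filter("".join(seq), profile).klass == "GSGR"


class TestDistances:
    def test_p_distance_cases(self):
        assert p_distance("AAAA", "AAAA") == 0.0
        assert p_distance("AAAA", "AAAT") == 0.25

    def test_gap_columns_excluded(self):
        # the shorter sequence aligns with terminal gaps; only gap-free
        # columns are compared
        assert p_distance("MKVLKVAE", "MKVLKV") == 0.0

    def test_poisson_closed_form_and_monotonicity(self):
        assert poisson_distance(0.0) == 0.0
        assert poisson_distance(0.1) == pytest.approx(0.10536, abs=1e-5)
        grid = np.linspace(0.0, 0.95, 50)
        values = [poisson_distance(p) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(d >= p for p, d in zip(grid, values))

    def test_poisson_rejects_saturation(self):
        with pytest.raises(ValueError):
            poisson_distance(1.0)
        with pytest.raises(ValueError):
            poisson_distance(-0.1)
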