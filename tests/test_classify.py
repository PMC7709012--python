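"""Screen logic: constructed positives/negatives, reasons, batch summaries."""

import dataclasses

import pytest

from siliscan.classify import batch_screen, screen_channel_sit, screen_lsi2, screen_slp1
from siliscan.config import DEFAULT, ScreenConfig
from siliscan.io import ProteinRecord
from siliscan.synthetic import SyntheticSpec, make_batch, make_channel_sit, make_lsi2, make_slp1


def record(seq, rid="r1"):
    return ProteinRecord(id=rid, seq=seq)


class TestChannelScreen:
    def positive(self, index=0):
        rec, meta = make_channel_sit(SyntheticSpec(mode="lsi1", seed=5), index)
        return rec, meta

    def test_canonical_positive_passes(self, profile):
        rec, meta = self.positive()
        call = screen_channel_sit(rec, profile)
        assert call.passes and call.reasons == ()
        assert call.sf.klass == meta["sf"]
        assert call.npa.spacing == meta["spacing"]

    def test_wrong_spacing_fails_with_reason(self, profile):
        rec, _ = self.positive()
        # insert two residues between the boxes: spacing 108 -> 110
        npa2 = rec.seq.index("NPA", 100)
        seq = rec.seq[: npa2 - 30] + "GS" + rec.seq[npa2 - 30 :]
        call = screen_channel_sit(record(seq), profile)
        assert not call.passes
        assert any(r.startswith("spacing") for r in call.reasons)

    def test_faar_filter_fails_with_reason(self, profile):
        rec, meta = self.positive()
        seq = list(rec.seq)
        for pos, res in zip(meta["sf_positions"], "FAAR"):
            seq[pos - 1] = res
        call = screen_channel_sit(record("".join(seq)), profile)
        assert not call.passes
        assert any(r.startswith("selectivity_filter") for r in call.reasons)

    def test_reasons_never_short_circuit(self, profile):
        # a soluble lysine-rich protein fails every channel rule at once
        call = screen_channel_sit(record("MK" + "KDESTGQR" * 40), profile)
        assert not call.passes
        codes = {r.split(":")[0] for r in call.reasons}
        assert {"npa", "spacing", "selectivity_filter", "tmd_count"} <= codes

    def test_strict_spacing_flag(self, profile):
        config = dataclasses.replace(
            DEFAULT, screen=ScreenConfig(strict_spacing_108=True)
        )
        for index in range(30):
            rec, meta = self.positive(index)
            call = screen_channel_sit(rec, profile, config)
            assert call.passes == (meta["spacing"] == 108)


class TestLsi2Screen:
    def test_planted_counts_decide(self):
        pos, pmeta = make_lsi2(SyntheticSpec(mode="lsi2", seed=5), 0)
        neg, nmeta = make_lsi2(SyntheticSpec(mode="negative", screen="lsi2", seed=5), 0)
        assert screen_lsi2(pos).passes
        call = screen_lsi2(neg)
        assert not call.passes and call.reasons[0].startswith("tmd_count")

    def test_signature_annotated_independently(self):
        for index in range(10):
            rec, meta = make_lsi2(SyntheticSpec(mode="lsi2", seed=7), index)
            call = screen_lsi2(rec)
            assert call.passes
            assert call.monocot_signature == meta["signature"]


class TestSlp1Screen:
    def test_accumulator_positive(self):
        for index in range(10):
            rec, meta = make_slp1(SyntheticSpec(mode="slp1", seed=3), index)
            call = screen_slp1(rec)
            assert call.passes
            assert call.pi >= 7.0
            assert call.signal.present and call.signal.cleavage_pos is not None
            if meta["expected_class"] == "ACCUMULATOR":
                assert call.accumulator_class == "ACCUMULATOR"

    def test_constructed_moderate_lacks_hd_and_pty(self):
        seq = (
            "MKRNQ" + "LLIFLILFIL" + "QASA"
            + ("W" * 8 + "KPEKKEKPEKKEKE") * 3 + "W" * 8
        )
        call = screen_slp1(record(seq))
        assert call.accumulator_class == "MODERATE"

    def test_acidic_negative_fails_on_pi(self):
        rec, meta = None, None
        spec = SyntheticSpec(mode="negative", screen="slp1", seed=11)
        for index in range(30):
            rec, meta = make_slp1(spec, index)
            call = screen_slp1(rec)
            assert call.passes is False
            if meta["defect"] == "acidic":
                assert any(r.startswith("pi") for r in call.reasons)
            else:
                assert any(r.startswith("signal_peptide") for r in call.reasons)


class TestBatchScreen:
    def test_conservation_and_summary(self, profile):
        pos, _ = make_batch(SyntheticSpec(mode="lsi1", n=10, seed=1))
        neg, _ = make_batch(SyntheticSpec(mode="negative", screen="lsi1", n=10, seed=2))
        calls, summary = batch_screen(pos + neg, "lsi1", profile=profile)
        assert len(calls) == 20
        assert summary["passed"] == 10
        assert summary["passed"] + summary["failed"] == summary["input"]
        assert sum(summary["failed_by_reason"].values()) >= summary["failed"]

    def test_empty_input(self):
        calls, summary = batch_screen([], "lsi2")
        assert calls == [] and summary["input"] == 0 and summary["passed"] == 0

    def test_reasons_empty_iff_passes(self, profile):
        records = (
            make_batch(SyntheticSpec(mode="slp1", n=5, seed=4))[0]
            + make_batch(SyntheticSpec(mode="negative", screen="slp1", n=5, seed=5))[0]
        )
        calls, _ = batch_screen(records, "slp1")
        for call in calls:
            assert (call.reasons == ()) == call.passes

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            batch_screen([], "lsi9")
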