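"""Consequence calling and the pathogenicity decision cascade."""

import itertools

import numpy as np
import pytest

from panelburden.classify import (
    Consequence,
    ConsequenceKind,
    PTV_KINDS,
    Reason,
    call_consequence,
    classify_variant,
    in_last_coding_exon,
    is_rare,
    leans_pathogenic,
)
from panelburden.data_io import (
    ClassificationRecord,
    Significance,
    TranscriptModel,
    VariantKey,
    normalize_variant,
)
from panelburden.simulate import (
    EXON_LEN,
    genomic_base,
    genomic_pos_of_cds_offset,
)
from oracles import oracle_consequence

KEY = VariantKey("chr1", 100, "A", "T")


class TestIsRare:
    def test_boundary_inclusive(self):
        assert is_rare(KEY, {KEY: 0.01})

    def test_common_variant(self):
        assert not is_rare(KEY, {KEY: 0.05})

    def test_absent_means_rare(self):
        assert is_rare(KEY, {})


def snv_at(tx, cds_offset, alt_cds_base):
    pos0 = genomic_pos_of_cds_offset(tx, cds_offset)
    ref = genomic_base(tx, pos0)
    alt = alt_cds_base if tx.strand == "+" else _rc(alt_cds_base)
    return normalize_variant(tx.chrom, pos0 + 1, ref, alt)


def _rc(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def deletion_at(tx, cds_offset, n_deleted):
    """Delete n CDS bases starting at cds_offset (all inside one exon),
    VCF-anchored on the preceding base."""
    positions = sorted(
        genomic_pos_of_cds_offset(tx, cds_offset + i) for i in range(n_deleted)
    )
    anchor = positions[0] - 1
    ref = "".join(genomic_base(tx, p) for p in [anchor] + positions)
    return normalize_variant(tx.chrom, anchor + 1, ref, ref[0])


class TestCallConsequence:
    def test_planted_stop_codon_snv(self, plus_tx):
        # codon 10 is TAC; C->A makes TAA
        key = snv_at(plus_tx, 10 * 3 + 2, "A")
        cons = call_consequence(key, plus_tx)
        assert cons.kind is ConsequenceKind.stop_gained
        assert cons.cds_position == 10 * 3 + 3
        assert cons.exon_index == 1

    def test_two_bp_deletion_is_frameshift(self, plus_tx):
        cons = call_consequence(deletion_at(plus_tx, 120, 2), plus_tx)
        assert cons.kind is ConsequenceKind.frameshift
        assert cons.exon_index == 2

    def test_three_bp_deletion_is_inframe(self, plus_tx):
        cons = call_consequence(deletion_at(plus_tx, 120, 3), plus_tx)
        assert cons.kind is ConsequenceKind.inframe_indel

    def test_intronic_splice_window(self, plus_tx):
        # two bases after exon 1's genomic end: canonical donor
        exon1_end = sorted(plus_tx.cds_exons)[0][1]
        for offset in (0, 1):
            key = VariantKey(plus_tx.chrom, exon1_end + offset + 1, "A", "G")
            cons = call_consequence(key, plus_tx)
            assert cons.kind is ConsequenceKind.canonical_splice
        # three bases in: plain intron
        deep = VariantKey(plus_tx.chrom, exon1_end + 3, "A", "G")
        assert call_consequence(deep, plus_tx).kind is ConsequenceKind.other

    def test_outside_transcript_is_other_not_error(self, plus_tx):
        far = VariantKey(plus_tx.chrom, 5, "A", "G")
        assert call_consequence(far, plus_tx).kind is ConsequenceKind.other

    @pytest.mark.parametrize("tx_fixture", ["plus_tx", "minus_tx"])
    def test_matches_full_translation_oracle(self, tx_fixture, request, rng):
        """>= 500 random SNVs/indels against the rebuild-and-translate oracle."""
        tx = request.getfixturevalue(tx_fixture)
        n_checked = 0
        while n_checked < 500:
            kind = rng.integers(0, 4)
            if kind == 0:  # random SNV in CDS
                off = int(rng.integers(0, 3 * EXON_LEN))
                pos0 = genomic_pos_of_cds_offset(tx, off)
                ref = genomic_base(tx, pos0)
                alt = "ACGT"[int(rng.integers(0, 4))]
                if alt == ref:
                    continue
                key = normalize_variant(tx.chrom, pos0 + 1, ref, alt)
            elif kind == 1:  # deletion of 1-5 bases within one exon
                n_del = int(rng.integers(1, 6))
                off = int(rng.integers(2, 3 * EXON_LEN - n_del - 1))
                # the VCF anchor base must sit in the same exon: it precedes
                # the deleted span genomically, which is CDS offset off-1 on
                # the plus strand but off+n_del on the minus strand
                needed = (
                    range(off - 1, off + n_del)
                    if tx.strand == "+"
                    else range(off, off + n_del + 1)
                )
                if len({o // EXON_LEN for o in needed}) > 1:
                    continue
                key = deletion_at(tx, off, n_del)
            elif kind == 2:  # insertion of 1-4 bases after a CDS base
                off = int(rng.integers(1, 3 * EXON_LEN - 1))
                pos0 = genomic_pos_of_cds_offset(tx, off)
                anchor = genomic_base(tx, pos0)
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(1, 5))))
                key = normalize_variant(tx.chrom, pos0 + 1, anchor, anchor + ins)
            else:  # random position in or around the gene (introns, flanks)
                span = sorted(p for s, e in tx.cds_exons for p in (s, e))
                pos0 = int(rng.integers(span[0] - 30, span[-1] + 30))
                key = VariantKey(tx.chrom, pos0 + 1, "A", "G")
            got = call_consequence(key, tx).kind.value
            assert got == oracle_consequence(tx, key), f"{key} on {tx.strand} strand"
            n_checked += 1


class TestLastCodingExon:
    def test_exon_indices(self, plus_tx):
        last = Consequence(ConsequenceKind.frameshift, cds_position=250, exon_index=3)
        first = Consequence(ConsequenceKind.frameshift, cds_position=10, exon_index=1)
        assert in_last_coding_exon(last, plus_tx)
        assert not in_last_coding_exon(first, plus_tx)

    @pytest.mark.parametrize("tx_fixture", ["plus_tx", "minus_tx"])
    def test_final_intron_splice_assigned_downstream_last_exon(self, tx_fixture, request):
        """A canonical splice variant in the final intron belongs to the
        downstream (= last) coding exon, hand-checked on the toy layout."""
        tx = request.getfixturevalue(tx_fixture)
        exons_genomic = sorted(tx.cds_exons)
        if tx.strand == "+":
            # acceptor of the last exon: 2 bases before its genomic start
            pos0 = exons_genomic[2][0] - 1
        else:
            # transcription runs right-to-left: the final intron is the
            # genomically-left gap; donor sits just left of exon 2's start
            pos0 = exons_genomic[1][0] - 1
        key = VariantKey(tx.chrom, pos0 + 1, "A", "G")
        cons = call_consequence(key, tx)
        assert cons.kind is ConsequenceKind.canonical_splice
        assert cons.exon_index == 3
        assert in_last_coding_exon(cons, tx)

    def test_first_intron_splice_not_last_exon(self, plus_tx):
        exon1_end = sorted(plus_tx.cds_exons)[0][1]
        cons = call_consequence(
            VariantKey(plus_tx.chrom, exon1_end + 1, "A", "G"), plus_tx
        )
        assert cons.kind is ConsequenceKind.canonical_splice
        assert cons.exon_index == 2
        assert not in_last_coding_exon(cons, plus_tx)


def expected_reason(kind: ConsequenceKind, sig: Significance, last_exon: bool,
                    rare: bool, plp: int, blb: int) -> Reason:
    """Independently hand-specified truth table for the decision cascade."""
    is_ptv = kind in (
        ConsequenceKind.stop_gained,
        ConsequenceKind.frameshift,
        ConsequenceKind.canonical_splice,
    )
    if not rare:
        return Reason.not_rare
    if sig in (Significance.Pathogenic, Significance.LikelyPathogenic):
        return Reason.clinvar_plp
    if sig in (Significance.Benign, Significance.LikelyBenign):
        return Reason.clinvar_benign
    if is_ptv and sig is Significance.Conflicting and plp >= 1 and plp > blb:
        return Reason.conflicting_ptv
    if is_ptv and sig is Significance.Absent:
        return Reason.last_exon_ptv_excluded if last_exon else Reason.novel_ptv
    return Reason.non_truncating_unclassified


PATHOGENIC = {Reason.clinvar_plp, Reason.conflicting_ptv, Reason.novel_ptv}


class TestDecisionCascade:
    def _record(self, sig, plp, blb):
        if sig is Significance.Absent:
            return None
        return ClassificationRecord(KEY, sig, plp, blb)

    def test_exhaustive_enumeration(self):
        """Every consequence x significance x exon x rarity x submission
        combination maps to exactly the hand-specified reason."""
        submissions = [(0, 0), (1, 0), (2, 1), (1, 1), (0, 3)]
        n = 0
        for kind, sig, last_exon, rare, (plp, blb) in itertools.product(
            ConsequenceKind, Significance, (False, True), (False, True), submissions
        ):
            if sig is Significance.Absent and (plp or blb):
                continue
            cons = Consequence(kind, cds_position=1, exon_index=1)
            call = classify_variant(
                KEY, "GENE", cons, self._record(sig, plp, blb), rare, last_exon
            )
            want = expected_reason(kind, sig, last_exon, rare, plp, blb)
            assert call.reason is want, (kind, sig, last_exon, rare, plp, blb)
            assert call.pathogenic == (want in PATHOGENIC)
            n += 1
        assert n > 500  # the cascade really was enumerated

    def test_chek2_1100delc_like_conflicting_ptv(self):
        record = ClassificationRecord(KEY, Significance.Conflicting, 5, 1)
        call = classify_variant(
            KEY, "CHEK2", Consequence(ConsequenceKind.frameshift, 1, 1), record, True
        )
        assert call.pathogenic and call.reason is Reason.conflicting_ptv

    def test_novel_last_exon_frameshift_excluded(self):
        call = classify_variant(
            KEY, "BRCA2", Consequence(ConsequenceKind.frameshift, 250, 3),
            None, rare=True, last_coding_exon=True,
        )
        assert not call.pathogenic
        assert call.reason is Reason.last_exon_ptv_excluded

    def test_likely_pathogenic_missense(self):
        record = ClassificationRecord(KEY, Significance.LikelyPathogenic, 2, 0)
        call = classify_variant(
            KEY, "ATM", Consequence(ConsequenceKind.missense, 10, 1), record, True
        )
        assert call.pathogenic and call.reason is Reason.clinvar_plp

    def test_plp_overrides_last_exon_exclusion(self):
        record = ClassificationRecord(KEY, Significance.Pathogenic, 4, 0)
        call = classify_variant(
            KEY, "TP53", Consequence(ConsequenceKind.stop_gained, 280, 3),
            record, rare=True, last_coding_exon=True,
        )
        assert call.pathogenic and call.reason is Reason.clinvar_plp

    def test_benign_vetoes_ptv(self):
        record = ClassificationRecord(KEY, Significance.Benign, 0, 4)
        call = classify_variant(
            KEY, "ATM", Consequence(ConsequenceKind.stop_gained, 10, 1), record, True
        )
        assert not call.pathogenic and call.reason is Reason.clinvar_benign

    def test_monotone_in_evidence(self):
        """Upgrading Absent -> Pathogenic never flips pathogenic to not."""
        for kind, last_exon in itertools.product(ConsequenceKind, (False, True)):
            cons = Consequence(kind, 1, 1)
            before = classify_variant(KEY, "G", cons, None, True, last_exon)
            record = ClassificationRecord(KEY, Significance.Pathogenic, 1, 0)
            after = classify_variant(KEY, "G", cons, record, True, last_exon)
            assert after.pathogenic >= before.pathogenic

    def test_leans_pathogenic_rule(self):
        rec = lambda p, b: ClassificationRecord(KEY, Significance.Conflicting, p, b)
        assert leans_pathogenic(rec(1, 0))
        assert not leans_pathogenic(rec(0, 0))
        assert not leans_pathogenic(rec(2, 2))
        assert leans_pathogenic(rec(3, 2))
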