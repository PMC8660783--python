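"""Rarity filtering, consequence calling on transcript models, and the
rule-based pathogenicity decision cascade.

A variant is called *pathogenic* when it is rare (reference-population
MAF <= 0.01, with unobserved variants counted as rare) and either

* annotated Pathogenic / Likely Pathogenic in the ClinVar-style table, or
* a predicted protein-truncating variant (PTV: stop-gained, frameshift or
  canonical splice-site) with a "Conflicting" annotation whose submissions
  lean towards pathogenicity, or
* a PTV absent from the table, unless it falls in the last coding exon
  (where truncation is assumed to escape nonsense-mediated decay).

Benign / Likely Benign annotations veto pathogenicity even for PTVs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from Bio.Seq import Seq

from .data_io import (
    ClassificationRecord,
    Significance,
    TranscriptModel,
    VariantKey,
)

SPLICE_WINDOW = 2  # intronic bases on each side of a coding-exon boundary


class ConsequenceKind(str, Enum):
    stop_gained = "stop_gained"
    frameshift = "frameshift"
    canonical_splice = "canonical_splice"
    missense = "missense"
    synonymous = "synonymous"
    inframe_indel = "inframe_indel"
    other = "other"


PTV_KINDS = frozenset(
    {ConsequenceKind.stop_gained, ConsequenceKind.frameshift, ConsequenceKind.canonical_splice}
)


@dataclass(frozen=True)
class Consequence:
    kind: ConsequenceKind
    cds_position: int | None = None  # 1-based offset of first affected coding base
    exon_index: int | None = None  # 1-based, in transcription order

    @property
    def is_ptv(self) -> bool:
        return self.kind in PTV_KINDS


class Reason(str, Enum):
    clinvar_plp = "clinvar_plp"
    conflicting_ptv = "conflicting_ptv"
    novel_ptv = "novel_ptv"
    last_exon_ptv_excluded = "last_exon_ptv_excluded"
    clinvar_benign = "clinvar_benign"
    not_rare = "not_rare"
    non_truncating_unclassified = "non_truncating_unclassified"


PATHOGENIC_REASONS = frozenset({Reason.clinvar_plp, Reason.conflicting_ptv, Reason.novel_ptv})


@dataclass(frozen=True)
class PathogenicityCall:
    key: VariantKey
    gene: str
    pathogenic: bool
    reason: Reason
    is_ptv: bool

    def __post_init__(self) -> None:
        assert self.pathogenic == (self.reason in PATHOGENIC_REASONS)


def is_rare(
    key: VariantKey, freq_table: Mapping[VariantKey, float], maf_max: float = 0.01
) -> bool:
    """True iff the variant is absent from the reference frequency table or
    its MAF is <= ``maf_max`` (inclusive).  Absence means the variant was not
    observed in the reference population, hence below any rarity threshold.
    """
    maf = freq_table.get(key)
    return maf is None or maf <= maf_max


# ---------------------------------------------------------------------------
# Consequence calling
# ---------------------------------------------------------------------------

def _cds_offset(transcript: TranscriptModel, pos0: int) -> int | None:
    """0-based offset into the spliced CDS of genomic 0-based ``pos0``, or
    None if the position is not coding."""
    offset = 0
    for start, end in transcript.cds_exons:
        if start <= pos0 < end:
            if transcript.strand == "+":
                return offset + (pos0 - start)
            return offset + (end - 1 - pos0)
        offset += end - start
    return None


def _splice_exon_index(transcript: TranscriptModel, pos0: int) -> int | None:
    """If ``pos0`` lies within the canonical +/-2 intronic window of an
    internal coding-exon junction, return the 1-based transcription-order
    index of the *downstream* exon (the exon whose splicing the variant
    disrupts next in reading order); else None."""
    exons = transcript.cds_exons
    for i in range(len(exons) - 1):
        (s1, e1), (s2, e2) = exons[i], exons[i + 1]
        if transcript.strand == "+":
            donor = range(e1, e1 + SPLICE_WINDOW)
            acceptor = range(s2 - SPLICE_WINDOW, s2)
        else:
            donor = range(s1 - SPLICE_WINDOW, s1)
            acceptor = range(e2, e2 + SPLICE_WINDOW)
        if pos0 in donor or pos0 in acceptor:
            return i + 2  # downstream exon, 1-based
    return None


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def call_consequence(key: VariantKey, transcript: TranscriptModel) -> Consequence:
    """Predict the coding consequence of a normalised variant on one
    transcript.

    SNVs inside the CDS are classified by translating the affected codon
    (strand-aware); indels inside the CDS are frameshift when the length
    difference is not a multiple of three, in-frame otherwise.  Intronic
    positions within +/-2 bases of an internal coding-exon junction are
    canonical splice variants, attributed to the downstream exon.  Anything
    else is ``other`` — never an exception.
    """
    ref_span = range(key.pos - 1, key.pos - 1 + len(key.ref))
    offsets = [
        (p, off) for p in ref_span if (off := _cds_offset(transcript, p)) is not None
    ]
    if offsets:
        # first affected coding base in transcript reading order
        first_off = min(off for _, off in offsets)
        cds_pos = first_off + 1
        exon_idx = _exon_index_of_offset(transcript, first_off)
        if len(key.ref) == len(key.alt):
            return _substitution_consequence(key, transcript, first_off, cds_pos, exon_idx)
        if (len(key.ref) - len(key.alt)) % 3 != 0:
            return Consequence(ConsequenceKind.frameshift, cds_pos, exon_idx)
        return Consequence(ConsequenceKind.inframe_indel, cds_pos, exon_idx)
    splice_hits = [
        idx for p in ref_span if (idx := _splice_exon_index(transcript, p)) is not None
    ]
    if splice_hits:
        exon_idx = min(splice_hits)
        cds_pos = _offset_of_exon_start(transcript, exon_idx) + 1
        return Consequence(ConsequenceKind.canonical_splice, cds_pos, exon_idx)
    return Consequence(ConsequenceKind.other)


def _exon_index_of_offset(transcript: TranscriptModel, cds_offset: int) -> int:
    cum = 0
    for i, (start, end) in enumerate(transcript.cds_exons, 1):
        cum += end - start
        if cds_offset < cum:
            return i
    return len(transcript.cds_exons)


def _offset_of_exon_start(transcript: TranscriptModel, exon_index: int) -> int:
    return sum(e - s for s, e in transcript.cds_exons[: exon_index - 1])


def _substitution_consequence(
    key: VariantKey,
    transcript: TranscriptModel,
    cds_offset: int,
    cds_pos: int,
    exon_idx: int,
) -> Consequence:
    """Equal-length substitution (SNV or MNV): swap the affected bases into
    the coding sequence and compare the codons spanning them."""
    alt = key.alt if transcript.strand == "+" else _revcomp(key.alt)
    seq = transcript.cds_sequence
    length = len(alt)
    end_off = min(cds_offset + length, len(seq))
    alt = alt[: end_off - cds_offset]  # clip any part beyond the CDS
    lo = (cds_offset // 3) * 3
    hi = min(((end_off + 2) // 3) * 3, len(seq))
    old_span = seq[lo:hi]
    new_span = (
        seq[lo:cds_offset] + alt + seq[end_off:hi]
    )
    old_aa = str(Seq(old_span).translate())
    new_aa = str(Seq(new_span).translate())
    if "*" in new_aa and "*" not in old_aa:
        return Consequence(ConsequenceKind.stop_gained, cds_pos, exon_idx)
    if new_aa == old_aa:
        return Consequence(ConsequenceKind.synonymous, cds_pos, exon_idx)
    return Consequence(ConsequenceKind.missense, cds_pos, exon_idx)


def in_last_coding_exon(consequence: Consequence, transcript: TranscriptModel) -> bool:
    """Whether the consequence's first affected coding base (or, for splice
    variants, the downstream exon) lies in the transcript's final coding
    exon in transcription order."""
    if consequence.exon_index is None:
        raise ValueError("consequence has no exon index")
    return consequence.exon_index == transcript.n_coding_exons


# ---------------------------------------------------------------------------
# Decision cascade
# ---------------------------------------------------------------------------

def leans_pathogenic(record: ClassificationRecord, min_plp: int = 1) -> bool:
    """Operationalises "Conflicting, tending towards pathogenicity": at
    least ``min_plp`` P/LP submissions and strictly more P/LP than B/LB."""
    return (
        record.n_plp_submissions >= min_plp
        and record.n_plp_submissions > record.n_blb_submissions
    )


def classify_variant(
    key: VariantKey,
    gene: str,
    consequence: Consequence,
    record: ClassificationRecord | None,
    rare: bool,
    last_coding_exon: bool = False,
) -> PathogenicityCall:
    """Apply the pathogenicity decision cascade (first matching rule wins):

    1. not rare -> not pathogenic (``not_rare``);
    2. ClinVar Pathogenic/LikelyPathogenic -> pathogenic (``clinvar_plp``),
       regardless of exon position;
    3. ClinVar Benign/LikelyBenign -> not pathogenic (``clinvar_benign``),
       even for PTVs;
    4. PTV + Conflicting leaning pathogenic -> pathogenic (``conflicting_ptv``);
    5. PTV + Absent + not in the last coding exon -> pathogenic (``novel_ptv``);
    6. PTV + Absent + last coding exon -> not pathogenic
       (``last_exon_ptv_excluded``);
    7. otherwise not pathogenic (``non_truncating_unclassified``).

    ``record`` may be None, meaning the variant is absent from the
    classification table.
    """
    sig = record.significance if record is not None else Significance.Absent
    is_ptv = consequence.is_ptv

    def call(pathogenic: bool, reason: Reason) -> PathogenicityCall:
        return PathogenicityCall(key, gene, pathogenic, reason, is_ptv)

    if not rare:
        return call(False, Reason.not_rare)
    if sig in (Significance.Pathogenic, Significance.LikelyPathogenic):
        return call(True, Reason.clinvar_plp)
    if sig in (Significance.Benign, Significance.LikelyBenign):
        return call(False, Reason.clinvar_benign)
    if is_ptv and sig is Significance.Conflicting and record is not None and leans_pathogenic(record):
        return call(True, Reason.conflicting_ptv)
    if is_ptv and sig is Significance.Absent:
        if last_coding_exon:
            return call(False, Reason.last_exon_ptv_excluded)
        return call(True, Reason.novel_ptv)
    return call(False, Reason.non_truncating_unclassified)


def classify_calls(
    calls,
    transcripts: Mapping[str, TranscriptModel],
    classification: Mapping[VariantKey, ClassificationRecord],
    freq_table: Mapping[VariantKey, float],
    maf_max: float = 0.01,
) -> list[tuple[str, PathogenicityCall]]:
    """Classify a harmonised call set: returns (subject_id, call) pairs.

    The gene of each variant call selects its transcript; calls in genes
    without a transcript model, or whose gene is unknown, are classified as
    non-coding (``other``) with no PTV status.
    """
    out: list[tuple[str, PathogenicityCall]] = []
    cache: dict[tuple[VariantKey, str | None], PathogenicityCall] = {}
    for vc in calls:
        cache_key = (vc.key, vc.gene)
        if cache_key not in cache:
            transcript = transcripts.get(vc.gene) if vc.gene else None
            if transcript is not None:
                cons = call_consequence(vc.key, transcript)
                last = (
                    in_last_coding_exon(cons, transcript)
                    if cons.exon_index is not None
                    else False
                )
            else:
                cons, last = Consequence(ConsequenceKind.other), False
            cache[cache_key] = classify_variant(
                vc.key,
                vc.gene or "",
                cons,
                classification.get(vc.key),
                rare=is_rare(vc.key, freq_table, maf_max),
                last_coding_exon=last,
            )
        out.append((vc.subject_id, cache[cache_key]))
    return out


def write_classification_calls(pairs, path) -> None:
    """Per-variant classification TSV: subject, key, gene, verdict, reason."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "subject_id": sid,
                "key": str(pc.key),
                "gene": pc.gene,
                "verdict": "pathogenic" if pc.pathogenic else "not_pathogenic",
                "reason": pc.reason.value,
                "is_ptv": int(pc.is_ptv),
            }
            for sid, pc in pairs
        ]
    ).to_csv(path, sep="\t", index=False)
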