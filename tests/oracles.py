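"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own implementation paths: regions
are expanded to per-base sets, consequences are derived by rebuilding and
translating the whole mutant CDS, and allele trimming is re-derived with a
separate hand-written loop.
"""

from __future__ import annotations

from Bio.Seq import Seq

from panelburden.data_io import TranscriptModel, VariantKey


def hand_trim(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Reference trimming oracle: drop shared trailing bases, then shared
    leading bases (advancing the position), keeping >= 1 base each side."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def base_set(intervals) -> set[int]:
    """Per-base expansion of half-open intervals."""
    out: set[int] = set()
    for start, end in intervals:
        out.update(range(start, end))
    return out


def region_map_base_sets(regions: dict) -> dict[str, set[int]]:
    return {chrom: base_set(iv) for chrom, iv in regions.items()}


def _coding_positions(tx: TranscriptModel) -> list[int]:
    """Genomic 0-based coding positions in transcription order."""
    out = []
    for start, end in tx.cds_exons:
        span = range(start, end) if tx.strand == "+" else range(end - 1, start - 1, -1)
        out.extend(span)
    return out


def mutant_cds(tx: TranscriptModel, key: VariantKey) -> str | None:
    """Rebuild the spliced coding sequence with the variant applied, by
    editing genomic coding positions directly.  Returns None when no ref
    base falls inside the CDS.  Inserted/substituted bases are taken in
    genomic orientation and reverse-complemented for minus-strand genes."""
    order = _coding_positions(tx)
    index_of = {p: i for i, p in enumerate(order)}
    bases = list(tx.cds_sequence)
    ref_positions = list(range(key.pos - 1, key.pos - 1 + len(key.ref)))
    if not any(p in index_of for p in ref_positions):
        return None
    # delete the reference span's coding bases, remember the anchor slot
    hit_indices = sorted(index_of[p] for p in ref_positions if p in index_of)
    first = hit_indices[0]
    for i in reversed(hit_indices):
        bases[i] = ""
    alt = key.alt if tx.strand == "+" else str(Seq(key.alt).reverse_complement())
    # place the alternate allele at the first affected transcript slot; for
    # minus-strand genes the genomic alt maps to transcript order reversed,
    # which the reverse-complement above already handles
    bases[first] = alt
    return "".join(bases)


def oracle_consequence(tx: TranscriptModel, key: VariantKey) -> str:
    """Full-rebuild/translate consequence oracle for variants whose ref is
    fully inside one exon (SNVs and small indels).  Splice and off-CDS
    calls are classified by window arithmetic."""
    ref_positions = range(key.pos - 1, key.pos - 1 + len(key.ref))
    coding = set(_coding_positions(tx))
    if any(p in coding for p in ref_positions):
        if len(key.ref) != len(key.alt):
            return (
                "frameshift"
                if (len(key.ref) - len(key.alt)) % 3 != 0
                else "inframe_indel"
            )
        new_cds = mutant_cds(tx, key)
        old_protein = str(Seq(tx.cds_sequence).translate())
        new_protein = str(Seq(new_cds).translate())
        old_trunc = old_protein.split("*")[0]
        new_trunc = new_protein.split("*")[0]
        if len(new_trunc) < len(old_trunc):
            return "stop_gained"
        if new_protein == old_protein:
            return "synonymous"
        return "missense"
    # splice windows: two intronic bases flanking each internal junction
    windows: set[int] = set()
    exons = sorted(tx.cds_exons)
    for i in range(len(exons) - 1):
        windows.update(range(exons[i][1], exons[i][1] + 2))
        windows.update(range(exons[i + 1][0] - 2, exons[i + 1][0]))
    if any(p in windows for p in ref_positions):
        return "canonical_splice"
    return "other"


def g_test_p(n11: int, n10: int, n01: int, n00: int) -> float:
    """Likelihood-ratio (G) test p-value on a 2x2 table, 1 df."""
    import math

    from scipy import stats

    n = n11 + n10 + n01 + n00
    g = 0.0
    for obs, row, col in (
        (n11, n11 + n10, n11 + n01),
        (n10, n11 + n10, n10 + n00),
        (n01, n01 + n00, n11 + n01),
        (n00, n01 + n00, n10 + n00),
    ):
        expected = row * col / n
        if obs > 0:
            g += 2.0 * obs * math.log(obs / expected)
    return float(stats.chi2.sf(g, df=1))
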