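"""Domain types and readers/writers for the external file formats.

The pipeline consumes per-subject germline variant calls (VCF 4.x with
per-call depth and variant allele fraction), panel target regions (BED),
transcript models with CDS structure and sequence (TSV), a ClinVar-style
classification table, a reference minor-allele-frequency table and a
phenotype table.  Everything downstream works on the plain dataclasses
defined here.

Coordinate conventions
----------------------
VCF positions are 1-based inclusive; BED intervals are 0-based half-open.
All *internal* region logic is 0-based half-open; conversion happens only
at the read/write boundary.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

# the 24 genes on the panel, alphabetical
PANEL_GENES: tuple[str, ...] = (
    "ATM", "BARD1", "BRCA1", "BRCA2", "BRIP1", "CDH1", "CHEK2", "FANCM",
    "MLH1", "MRE11A", "MSH2", "MSH6", "MUTYH", "NBN", "NF1", "PALB2",
    "PMS2", "PTEN", "RAD50", "RAD51C", "RAD51D", "RECQL", "STK11", "TP53",
)


class Study(str, Enum):
    ABCFS = "ABCFS"
    ASPREE = "ASPREE"


class Sex(str, Enum):
    F = "F"
    M = "M"


class CaseStatus(str, Enum):
    case = "case"
    control = "control"


class ERStatus(str, Enum):
    positive = "positive"
    negative = "negative"
    unknown = "unknown"


class Platform(str, Enum):
    HiPlex = "HiPlex"
    HaloPlexHS = "HaloPlexHS"
    AmpliSeq = "AmpliSeq"


class Significance(str, Enum):
    Pathogenic = "Pathogenic"
    LikelyPathogenic = "LikelyPathogenic"
    Conflicting = "Conflicting"
    Benign = "Benign"
    LikelyBenign = "LikelyBenign"
    VUS = "VUS"
    Absent = "Absent"


@dataclass(frozen=True, order=True)
class VariantKey:
    """A normalised variant identity: shared-suffix/prefix-trimmed alleles.

    Construct through :func:`normalize_variant` so that two representations
    of the same underlying allele (e.g. padded with extra reference context)
    map to the same key.
    """

    chrom: str
    pos: int  # 1-based, after trimming
    ref: str
    alt: str

    def __str__(self) -> str:  # stable text form used in tables
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, ref, alt = text.split(":")
        return normalize_variant(chrom, int(pos), ref, alt)


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Normalise an allele pair: trim the shared suffix, then the shared
    prefix, always keeping at least one base on each side (VCF-style anchor).

    The position advances by the number of prefix bases removed.
    Idempotent, and independent of redundant reference padding.
    """
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}) at {chrom}:{pos}")
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


@dataclass
class Subject:
    """One study participant with the six adjustment covariates.

    ``age`` is age at diagnosis for cases and age at enrolment/baseline for
    controls.  Any covariate may be missing (``None``); missing values are
    preserved, never imputed — analyses are complete-case.
    """

    subject_id: str
    study: Study
    sex: Sex
    case_status: CaseStatus
    er_status: ERStatus = ERStatus.unknown
    age: float | None = None
    height: float | None = None  # metres
    bmi: float | None = None  # kg/m^2
    parity: int | None = None
    education: float | None = None  # years
    alcohol: float | None = None  # drinks/week
    prior_breast_cancer: bool | None = None
    family_history: bool | None = None

    def __post_init__(self) -> None:
        if self.age is not None and self.age <= 0:
            raise ValueError(f"age must be > 0, got {self.age} for {self.subject_id}")
        if self.case_status is CaseStatus.control:
            self.er_status = ERStatus.unknown


@dataclass
class VariantCall:
    """One observed variant in one subject, with its QC metrics."""

    subject_id: str
    key: VariantKey
    gene: str | None
    depth: int
    vaf: float
    platform: Platform
    qc_pass: bool | None = None  # set by the QC stage

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF out of [0,1]: {self.vaf}")
        if self.depth < 0:
            raise ValueError(f"negative depth: {self.depth}")


@dataclass
class PanelDesign:
    """Target regions of one sequencing panel.

    ``regions`` maps chromosome -> sorted list of disjoint ``(start, end)``
    half-open 0-based intervals (merged on construction).
    """

    name: str
    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Iterable[tuple[str, int, int]]
    ) -> "PanelDesign":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty/negative interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        merged = {c: merge_intervals(iv) for c, iv in by_chrom.items()}
        return cls(name, merged)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        for start, end in self.regions.get(chrom, ()):
            if start <= pos0 < end:
                return True
        return False

    def total_span(self) -> int:
        return sum(e - s for iv in self.regions.values() for s, e in iv)


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent half-open intervals."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


@dataclass
class TranscriptModel:
    """One coding transcript: CDS exon structure plus spliced CDS sequence.

    ``cds_exons`` are genomic half-open 0-based intervals listed in
    transcription order (ascending coordinates for '+' strand, descending
    for '-').  ``cds_sequence`` is the spliced coding-strand sequence whose
    length equals the summed exon lengths and is a multiple of three.
    """

    gene: str
    accession: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        total = sum(e - s for s, e in self.cds_exons)
        if total != len(self.cds_sequence):
            raise ValueError(
                f"{self.accession}: CDS sequence length {len(self.cds_sequence)} "
                f"!= summed exon length {total}"
            )
        if total % 3 != 0:
            raise ValueError(f"{self.accession}: CDS length {total} not a multiple of 3")
        coords = [s for s, _ in self.cds_exons]
        expect = sorted(coords, reverse=self.strand == "-")
        if coords != expect:
            raise ValueError(f"{self.accession}: exons not in transcription order")

    @property
    def n_coding_exons(self) -> int:
        return len(self.cds_exons)


@dataclass(frozen=True)
class ClassificationRecord:
    """ClinVar-style summary for one variant."""

    key: VariantKey
    significance: Significance
    n_plp_submissions: int = 0
    n_blb_submissions: int = 0

    def __post_init__(self) -> None:
        if self.significance is Significance.Absent and (
            self.n_plp_submissions or self.n_blb_submissions
        ):
            raise ValueError("Absent records must carry zero submission counts")


@dataclass(frozen=True)
class FrequencyRecord:
    """Reference-population minor allele frequency for one variant."""

    key: VariantKey
    maf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"MAF out of [0, 0.5]: {self.maf}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    platform: Platform | str,
    depth_field: str = "DP",
    vaf_fields: Sequence[str] = ("AF", "VAF"),
    gene_field: str = "GENE",
    subject_id: str | None = None,
) -> list[VariantCall]:
    """Read a single-sample VCF into a list of :class:`VariantCall`.

    Multi-allelic records are split into one call per alternate allele.
    Depth is taken from the per-sample FORMAT field ``depth_field`` and the
    allele fraction from the first of ``vaf_fields`` present; a record
    missing either is a hard error.  The gene symbol is taken from the INFO
    field ``gene_field`` when present.  The subject id defaults to the VCF
    sample name.
    """
    from cyvcf2 import VCF

    platform = Platform(platform)
    vcf = VCF(str(path))
    if subject_id is None:
        if len(vcf.samples) != 1:
            raise ValueError(
                f"{path}: expected a single-sample VCF, found samples {vcf.samples}"
            )
        subject_id = vcf.samples[0]
    calls: list[VariantCall] = []
    for rec in vcf:
        where = f"{path}:{rec.CHROM}:{rec.POS}"
        dp = rec.format(depth_field)
        if dp is None:
            raise ValueError(f"missing per-sample {depth_field} at {where}")
        depth = int(dp[0][0])
        vaf_arr = None
        for name in vaf_fields:
            vaf_arr = rec.format(name)
            if vaf_arr is not None:
                break
        if vaf_arr is None:
            raise ValueError(
                f"missing per-sample allele fraction ({'/'.join(vaf_fields)}) at {where}"
            )
        vafs = [float(v) for v in vaf_arr[0]]
        gene = rec.INFO.get(gene_field)
        for i, alt in enumerate(rec.ALT):
            key = normalize_variant(rec.CHROM, rec.POS, rec.REF, alt)
            vaf = vafs[i] if i < len(vafs) else vafs[0]
            calls.append(
                VariantCall(
                    subject_id=subject_id,
                    key=key,
                    gene=gene,
                    depth=depth,
                    vaf=vaf,
                    platform=platform,
                )
            )
    return calls


def read_panel_bed(path: str | Path, name: str) -> PanelDesign:
    """Read a BED3+ file (0-based half-open) into a merged :class:`PanelDesign`."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            intervals.append((chrom, start, end))
    return PanelDesign.from_intervals(name, intervals)


_BOOL_CODES = {
    "1": True, "0": False, "true": True, "false": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_bool(text: str, *, column: str, row: int) -> bool:
    try:
        return _BOOL_CODES[text.strip().lower()]
    except KeyError:
        raise ValueError(f"row {row}: unrecognised {column} code {text!r}") from None


def _sniff_delimiter(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_phenotypes(path: str | Path) -> list[Subject]:
    """Read the phenotype table (CSV or TSV, sniffed from the header row).

    Unknown columns are ignored; empty cells become missing values.  Unknown
    study/sex/case codes are a hard error listing the offending rows.
    """
    delim = _sniff_delimiter(path)
    subjects: list[Subject] = []
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        for i, row in enumerate(reader, 2):  # header is line 1
            try:
                subjects.append(_subject_from_row(row, i))
            except (ValueError, KeyError) as exc:
                errors.append(str(exc))
    if errors:
        raise ValueError(
            f"{path}: {len(errors)} malformed phenotype row(s):\n" + "\n".join(errors)
        )
    return subjects


def _opt(row: dict, col: str) -> str | None:
    val = row.get(col)
    if val is None or val.strip() == "" or val.strip().upper() in ("NA", "NAN"):
        return None
    return val.strip()


def _subject_from_row(row: dict, lineno: int) -> Subject:
    def req(col: str) -> str:
        val = _opt(row, col)
        if val is None:
            raise ValueError(f"row {lineno}: missing required column {col!r}")
        return val

    try:
        study = Study(req("study"))
    except ValueError:
        raise ValueError(f"row {lineno}: unknown study code {row.get('study')!r}")
    try:
        sex = Sex(req("sex"))
    except ValueError:
        raise ValueError(f"row {lineno}: unknown sex code {row.get('sex')!r}")
    try:
        case_status = CaseStatus(req("case_status"))
    except ValueError:
        raise ValueError(
            f"row {lineno}: unknown case_status code {row.get('case_status')!r}"
        )
    er_raw = _opt(row, "er_status")
    er = ERStatus(er_raw) if er_raw is not None else ERStatus.unknown

    def num(col: str) -> float | None:
        val = _opt(row, col)
        return float(val) if val is not None else None

    def integer(col: str) -> int | None:
        val = _opt(row, col)
        return int(float(val)) if val is not None else None

    def boolean(col: str) -> bool | None:
        val = _opt(row, col)
        return _parse_bool(val, column=col, row=lineno) if val is not None else None

    return Subject(
        subject_id=req("subject_id"),
        study=study,
        sex=sex,
        case_status=case_status,
        er_status=er,
        age=num("age"),
        height=num("height"),
        bmi=num("bmi"),
        parity=integer("parity"),
        education=num("education"),
        alcohol=num("alcohol"),
        prior_breast_cancer=boolean("prior_breast_cancer"),
        family_history=boolean("family_history"),
    )


_PHENO_COLUMNS = [
    "subject_id", "study", "sex", "case_status", "er_status", "age", "height",
    "bmi", "parity", "education", "alcohol", "prior_breast_cancer",
    "family_history",
]


def write_phenotypes(subjects: Sequence[Subject], path: str | Path) -> None:
    """Write the phenotype table as CSV; missing values become empty cells.

    ``write_phenotypes`` then :func:`read_phenotypes` round-trips exactly.
    """
    def cell(val) -> str:
        if val is None:
            return ""
        if isinstance(val, bool):
            return "1" if val else "0"
        if isinstance(val, Enum):
            return val.value
        if isinstance(val, float) and val == int(val):
            return str(int(val))
        return str(val)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PHENO_COLUMNS)
        for s in subjects:
            writer.writerow([cell(getattr(s, col)) for col in _PHENO_COLUMNS])


def read_classification_table(path: str | Path) -> dict[VariantKey, ClassificationRecord]:
    """Read the ClinVar-style TSV: chrom, pos, ref, alt, significance,
    n_plp_submissions, n_blb_submissions."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    records: dict[VariantKey, ClassificationRecord] = {}
    for i, row in df.iterrows():
        try:
            key = normalize_variant(
                str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"]
            )
            sig = Significance(row["significance"])
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from None
        records[key] = ClassificationRecord(
            key=key,
            significance=sig,
            n_plp_submissions=int(row.get("n_plp_submissions", 0) or 0),
            n_blb_submissions=int(row.get("n_blb_submissions", 0) or 0),
        )
    return records


def write_classification_table(
    records: Iterable[ClassificationRecord], path: str | Path
) -> None:
    rows = [
        {
            "chrom": r.key.chrom, "pos": r.key.pos, "ref": r.key.ref,
            "alt": r.key.alt, "significance": r.significance.value,
            "n_plp_submissions": r.n_plp_submissions,
            "n_blb_submissions": r.n_blb_submissions,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_frequency_table(path: str | Path) -> dict[VariantKey, float]:
    """Read the reference MAF TSV: chrom, pos, ref, alt, maf."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[VariantKey, float] = {}
    for i, row in df.iterrows():
        maf = float(row["maf"])
        if not 0.0 <= maf <= 0.5:
            raise ValueError(f"{path}: row {i + 2}: MAF out of [0, 0.5]: {maf}")
        key = normalize_variant(str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
        out[key] = maf
    return out


def write_frequency_table(table: dict[VariantKey, float], path: str | Path) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "maf": maf}
        for k, maf in sorted(table.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_transcripts(path: str | Path) -> dict[str, TranscriptModel]:
    """Read transcript models from TSV: gene, accession, chrom, strand,
    cds_exons (semicolon-joined ``start-end`` half-open intervals in
    transcription order), cds_sequence.  One transcript per gene.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, TranscriptModel] = {}
    for i, row in df.iterrows():
        exons = []
        for token in row["cds_exons"].split(";"):
            start, end = token.split("-")
            exons.append((int(start), int(end)))
        model = TranscriptModel(
            gene=row["gene"],
            accession=row["accession"],
            chrom=str(row["chrom"]),
            strand=row["strand"],
            cds_exons=exons,
            cds_sequence=row["cds_sequence"].upper(),
        )
        if model.gene in out:
            raise ValueError(f"{path}: duplicate transcript for gene {model.gene}")
        out[model.gene] = model
    return out


def write_transcripts(models: Iterable[TranscriptModel], path: str | Path) -> None:
    rows = [
        {
            "gene": m.gene, "accession": m.accession, "chrom": m.chrom,
            "strand": m.strand,
            "cds_exons": ";".join(f"{s}-{e}" for s, e in m.cds_exons),
            "cds_sequence": m.cds_sequence,
        }
        for m in models
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for printed percentages),
    unlike banker's rounding."""
    factor = 10 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def write_association_table(results, path: str | Path) -> None:
    """Write per-gene association results as a TSV mirroring the published
    table layout; non-estimable cells are rendered as an en-dash."""
    rows = []
    for r in results:
        if r.estimable:
            rows.append(
                {
                    "gene": r.gene,
                    "n_case_carriers": r.n_case_carriers,
                    "case_pct": round_half_up(100.0 * r.case_fraction, 1)
                    if r.case_fraction is not None else "",
                    "n_control_carriers": r.n_control_carriers,
                    "control_pct": round_half_up(100.0 * r.control_fraction, 1)
                    if r.control_fraction is not None else "",
                    "or": f"{r.odds_ratio:.6g}",
                    "ci_low": f"{r.ci_low:.6g}",
                    "ci_high": f"{r.ci_high:.6g}",
                    "p": f"{r.p_value:.4g}",
                }
            )
        else:
            rows.append(
                {
                    "gene": r.gene,
                    "n_case_carriers": r.n_case_carriers,
                    "case_pct": round_half_up(100.0 * r.case_fraction, 1)
                    if r.case_fraction is not None else "",
                    "n_control_carriers": r.n_control_carriers,
                    "control_pct": round_half_up(100.0 * r.control_fraction, 1)
                    if r.control_fraction is not None else "",
                    "or": "–", "ci_low": "–", "ci_high": "–", "p": "–",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
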