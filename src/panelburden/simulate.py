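"""Synthetic study generator: complete, self-consistent inputs with known
ground truth, emulating a population-based breast cancer case-control study
(age-matched cases/controls plus a large elderly cancer-free control arm)
genotyped on a 24-gene panel across three sequencing platforms.

The generator works mechanically from a single disease model rather than
painting arm-level summaries on:

* every woman has per-gene carrier states drawn independently at the
  population carrier frequency ``f_g``;
* her probability of having been diagnosed with breast cancer by her
  current age follows a logistic model with an intercept, a linear age
  term and additive per-gene carrier effects ``beta_g``;
* cases are sampled from affected women with a soft early-onset weighting,
  age-matched controls from unaffected women of the same age distribution,
  and elderly controls from women still unaffected at age >= 70.

Because carriers are more likely to be affected by age 70, elderly
controls come out depleted of high-risk alleles without any explicit
depletion knob — the age-ascertainment bias the adjusted analyses must
correct for.

Planted artefacts (a common variant above the cohort-frequency threshold,
a depth-49 call, a low-call-rate locus, an off-target call, a caller-
discordant call, last-exon and ClinVar-benign PTVs, a common-MAF variant,
mono-allelic MUTYH carriers and one multi-gene carrier) each have exactly
one pipeline rule designed to remove them, so attrition can be audited
one-to-one against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    CaseStatus,
    ClassificationRecord,
    ERStatus,
    FrequencyRecord,
    PANEL_GENES,
    PanelDesign,
    Platform,
    Sex,
    Significance,
    Study,
    Subject,
    TranscriptModel,
    VariantCall,
    VariantKey,
    normalize_variant,
    write_classification_table,
    write_frequency_table,
    write_phenotypes,
    write_transcripts,
)

# population carrier frequencies loosely matched to the observed
# control-arm prevalences of the study design being emulated
DEFAULT_CARRIER_FREQ: dict[str, float] = {
    "ATM": 0.0034, "BARD1": 0.0004, "BRCA1": 0.0010, "BRCA2": 0.0028,
    "BRIP1": 0.0018, "CDH1": 0.0002, "CHEK2": 0.0047, "FANCM": 0.0026,
    "MLH1": 0.0002, "MRE11A": 0.0007, "MSH2": 0.00015, "MSH6": 0.0004,
    "MUTYH": 0.0065, "NBN": 0.0015, "NF1": 0.00055, "PALB2": 0.0014,
    "PMS2": 0.0002, "PTEN": 0.00015, "RAD50": 0.0015, "RAD51C": 0.00055,
    "RAD51D": 0.00055, "RECQL": 0.0002, "STK11": 0.0002, "TP53": 0.0005,
}

# true odds ratios per gene: the published point estimates for the genes
# with estimable effects, 1.0 elsewhere (MUTYH mono-allelic is risk-neutral)
DEFAULT_TRUE_OR: dict[str, float] = {
    "ATM": 3.4, "BARD1": 8.2, "BRCA1": 5.3, "BRCA2": 4.0, "BRIP1": 2.8,
    "CHEK2": 1.3, "FANCM": 0.8, "MSH6": 4.7, "NBN": 2.0, "NF1": 4.7,
    "PALB2": 4.3, "RAD50": 0.3, "RAD51D": 0.25, "TP53": 19.9,
}


@dataclass
class SpikeIns:
    """Artefact spike-in knobs; each maps to exactly one pipeline filter."""

    common_artifact_freq: float = 0.002  # > cohort_freq_max -> cohort filter
    n_low_depth_calls: int = 1  # depth-49 HiPlex calls -> platform QC
    low_callrate_subjects: int = 2  # variant carriers at the badly-called locus
    low_callrate_pass_fraction: float = 0.94  # locus coverage QC rate -> call-rate filter
    n_offtarget_calls: int = 5  # outside the panel intersection -> region filter
    n_caller_discordant: int = 5  # primary-caller-only calls -> intersection
    n_last_exon_ptv: int = 8  # classifier: last_exon_ptv_excluded
    n_benign_ptv: int = 6  # classifier: clinvar_benign
    n_common_maf: int = 8  # MAF 0.02 in reference table: not_rare
    n_multigene: int = 1  # carrier in two genes -> multi-gene exclusion
    n_males: int = 3  # -> male exclusion
    n_aspree_prior_bc: int = 30  # -> prior-breast-cancer exclusion
    # recurrent-variant budget: carriers of any one shared variant in the
    # elderly arm are capped at this cohort fraction so that genuinely
    # pathogenic recurrent variants never trip the artefact filter
    shared_variant_cohort_cap: float = 0.0005


@dataclass
class SyntheticConfig:
    """All generator knobs.  Defaults emulate the study design: 1464 cases
    and 862 age-matched controls (median age ~40) plus 6549 elderly
    controls (median age ~74)."""

    n_cases: int = 1464
    n_abcfs_controls: int = 862
    n_aspree_controls: int = 6549
    genes: tuple[str, ...] = PANEL_GENES
    carrier_freq: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRIER_FREQ)
    )
    true_or: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_OR))
    # optional ER-subtype-specific odds ratios: gene -> (OR_pos, OR_neg)
    subtype_or: dict[str, tuple[float, float]] = field(default_factory=dict)
    baseline_intercept: float = -5.5  # logit P(affected) at age 0 for non-carriers
    age_log_or: float = 0.04  # per year of age
    er_positive_fraction: float = 0.75
    er_unknown_fraction: float = 0.05
    abcfs_age_median: float = 40.0
    abcfs_age_iqr: float = 14.0
    aspree_age_median: float = 74.0
    aspree_age_iqr: float = 5.8
    aspree_min_age: float = 70.0
    early_onset_soft_cap: float = 50.0  # case-sampling weight decays beyond this age
    early_onset_scale: float = 8.0
    parity_missing_aspree: float = 0.043
    covariate_missing: float = 0.005
    family_history_base: float = 0.15
    family_history_brca: float = 0.45
    family_history_other: float = 0.18
    spikes: SpikeIns = field(default_factory=SpikeIns)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_abcfs_controls, self.n_aspree_controls) <= 0:
            raise ValueError("all study arms must be non-empty")
        for g, f in self.carrier_freq.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"carrier frequency for {g} out of (0,1): {f}")

    def beta(self, gene: str) -> float:
        return math.log(self.true_or.get(gene, 1.0))


@dataclass
class SyntheticPopulation:
    subjects: list[Subject]
    carrier: pd.DataFrame  # bool, index subject_id, columns genes (ground truth)
    config: SyntheticConfig

    def true_carriers(self, gene: str) -> list[str]:
        return list(self.carrier.index[self.carrier[gene]])


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def _trunc_normal(rng, n, median, iqr, lo, hi):
    sd = iqr / 1.349
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(median, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_population(config: SyntheticConfig, seed: int | None = None) -> SyntheticPopulation:
    """Sample the three study arms from the common disease model.

    Returns subjects (cases flagged with ER status, covariates drawn per
    arm, missingness applied) plus the ground-truth carrier matrix.  Raises
    if the disease model yields no affected women to sample cases from.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = list(config.genes)
    freqs = np.array([config.carrier_freq.get(g, 0.0005) for g in genes])
    betas = np.array([config.beta(g) for g in genes])

    subjects: list[Subject] = []
    carrier_rows: list[np.ndarray] = []
    counter = [0]

    def new_id(prefix: str) -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]:06d}"

    def draw_arm(n_needed, arm: str):
        """Rejection-sample one arm; returns (ages, carriers, er_types)."""
        got_ages, got_carriers, got_types = [], [], []
        n_have, rounds = 0, 0
        while n_have < n_needed:
            rounds += 1
            if rounds > 200:
                raise RuntimeError(
                    f"could not sample {n_needed} subjects for arm {arm}: "
                    "disease model too extreme; enlarge the base population "
                    "or soften the age/effect parameters"
                )
            m = max(4 * (n_needed - n_have), 1000)
            if arm == "aspree":
                ages = _trunc_normal(
                    rng, m, config.aspree_age_median + 0.5, config.aspree_age_iqr,
                    config.aspree_min_age, 95.0,
                )
            else:
                ages = _trunc_normal(
                    rng, m, config.abcfs_age_median, config.abcfs_age_iqr, 22.0, 69.0
                )
            carriers = rng.random((m, len(genes))) < freqs
            logit = config.baseline_intercept + config.age_log_or * ages + carriers @ betas
            if config.subtype_or:
                p_aff, er_type = _subtype_disease(config, rng, ages, carriers, genes)
                affected = rng.random(m) < p_aff
            else:
                p_aff = 1.0 / (1.0 + np.exp(-logit))
                affected = rng.random(m) < p_aff
                er_type = None
            if arm == "case":
                weight = np.where(
                    ages <= config.early_onset_soft_cap,
                    1.0,
                    np.exp(-(ages - config.early_onset_soft_cap) / config.early_onset_scale),
                )
                accept = affected & (rng.random(m) < weight)
            else:
                accept = ~affected
            idx = np.flatnonzero(accept)[: n_needed - n_have]
            got_ages.append(ages[idx])
            got_carriers.append(carriers[idx])
            if er_type is not None:
                got_types.append(er_type[idx])
            n_have += len(idx)
        ages = np.concatenate(got_ages)
        carr = np.vstack(got_carriers)
        types = np.concatenate(got_types) if got_types else None
        return ages, carr, types

    def covariates(arm: str, n, rng):
        if arm == "aspree":
            height = _trunc_normal(rng, n, 1.59, 0.08, 1.40, 1.90)
            bmi = _trunc_normal(rng, n, 27.4, 6.6, 15.0, 55.0)
            parity = rng.poisson(2.8, n)
            education = np.round(_trunc_normal(rng, n, 11.0, 3.0, 5.0, 22.0))
            alcohol = np.round(rng.exponential(1.0 / math.log(2.0), n))
        else:
            height = _trunc_normal(rng, n, 1.63, 0.11, 1.40, 1.95)
            bmi = _trunc_normal(rng, n, 23.5, 5.5, 15.0, 55.0)
            parity = rng.poisson(2.2, n)
            education = np.round(_trunc_normal(rng, n, 11.0, 2.0, 5.0, 22.0))
            alcohol = np.round(rng.exponential(2.0 / math.log(2.0), n))
        return height, bmi, parity, education, alcohol

    brca_idx = [i for i, g in enumerate(genes) if g in ("BRCA1", "BRCA2")]
    other_idx = [
        i for i, g in enumerate(genes) if g not in ("BRCA1", "BRCA2", "MUTYH")
    ]

    def emit(arm: str, study: Study, case_status: CaseStatus, n: int, prefix: str):
        ages, carr, er_types = draw_arm(n, arm)
        height, bmi, parity, education, alcohol = covariates(
            "aspree" if study is Study.ASPREE else "abcfs", n, rng
        )
        fh_prob = np.full(n, config.family_history_base)
        fh_prob[carr[:, other_idx].any(axis=1)] = config.family_history_other
        fh_prob[carr[:, brca_idx].any(axis=1)] = config.family_history_brca
        family_history = rng.random(n) < fh_prob
        for i in range(n):
            er = ERStatus.unknown
            if case_status is CaseStatus.case:
                if rng.random() < config.er_unknown_fraction:
                    er = ERStatus.unknown
                elif er_types is not None:
                    er = ERStatus.positive if er_types[i] == 1 else ERStatus.negative
                else:
                    p_pos = config.er_positive_fraction
                    if "BRCA1" in genes and carr[i, genes.index("BRCA1")]:
                        p_pos = 0.25  # BRCA1 disease is predominantly ER-negative
                    er = ERStatus.positive if rng.random() < p_pos else ERStatus.negative
            subjects.append(
                Subject(
                    subject_id=new_id(prefix),
                    study=study,
                    sex=Sex.F,
                    case_status=case_status,
                    er_status=er,
                    age=float(np.round(ages[i], 1)),
                    height=float(np.round(height[i], 2)),
                    bmi=float(np.round(bmi[i], 1)),
                    parity=int(parity[i]),
                    education=float(education[i]),
                    alcohol=float(alcohol[i]),
                    prior_breast_cancer=False if study is Study.ASPREE else None,
                    family_history=bool(family_history[i]),
                )
            )
            carrier_rows.append(carr[i])

    def draw_prior_bc(n: int):
        """Elderly women who are affected (prior diagnosis) but enrolled."""
        got = 0
        while got < n:
            m = 50 * n + 200
            ages = _trunc_normal(
                rng, m, config.aspree_age_median + 0.5, config.aspree_age_iqr,
                config.aspree_min_age, 95.0,
            )
            carr = rng.random((m, len(genes))) < freqs
            logit = config.baseline_intercept + config.age_log_or * ages + carr @ betas
            affected = rng.random(m) < 1.0 / (1.0 + np.exp(-logit))
            idx = np.flatnonzero(affected)[: n - got]
            for j in idx:
                height, bmi, parity, education, alcohol = covariates("aspree", 1, rng)
                subjects.append(
                    Subject(
                        subject_id=new_id("ASP-X"),
                        study=Study.ASPREE,
                        sex=Sex.F,
                        case_status=CaseStatus.control,
                        age=float(np.round(ages[j], 1)),
                        height=float(np.round(height[0], 2)),
                        bmi=float(np.round(bmi[0], 1)),
                        parity=int(parity[0]),
                        education=float(education[0]),
                        alcohol=float(alcohol[0]),
                        prior_breast_cancer=True,
                        family_history=bool(rng.random() < config.family_history_base),
                    )
                )
                carrier_rows.append(carr[j])
            got += len(idx)

    emit("case", Study.ABCFS, CaseStatus.case, config.n_cases, "ABC-C")
    emit("control", Study.ABCFS, CaseStatus.control, config.n_abcfs_controls, "ABC-N")
    emit("aspree", Study.ASPREE, CaseStatus.control, config.n_aspree_controls, "ASP-")
    if config.spikes.n_aspree_prior_bc:
        draw_prior_bc(config.spikes.n_aspree_prior_bc)
    for _ in range(config.spikes.n_males):
        subjects.append(
            Subject(
                subject_id=new_id("ASP-M"),
                study=Study.ASPREE,
                sex=Sex.M,
                case_status=CaseStatus.control,
                age=float(np.round(rng.uniform(70, 85), 1)),
                prior_breast_cancer=False,
            )
        )
        carrier_rows.append(np.zeros(len(genes), dtype=bool))

    # apply covariate missingness
    for s in subjects:
        if s.study is Study.ASPREE and rng.random() < config.parity_missing_aspree:
            s.parity = None
        for name in ("height", "bmi", "education", "alcohol"):
            if getattr(s, name) is not None and rng.random() < config.covariate_missing:
                setattr(s, name, None)

    carrier = pd.DataFrame(
        np.vstack(carrier_rows),
        index=[s.subject_id for s in subjects],
        columns=genes,
        dtype=bool,
    )

    # one spiked multi-gene carrier: give the first single-gene case carrier
    # a second gene
    spiked = 0
    for s in subjects:
        if spiked >= config.spikes.n_multigene:
            break
        if s.case_status is CaseStatus.case:
            carried = carrier.loc[s.subject_id]
            if carried.sum() == 1:
                gene = carried.idxmax()
                for g2 in genes:
                    if g2 not in (gene, "MUTYH"):
                        carrier.loc[s.subject_id, g2] = True
                        spiked += 1
                        break
    return SyntheticPopulation(subjects=subjects, carrier=carrier, config=config)


def _subtype_disease(config, rng, ages, carriers, genes):
    """Two-disease model when ER-subtype-specific effects are configured.

    ER+ and ER- disease have separate carrier effects; the baseline odds
    split by the configured ER+ fraction.  Returns (P(either), type array
    with 1 = ER+ among a pre-drawn latent assignment)."""
    base = config.baseline_intercept + config.age_log_or * ages
    b_pos = np.array(
        [math.log(config.subtype_or.get(g, (config.true_or.get(g, 1.0),) * 2)[0])
         for g in genes]
    )
    b_neg = np.array(
        [math.log(config.subtype_or.get(g, (config.true_or.get(g, 1.0),) * 2)[1])
         for g in genes]
    )
    logit_pos = base + math.log(config.er_positive_fraction) + carriers @ b_pos
    logit_neg = base + math.log(1.0 - config.er_positive_fraction) + carriers @ b_neg
    p_pos = 1.0 / (1.0 + np.exp(-logit_pos))
    p_neg = 1.0 / (1.0 + np.exp(-logit_neg))
    p_any = 1.0 - (1.0 - p_pos) * (1.0 - p_neg)
    with np.errstate(invalid="ignore"):
        frac_pos = np.where(p_any > 0, p_pos / np.maximum(p_pos + p_neg, 1e-300), 0.5)
    er_type = (rng.random(len(ages)) < frac_pos).astype(int)
    return p_any, er_type


def population_to_analysis_table(pop: SyntheticPopulation) -> pd.DataFrame:
    """Analysis table straight from ground-truth carrier states (bypassing
    the sequencing layer), for studies of the statistical model alone."""
    from .association import build_analysis_table
    from .carriers import CarrierPolicy, build_carrier_matrix
    from .classify import PathogenicityCall, Reason
    from .data_io import VariantKey as VK

    pairs = []
    arr = pop.carrier.to_numpy()
    sids = list(pop.carrier.index)
    cols = list(pop.carrier.columns)
    for i, j in zip(*np.nonzero(arr)):
        key = VK("chrT", 1 + int(j), "A", "C")
        pairs.append(
            (sids[i], PathogenicityCall(key, cols[j], True, Reason.clinvar_plp, False))
        )
    matrix = build_carrier_matrix(pop.subjects, pairs, CarrierPolicy(genes=tuple(pop.carrier.columns)))
    return build_analysis_table(matrix)


# ---------------------------------------------------------------------------
# Transcripts, variant catalogue and sequencing layer
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]

EXON_LEN = 100  # three 100-bp coding exons per toy gene
INTRON_LEN = 100
GENE_BASE = 100_000


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def make_toy_transcripts(
    genes: Sequence[str] = PANEL_GENES, seed: int = 7
) -> dict[str, TranscriptModel]:
    """Deterministic 3-exon ~300-bp toy transcripts, one per gene, with
    known mutation sites: codon 10 is TAC (one SNV from a stop), codon 45
    is GCT (missense target), and exon 3 is the last coding exon.  Every
    third gene is on the minus strand."""
    rng = np.random.default_rng(seed)
    out = {}
    for i, gene in enumerate(genes):
        codons = [
            _CODONS[j] for j in rng.integers(0, len(_CODONS), size=EXON_LEN * 3 // 3)
        ]
        codons[10] = "TAC"  # TAC -> TAA is stop-gained
        codons[45] = "GCT"  # GCT -> CCT is missense
        codons[-1] = "TAA"  # terminal stop codon
        cds = "".join(codons)
        strand = "-" if i % 3 == 2 else "+"
        base = GENE_BASE
        bounds = [
            (base, base + EXON_LEN),
            (base + EXON_LEN + INTRON_LEN, base + 2 * EXON_LEN + INTRON_LEN),
            (base + 2 * (EXON_LEN + INTRON_LEN), base + 3 * EXON_LEN + 2 * INTRON_LEN),
        ]
        exons = bounds if strand == "+" else bounds[::-1]
        out[gene] = TranscriptModel(
            gene=gene,
            accession=f"NM_{900000 + i}.1",
            chrom=f"chr{i + 1}",
            strand=strand,
            cds_exons=exons,
            cds_sequence=cds,
        )
    return out


def genomic_pos_of_cds_offset(transcript: TranscriptModel, offset: int) -> int:
    """0-based genomic position of the CDS base at 0-based ``offset``."""
    cum = 0
    for start, end in transcript.cds_exons:
        length = end - start
        if offset < cum + length:
            within = offset - cum
            return start + within if transcript.strand == "+" else end - 1 - within
        cum += length
    raise IndexError(f"CDS offset {offset} beyond transcript {transcript.accession}")


def genomic_base(transcript: TranscriptModel, pos0: int) -> str:
    """Reference base (genomic forward strand) at a coding position."""
    cum = 0
    for start, end in transcript.cds_exons:
        if start <= pos0 < end:
            if transcript.strand == "+":
                off = cum + (pos0 - start)
                return transcript.cds_sequence[off]
            off = cum + (end - 1 - pos0)
            return _revcomp(transcript.cds_sequence[off])
        cum += end - start
    raise IndexError(f"{pos0} not coding in {transcript.accession}")


def _snv_key(transcript: TranscriptModel, cds_offset: int, alt_cds_base: str) -> VariantKey:
    pos0 = genomic_pos_of_cds_offset(transcript, cds_offset)
    ref = genomic_base(transcript, pos0)
    alt = alt_cds_base if transcript.strand == "+" else _revcomp(alt_cds_base)
    return normalize_variant(transcript.chrom, pos0 + 1, ref, alt)


def _del1_key(transcript: TranscriptModel, cds_offset: int) -> VariantKey:
    """Single-base deletion with a VCF anchor base; both bases inside one
    exon (callers must choose ``cds_offset`` accordingly)."""
    pos0 = genomic_pos_of_cds_offset(transcript, cds_offset)
    anchor0 = pos0 - 1
    ref = genomic_base(transcript, anchor0) + genomic_base(transcript, pos0)
    alt = genomic_base(transcript, anchor0)
    return normalize_variant(transcript.chrom, anchor0 + 1, ref, alt)


@dataclass(frozen=True)
class CatalogueVariant:
    key: VariantKey
    gene: str
    category: str  # see VariantCatalogue docstring


@dataclass
class VariantCatalogue:
    """Per-gene variant menu plus the side tables it implies.

    Categories:
      plp_missense      ClinVar LikelyPathogenic missense (pathogenic)
      novel_stop        stop-gained, absent from ClinVar (pathogenic)
      novel_frameshift  frameshift, absent from ClinVar (pathogenic)
      conflicting_fs    frameshift, ClinVar Conflicting leaning pathogenic
      mutyh_plp         ClinVar Pathogenic missense in MUTYH
      last_exon_fs      frameshift in the last coding exon, absent (trap)
      benign_stop       stop-gained annotated Benign (trap)
      common_missense   missense with reference MAF 0.02 (trap)
      artifact          recurrent artefact call (trap: cohort frequency)
      lowcall           variant at a poorly-called locus (trap: call rate)
      offtarget         call outside the panel intersection (trap: regions)
    """

    transcripts: dict[str, TranscriptModel]
    variants: dict[tuple[str, str], CatalogueVariant]  # (gene, category) -> variant
    classification: dict[VariantKey, ClassificationRecord]
    frequency: dict[VariantKey, float]

    def get(self, gene: str, category: str) -> CatalogueVariant:
        return self.variants[(gene, category)]


# CDS offsets (0-based) of the planted sites, per toy transcript layout
STOP_SNV_OFFSET = 10 * 3 + 2  # third base of codon 10 (TAC -> TAA)
MISSENSE_OFFSET = 45 * 3  # first base of codon 45 (GCT -> CCT)
FRAMESHIFT_OFFSET = 130  # mid exon 2
LAST_EXON_FS_OFFSET = 250  # mid exon 3 (last coding exon)
BENIGN_STOP_GENE_OFFSET = STOP_SNV_OFFSET  # reuse the stop site, distinct alt
COMMON_MISSENSE_OFFSET = 45 * 3 + 1  # second base of codon 45


def build_variant_catalogue(
    genes: Sequence[str] = PANEL_GENES, seed: int = 7
) -> VariantCatalogue:
    transcripts = make_toy_transcripts(genes, seed=seed)
    variants: dict[tuple[str, str], CatalogueVariant] = {}
    classification: dict[VariantKey, ClassificationRecord] = {}
    frequency: dict[VariantKey, float] = {}

    def add(gene: str, category: str, key: VariantKey,
            sig: Significance | None = None, n_plp: int = 0, n_blb: int = 0,
            maf: float | None = None) -> None:
        variants[(gene, category)] = CatalogueVariant(key, gene, category)
        if sig is not None:
            classification[key] = ClassificationRecord(key, sig, n_plp, n_blb)
        if maf is not None:
            frequency[key] = maf

    for gene, tx in transcripts.items():
        add(gene, "plp_missense", _snv_key(tx, MISSENSE_OFFSET, "C"),
            sig=Significance.LikelyPathogenic, n_plp=3)
        add(gene, "novel_stop", _snv_key(tx, STOP_SNV_OFFSET, "A"))
        add(gene, "novel_frameshift", _del1_key(tx, FRAMESHIFT_OFFSET))
        add(gene, "last_exon_fs", _del1_key(tx, LAST_EXON_FS_OFFSET))
        add(gene, "common_missense", _snv_key(tx, COMMON_MISSENSE_OFFSET, "A"),
            maf=0.02)
    # gene-specific extras
    chek2 = transcripts["CHEK2"]
    add("CHEK2", "conflicting_fs", _del1_key(chek2, FRAMESHIFT_OFFSET + 30),
        sig=Significance.Conflicting, n_plp=5, n_blb=1)
    mutyh = transcripts["MUTYH"]
    add("MUTYH", "mutyh_plp", _snv_key(mutyh, MISSENSE_OFFSET + 30, "T"),
        sig=Significance.Pathogenic, n_plp=4)
    add("MUTYH", "mutyh_plp2", _snv_key(mutyh, MISSENSE_OFFSET + 60, "T"),
        sig=Significance.Pathogenic, n_plp=2)
    first = transcripts[genes[0]]
    add(genes[0], "benign_stop", _snv_key(first, STOP_SNV_OFFSET, "G"),
        sig=Significance.Benign, n_blb=4)
    # artefact: a novel-PTV-looking call recurring across the elderly cohort
    second = transcripts[genes[1]]
    add(genes[1], "artifact", _snv_key(second, STOP_SNV_OFFSET, "G"))
    # low-call-rate locus: synonymous SNV, removed only by the call-rate rule
    third = transcripts[genes[2]]
    add(genes[2], "lowcall", _snv_key(third, 11 * 3 + 2, _silent_alt(third, 11)))
    # off-target call: just beyond the panels' shared 3' flank
    add(genes[3], "offtarget",
        VariantKey(transcripts[genes[3]].chrom, GENE_BASE + 3 * EXON_LEN + 2 * INTRON_LEN + 60, "A", "G"))
    # caller-discordant: an otherwise-pathogenic PTV seen by one caller only
    fifth = transcripts[genes[4]]
    add(genes[4], "caller_discordant", _del1_key(fifth, FRAMESHIFT_OFFSET + 33))
    return VariantCatalogue(transcripts, variants, classification, frequency)


def _silent_alt(tx: TranscriptModel, codon_idx: int) -> str:
    """Alternate third base keeping the amino acid (works for 4-fold codons;
    falls back to any non-ref base if the codon is not 4-fold degenerate)."""
    from Bio.Seq import Seq

    codon = tx.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3]
    aa = str(Seq(codon).translate())
    for b in "ACGT":
        if b != codon[2]:
            alt = codon[:2] + b
            if alt not in _STOPS and str(Seq(alt).translate()) == aa:
                return b
    for b in "ACGT":
        if b != codon[2] and codon[:2] + b not in _STOPS:
            return b
    raise AssertionError("unreachable")


def make_panels(genes: Sequence[str] = PANEL_GENES) -> list[PanelDesign]:
    """Three panel designs whose pairwise targets differ at the flanks, so
    the three-way intersection is a strict subset of each panel."""
    span_end = GENE_BASE + 3 * EXON_LEN + 2 * INTRON_LEN
    hi, halo, ampli = [], [], []
    for i, gene in enumerate(genes):
        chrom = f"chr{i + 1}"
        hi.append((chrom, GENE_BASE - 60, span_end + 100))
        halo.append((chrom, GENE_BASE - 30, span_end + 80))
        ampli.append((chrom, GENE_BASE - 45, span_end + 40))
    return [
        PanelDesign.from_intervals("HiPlex", hi),
        PanelDesign.from_intervals("HaloPlexHS", halo),
        PanelDesign.from_intervals("AmpliSeq", ampli),
    ]


class _PrivateSites:
    """Deterministic pools of unique (private) variant sites in one toy
    transcript: each true carrier receives their own variant, mimicking the
    allelic heterogeneity of real truncating-variant spectra so that no
    genuinely pathogenic variant recurs often enough to look like a
    cohort-level artefact."""

    # CDS offsets reserved for the fixed catalogue entries and offsets where
    # a single-base deletion's VCF anchor would cross an exon boundary
    _RESERVED = {0, 1, 99, 100, 101, 199, STOP_SNV_OFFSET, FRAMESHIFT_OFFSET,
                 FRAMESHIFT_OFFSET + 30, FRAMESHIFT_OFFSET + 33}

    def __init__(self, tx: TranscriptModel, rng: np.random.Generator) -> None:
        from Bio.Seq import Seq

        self.tx = tx
        fs_pool = [o for o in range(2, 199) if o not in self._RESERVED]
        rng.shuffle(fs_pool)
        self._fs_pool = fs_pool
        mis_pool = []
        for codon_idx in range(1, 65):
            if codon_idx in (10, 45):
                continue
            codon = tx.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3]
            aa = str(Seq(codon).translate())
            for b in "ACGT":
                if b == codon[1]:
                    continue
                new = codon[0] + b + codon[2]
                if new in _STOPS or str(Seq(new).translate()) == aa:
                    continue
                mis_pool.append((codon_idx * 3 + 1, b))
                break
        rng.shuffle(mis_pool)
        self._mis_pool = mis_pool

    def next_frameshift(self) -> VariantKey:
        if not self._fs_pool:
            raise RuntimeError(f"frameshift site pool exhausted for {self.tx.gene}")
        return _del1_key(self.tx, self._fs_pool.pop())

    def next_missense(self) -> VariantKey:
        if self._mis_pool:
            off, alt = self._mis_pool.pop()
            return _snv_key(self.tx, off, alt)
        # overflow: fall back to a private frameshift (still one carrier,
        # still classified by its ClinVar record)
        return self.next_frameshift()


@dataclass
class CallBundle:
    calls: list[VariantCall]
    secondary_keys: dict[str, set[VariantKey]]  # second caller, elderly arm
    planted: pd.DataFrame  # artefact audit table: subject, key, trap
    locus_pass_fractions: dict[tuple[str, int], float]  # coverage sidecar


def assign_calls(
    pop: SyntheticPopulation,
    catalogue: VariantCatalogue,
    seed: int | None = None,
) -> CallBundle:
    """Turn ground-truth carrier states into per-subject variant calls with
    platform-dependent depth/VAF, plus all configured artefact spike-ins."""
    config = pop.config
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    genes = list(pop.carrier.columns)
    platform_of: dict[str, Platform] = {}
    for s in pop.subjects:
        if s.study is Study.ASPREE:
            platform_of[s.subject_id] = Platform.AmpliSeq
        else:
            platform_of[s.subject_id] = (
                Platform.HiPlex if rng.random() < 0.6 else Platform.HaloPlexHS
            )

    def call_metrics(platform: Platform):
        mean = {Platform.HiPlex: 160, Platform.HaloPlexHS: 90, Platform.AmpliSeq: 130}[platform]
        depth = max(int(rng.poisson(mean)), 51 if platform is not Platform.HaloPlexHS else 31)
        vaf = float(np.clip(rng.normal(0.5, 0.06), 0.25, 0.85))
        return depth, vaf

    calls: list[VariantCall] = []
    planted_rows: list[dict] = []

    def add_call(sid: str, cv: CatalogueVariant, depth=None, vaf=None):
        d, v = call_metrics(platform_of[sid])
        calls.append(
            VariantCall(
                subject_id=sid, key=cv.key, gene=cv.gene,
                depth=depth if depth is not None else d,
                vaf=vaf if vaf is not None else v,
                platform=platform_of[sid],
            )
        )

    aspree_ids = [s.subject_id for s in pop.subjects
                  if s.study is Study.ASPREE and s.sex is Sex.F]
    aspree_set = set(aspree_ids)
    abcfs_ids = [s.subject_id for s in pop.subjects if s.study is Study.ABCFS]
    spikes = config.spikes

    # true carriers: one *private* pathogenic variant each.  Only the
    # designated recurrent variant (a c.1100delC-like conflicting frameshift
    # in CHEK2) is shared, and its elderly-arm carrier count is capped below
    # the cohort-frequency threshold so the artefact filter never touches a
    # genuine pathogenic variant.
    sites = {g: _PrivateSites(catalogue.transcripts[g], rng)
             for g in genes if g in catalogue.transcripts}

    def private_call(sid: str, gene: str, category: str) -> None:
        pool = sites[gene]
        if category == "plp_missense":
            key = pool.next_missense()
            catalogue.classification[key] = ClassificationRecord(
                key, Significance.LikelyPathogenic, n_plp_submissions=2
            )
        elif category == "conflicting_fs":
            key = pool.next_frameshift()
            catalogue.classification[key] = ClassificationRecord(
                key, Significance.Conflicting, n_plp_submissions=3, n_blb_submissions=1
            )
        elif category == "mutyh_plp":
            key = pool.next_missense()
            catalogue.classification[key] = ClassificationRecord(
                key, Significance.Pathogenic, n_plp_submissions=3
            )
        else:  # novel_frameshift: absent from the classification table
            key = pool.next_frameshift()
        add_call(sid, CatalogueVariant(key, gene, category))

    shared_cv = catalogue.get("CHEK2", "conflicting_fs") if "CHEK2" in genes else None
    shared_budget = int(math.floor(spikes.shared_variant_cohort_cap * max(len(aspree_ids), 1)))
    shared_used_aspree = 0
    for gene in genes:
        if gene not in sites:
            continue
        if gene == "MUTYH":
            for sid in pop.true_carriers(gene):
                private_call(sid, gene, "mutyh_plp")
                planted_rows.append({"subject_id": sid, "gene": gene,
                                     "trap": "mutyh_monoallelic", "key": ""})
            continue
        for sid in pop.true_carriers(gene):
            if gene == "CHEK2" and shared_cv is not None:
                if sid in aspree_set:
                    if shared_used_aspree < shared_budget and rng.random() < 0.3:
                        shared_used_aspree += 1
                        add_call(sid, shared_cv)
                        continue
                elif rng.random() < 0.5:
                    add_call(sid, shared_cv)
                    continue
                cat = ("conflicting_fs", "plp_missense", "novel_frameshift")[
                    int(rng.integers(0, 3))
                ]
            else:
                cat = "plp_missense" if rng.random() < 0.5 else "novel_frameshift"
            private_call(sid, gene, cat)

    def plant(ids, cv: CatalogueVariant, trap: str, **kw):
        for sid in ids:
            add_call(sid, cv, **kw)
            planted_rows.append(
                {"subject_id": sid, "gene": cv.gene, "trap": trap, "key": str(cv.key)}
            )

    # cohort-frequency artefact across the elderly arm
    n_artifact = max(int(round(spikes.common_artifact_freq * len(aspree_ids))), 0)
    if n_artifact:
        ids = rng.choice(aspree_ids, size=n_artifact, replace=False)
        plant(ids, catalogue.get(genes[1], "artifact"), "cohort_frequency")
    # low-call-rate locus: the variant itself is rare and clean, but the
    # coverage sidecar reports that <95% of genotype calls at the site
    # passed QC, so the call-rate rule removes it
    locus_pass_fractions: dict[tuple[str, int], float] = {}
    if spikes.low_callrate_subjects:
        # keep the variant itself under the cohort-frequency cap so only the
        # call-rate rule can remove it
        cap = max(int(math.floor(spikes.shared_variant_cohort_cap * len(aspree_ids))), 1)
        n = min(spikes.low_callrate_subjects, cap, len(aspree_ids))
        ids = rng.choice(aspree_ids, size=n, replace=False)
        cv = catalogue.get(genes[2], "lowcall")
        plant(ids, cv, "locus_call_rate")
        locus_pass_fractions[(cv.key.chrom, cv.key.pos)] = spikes.low_callrate_pass_fraction
    # depth-49 HiPlex call(s): would otherwise be a pathogenic PTV
    hiplex_ids = [sid for sid in abcfs_ids if platform_of[sid] is Platform.HiPlex]
    if spikes.n_low_depth_calls:
        ids = rng.choice(hiplex_ids, size=spikes.n_low_depth_calls, replace=False)
        plant(ids, catalogue.get(genes[0], "novel_stop"), "platform_qc", depth=49)
    # off-target calls
    if spikes.n_offtarget_calls:
        ids = rng.choice(abcfs_ids, size=spikes.n_offtarget_calls, replace=False)
        plant(ids, catalogue.get(genes[3], "offtarget"), "region_restriction")
    # caller-discordant calls in the elderly arm (primary caller only)
    discordant_ids: set[str] = set()
    if spikes.n_caller_discordant:
        ids = rng.choice(aspree_ids, size=spikes.n_caller_discordant, replace=False)
        discordant_ids = set(ids)
        plant(ids, catalogue.get(genes[4], "caller_discordant"), "caller_intersection")
    # classifier traps
    if spikes.n_last_exon_ptv:
        ids = rng.choice(abcfs_ids, size=spikes.n_last_exon_ptv, replace=False)
        for sid in ids:
            gene = genes[int(rng.integers(0, len(genes)))]
            plant([sid], catalogue.get(gene, "last_exon_fs"), "last_exon_ptv")
    if spikes.n_benign_ptv:
        ids = rng.choice(abcfs_ids, size=spikes.n_benign_ptv, replace=False)
        plant(ids, catalogue.get(genes[0], "benign_stop"), "clinvar_benign")
    if spikes.n_common_maf:
        ids = rng.choice(abcfs_ids, size=spikes.n_common_maf, replace=False)
        for sid in ids:
            gene = genes[int(rng.integers(0, len(genes)))]
            plant([sid], catalogue.get(gene, "common_missense"), "not_rare")

    # second caller over the elderly arm: agrees everywhere except the
    # caller-discordant spike-ins
    secondary: dict[str, set[VariantKey]] = {sid: set() for sid in aspree_ids}
    discordant_key = catalogue.get(genes[4], "caller_discordant").key
    for c in calls:
        if c.subject_id in secondary:
            if c.subject_id in discordant_ids and c.key == discordant_key:
                continue
            secondary[c.subject_id].add(c.key)
    return CallBundle(
        calls=calls,
        secondary_keys=secondary,
        planted=pd.DataFrame(planted_rows,
                             columns=["subject_id", "gene", "trap", "key"]),
        locus_pass_fractions=locus_pass_fractions,
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_vcf(path: Path, subject_id: str, calls: Sequence[VariantCall],
              chrom_order: Mapping[str, int]) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Variant allele fraction">',
    ]
    for chrom in sorted({c.key.chrom for c in calls}, key=lambda c: chrom_order.get(c, 999)):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + subject_id
    )
    for c in sorted(calls, key=lambda c: (chrom_order.get(c.key.chrom, 999), c.key.pos)):
        info = f"GENE={c.gene}" if c.gene else "."
        lines.append(
            f"{c.key.chrom}\t{c.key.pos}\t.\t{c.key.ref}\t{c.key.alt}\t.\tPASS\t"
            f"{info}\tGT:DP:AF\t0/1:{c.depth}:{c.vaf:.4f}"
        )
    path.write_text("\n".join(lines) + "\n")


def emit_study_files(
    pop: SyntheticPopulation,
    bundle: CallBundle,
    catalogue: VariantCatalogue,
    outdir: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write the complete study bundle: per-subject VCFs, three panel BEDs,
    transcript/classification/frequency tables, the phenotype CSV and a
    ground-truth TSV (for test harnesses, not a pipeline input)."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty (pass overwrite=True)")
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    chrom_order = {f"chr{i + 1}": i for i in range(len(catalogue.transcripts))}

    by_subject: dict[str, list[VariantCall]] = {}
    for c in bundle.calls:
        by_subject.setdefault(c.subject_id, []).append(c)
    platforms: dict[str, str] = {}
    for sid, subject_calls in by_subject.items():
        platforms[sid] = subject_calls[0].platform.value
        write_vcf(outdir / "vcf" / f"{sid}.vcf", sid, subject_calls, chrom_order)
    pd.DataFrame(
        [{"subject_id": sid, "platform": p} for sid, p in sorted(platforms.items())]
    ).to_csv(outdir / "platforms.tsv", sep="\t", index=False)

    for panel in make_panels(list(catalogue.transcripts)):
        with open(outdir / f"panel_{panel.name}.bed", "w") as fh:
            for chrom in sorted(panel.regions, key=lambda c: chrom_order.get(c, 999)):
                for start, end in panel.regions[chrom]:
                    fh.write(f"{chrom}\t{start}\t{end}\n")

    write_transcripts(catalogue.transcripts.values(), outdir / "transcripts.tsv")
    write_classification_table(
        catalogue.classification.values(), outdir / "classification.tsv"
    )
    write_frequency_table(catalogue.frequency, outdir / "frequency.tsv")
    write_phenotypes(pop.subjects, outdir / "phenotypes.csv")

    truth_rows = []
    for sid in pop.carrier.index:
        for gene in pop.carrier.columns:
            if pop.carrier.loc[sid, gene]:
                truth_rows.append(
                    {"subject_id": sid, "gene": gene, "carrier": 1,
                     "true_or": pop.config.true_or.get(gene, 1.0)}
                )
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    bundle.planted.to_csv(outdir / "planted_artifacts.tsv", sep="\t", index=False)
    secondary_rows = [
        {"subject_id": sid, "keys": ";".join(str(k) for k in sorted(keys))}
        for sid, keys in sorted(bundle.secondary_keys.items())
    ]
    pd.DataFrame(secondary_rows).to_csv(
        outdir / "secondary_calls.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"chrom": c, "pos": p, "pass_fraction": f}
         for (c, p), f in sorted(bundle.locus_pass_fractions.items())]
    ).to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    return {
        "vcf_dir": outdir / "vcf",
        "phenotypes": outdir / "phenotypes.csv",
        "transcripts": outdir / "transcripts.tsv",
        "classification": outdir / "classification.tsv",
        "frequency": outdir / "frequency.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }


# ---------------------------------------------------------------------------
# Printed-table fixture
# ---------------------------------------------------------------------------

# per-gene carrier counts as printed: (case carriers, control carriers)
PUBLISHED_CARRIER_COUNTS: dict[str, tuple[int, int]] = {
    "ATM": (17, 25), "BARD1": (3, 3), "BRCA1": (46, 6), "BRCA2": (43, 21),
    "BRIP1": (8, 13), "CDH1": (1, 0), "CHEK2": (19, 35), "FANCM": (3, 19),
    "MLH1": (0, 0), "MRE11A": (0, 5), "MSH2": (0, 1), "MSH6": (3, 3),
    "MUTYH": (0, 0), "NBN": (1, 11), "NF1": (2, 4), "PALB2": (7, 10),
    "PMS2": (0, 0), "PTEN": (0, 1), "RAD50": (2, 11), "RAD51C": (0, 4),
    "RAD51D": (1, 4), "RECQL": (0, 0), "STK11": (0, 0), "TP53": (6, 1),
}

FIXTURE_N_CASES = 1464
FIXTURE_N_ABCFS_CONTROLS = 862
FIXTURE_N_ASPREE_CONTROLS = 6549
_FIXTURE_ABCFS_CONTROL_CARRIERS = 32  # of 177 control carriers overall


def _split_control_carriers() -> dict[str, tuple[int, int]]:
    """Deterministically split each gene's control carriers between the
    age-matched and elderly arms (largest-remainder apportionment of the
    age-matched arm's 32 carriers)."""
    total_controls = sum(c for _, c in PUBLISHED_CARRIER_COUNTS.values())
    target = _FIXTURE_ABCFS_CONTROL_CARRIERS
    quotas = {
        g: c * target / total_controls for g, (_, c) in PUBLISHED_CARRIER_COUNTS.items()
    }
    floors = {g: int(math.floor(q)) for g, q in quotas.items()}
    leftover = target - sum(floors.values())
    by_rem = sorted(quotas, key=lambda g: (-(quotas[g] - floors[g]), g))
    for g in by_rem[:leftover]:
        floors[g] += 1
    return {
        g: (floors[g], PUBLISHED_CARRIER_COUNTS[g][1] - floors[g]) for g in PUBLISHED_CARRIER_COUNTS
    }


def published_counts_fixture() -> "CarrierMatrix":
    """Deterministic analysis-ready carrier matrix reproducing the printed
    per-gene carrier counts (1464 cases, 862 age-matched controls, 6549
    elderly controls; each carrier carries exactly one gene).

    Ages are deterministic spreads around the arm medians so descriptive
    summaries are well defined; no other covariates are filled in.
    """
    from .carriers import CarrierMatrix, CarrierPolicy, ExclusionLedger
    from .classify import PathogenicityCall, Reason

    split = _split_control_carriers()
    subjects: list[Subject] = []
    pairs: list[tuple[str, PathogenicityCall]] = []
    genes = tuple(PUBLISHED_CARRIER_COUNTS)

    def age_seq(n: int, median: float, spread: float):
        # symmetric deterministic spread: median +/- up to `spread`
        return [
            round(median + spread * ((2.0 * i / max(n - 1, 1)) - 1.0), 1)
            for i in range(n)
        ]

    def add_arm(prefix: str, n: int, study: Study, status: CaseStatus,
                counts: Mapping[str, int], median_age: float):
        ages = age_seq(n, median_age, 8.0)
        assignments: list[str | None] = []
        for g in genes:
            assignments.extend([g] * counts.get(g, 0))
        if len(assignments) > n:
            raise ValueError("carrier counts exceed arm size")
        assignments.extend([None] * (n - len(assignments)))
        for i in range(n):
            sid = f"{prefix}{i + 1:05d}"
            subjects.append(
                Subject(subject_id=sid, study=study, sex=Sex.F, case_status=status,
                        age=ages[i])
            )
            gene = assignments[i]
            if gene is not None:
                tx_chrom = f"chr{list(genes).index(gene) + 1}"
                key = VariantKey(tx_chrom, 100_001 + i, "A", "T")
                pairs.append(
                    (sid, PathogenicityCall(key, gene, True, Reason.clinvar_plp, False))
                )

    add_arm("CASE", FIXTURE_N_CASES, Study.ABCFS, CaseStatus.case,
            {g: c for g, (c, _) in PUBLISHED_CARRIER_COUNTS.items()}, 40.0)
    add_arm("ABCN", FIXTURE_N_ABCFS_CONTROLS, Study.ABCFS, CaseStatus.control,
            {g: a for g, (a, _) in split.items()}, 39.4)
    add_arm("ASPN", FIXTURE_N_ASPREE_CONTROLS, Study.ASPREE, CaseStatus.control,
            {g: b for g, (_, b) in split.items()}, 74.0)

    from .carriers import build_carrier_matrix

    return build_carrier_matrix(subjects, pairs, CarrierPolicy(genes=genes))


# ---------------------------------------------------------------------------
# Estimator validation studies on synthetic cohorts
# ---------------------------------------------------------------------------

# the benchmark scenario: a four-gene panel spanning strong, moderate and
# null effects at study-like carrier frequencies and arm sizes
RECOVERY_GENES = ("BRCA1", "BRCA2", "ATM", "CHEK2")
RECOVERY_TRUE_OR = {"BRCA1": 5.0, "BRCA2": 4.0, "ATM": 3.5, "CHEK2": 1.0}
RECOVERY_FREQ = {"BRCA1": 0.002, "BRCA2": 0.004, "ATM": 0.004, "CHEK2": 0.006}


def or_recovery_study(
    n_replicates: int = 100,
    seed: int = 0,
    n_cases: int = 1500,
    n_abcfs_controls: int = 850,
    n_aspree_controls: int = 6500,
) -> pd.DataFrame:
    """Repeatedly simulate the study design and refit per-gene odds ratios.

    For each replicate and gene, records the unadjusted and age-adjusted
    estimates with Wald CIs, plus the age-adjusted estimate after dropping
    the elderly control arm (the design-validation sensitivity analysis).
    Returns one row per replicate x gene x model.
    """
    from .association import AdjustmentSet, fit_gene_or, run_sensitivity

    rows = []
    for rep in range(n_replicates):
        cfg = SyntheticConfig(
            n_cases=n_cases,
            n_abcfs_controls=n_abcfs_controls,
            n_aspree_controls=n_aspree_controls,
            genes=RECOVERY_GENES,
            carrier_freq=dict(RECOVERY_FREQ),
            true_or=dict(RECOVERY_TRUE_OR),
            seed=(seed + rep) % 2**31,
        )
        table = population_to_analysis_table(generate_population(cfg))
        fits = {
            "unadjusted": [
                fit_gene_or(table, g, AdjustmentSet.unadjusted) for g in RECOVERY_GENES
            ],
            "age_adjusted": [
                fit_gene_or(table, g, AdjustmentSet.age_only) for g in RECOVERY_GENES
            ],
            "age_adjusted_no_elderly": run_sensitivity(
                table, RECOVERY_GENES, "exclude_aspree", AdjustmentSet.age_only
            ),
        }
        for model, results in fits.items():
            for res in results:
                rows.append(
                    {
                        "replicate": rep,
                        "gene": res.gene,
                        "model": model,
                        "true_or": RECOVERY_TRUE_OR[res.gene],
                        "estimable": res.estimable,
                        "or": res.odds_ratio,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p": res.p_value,
                    }
                )
    return pd.DataFrame(rows)


def type_one_error_study(
    n_replicates: int = 1000,
    seed: int = 0,
    n_cases: int = 400,
    n_abcfs_controls: int = 300,
    n_aspree_controls: int = 300,
    carrier_freq: float = 0.05,
    alpha: float = 0.05,
) -> dict:
    """Null-gene calibration: simulate a risk-neutral gene (true OR 1) on
    small cohorts and count likelihood-ratio rejections at ``alpha``."""
    from .association import AdjustmentSet, fit_gene_or

    rejections = 0
    n_estimable = 0
    for rep in range(n_replicates):
        cfg = SyntheticConfig(
            n_cases=n_cases,
            n_abcfs_controls=n_abcfs_controls,
            n_aspree_controls=n_aspree_controls,
            genes=("NULLGENE",),
            carrier_freq={"NULLGENE": carrier_freq},
            true_or={"NULLGENE": 1.0},
            spikes=SpikeIns(n_multigene=0, n_males=0, n_aspree_prior_bc=0),
            seed=(seed + rep) % 2**31,
        )
        table = population_to_analysis_table(generate_population(cfg))
        res = fit_gene_or(table, "NULLGENE", AdjustmentSet.age_only)
        if res.estimable:
            n_estimable += 1
            rejections += res.p_value < alpha
    return {
        "n_replicates": n_replicates,
        "n_estimable": n_estimable,
        "n_rejections": rejections,
        "rejection_rate": rejections / max(n_estimable, 1),
        "alpha": alpha,
    }
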