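"""Platform-specific QC, multi-panel region harmonisation and cohort-level
artefact filters.

The harmonisation pipeline runs in a fixed order:

1. platform QC — per-platform depth and allele-fraction thresholds
   (inclusive: a call passes at exactly the threshold);
2. restriction to the intersection of the three panels' target regions;
3. optional per-subject caller intersection (keys called by a second
   variant caller, for the cohorts where two callers were run);
4. cohort-frequency filter — variants seen in more than a set fraction of
   all scoped-cohort participants are treated as sequencing artefacts or
   too common to drive risk, and removed;
5. locus call-rate filter — variant sites where fewer than a set fraction
   of the scoped cohort's genotype calls passed QC are removed entirely.

Filters 4 and 5 are computed on, and applied to, a configurable cohort
scope (by default the elderly-control arm only, matching the design where
those samples were sequenced on a separate platform).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .data_io import PanelDesign, Platform, Study, VariantCall, VariantKey, merge_intervals

log = logging.getLogger("panelburden.qc")

DEFAULT_THRESHOLDS: dict[Platform, tuple[int, float]] = {
    Platform.HiPlex: (50, 0.20),
    Platform.AmpliSeq: (50, 0.20),
    Platform.HaloPlexHS: (30, 0.15),
}


@dataclass
class QCPolicy:
    """Thresholds for the harmonisation pipeline.

    ``thresholds`` maps platform -> (min_depth, min_vaf), both inclusive.
    ``cohort_freq_max`` is the maximum fraction of scoped-cohort
    participants that may carry a variant (strictly-greater frequencies are
    removed).  ``min_locus_call_rate`` is the minimum fraction of QC-passing
    genotype calls at a site.  ``cohort_filter_scope`` lists the studies the
    two cohort-level filters are computed on and applied to.
    """

    thresholds: dict[Platform, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    cohort_freq_max: float = 0.0005
    min_locus_call_rate: float = 0.95
    cohort_filter_scope: tuple[Study, ...] = (Study.ASPREE,)

    def __post_init__(self) -> None:
        for platform, (min_depth, min_vaf) in self.thresholds.items():
            if min_depth <= 0 or not 0.0 < min_vaf < 1.0:
                raise ValueError(f"invalid thresholds for {platform}: {min_depth}, {min_vaf}")
        if not 0.0 < self.cohort_freq_max <= 1.0:
            raise ValueError(f"cohort_freq_max out of (0,1]: {self.cohort_freq_max}")
        if not 0.0 < self.min_locus_call_rate <= 1.0:
            raise ValueError(
                f"min_locus_call_rate out of (0,1]: {self.min_locus_call_rate}"
            )


@dataclass
class AttritionStep:
    step: str
    n_in: int
    n_out: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


def apply_platform_qc(
    calls: Iterable[VariantCall], policy: QCPolicy
) -> list[VariantCall]:
    """Set ``qc_pass`` on every call; nothing is removed at this stage."""
    out = []
    for call in calls:
        if call.platform not in policy.thresholds:
            raise ValueError(f"no QC thresholds configured for platform {call.platform}")
        min_depth, min_vaf = policy.thresholds[call.platform]
        call.qc_pass = call.depth >= min_depth and call.vaf >= min_vaf
        out.append(call)
    return out


def intersect_panels(panels: Sequence[PanelDesign]) -> PanelDesign:
    """Set-intersection of the panels' merged target regions."""
    if not panels:
        raise ValueError("need at least one panel")
    result = panels[0].regions
    for panel in panels[1:]:
        result = _intersect_region_maps(result, panel.regions)
    name = "&".join(p.name for p in panels)
    return PanelDesign(name, {c: iv for c, iv in result.items() if iv})


def _intersect_region_maps(
    a: Mapping[str, list[tuple[int, int]]], b: Mapping[str, list[tuple[int, int]]]
) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in set(a) & set(b):
        ivs = []
        for s1, e1 in a[chrom]:
            for s2, e2 in b[chrom]:
                lo, hi = max(s1, s2), min(e1, e2)
                if lo < hi:
                    ivs.append((lo, hi))
        if ivs:
            out[chrom] = merge_intervals(ivs)
    return out


def restrict_to_regions(
    calls: Iterable[VariantCall], regions: PanelDesign
) -> list[VariantCall]:
    """Keep calls whose (1-based) position falls inside a target region."""
    return [c for c in calls if regions.contains(c.key.chrom, c.key.pos - 1)]


def cohort_frequency_filter(
    carriers_by_key: Mapping[VariantKey, set[str]],
    n_participants: int,
    cohort_freq_max: float,
) -> set[VariantKey]:
    """Keys surviving the common-artefact filter.

    A key survives iff carriers/n_participants <= cohort_freq_max; removal
    is strict ("more than" the threshold).
    """
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    return {
        key
        for key, subjects in carriers_by_key.items()
        if len(subjects) / n_participants <= cohort_freq_max
    }


def locus_call_rate_filter(
    pass_fraction_by_locus: Mapping[tuple[str, int], float],
    min_locus_call_rate: float,
) -> set[tuple[str, int]]:
    """Loci surviving the call-rate filter: pass fraction >= threshold."""
    for locus, frac in pass_fraction_by_locus.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"pass fraction out of [0,1] at {locus}: {frac}")
    return {
        locus
        for locus, frac in pass_fraction_by_locus.items()
        if frac >= min_locus_call_rate
    }


@dataclass
class HarmonisationResult:
    calls: list[VariantCall]
    attrition: list[AttritionStep]
    removed_common_keys: set[VariantKey]
    removed_loci: set[tuple[str, int]]


def harmonise_callsets(
    calls: Sequence[VariantCall],
    policy: QCPolicy,
    panels: Sequence[PanelDesign],
    study_by_subject: Mapping[str, Study],
    n_scope_participants: int | None = None,
    secondary_keys_by_subject: Mapping[str, set[VariantKey]] | None = None,
    locus_pass_fractions: Mapping[tuple[str, int], float] | None = None,
) -> HarmonisationResult:
    """Run the full fixed-order harmonisation pipeline.

    ``study_by_subject`` assigns each subject to a study arm so the
    cohort-level filters can be restricted to ``policy.cohort_filter_scope``.
    ``n_scope_participants`` is the denominator for the cohort-frequency
    filter (all sequenced participants in scope, defaulting to the number of
    scoped subjects appearing in ``study_by_subject``).
    ``secondary_keys_by_subject``, when given, holds each subject's key set
    from a second variant caller; scoped subjects present in this mapping
    keep only keys called by both callers.
    ``locus_pass_fractions`` optionally supplies per-locus QC pass rates
    from coverage data; entries override the rates derived from the variant
    calls themselves (variant calls alone cannot see reference genotypes).
    """
    attrition: list[AttritionStep] = []

    def scoped(call: VariantCall) -> bool:
        return study_by_subject.get(call.subject_id) in policy.cohort_filter_scope

    # 1. platform QC: flag, then drop failing calls
    flagged = apply_platform_qc(list(calls), policy)
    passed = [c for c in flagged if c.qc_pass]
    attrition.append(AttritionStep("platform_qc", len(flagged), len(passed)))

    # 2. region restriction to the panel intersection; locus call rates are
    # computed here, from all flagged in-region scoped calls, before any
    # cohort-level removal
    target = intersect_panels(panels) if panels else None
    if target is not None:
        in_region = restrict_to_regions(passed, target)
        flagged_in_region = restrict_to_regions(flagged, target)
    else:
        in_region, flagged_in_region = passed, flagged
    attrition.append(AttritionStep("region_restriction", len(passed), len(in_region)))

    # 3. caller intersection (scoped subjects with a secondary call set)
    if secondary_keys_by_subject is not None:
        kept = []
        for c in in_region:
            if scoped(c) and c.subject_id in secondary_keys_by_subject:
                if c.key in secondary_keys_by_subject[c.subject_id]:
                    kept.append(c)
            else:
                kept.append(c)
    else:
        kept = in_region
    attrition.append(AttritionStep("caller_intersection", len(in_region), len(kept)))

    # 4. cohort-frequency filter on scoped calls
    carriers: dict[VariantKey, set[str]] = {}
    for c in kept:
        if scoped(c):
            carriers.setdefault(c.key, set()).add(c.subject_id)
    if n_scope_participants is None:
        n_scope_participants = sum(
            1 for st in study_by_subject.values() if st in policy.cohort_filter_scope
        )
    if carriers and n_scope_participants > 0:
        log.info(
            "cohort-frequency filter: threshold %.4g of %d participants "
            "(implied max carriers per variant: %d)",
            policy.cohort_freq_max, n_scope_participants,
            math.floor(policy.cohort_freq_max * n_scope_participants),
        )
        surviving = cohort_frequency_filter(
            carriers, n_scope_participants, policy.cohort_freq_max
        )
        removed_common = set(carriers) - surviving
    else:
        removed_common = set()
    after_freq = [
        c for c in kept if not (scoped(c) and c.key in removed_common)
    ]
    attrition.append(AttritionStep("cohort_frequency", len(kept), len(after_freq)))

    # 5. locus call-rate filter: fraction of scoped genotype calls at each
    # variant site that passed platform QC
    locus_counts: dict[tuple[str, int], list[int]] = {}
    for c in flagged_in_region:
        if scoped(c):
            n_pass, n_all = locus_counts.setdefault((c.key.chrom, c.key.pos), [0, 0])
            locus_counts[(c.key.chrom, c.key.pos)] = [n_pass + bool(c.qc_pass), n_all + 1]
    pass_fracs = {
        locus: n_pass / n_all for locus, (n_pass, n_all) in locus_counts.items() if n_all
    }
    if locus_pass_fractions:
        pass_fracs.update(locus_pass_fractions)
    surviving_loci = locus_call_rate_filter(pass_fracs, policy.min_locus_call_rate)
    removed_loci = set(pass_fracs) - surviving_loci
    final = [
        c
        for c in after_freq
        if not (scoped(c) and (c.key.chrom, c.key.pos) in removed_loci)
    ]
    attrition.append(AttritionStep("locus_call_rate", len(after_freq), len(final)))

    return HarmonisationResult(
        calls=final,
        attrition=attrition,
        removed_common_keys=removed_common,
        removed_loci=removed_loci,
    )


def write_attrition_log(attrition: Sequence[AttritionStep], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"step": a.step, "n_in": a.n_in, "n_out": a.n_out} for a in attrition]
    ).to_csv(path, sep="\t", index=False)
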