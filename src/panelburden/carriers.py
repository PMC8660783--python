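"""Carrier-matrix construction, subject-level exclusions and descriptive
tabulation of the case/control arms.

Subject-level exclusions are applied in a fixed order and recorded in an
exclusion ledger (each subject is removed by exactly one rule):

1. males;
2. elderly-cohort (ASPREE) women with a prior breast cancer diagnosis;
3. subjects with no gene-panel data;
4. women with pathogenic variants in two or more genes (main analysis
   only; re-admitted in the multi-gene sensitivity analysis).

MUTYH is handled recessively: carrier status requires two or more distinct
pathogenic MUTYH variants; mono-allelic carriers are demoted to
non-carriers but logged.  MUTYH does not count towards the multi-gene rule
unless the bi-allelic proxy is met.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import PathogenicityCall
from .data_io import CaseStatus, PANEL_GENES, Sex, Study, Subject, round_half_up


@dataclass
class CarrierPolicy:
    """Knobs for :func:`build_carrier_matrix`.

    ``include_multigene`` re-admits women carrying pathogenic variants in
    two or more genes (the sensitivity analysis); the main analysis excludes
    them.  ``recessive_gene`` names the gene whose risk is recessive, so
    carrier status requires two or more distinct pathogenic variants
    (bi-allelic proxy; phase is unknowable from the call data).
    """

    genes: tuple[str, ...] = field(default_factory=lambda: PANEL_GENES)
    include_multigene: bool = False
    recessive_gene: str = "MUTYH"


@dataclass
class ExclusionLedger:
    """Ordered record of subject-level removals plus MUTYH demotions."""

    entries: list[tuple[str, int, list[str]]] = field(default_factory=list)
    mutyh_monoallelic: list[str] = field(default_factory=list)

    def add(self, rule: str, subject_ids: Sequence[str]) -> None:
        self.entries.append((rule, len(subject_ids), sorted(subject_ids)))

    @property
    def n_excluded(self) -> int:
        return sum(n for _, n, _ in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"rule": rule, "n_removed": n, "subject_ids": ";".join(ids)}
                for rule, n, ids in self.entries
            ]
        )


@dataclass
class CarrierMatrix:
    """Analysis-ready subject x gene carrier status."""

    subjects: list[Subject]
    genes: tuple[str, ...]
    carrier: pd.DataFrame  # bool, index subject_id, columns genes
    variants_by_subject: dict[str, list[PathogenicityCall]]
    ledger: ExclusionLedger

    def carried_genes(self, subject_id: str) -> list[str]:
        row = self.carrier.loc[subject_id]
        return [g for g in self.genes if row[g]]


def build_carrier_matrix(
    subjects: Sequence[Subject],
    pathogenic_calls: Iterable[tuple[str, PathogenicityCall]],
    policy: CarrierPolicy | None = None,
    tested_subjects: set[str] | None = None,
) -> CarrierMatrix:
    """Construct the carrier matrix and exclusion ledger.

    ``pathogenic_calls`` are (subject_id, call) pairs from the classifier;
    only calls with a pathogenic verdict contribute.  ``tested_subjects``
    lists subjects with gene-panel data (default: all).
    """
    policy = policy or CarrierPolicy()
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")

    # distinct pathogenic variants per subject x gene
    variants: dict[str, dict[str, set]] = {}
    calls_by_subject: dict[str, list[PathogenicityCall]] = {}
    for sid, call in pathogenic_calls:
        if call.pathogenic:
            variants.setdefault(sid, {}).setdefault(call.gene, set()).add(call.key)
            calls_by_subject.setdefault(sid, []).append(call)

    ledger = ExclusionLedger()
    remaining = list(subjects)

    def exclude(rule: str, pred) -> None:
        nonlocal remaining
        removed = [s for s in remaining if pred(s)]
        ledger.add(rule, [s.subject_id for s in removed])
        remaining = [s for s in remaining if not pred(s)]

    exclude("males", lambda s: s.sex is Sex.M)
    exclude(
        "aspree_prior_breast_cancer",
        lambda s: s.study is Study.ASPREE and s.prior_breast_cancer is True,
    )
    if tested_subjects is not None:
        exclude("no_panel_data", lambda s: s.subject_id not in tested_subjects)
    else:
        ledger.add("no_panel_data", [])

    _carrier_cache: dict[str, set[str]] = {}

    def gene_carrier_set(sid: str) -> set[str]:
        """Genes with carrier status, MUTYH under the bi-allelic proxy."""
        if sid in _carrier_cache:
            return _carrier_cache[sid]
        per_gene = variants.get(sid, {})
        out = set()
        for gene, keys in per_gene.items():
            if gene == policy.recessive_gene:
                if len(keys) >= 2:
                    out.add(gene)
            elif keys:
                out.add(gene)
        _carrier_cache[sid] = out
        return out

    if not policy.include_multigene:
        exclude("multi_gene_carriers", lambda s: len(gene_carrier_set(s.subject_id)) >= 2)
    else:
        ledger.add("multi_gene_carriers", [])

    # MUTYH demotion log (analysis-set subjects with exactly one distinct
    # pathogenic variant in the recessive gene)
    for s in remaining:
        keys = variants.get(s.subject_id, {}).get(policy.recessive_gene, set())
        if len(keys) == 1:
            ledger.mutyh_monoallelic.append(s.subject_id)

    genes = tuple(policy.genes)
    data = {
        g: [g in gene_carrier_set(s.subject_id) for s in remaining] for g in genes
    }
    carrier = pd.DataFrame(data, index=[s.subject_id for s in remaining], dtype=bool)
    return CarrierMatrix(
        subjects=remaining,
        genes=genes,
        carrier=carrier,
        variants_by_subject={
            s.subject_id: calls_by_subject.get(s.subject_id, []) for s in remaining
        },
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

ARMS = ("ASPREE_controls", "ABCFS_cases", "ABCFS_controls")


def _arm_of(subject: Subject) -> str:
    if subject.study is Study.ASPREE:
        return "ASPREE_controls"
    return "ABCFS_cases" if subject.case_status is CaseStatus.case else "ABCFS_controls"


def summarize_cohort(matrix: CarrierMatrix) -> dict[str, pd.DataFrame]:
    """Per-arm carrier counts/percentages and covariate medians/IQRs.

    Returns ``{"carriers": ..., "covariates": ...}``.  Percentages use the
    arm size as denominator and are rounded half-up to one decimal; an empty
    arm reports zero counts with an ``n=0`` flag (percentage 0).
    """
    by_arm: dict[str, list[Subject]] = {arm: [] for arm in ARMS}
    for s in matrix.subjects:
        by_arm[_arm_of(s)].append(s)

    carrier_rows = []
    brca = {"BRCA1", "BRCA2"}
    for arm in ARMS:
        members = by_arm[arm]
        n = len(members)
        idx = [s.subject_id for s in members]
        sub = matrix.carrier.loc[idx]

        def pct(count: int) -> float:
            return round_half_up(100.0 * count / n, 1) if n else 0.0

        any_gene = int(sub.any(axis=1).sum())
        non_brca_cols = [g for g in matrix.genes if g not in brca]
        non_brca = int(sub[non_brca_cols].any(axis=1).sum())
        row = {"arm": arm, "n": n, "any_gene": any_gene, "any_gene_pct": pct(any_gene),
               "non_brca12": non_brca, "non_brca12_pct": pct(non_brca)}
        for g in matrix.genes:
            count = int(sub[g].sum())
            row[g] = count
            row[f"{g}_pct"] = pct(count)
        carrier_rows.append(row)

    cov_rows = []
    for arm in ARMS:
        members = by_arm[arm]
        for name in ("age", "height", "bmi", "parity", "education", "alcohol"):
            vals = [getattr(s, name) for s in members if getattr(s, name) is not None]
            if vals:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                cov_rows.append(
                    {"arm": arm, "covariate": name, "median": float(med),
                     "iqr": float(q3 - q1), "n": len(vals)}
                )
            else:
                cov_rows.append(
                    {"arm": arm, "covariate": name, "median": float("nan"),
                     "iqr": float("nan"), "n": 0}
                )
    return {
        "carriers": pd.DataFrame(carrier_rows),
        "covariates": pd.DataFrame(cov_rows),
    }


@dataclass
class GroupComparison:
    variable: str
    group_a: str
    group_b: str
    estimate: float  # mean difference (continuous) or odds ratio (binary)
    ci_low: float
    ci_high: float
    p_value: float
    test: str
    mean_a: float | None = None
    ci_a: tuple[float, float] | None = None
    mean_b: float | None = None
    ci_b: tuple[float, float] | None = None


def compare_carrier_groups(
    matrix: CarrierMatrix,
    variable: str,
    group_genes: Iterable[str] = ("BRCA1", "BRCA2"),
) -> GroupComparison:
    """Compare BRCA1/2 carriers against carriers of the other panel genes,
    among cases only.

    ``variable`` is ``age`` (Welch two-sample t-test with group means and
    95% CIs) or ``family_history`` (chi-square, or Fisher's exact test when
    any expected cell count is below 5).
    """
    group_genes = set(group_genes) & set(matrix.genes)
    if not group_genes:
        raise ValueError("no grouping genes present in the carrier matrix")
    other_genes = [g for g in matrix.genes if g not in group_genes]
    a_vals, b_vals = [], []
    for s in matrix.subjects:
        if s.case_status is not CaseStatus.case:
            continue
        row = matrix.carrier.loc[s.subject_id]
        in_a = bool(row[list(group_genes)].any())
        in_b = bool(row[other_genes].any())
        if not (in_a or in_b):
            continue
        val = getattr(s, variable)
        if val is None:
            continue
        # multi-gene carriers spanning both groups go to the BRCA group
        (a_vals if in_a else b_vals).append(val)
    if not a_vals or not b_vals:
        raise ValueError(
            f"cannot compare {variable}: empty carrier group "
            f"(n_a={len(a_vals)}, n_b={len(b_vals)})"
        )
    label_a, label_b = "+".join(sorted(group_genes)), "other_genes"
    if variable == "family_history":
        a_yes, b_yes = sum(a_vals), sum(b_vals)
        table = np.array(
            [[a_yes, len(a_vals) - a_yes], [b_yes, len(b_vals) - b_yes]], dtype=float
        )
        expected = stats.contingency.expected_freq(table)
        odds = stats.contingency.odds_ratio(table.astype(int), kind="sample")
        ci = odds.confidence_interval(0.95)
        if (expected < 5).any():
            _, p = stats.fisher_exact(table.astype(int))
            test = "fisher_exact"
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
            test = "chi2"
        return GroupComparison(
            variable, label_a, label_b, float(odds.statistic),
            float(ci.low), float(ci.high), float(p), test,
        )
    # continuous: Welch t-test
    res = stats.ttest_ind(a_vals, b_vals, equal_var=False)
    diff = statistics.fmean(a_vals) - statistics.fmean(b_vals)
    se = np.sqrt(
        np.var(a_vals, ddof=1) / len(a_vals) + np.var(b_vals, ddof=1) / len(b_vals)
    )
    tcrit = stats.t.ppf(0.975, res.df)

    def group_ci(vals):
        m = statistics.fmean(vals)
        half = stats.t.ppf(0.975, len(vals) - 1) * np.sqrt(np.var(vals, ddof=1) / len(vals))
        return m, (m - half, m + half)

    mean_a, ci_a = group_ci(a_vals)
    mean_b, ci_b = group_ci(b_vals)
    return GroupComparison(
        variable, label_a, label_b, float(diff),
        float(diff - tcrit * se), float(diff + tcrit * se),
        float(res.pvalue), "welch_t",
        mean_a=mean_a, ci_a=ci_a, mean_b=mean_b, ci_b=ci_b,
    )
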