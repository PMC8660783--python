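"""Per-gene odds-ratio estimation by unconditional logistic regression.

For each gene the exposure is the carrier indicator; carriers of other
genes stay in the unexposed pool (multi-gene carriers are excluded
upstream in the main analysis, so overlap cannot occur).  Models are fit
by maximum likelihood; 95% confidence intervals are Wald intervals
``exp(beta +/- 1.96 * SE)`` and p-values come from the likelihood-ratio
test of the carrier term, with the reduced model refit on exactly the same
complete-case rows.  No multiple-testing correction is applied.

A gene is estimable only when at least one carrier is present among cases
and among controls (after complete-case filtering); otherwise no model is
fit and the result carries ``estimable=False``.  No penalised or exact
fallback is used for sparse tables — wide Wald intervals are reported as
fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .carriers import CarrierMatrix
from .data_io import CaseStatus, ERStatus, Study, Subject

Z95 = 1.959963984540054  # Phi^{-1}(0.975)

COVARIATES = ("age", "height", "bmi", "parity", "education", "alcohol")


class AdjustmentSet(str, Enum):
    """Confounder sets: none, age only, or the six study covariates."""

    unadjusted = "unadjusted"
    age_only = "age_only"
    full = "full"

    @property
    def covariates(self) -> tuple[str, ...]:
        if self is AdjustmentSet.unadjusted:
            return ()
        if self is AdjustmentSet.age_only:
            return ("age",)
        return COVARIATES


@dataclass
class ORResult:
    gene: str
    adjustment: AdjustmentSet
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    n_case_carriers: int
    n_control_carriers: int
    n_cases: int
    n_controls: int
    estimable: bool
    separation: bool = False
    mode: str = "main"

    @property
    def case_fraction(self) -> float | None:
        return self.n_case_carriers / self.n_cases if self.n_cases else None

    @property
    def control_fraction(self) -> float | None:
        return self.n_control_carriers / self.n_controls if self.n_controls else None


def build_analysis_table(matrix: CarrierMatrix) -> pd.DataFrame:
    """Flatten a carrier matrix into the analysis table used by the model
    fits: one row per subject with case status, covariates and one boolean
    ``carrier_<gene>`` column per gene."""
    rows = []
    for s in matrix.subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "study": s.study.value,
                "case": int(s.case_status is CaseStatus.case),
                "er_status": s.er_status.value,
                "age": s.age,
                "height": s.height,
                "bmi": s.bmi,
                "parity": s.parity,
                "education": s.education,
                "alcohol": s.alcohol,
            }
        )
    df = pd.DataFrame(rows).set_index("subject_id", drop=False)
    for g in matrix.genes:
        df[f"carrier_{g}"] = matrix.carrier[g].astype(bool)
    return df


def _complete_case(table: pd.DataFrame, adjustment: AdjustmentSet) -> pd.DataFrame:
    cols = list(adjustment.covariates)
    return table.dropna(subset=cols) if cols else table


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[sm.Logit, object, bool]:
    """ML logistic fit; returns (model, results, separation_flag)."""
    model = sm.Logit(y, X)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, method="newton", maxiter=200)
        except Exception:
            try:
                res = model.fit(disp=0, method="bfgs", maxiter=500)
            except Exception:
                return model, None, True
    if res is not None and (not res.mle_retvals.get("converged", True)):
        separation = True
    if res is not None and np.any(np.abs(res.params) > 30):
        # effectively infinite coefficient: (quasi-)separation
        separation = True
    return model, res, separation


def fit_gene_or(
    table: pd.DataFrame,
    gene: str,
    adjustment: AdjustmentSet = AdjustmentSet.full,
    mode: str = "main",
) -> ORResult:
    """Fit the per-gene logistic model on complete-case rows.

    Raises ``ValueError`` on collinear covariates.  Perfect separation is
    reported via ``separation=True`` with ``estimable=False``.
    """
    data = _complete_case(table, adjustment)
    carrier = data[f"carrier_{gene}"].to_numpy(dtype=float)
    y = data["case"].to_numpy(dtype=float)
    n_cases = int(y.sum())
    n_controls = int(len(y) - y.sum())
    n_case_carriers = int(carrier[y == 1].sum())
    n_control_carriers = int(carrier[y == 0].sum())

    base = ORResult(
        gene=gene, adjustment=adjustment, odds_ratio=None, ci_low=None,
        ci_high=None, p_value=None, n_case_carriers=n_case_carriers,
        n_control_carriers=n_control_carriers, n_cases=n_cases,
        n_controls=n_controls, estimable=False, mode=mode,
    )
    if n_case_carriers == 0 or n_control_carriers == 0:
        return base

    covars = data[list(adjustment.covariates)].to_numpy(dtype=float)
    X_full = np.column_stack([np.ones(len(y)), carrier, covars]) if covars.size else \
        np.column_stack([np.ones(len(y)), carrier])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(f"collinear design matrix for gene {gene} ({adjustment.value})")

    _, res_full, sep_full = _fit_logit(y, X_full)
    if sep_full or res_full is None:
        base.separation = True
        return base

    X_red = np.delete(X_full, 1, axis=1)
    _, res_red, sep_red = _fit_logit(y, X_red)
    if sep_red or res_red is None:
        base.separation = True
        return base

    beta = float(res_full.params[1])
    se = float(res_full.bse[1])
    lrt = 2.0 * (res_full.llf - res_red.llf)
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    base.odds_ratio = float(np.exp(beta))
    base.ci_low = float(np.exp(beta - Z95 * se))
    base.ci_high = float(np.exp(beta + Z95 * se))
    base.p_value = p
    base.estimable = True
    return base


def run_panel_association(
    table: pd.DataFrame,
    genes: Sequence[str],
    adjustment: AdjustmentSet = AdjustmentSet.full,
    mode: str = "main",
) -> list[ORResult]:
    """One fit per gene, sorted by p-value with non-estimable genes last."""
    results = [fit_gene_or(table, g, adjustment, mode=mode) for g in genes]
    return sorted(
        results,
        key=lambda r: (not r.estimable, r.p_value if r.p_value is not None else np.inf),
    )


def run_subtype_association(
    table: pd.DataFrame,
    gene: str,
    subtype: str,
    adjustment: AdjustmentSet = AdjustmentSet.full,
) -> ORResult:
    """Per-gene fit treating one ER subtype as the disease.

    Cases are restricted to the given subtype (``positive``/``negative``;
    ER-unknown cases are dropped); all controls are retained.
    """
    subtype = ERStatus(subtype).value
    if subtype == ERStatus.unknown.value:
        raise ValueError("subtype must be 'positive' or 'negative'")
    keep = (table["case"] == 0) | (table["er_status"] == subtype)
    sub = table[keep]
    if int(sub["case"].sum()) == 0:
        raise ValueError(f"no {subtype} cases available for subtype analysis")
    return fit_gene_or(sub, gene, adjustment, mode=f"er_{subtype}")


@dataclass
class VariantSplitResult:
    split: ORResult
    other: ORResult
    equality_p: float | None  # LRT of equal effects; None if a stratum is empty


def run_variant_split(
    table: pd.DataFrame,
    gene: str,
    split_carrier: pd.Series,
    adjustment: AdjustmentSet = AdjustmentSet.full,
) -> VariantSplitResult:
    """Split one gene's carriers into a designated variant vs all other
    pathogenic variants and fit both effects jointly.

    ``split_carrier`` is a boolean Series (indexed by subject id) marking
    carriers of the designated variant; carriers of both the designated and
    another variant go to the designated stratum.  The equality p-value is
    a 1-df likelihood-ratio test of the two log-odds coefficients being
    equal (common-coefficient model vs free model).
    """
    data = _complete_case(table, adjustment)
    carrier = data[f"carrier_{gene}"].to_numpy(dtype=bool)
    split = split_carrier.reindex(data["subject_id"]).fillna(False).to_numpy(dtype=bool)
    split = split & carrier
    other = carrier & ~split
    y = data["case"].to_numpy(dtype=float)
    covars = data[list(adjustment.covariates)].to_numpy(dtype=float)

    def stratum_result(ind: np.ndarray, label: str) -> ORResult:
        n_case = int(ind[y == 1].sum())
        n_control = int(ind[y == 0].sum())
        return ORResult(
            gene=f"{gene}:{label}", adjustment=adjustment, odds_ratio=None,
            ci_low=None, ci_high=None, p_value=None, n_case_carriers=n_case,
            n_control_carriers=n_control, n_cases=int(y.sum()),
            n_controls=int(len(y) - y.sum()), estimable=False, mode="variant_split",
        )

    res_split = stratum_result(split, "split")
    res_other = stratum_result(other, "other")
    both_estimable = (
        res_split.n_case_carriers > 0 and res_split.n_control_carriers > 0
        and res_other.n_case_carriers > 0 and res_other.n_control_carriers > 0
    )
    if not both_estimable:
        # degenerate: with an empty stratum the split reduces to the plain
        # per-gene fit of the remaining stratum; equality test undefined
        if split.sum() == 0 and other.sum() > 0:
            single = fit_gene_or(data, gene, adjustment, mode="variant_split")
            single.gene = f"{gene}:other"
            res_other = single
        elif other.sum() == 0 and split.sum() > 0:
            single = fit_gene_or(data, gene, adjustment, mode="variant_split")
            single.gene = f"{gene}:split"
            res_split = single
        return VariantSplitResult(res_split, res_other, None)

    base_cols = [np.ones(len(y))]
    if covars.size:
        X_free = np.column_stack(base_cols + [split.astype(float), other.astype(float), covars])
        X_common = np.column_stack(base_cols + [(split | other).astype(float), covars])
    else:
        X_free = np.column_stack(base_cols + [split.astype(float), other.astype(float)])
        X_common = np.column_stack(base_cols + [(split | other).astype(float)])

    _, fit_free, sep1 = _fit_logit(y, X_free)
    _, fit_common, sep2 = _fit_logit(y, X_common)
    if sep1 or sep2 or fit_free is None or fit_common is None:
        res_split.separation = res_other.separation = True
        return VariantSplitResult(res_split, res_other, None)

    for idx, res in ((1, res_split), (2, res_other)):
        beta, se = float(fit_free.params[idx]), float(fit_free.bse[idx])
        res.odds_ratio = float(np.exp(beta))
        res.ci_low = float(np.exp(beta - Z95 * se))
        res.ci_high = float(np.exp(beta + Z95 * se))
        res.estimable = True
        # per-stratum Wald p for reference
        res.p_value = float(stats.chi2.sf((beta / se) ** 2, df=1))
    lrt = 2.0 * (fit_free.llf - fit_common.llf)
    equality_p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    return VariantSplitResult(res_split, res_other, equality_p)


def run_sensitivity(
    table: pd.DataFrame,
    genes: Sequence[str],
    mode: str,
    adjustment: AdjustmentSet = AdjustmentSet.full,
    multigene_table: pd.DataFrame | None = None,
) -> list[ORResult]:
    """Sensitivity analyses.

    ``exclude_aspree`` refits on the age-matched study only (all ASPREE
    subjects dropped).  ``include_multigene`` refits on a table built with
    multi-gene carriers re-admitted (pass it as ``multigene_table``; each
    such woman counts as a carrier of every gene she carries).
    """
    if mode == "exclude_aspree":
        sub = table[table["study"] != Study.ASPREE.value]
        return run_panel_association(sub, genes, adjustment, mode=mode)
    if mode == "include_multigene":
        if multigene_table is None:
            raise ValueError(
                "include_multigene requires the analysis table built with "
                "CarrierPolicy(include_multigene=True)"
            )
        return run_panel_association(multigene_table, genes, adjustment, mode=mode)
    raise ValueError(f"unknown sensitivity mode {mode!r}")


def crude_or(n11: int, n10: int, n01: int, n00: int) -> float:
    """2x2 cross-product odds ratio (exposed/unexposed cases x controls)."""
    return (n11 * n00) / (n10 * n01)
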