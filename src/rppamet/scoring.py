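"""Signature scoring and external validation of metagenes.

The signature score of a metagene on a sample is the scalar product of the
member coefficients with the member expression values,

    score = sum_i  s_i * e_i,        s_i in {-1, +1},

so a sample with high expression of the up-members and low expression of the
down-members scores high.  Validation on an independent matched
expression+RPPA dataset applies a two-gate rule: the score must correlate
with the continuous protein level (Pearson r >= 0.5) and must discriminate
the dataset's own protein-low versus protein-high quartile strata
(Mann-Whitney AUC, BH-adjusted p <= 0.05 across the metagenes tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .derivation import Metagene, assign_groups, bh_adjust
from .exceptions import CoverageError, DataError, DegenerateDataError, InsufficientDataError
from .io import ExpressionMatrix, RPPAMatrix

logger = logging.getLogger(__name__)

#: Default minimum fraction of members that must be present in a dataset.
MIN_COVERAGE = 0.5

#: Validation gates.
R_THRESHOLD = 0.5
FDR_THRESHOLD = 0.05


@dataclass
class ScoreVector:
    """Per-sample signature scores of one metagene on one expression dataset."""

    metagene_name: str
    scores: pd.Series
    n_genes_used: int
    coverage: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)


def sigscore(
    metagene: Metagene,
    expr: ExpressionMatrix,
    min_coverage: float = MIN_COVERAGE,
) -> ScoreVector:
    """Signed-sum signature score of ``metagene`` on every sample of ``expr``.

    Members absent from the dataset are skipped and reflected in
    ``coverage``; below ``min_coverage`` the score is refused since too much
    of the signature would be silently dropped.
    """
    genes = set(expr.gene_ids)
    present = [g for g in metagene.genes if g in genes]
    coverage = len(present) / len(metagene)
    if coverage < min_coverage or not present:
        missing = sorted(set(metagene.genes) - genes)
        preview = ", ".join(missing[:10]) + ("..." if len(missing) > 10 else "")
        raise CoverageError(
            f"metagene {metagene.name!r}: only {len(present)}/{len(metagene)} "
            f"members present (coverage {coverage:.2f} < {min_coverage}); "
            f"missing: {preview}"
        )
    coeffs = np.array([metagene.members[g] for g in present], dtype=float)
    values = expr.data.loc[present].to_numpy()
    scores = pd.Series(coeffs @ values, index=expr.sample_ids, name=metagene.name)
    return ScoreVector(
        metagene_name=metagene.name,
        scores=scores,
        n_genes_used=len(present),
        coverage=coverage,
    )


def auc_high_vs_low(
    scores: Sequence[float],
    labels: Sequence[str],
) -> tuple[float, float]:
    """Mann-Whitney AUC of scores for 'high' versus 'low' labelled samples.

    AUC = U / (n_high * n_low) with ties counted one half; the p-value is the
    two-sided Mann-Whitney test (normal approximation with tie correction),
    equivalent to testing AUC = 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    bad = set(labels) - {"low", "high"}
    if bad:
        raise DataError(f"labels must be 'low'/'high', got {sorted(bad)}")
    hi = scores[labels == "high"]
    lo = scores[labels == "low"]
    if len(hi) < 3 or len(lo) < 3:
        raise InsufficientDataError(
            f"need >= 3 samples per class, got high={len(hi)}, low={len(lo)}"
        )
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method="asymptotic")
    auc = float(res.statistic) / (len(hi) * len(lo))
    return auc, float(res.pvalue)


@dataclass
class ValidationResult:
    """Two-gate external-validation outcome for one metagene.

    ``passed`` is True iff pearson_r >= r_threshold and auc_q <= fdr
    threshold; ``testable`` is False when the source protein is absent or
    degenerate in the validation RPPA matrix (such metagenes are excluded
    from the BH adjustment).
    """

    metagene_name: str
    n_genes_used: int = 0
    coverage: float = float("nan")
    pearson_r: float = float("nan")
    auc: float = float("nan")
    auc_p: float = float("nan")
    auc_q: float = float("nan")
    passed: bool = False
    testable: bool = True
    reason: str = ""


def _pairwise_pearson(x: pd.Series, y: pd.Series) -> float:
    """Pearson r on the samples where both series are non-missing."""
    df = pd.concat([x, y], axis=1, join="inner").dropna()
    if len(df) < 3:
        raise InsufficientDataError("fewer than 3 complete pairs for correlation")
    return float(stats.pearsonr(df.iloc[:, 0], df.iloc[:, 1]).statistic)


def validate_metagenes(
    metagenes: Sequence[Metagene],
    expr_val: ExpressionMatrix,
    rppa_val: RPPAMatrix,
    r_threshold: float = R_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    min_coverage: float = MIN_COVERAGE,
) -> list[ValidationResult]:
    """Apply the two-gate validation rule on an independent matched dataset.

    Per metagene: Pearson r between its score and the continuous RPPA level
    of its source protein (pairwise-complete over matched samples, the
    signed r must reach ``r_threshold``); Mann-Whitney AUC of the score over
    the validation dataset's own quartile-derived protein-low/high strata
    (intermediate samples excluded from the AUC only).  BH adjustment of the
    AUC p-values runs across all testable metagenes.
    """
    shared = [s for s in expr_val.sample_ids if s in set(rppa_val.sample_ids)]
    if len(shared) < 8:
        raise InsufficientDataError(
            f"only {len(shared)} matched expression/RPPA samples in validation data"
        )
    results: list[ValidationResult] = []
    for mg in metagenes:
        res = ValidationResult(metagene_name=mg.name)
        if mg.name not in set(rppa_val.protein_ids):
            res.testable = False
            res.reason = "source protein absent from validation RPPA"
            results.append(res)
            continue
        try:
            sv = sigscore(mg, expr_val, min_coverage=min_coverage)
        except CoverageError as exc:
            res.testable = False
            res.reason = str(exc)
            results.append(res)
            continue
        res.n_genes_used = sv.n_genes_used
        res.coverage = sv.coverage
        protein = rppa_val.data.loc[mg.name, shared]
        score = sv.scores.loc[shared]
        try:
            res.pearson_r = _pairwise_pearson(score, protein)
            grouping = assign_groups(protein, protein_id=mg.name)
            extreme = [s for s in shared
                       if grouping.group_of_sample.get(s) in ("low", "high")]
            labels = [grouping.group_of_sample[s] for s in extreme]
            res.auc, res.auc_p = auc_high_vs_low(score.loc[extreme], labels)
        except (DegenerateDataError, InsufficientDataError) as exc:
            res.testable = False
            res.reason = str(exc)
            results.append(res)
            continue
        results.append(res)

    testable = [r for r in results if r.testable]
    if testable:
        qs = bh_adjust([r.auc_p for r in testable])
        for r, q in zip(testable, qs):
            r.auc_q = float(q)
            r.passed = (r.pearson_r >= r_threshold) and (r.auc_q <= fdr_threshold)
    return results


def validation_report(results: Sequence[ValidationResult]) -> pd.DataFrame:
    """Tabular validation report (one row per metagene)."""
    return pd.DataFrame(
        [
            {
                "metagene": r.metagene_name,
                "n_genes_used": r.n_genes_used,
                "coverage": r.coverage,
                "pearson_r": r.pearson_r,
                "auc": r.auc,
                "auc_p": r.auc_p,
                "auc_q": r.auc_q,
                "passed": r.passed,
                "testable": r.testable,
                "reason": r.reason,
            }
            for r in results
        ]
    ).set_index("metagene")
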