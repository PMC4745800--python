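"""Treatment-benefit survival screen over validated metagenes.

For each metagene the signature score is dichotomized at its median; within
each stratum a Cox proportional-hazards model (Efron tie handling) estimates
the treated-versus-control hazard ratio for distant disease-free survival,
and a Wald test of the arm x score product term — with the score entered
both dichotomous and continuous — quantifies benefit modification.  BH runs
across metagenes on the dichotomous interaction p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test
from lifelines.utils import ConvergenceWarning

from .derivation import Metagene, bh_adjust
from .exceptions import CoverageError, DataError, DegenerateDataError
from .io import ClinicalTable, ExpressionMatrix, QUANTILE_METHOD
from .network import Partition
from .scoring import ScoreVector, sigscore

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# Median dichotomization
# ---------------------------------------------------------------------------

def dichotomize_at_median(scores: ScoreVector | pd.Series) -> Partition:
    """Split samples into low (score <= median) and high (score > median).

    The median uses the package-wide linear-interpolation convention; samples
    tied at the median fall into the low stratum.
    """
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    arr = s.to_numpy(dtype=float)
    if len(np.unique(arr)) < 2:
        raise DegenerateDataError("all scores equal; cannot dichotomize")
    med = float(np.quantile(arr, 0.5, method=QUANTILE_METHOD))
    labels = np.where(arr <= med, 1, 2)
    return Partition(
        item_ids=list(s.index.astype(str)),
        labels=labels,
        label_names={1: "low", 2: "high"},
    )


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Hazard ratio for treatment with Wald confidence interval and p-value."""

    hr: float
    ci_lo: float
    ci_hi: float
    p: float
    n: int
    n_events: int
    converged: bool = True

    def __iter__(self):
        return iter((self.hr, self.ci_lo, self.ci_hi, self.p))


def _design_frame(
    clinical: ClinicalTable,
    covariates: Sequence[str],
    extra: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Model frame: time, event, binary arm, dummy-coded covariates, extras."""
    df = clinical.data
    out = pd.DataFrame(
        {
            "time": df["time"],
            "event": df["event"],
            "arm": (df["arm"] == "treated").astype(float),
        },
        index=df.index,
    )
    for cov in covariates:
        if cov not in df.columns:
            raise DataError(f"covariate {cov!r} not in clinical table")
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            out[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            out = pd.concat([out, dummies.astype(float)], axis=1)
    for name, series in (extra or {}).items():
        out[name] = series.reindex(df.index).astype(float)
    out = out.dropna()
    return out


def _fit_cox(frame: pd.DataFrame) -> CoxPHFitter | None:
    """Partial-likelihood fit with Efron ties; None on non-convergence."""
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            cph.fit(frame, duration_col="time", event_col="event")
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("Cox fit did not converge: %s", exc)
            return None
    return cph


def cox_treatment_hr(
    clinical: ClinicalTable,
    covariates: Sequence[str] = (),
) -> CoxResult:
    """Treated-versus-control hazard ratio from a proportional-hazards fit.

    Non-convergence (e.g. monotone likelihood when one arm has no events)
    yields a flagged result with an infinite confidence interval rather than
    an exception, so a screen over many metagenes is not aborted by one
    degenerate stratum.
    """
    df = clinical.data
    if int(df["event"].sum()) == 0:
        raise DegenerateDataError("no events in the data; Cox model undefined")
    if df["arm"].nunique() < 2:
        raise DegenerateDataError("both treatment arms must be represented")
    frame = _design_frame(clinical, covariates)
    n, n_events = len(frame), int(frame["event"].sum())
    cph = _fit_cox(frame)
    if cph is None or not np.isfinite(cph.summary.loc["arm", "se(coef)"]) \
            or cph.summary.loc["arm", "se(coef)"] > 1e3:
        return CoxResult(hr=float("nan"), ci_lo=0.0, ci_hi=float("inf"),
                         p=float("nan"), n=n, n_events=n_events, converged=False)
    row = cph.summary.loc["arm"]
    return CoxResult(
        hr=float(np.exp(row["coef"])),
        ci_lo=float(np.exp(row["coef lower 95%"])),
        ci_hi=float(np.exp(row["coef upper 95%"])),
        p=float(row["p"]),
        n=n,
        n_events=n_events,
    )


def interaction_test(
    clinical: ClinicalTable,
    scores: ScoreVector | pd.Series | Partition,
    covariates: Sequence[str] = (),
) -> float:
    """Wald p-value for the arm x score product term.

    The model contains the treatment main effect, the score main effect
    (continuous, or 0/1 for a low/high partition), the listed covariates and
    the product term; the returned p is the Wald test of the product
    coefficient.  Returns NaN (with a logged warning) when the fit does not
    converge.
    """
    if isinstance(scores, Partition):
        score = scores.to_series().map({"low": 0.0, "high": 1.0})
        score.index = pd.Index(scores.item_ids)
    elif isinstance(scores, ScoreVector):
        score = scores.scores
    else:
        score = scores
    score = score.astype(float)
    df = clinical.data
    if int(df["event"].sum()) == 0:
        raise DegenerateDataError("no events in the data; Cox model undefined")
    aligned = score.reindex(df.index)
    if aligned.dropna().nunique() < 2:
        raise DegenerateDataError("score is constant; interaction undefined")
    arm = (df["arm"] == "treated").astype(float)
    frame = _design_frame(
        clinical, covariates,
        extra={"score": aligned, "arm_x_score": arm * aligned},
    )
    cph = _fit_cox(frame)
    if cph is None:
        return float("nan")
    return float(cph.summary.loc["arm_x_score", "p"])


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_logrank(
    groups: Partition | pd.Series,
    clinical: ClinicalTable,
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Product-limit survival curves per group and the log-rank comparison.

    Returns (curves, chi2, p) where ``curves`` maps each group name to a
    DataFrame of (time, survival) step-function coordinates.  Two groups use
    the standard two-sample log-rank test; more use its k-sample extension.
    """
    labels = groups.to_series() if isinstance(groups, Partition) else groups.astype(str)
    df = clinical.data
    labels = labels.reindex(df.index).dropna()
    df = df.loc[labels.index]
    names = sorted(labels.unique())
    if len(names) < 2:
        raise DegenerateDataError("log-rank needs >= 2 groups")
    curves: dict[str, pd.DataFrame] = {}
    for name in names:
        mask = labels == name
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask, "time"], df.loc[mask, "event"], label=str(name))
        sf = kmf.survival_function_
        curves[str(name)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    if len(names) == 2:
        a, b = names
        res = logrank_test(
            df.loc[labels == a, "time"], df.loc[labels == b, "time"],
            df.loc[labels == a, "event"], df.loc[labels == b, "event"],
        )
    else:
        res = multivariate_logrank_test(df["time"], labels, df["event"])
    return curves, float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Treatment-benefit screen outcome for one metagene."""

    metagene_name: str
    hr_low: CoxResult | None = None
    hr_high: CoxResult | None = None
    p_interaction_dichotomous: float = float("nan")
    p_interaction_continuous: float = float("nan")
    q_interaction: float = float("nan")
    n_per_cell: dict[str, int] = field(default_factory=dict)
    testable: bool = True
    reason: str = ""


def screen(
    metagenes: Sequence[Metagene],
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    covariates: Sequence[str] = (),
    fdr_threshold: float = FDR_THRESHOLD,
    subgroup: tuple[str, str] | None = None,
) -> list[ScreenResult]:
    """Screen metagenes for modification of treatment benefit.

    Per metagene: score -> median split -> per-stratum treatment HR (with
    covariates) -> Wald interaction p, dichotomous and continuous.  BH runs
    across testable metagenes on the dichotomous interaction p.  A metagene
    with an empty stratum x arm cell is flagged untestable and excluded from
    BH.  ``subgroup=(column, value)`` restricts the screen to the matching
    clinical subset before anything else happens.
    """
    if subgroup is not None:
        col, val = subgroup
        if col not in clinical.data.columns:
            raise DataError(f"subgroup column {col!r} not in clinical table")
        keep = clinical.data.index[clinical.data[col].astype(str) == str(val)]
        clinical = ClinicalTable(clinical.data.loc[keep])
    shared = [s for s in clinical.sample_ids if s in set(expr.sample_ids)]
    if not shared:
        raise DataError("no samples shared between clinical table and expression matrix")
    clinical = clinical.subset(shared)

    results: list[ScreenResult] = []
    for mg in metagenes:
        res = ScreenResult(metagene_name=mg.name)
        try:
            sv = sigscore(mg, expr)
            score = sv.scores.loc[shared]
            part = dichotomize_at_median(score)
        except (CoverageError, DegenerateDataError) as exc:
            res.testable = False
            res.reason = str(exc)
            results.append(res)
            continue
        strata = part.to_series()
        cells = {}
        for stratum in ("low", "high"):
            for arm in ("treated", "control"):
                ids = [s for s in shared
                       if strata[s] == stratum and clinical.data.loc[s, "arm"] == arm]
                cells[f"{stratum}/{arm}"] = len(ids)
        res.n_per_cell = cells
        if min(cells.values()) == 0:
            res.testable = False
            res.reason = "empty stratum x arm cell"
            results.append(res)
            continue
        try:
            for stratum, attr in (("low", "hr_low"), ("high", "hr_high")):
                ids = [s for s in shared if strata[s] == stratum]
                setattr(res, attr,
                        cox_treatment_hr(clinical.subset(ids), covariates))
            res.p_interaction_dichotomous = interaction_test(clinical, part, covariates)
            res.p_interaction_continuous = interaction_test(clinical, score, covariates)
        except (DegenerateDataError, DataError) as exc:
            res.testable = False
            res.reason = str(exc)
            results.append(res)
            continue
        if not np.isfinite(res.p_interaction_dichotomous):
            res.testable = False
            res.reason = "interaction model did not converge"
        results.append(res)

    testable = [r for r in results if r.testable]
    if testable:
        qs = bh_adjust([r.p_interaction_dichotomous for r in testable])
        for r, q in zip(testable, qs):
            r.q_interaction = float(q)
    return results


_SCREEN_COLUMNS = [
    "metagene", "p_interaction_dichotomous", "p_interaction_continuous",
    "q_interaction", "testable", "reason",
    "hr_low", "hr_low_ci_lo", "hr_low_ci_hi", "hr_low_p",
    "hr_high", "hr_high_ci_lo", "hr_high_ci_hi", "hr_high_p",
]

_FOREST_COLUMNS = ["metagene", "stratum", "hr", "ci_lo", "ci_hi", "p",
                   "n", "n_events", "converged"]


def screen_report(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Screen summary table, sorted by interaction q."""
    if not results:
        return pd.DataFrame(columns=_SCREEN_COLUMNS).set_index("metagene")
    rows = []
    for r in results:
        row = {
            "metagene": r.metagene_name,
            "p_interaction_dichotomous": r.p_interaction_dichotomous,
            "p_interaction_continuous": r.p_interaction_continuous,
            "q_interaction": r.q_interaction,
            "testable": r.testable,
            "reason": r.reason,
        }
        for stratum, cox in (("low", r.hr_low), ("high", r.hr_high)):
            row[f"hr_{stratum}"] = cox.hr if cox else float("nan")
            row[f"hr_{stratum}_ci_lo"] = cox.ci_lo if cox else float("nan")
            row[f"hr_{stratum}_ci_hi"] = cox.ci_hi if cox else float("nan")
            row[f"hr_{stratum}_p"] = cox.p if cox else float("nan")
        rows.append(row)
    df = pd.DataFrame(rows).set_index("metagene")
    return df.sort_values("q_interaction", na_position="last")


def forest_table(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Long-format forest-plot data: one row per metagene x stratum."""
    if not results:
        return pd.DataFrame(columns=_FOREST_COLUMNS)
    rows = []
    for r in results:
        for stratum, cox in (("low", r.hr_low), ("high", r.hr_high)):
            if cox is None:
                continue
            rows.append(
                {
                    "metagene": r.metagene_name, "stratum": stratum,
                    "hr": cox.hr, "ci_lo": cox.ci_lo, "ci_hi": cox.ci_hi,
                    "p": cox.p, "n": cox.n, "n_events": cox.n_events,
                    "converged": cox.converged,
                }
            )
    return pd.DataFrame(rows, columns=_FOREST_COLUMNS)
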