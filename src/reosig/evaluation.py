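"""Evaluation of signature predictions: confusion metrics, AUC, survival.

The classification part treats *responder* as the positive class and
reports sensitivity, specificity and accuracy (the pipeline's "F-score").
The AUC is the rank-sum (Mann-Whitney) formulation, appropriate for the
small integer scores a vote signature produces.  The survival part
validates a predicted grouping against progression-free survival with
Kaplan-Meier estimates and Cox proportional-hazards fits (responder coded
1, so a hazard ratio below 1 means predicted responders do better),
optionally adjusted for clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter

from .data_io import ClinicalTable, ResponseLabels, RESPONDER
from .signature import ScoreResult


@dataclass
class EvalReport:
    """Classification and/or survival results of a signature evaluation."""

    tp: int | None = None
    tn: int | None = None
    fp: int | None = None
    fn: int | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    f_score: float | None = None
    auc: float | None = None
    hr_univariate: dict | None = None
    hr_multivariate: dict | None = None
    km_curves: dict | None = field(default=None, repr=False)
    survival_estimable: bool | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if d.get("km_curves"):
            d["km_curves"] = {
                g: {"time": list(map(float, c["time"])),
                    "survival": list(map(float, c["survival"]))}
                for g, c in d["km_curves"].items()
            }
        return d


def confusion_metrics(predicted: ScoreResult | pd.Series, labels: ResponseLabels) -> EvalReport:
    """Confusion counts and rates of predicted vs true responder labels."""
    pred = predicted.predicted if isinstance(predicted, ScoreResult) else predicted
    missing = [s for s in labels.sample_ids if s not in pred.index]
    if missing:
        raise ValueError(f"missing predictions for samples: {missing[:5]}")
    pred = pred.loc[labels.sample_ids]
    y = labels.as_bool()
    yhat = (pred == RESPONDER).to_numpy()
    tp = int((y & yhat).sum())
    tn = int((~y & ~yhat).sum())
    fp = int((~y & yhat).sum())
    fn = int((y & ~yhat).sum())
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        f_score=(tp + tn) / (tp + tn + fp + fn),
    )


def auc_from_scores(scores: pd.Series | np.ndarray, labels: ResponseLabels) -> float:
    """Rank-based AUC of scores for discriminating responders.

    Equals the probability that a random responder outscores a random
    non-responder, ties counting one half — the Mann-Whitney formulation.
    """
    if isinstance(scores, pd.Series):
        scores = scores.loc[labels.sample_ids].to_numpy(dtype=float)
    else:
        scores = np.asarray(scores, dtype=float)
    y = labels.as_bool()
    if y.all() or not y.any():
        raise ValueError("AUC needs both classes present")
    n1, n2 = int(y.sum()), int((~y).sum())
    ranks = stats.rankdata(scores)
    r1 = ranks[y].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2))


def survival_validation(
    groups: pd.Series,
    clinical: ClinicalTable,
    covariates: Sequence[str] = (),
) -> EvalReport:
    """Validate a predicted responder/non-responder grouping against PFS.

    Parameters
    ----------
    groups : sample_id -> predicted group ('responder'/'non_responder').
    clinical : must provide pfs_time and pfs_event for the grouped samples.
    covariates : clinical column names to adjust for in the multivariate
        fit; categorical columns are one-hot encoded (first level dropped).

    The Cox predictor is the responder indicator, so HR < 1 means predicted
    responders progress later.  With a single predicted group or no events
    the survival part is flagged not estimable rather than raising.
    """
    clin = clinical.data.set_index("sample_id")
    missing = [s for s in groups.index if s not in clin.index]
    if missing:
        raise ValueError(f"samples absent from clinical table: {missing[:5]}")
    df = clin.loc[groups.index, ["pfs_time", "pfs_event"] + list(covariates)].copy()
    df["responder"] = (groups == RESPONDER).astype(float)
    df = df.dropna(subset=["pfs_time", "pfs_event"])

    report = EvalReport(survival_estimable=True)
    if df.empty or df["responder"].nunique() < 2 or df["pfs_event"].sum() == 0:
        report.survival_estimable = False
        return report

    # Kaplan-Meier per predicted group
    km: dict[str, dict] = {}
    for grp_name, flag in (("responder", 1.0), ("non_responder", 0.0)):
        sub = df[df["responder"] == flag]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["pfs_time"], sub["pfs_event"])
        sf = kmf.survival_function_
        km[grp_name] = {
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
        }
    report.km_curves = km

    report.hr_univariate = _cox_hr(df[["pfs_time", "pfs_event", "responder"]])
    if covariates:
        model = pd.get_dummies(
            df, columns=[c for c in covariates if df[c].dtype == object],
            drop_first=True, dtype=float,
        )
        report.hr_multivariate = _cox_hr(model)
    return report


def _cox_hr(df: pd.DataFrame) -> dict:
    cph = CoxPHFitter()
    cph.fit(df, duration_col="pfs_time", event_col="pfs_event")
    s = cph.summary.loc["responder"]
    return {
        "hr": float(s["exp(coef)"]),
        "ci_low": float(s["exp(coef) lower 95%"]),
        "ci_high": float(s["exp(coef) upper 95%"]),
        "p": float(s["p"]),
    }


def power_wilcoxon_mc(
    n1: int,
    n2: int,
    effect: float,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the two-sided Wilcoxon rank-sum test.

    Samples group 1 from N(effect, 1) and group 2 from N(0, 1) (a location
    shift of ``effect`` standard deviations) and reports the empirical
    rejection rate at level ``alpha``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if n_reps < 100:
        raise ValueError("need >= 100 replicates")
    rng = np.random.default_rng(seed)
    x = rng.normal(effect, 1.0, size=(n_reps, n1))
    y = rng.normal(0.0, 1.0, size=(n_reps, n2))
    p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=1).pvalue
    return float((np.asarray(p) < alpha).mean())
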