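"""Outcome-analysis pipeline: ROC cutoffs, Kaplan–Meier, log-rank, Cox.

Operates on per-patient records carrying a time-to-first-event (days),
an event indicator (1 = death or heart-failure rehospitalization), and
named numeric covariates (e.g. ``itapse_posterior`` in mm/m²,
``itapse_volume`` in ml/m², ``rvef``/``lvef`` in %).

The Kaplan–Meier estimator, log-rank test, and Cox proportional-hazards
fits are delegated to :mod:`lifelines` (Efron tie handling for Cox —
appropriate for day-resolution follow-up with ties). The ROC cutoff
search implements the all-thresholds Youden scan directly, because its
tie-breaking and threshold-grid conventions are part of this package's
contract. All operations are deterministic given fixed input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats as _scipy_stats

logger = logging.getLogger(__name__)

__all__ = [
    "CohortRecord",
    "KMEstimate",
    "CoxEntry",
    "CoxFit",
    "ScreenResult",
    "CutoffResult",
    "records_to_frame",
    "frame_to_records",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "screen_then_multivariate",
    "roc_cutoff",
    "roc_cutoff_from_values",
    "stratify_rvef_itapse",
    "pearson_corr",
]

ONE_YEAR_DAYS = 365.0


@dataclass
class CohortRecord:
    """One patient's follow-up outcome, covariates and group flags."""

    patient_id: str
    time: float
    event: int
    covariates: dict[str, float] = field(default_factory=dict)
    groups: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.time >= 0):
            raise ValueError(f"{self.patient_id}: time must be >= 0 days, got {self.time}")
        if int(self.event) not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1, got {self.event}")
        self.event = int(self.event)


def records_to_frame(records) -> pd.DataFrame:
    """Flatten records (or pass through a DataFrame) to tabular form."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "time": r.time, "event": r.event}
        row.update(r.covariates)
        row.update({k: bool(v) for k, v in r.groups.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[CohortRecord]:
    """Rebuild :class:`CohortRecord` objects from a cohort table."""
    base = {"patient_id", "time", "event"}
    records = []
    for _, row in df.iterrows():
        cov = {}
        grp = {}
        for name, value in row.items():
            if name in base:
                continue
            if isinstance(value, (bool, np.bool_)):
                grp[name] = bool(value)
            else:
                cov[name] = float(value)
        records.append(
            CohortRecord(str(row["patient_id"]), float(row["time"]), int(row["event"]), cov, grp)
        )
    return records


@dataclass
class KMEstimate:
    """Product-limit survival curve for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int
    median_followup: float
    event_rate_1yr: float

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value of S at time t."""
        if len(self.times) == 0 or t < self.times[0]:
            return 1.0
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.survival[idx])


def _km_one(df: pd.DataFrame, group: str) -> KMEstimate:
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    # Median follow-up by reverse Kaplan-Meier (censoring distribution).
    rkm = KaplanMeierFitter()
    rkm.fit(df["time"], 1 - df["event"])
    est = KMEstimate(
        group=group,
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=float),
        n=len(df),
        n_events=int(df["event"].sum()),
        median_followup=float(rkm.median_survival_time_),
        event_rate_1yr=np.nan,
    )
    est.event_rate_1yr = 1.0 - est.survival_at(ONE_YEAR_DAYS)
    return est


def km_estimate(records, group_flag: str | None = None) -> dict[str, KMEstimate]:
    """Kaplan–Meier curves, overall or per level of a binary group flag.

    Each estimate carries the at-risk table, the reverse-KM median
    follow-up, and the 1-year endpoint rate read off the curve as
    ``1 - S(365 d)``.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records to estimate from")
    if group_flag is None:
        return {"all": _km_one(df, "all")}
    if group_flag not in df.columns:
        raise KeyError(f"group flag '{group_flag}' not present in records")
    out: dict[str, KMEstimate] = {}
    for value, sub in df.groupby(df[group_flag].astype(bool), sort=True):
        if sub.empty:
            raise ValueError(f"group {group_flag}={value} is empty")
        name = f"{group_flag}={value}"
        out[name] = _km_one(sub, name)
    if len(out) < 2:
        raise ValueError(f"group flag '{group_flag}' has a single level; both groups required")
    return out


def logrank_test(records, group_flag: str) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    df = records_to_frame(records)
    if group_flag not in df.columns:
        raise KeyError(f"group flag '{group_flag}' not present in records")
    mask = df[group_flag].astype(bool)
    a, b = df[mask], df[~mask]
    if a.empty or b.empty:
        raise ValueError(f"log-rank needs two nonempty groups for '{group_flag}'")
    res = _lifelines_logrank(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxEntry:
    """One covariate's Cox estimate: log-hazard coefficient and Wald CI."""

    coef: float
    hr: float
    ci_lower: float
    ci_upper: float
    p: float


@dataclass
class CoxFit:
    """A fitted proportional-hazards model (Efron ties, Wald inference)."""

    label: str
    covariates: list[str]
    entries: dict[str, CoxEntry]
    n: int
    n_events: int
    n_excluded: int

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "covariates": list(self.covariates),
            "n": self.n,
            "n_events": self.n_events,
            "n_excluded": self.n_excluded,
            "entries": {
                k: {"coef": e.coef, "hr": e.hr, "ci_lower": e.ci_lower,
                    "ci_upper": e.ci_upper, "p": e.p}
                for k, e in self.entries.items()
            },
        }


def cox_fit(records, covariate_names, label: str | None = None) -> CoxFit:
    """Cox proportional-hazards fit over the named covariates.

    Binary group flags and continuous covariates are both admitted (the
    former as 0/1). Rows with a missing value in any used covariate are
    dropped (complete-case) with the exclusion count logged and
    reported. Raises if no event remains, if a covariate pair is
    perfectly collinear, or if the partial-likelihood optimisation does
    not converge.
    """
    covariate_names = list(covariate_names)
    df = records_to_frame(records)
    missing = [c for c in covariate_names if c not in df.columns]
    if missing:
        raise KeyError(f"covariates not present in records: {missing}")
    use = df[["time", "event"] + covariate_names].copy()
    for c in covariate_names:
        use[c] = pd.to_numeric(use[c].astype(float))
    complete = use.dropna()
    n_excluded = len(use) - len(complete)
    if n_excluded:
        logger.info("cox_fit(%s): excluded %d record(s) with missing covariates", label, n_excluded)
    n_events = int(complete["event"].sum())
    if n_events < 1:
        raise ValueError(f"cox_fit({label}): zero events; hazard model is not identifiable")
    x = complete[covariate_names].to_numpy(dtype=float)
    if len(covariate_names) > 1:
        centered = x - x.mean(axis=0)
        if np.linalg.matrix_rank(centered) < len(covariate_names):
            raise ValueError(f"cox_fit({label}): perfectly collinear covariates {covariate_names}")
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(complete, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"cox_fit({label}): partial likelihood failed to converge: {exc}") from exc
    summary = fitter.summary
    entries = {
        name: CoxEntry(
            coef=float(summary.loc[name, "coef"]),
            hr=float(summary.loc[name, "exp(coef)"]),
            ci_lower=float(summary.loc[name, "exp(coef) lower 95%"]),
            ci_upper=float(summary.loc[name, "exp(coef) upper 95%"]),
            p=float(summary.loc[name, "p"]),
        )
        for name in covariate_names
    }
    return CoxFit(
        label=label or "+".join(covariate_names),
        covariates=covariate_names,
        entries=entries,
        n=len(complete),
        n_events=n_events,
        n_excluded=n_excluded,
    )


@dataclass
class ScreenResult:
    """Univariate screen plus the downstream multivariate models."""

    univariate: dict[str, CoxFit]
    retained: list[str]
    multivariate: list[CoxFit]

    def as_dict(self) -> dict:
        return {
            "univariate": {k: v.as_dict() for k, v in self.univariate.items()},
            "retained": list(self.retained),
            "multivariate": [m.as_dict() for m in self.multivariate],
        }


def screen_then_multivariate(
    records,
    candidate_covariates,
    screen_p: float = 0.1,
    anchor: str = "lvef",
    model_spec: list[list[str]] | None = None,
) -> ScreenResult:
    """Univariate Cox screen feeding the multivariate models.

    Each candidate is first fit alone; candidates with p < `screen_p`
    are retained. By default the multivariate stage fits one pairwise
    model per retained non-anchor covariate together with the `anchor`
    covariate (LVEF), which avoids placing collinear CT metrics in a
    single model; if the anchor is not retained, a single model over all
    retained covariates is fit instead. An explicit `model_spec` (list
    of covariate lists, each filtered to retained covariates) overrides
    the default. If nothing passes the screen, the univariate results
    are returned with an empty multivariate set and a warning.
    """
    candidates = list(candidate_covariates)
    univariate = {c: cox_fit(records, [c], label=f"univariate:{c}") for c in candidates}
    retained = [c for c in candidates if univariate[c].entries[c].p < screen_p]
    if not retained:
        warnings.warn("no candidate passed the univariate screen; multivariate set is empty")
        return ScreenResult(univariate=univariate, retained=[], multivariate=[])
    if model_spec is None:
        if anchor in retained and len(retained) > 1:
            models = [[anchor, c] for c in retained if c != anchor]
        else:
            models = [list(retained)]
    else:
        models = []
        for spec in model_spec:
            kept = [c for c in spec if c in retained]
            if len(kept) >= 1:
                models.append(kept)
    multivariate = [
        cox_fit(records, model, label="multivariate:" + "+".join(model)) for model in models
    ]
    return ScreenResult(univariate=univariate, retained=retained, multivariate=multivariate)


@dataclass
class CutoffResult:
    """ROC summary for dichotomizing a covariate against the outcome."""

    covariate: str
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # 'low_positive': values <= cutoff predict the event

    def as_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "auc": self.auc,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "direction": self.direction,
        }


def roc_cutoff_from_values(values, labels, covariate: str = "covariate") -> CutoffResult:
    """All-thresholds ROC scan with Youden's J cutoff selection.

    Candidate thresholds are the midpoints between consecutive sorted
    unique covariate values; the AUC is the trapezoidal area under the
    (FPR, TPR) curve over all thresholds. The scoring orientation
    (whether high or low values predict the event) is chosen to give
    AUC >= 0.5. The optimal cutoff maximises Youden's
    J = sensitivity + specificity - 1; ties are broken toward higher
    specificity, then toward the lowest threshold.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and labels must be 1D arrays of equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{covariate}: non-finite covariate values")
    pos, neg = x[y == 1], x[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(f"{covariate}: both outcome classes must be present")
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValueError(f"{covariate}: covariate is constant; no threshold exists")
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    # 'high_positive' orientation: predict the event when x >= threshold.
    sens_hi = (pos[:, None] >= mids).mean(axis=0)
    spec_hi = (neg[:, None] < mids).mean(axis=0)
    # In ascending-midpoint (descending-permissiveness) order both rates
    # fall monotonically from (1, 1) to (0, 0); integrate that staircase.
    fpr = np.concatenate([[1.0], 1.0 - spec_hi, [0.0]])[::-1]
    tpr = np.concatenate([[1.0], sens_hi, [0.0]])[::-1]
    auc_hi = float(np.trapezoid(tpr, fpr))
    if auc_hi >= 0.5:
        direction, auc, sens, spec = "high_positive", auc_hi, sens_hi, spec_hi
    else:
        # Midpoints never coincide with data, so flipping is exact.
        direction, auc = "low_positive", 1.0 - auc_hi
        sens, spec = 1.0 - sens_hi, 1.0 - spec_hi
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    best = best[spec[best] == spec[best].max()]
    k = int(best[0])
    return CutoffResult(
        covariate=covariate,
        auc=auc,
        cutoff=float(mids[k]),
        sensitivity=float(sens[k]),
        specificity=float(spec[k]),
        direction=direction,
    )


def roc_cutoff(records, covariate: str, outcome_flag: str = "event") -> CutoffResult:
    """ROC cutoff for a named covariate against a binary outcome column."""
    df = records_to_frame(records)
    for col in (covariate, outcome_flag):
        if col not in df.columns:
            raise KeyError(f"column '{col}' not present in records")
    return roc_cutoff_from_values(
        df[covariate].to_numpy(dtype=float),
        df[outcome_flag].astype(int).to_numpy(),
        covariate=covariate,
    )


def stratify_rvef_itapse(
    records,
    rvef_cut: float = 45.0,
    itapse_cut: float = 4.5,
    rvef_key: str = "rvef",
    itapse_key: str = "itapse_posterior",
) -> np.ndarray:
    """Three-group RVEF × posterior-iTAPSE stratification.

    Group 1: both preserved (RVEF >= `rvef_cut` AND posterior iTAPSE
    > `itapse_cut`); group 2: exactly one preserved; group 3: both
    reduced. Note the asymmetric boundary convention: RVEF exactly at
    the cut counts as preserved, iTAPSE exactly at the cut as reduced.
    """
    df = records_to_frame(records)
    for col in (rvef_key, itapse_key):
        if col not in df.columns:
            raise KeyError(f"covariate '{col}' required for stratification")
        if df[col].isna().any():
            raise ValueError(f"covariate '{col}' has missing values; cannot stratify")
    rvef_ok = df[rvef_key].to_numpy(dtype=float) >= rvef_cut
    itapse_ok = df[itapse_key].to_numpy(dtype=float) > itapse_cut
    preserved = rvef_ok.astype(int) + itapse_ok.astype(int)
    return np.select([preserved == 2, preserved == 1], [1, 2], default=3)


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value.

    Requires n >= 3 and nonzero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson_corr needs paired 1D samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_corr: zero variance in at least one variable")
    r, p = _scipy_stats.pearsonr(x, y)
    return float(r), float(p)
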