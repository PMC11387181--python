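"""Cohort assembly filters, dnDSA event definition, ROC/cutpoint analysis,
two-stage threshold derivation, and survival machinery (KM, log-rank, Cox).

Days are converted to years with 365.25.  Death and graft loss are treated
as censoring for dnDSA-free survival (no competing-risk model).  Cox models
are fit by partial likelihood with the Efron approximation for ties
(delegated to lifelines) and support categorical covariates with declared
reference levels plus arbitrary pairwise level contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ContractError, CoxError, DerivationError, ParseError
from .mismatch import attribute_dsa_to_molecules
from .registry import Molecule
from .risk import CategoryScheme, RiskCategory, classify

DAYS_PER_YEAR = 365.25

#: exclusion reasons in the order they are tallied (first match wins)
EXCLUSION_ORDER = [
    "primary_non_function",
    "spk",
    "abo_incompatible",
    "pretransplant_dsa",
    "positive_crossmatch",
    "inadequate_pretransplant_assessment",
    "dsa_within_14d",
]


@dataclass(frozen=True)
class Detection:
    day: float
    specificity: str
    mfi: float | None


@dataclass
class CohortRecord:
    pair_id: str
    ethnicity: str = ""
    donor_type: str = "living"
    cni: str = "cyclosporine"
    antimetabolite: str = "mycophenolate"
    induction: str = "basiliximab"
    follow_up_years: float = 0.0
    detections: list[Detection] = field(default_factory=list)
    flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if self.follow_up_years <= 0:
            raise ContractError(f"{self.pair_id}: follow-up must be positive")
        for d in self.detections:
            if d.day < 0:
                raise ContractError(f"{self.pair_id}: detection day must be >= 0")


@dataclass(frozen=True)
class EventRecord:
    pair_id: str
    locus: str  # "DR" | "DQ"
    event: bool
    time_years: float


def apply_cohort_filters(records: list[CohortRecord]):
    """Split records into retained vs excluded, tallying exclusion reasons.

    Each excluded record is counted once, under the first flag set in
    :data:`EXCLUSION_ORDER`.
    """
    retained = []
    tally = {reason: 0 for reason in EXCLUSION_ORDER}
    for rec in records:
        reason = next((r for r in EXCLUSION_ORDER if rec.flags.get(r)), None)
        if reason is None:
            retained.append(rec)
        else:
            tally[reason] += 1
    return retained, tally


def flag_early_dsa(
    record: CohortRecord,
    donor_mols: list[Molecule],
    mfi_cutoff: float = 500.0,
    memory_days: float = 14.0,
) -> bool:
    """True when a donor-attributed detection at/below ``memory_days`` qualifies."""
    for det in record.detections:
        if det.mfi is None or det.mfi < mfi_cutoff or det.day > memory_days:
            continue
        if attribute_dsa_to_molecules(det.specificity, donor_mols):
            return True
    return False


def define_dndsa_events(
    record: CohortRecord,
    donor_mols: list[Molecule],
    mfi_cutoff: float = 500.0,
    memory_days: float = 14.0,
    missing_mfi: str = "skip",
) -> dict[str, EventRecord]:
    """Per-locus (DR, DQ) dnDSA event records for one retained recipient.

    The event time is the earliest detection with MFI >= ``mfi_cutoff``,
    day > ``memory_days``, and a specificity attributable to a donor
    molecule of that locus class; otherwise the record is censored at
    follow-up.  ``missing_mfi`` is ``"skip"`` (treat as screening-only) or
    ``"error"``.
    """
    if missing_mfi not in ("skip", "error"):
        raise ContractError(f"missing_mfi must be 'skip' or 'error', got {missing_mfi!r}")
    mols_by_id = {m.molecule_id: m for m in donor_mols}
    earliest: dict[str, float] = {}
    for det in record.detections:
        if det.mfi is None:
            if missing_mfi == "error":
                raise ParseError(
                    f"{record.pair_id}: detection at day {det.day} has no MFI"
                )
            continue
        if det.mfi < mfi_cutoff or det.day <= memory_days:
            continue
        if det.day / DAYS_PER_YEAR > record.follow_up_years + 1e-9:
            continue
        matched = attribute_dsa_to_molecules(det.specificity, donor_mols)
        if not matched:
            continue
        locus = "DR" if mols_by_id[matched[0]].kind == "DR_beta" else "DQ"
        if locus not in earliest or det.day < earliest[locus]:
            earliest[locus] = det.day
    out = {}
    for locus in ("DR", "DQ"):
        if locus in earliest:
            out[locus] = EventRecord(
                record.pair_id, locus, True, earliest[locus] / DAYS_PER_YEAR
            )
        else:
            out[locus] = EventRecord(
                record.pair_id, locus, False, record.follow_up_years
            )
    return out


# ---------------------------------------------------------------------------
# ROC / cutpoints
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    auc: float
    thresholds: np.ndarray  # candidate thresholds, ascending
    sensitivity: np.ndarray
    specificity: np.ndarray
    chosen_threshold: int | None = None


def roc_auc(scores, labels) -> ROCResult:
    """ROC over integer scores with orientation ``score >= t`` => positive.

    The AUC is the Mann-Whitney probability with ties counted one half,
    computed from mid-ranks.  Operating points are evaluated at every
    distinct observed score plus one point above the maximum (the
    all-negative corner).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ContractError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ContractError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    thresholds = np.unique(scores)
    thresholds = np.append(thresholds, thresholds[-1] + 1)
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = scores >= t
        sens[i] = (pred & (labels == 1)).sum() / n_pos
        spec[i] = (~pred & (labels == 0)).sum() / n_neg
    return ROCResult(float(auc), thresholds, sens, spec)


def optimal_cutpoint(roc: ROCResult) -> int:
    """Youden's J maximizer; exact ties broken toward the higher threshold."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = j.max()
    idx = np.nonzero(j >= best - 1e-12)[0][-1]
    t = roc.thresholds[idx]
    return int(round(float(t)))


def derive_two_stage_thresholds(
    molecule_data: dict[str, pd.DataFrame],
    summaries,
    low_scheme: CategoryScheme,
    name: str = "derived",
) -> CategoryScheme:
    """Cohort-specific scheme: keep the low cutoffs, re-derive high cutoffs.

    Recipients classified LOW under ``low_scheme`` are removed; a fresh
    per-class ROC is run on the remaining molecule-level data (frames with
    columns pair_id, score, label keyed ``"DR"``/``"DQ"``); the high rule
    becomes the conjunction of the two Youden-optimal cutpoints.
    """
    low_pairs = set()
    for item in summaries:
        if hasattr(item, "dr_max"):
            pid, dr, dq = item.pair_id, item.dr_max, item.dq_max
        else:
            pid, dr, dq = item
        if classify(dr, dq, low_scheme) == RiskCategory.LOW:
            low_pairs.add(pid)
    cutpoints = {}
    for cls in ("DR", "DQ"):
        df = molecule_data[cls]
        sub = df[~df["pair_id"].isin(low_pairs)]
        if len(sub) == 0 or sub["label"].nunique() < 2:
            raise DerivationError(
                f"{cls}: no class variation left after excluding "
                f"{len(low_pairs)} low-risk recipients"
            )
        cutpoints[cls] = optimal_cutpoint(roc_auc(sub["score"], sub["label"]))
    return CategoryScheme(
        name=name,
        dr_low_lt=low_scheme.dr_low_lt,
        dq_low_lt=low_scheme.dq_low_lt,
        high_dr_ge=cutpoints["DR"],
        high_dq_ge=cutpoints["DQ"],
    )


# ---------------------------------------------------------------------------
# Survival machinery
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(durations, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate (starts at S(0)=1)."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(durations) == 0:
        raise ContractError("km_estimate requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([(durations >= t).sum() for t in times])
    return SurvivalCurve(times, surv, at_risk)


def logrank_test(durations_a, events_a, durations_b, events_b) -> tuple[float, float]:
    """Two-sided log-rank test; returns (chi2 statistic, p-value)."""
    res = _ll_logrank(
        np.asarray(durations_a, dtype=float),
        np.asarray(durations_b, dtype=float),
        event_observed_A=np.asarray(events_a, dtype=int),
        event_observed_B=np.asarray(events_b, dtype=int),
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """Fitted proportional-hazards model.

    ``summary`` has one row per design term: coef, hr, ci_low, ci_high, p.
    ``contrast`` computes any pairwise categorical-level contrast from the
    coefficient covariance (the reference level has coefficient 0).
    """

    summary: pd.DataFrame
    log_likelihood: float
    params: pd.Series
    covariance: pd.DataFrame
    categorical_levels: dict[str, list[str]]

    def term(self, name: str) -> dict:
        row = self.summary.loc[name]
        return row.to_dict()

    def hazard_ratio(self, name: str) -> float:
        return float(self.summary.loc[name, "hr"])

    def contrast(self, col: str, level_a: str, level_b: str) -> dict:
        """Log-HR of ``level_a`` vs ``level_b`` for categorical ``col``."""
        levels = self.categorical_levels.get(col)
        if levels is None:
            raise ContractError(f"{col} was not declared categorical")
        ref = levels[0]

        def beta_var(level):
            if level == ref:
                return 0.0, None
            return float(self.params[f"{col}[{level}]"]), f"{col}[{level}]"

        ba, na = beta_var(level_a)
        bb, nb = beta_var(level_b)
        coef = ba - bb
        var = 0.0
        if na is not None:
            var += float(self.covariance.loc[na, na])
        if nb is not None:
            var += float(self.covariance.loc[nb, nb])
        if na is not None and nb is not None:
            var -= 2 * float(self.covariance.loc[na, nb])
        se = math.sqrt(max(var, 0.0))
        z = coef / se if se > 0 else float("inf") * np.sign(coef or 1.0)
        from scipy.stats import norm

        p = 2 * norm.sf(abs(z)) if np.isfinite(z) else 0.0
        return {
            "coef": coef,
            "hr": math.exp(coef),
            "ci_low": math.exp(coef - 1.959963984540054 * se),
            "ci_high": math.exp(coef + 1.959963984540054 * se),
            "p": float(p),
        }


def cox_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    categorical: dict[str, list[str]] | None = None,
) -> CoxFit:
    """Cox partial-likelihood fit (Efron ties) with categorical support.

    ``categorical`` maps a column to its ordered level list; the first
    level is the reference.  Constant covariates and non-convergence raise
    :class:`~epletmm.errors.CoxError`; complete separation surfaces as a
    warning, not an error.
    """
    categorical = categorical or {}
    design = pd.DataFrame(index=df.index)
    for col in covariates:
        if col in categorical:
            levels = categorical[col]
            observed = set(df[col].unique())
            unknown = observed - set(levels)
            if unknown:
                raise ContractError(f"{col}: undeclared levels {sorted(unknown)}")
            for level in levels[1:]:
                design[f"{col}[{level}]"] = (df[col] == level).astype(float)
        else:
            design[col] = pd.to_numeric(df[col])
    for c in design.columns:
        if design[c].nunique() < 2:
            raise CoxError(f"covariate {c} is constant across subjects")
    design[duration_col] = df[duration_col].astype(float)
    design[event_col] = df[event_col].astype(int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as e:
        raise CoxError(f"Cox model failed to converge: {e}") from e
    summ = cph.summary
    out = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_low": np.exp(summ["coef lower 95%"]),
            "ci_high": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    return CoxFit(
        summary=out,
        log_likelihood=float(cph.log_likelihood_),
        params=cph.params_.copy(),
        covariance=cph.variance_matrix_.copy(),
        categorical_levels=dict(categorical),
    )


# ---------------------------------------------------------------------------
# Outcomes I/O
# ---------------------------------------------------------------------------

OUTCOME_COLUMNS = [
    "pair_id",
    "ethnicity",
    "donor_type",
    "cni",
    "antimetabolite",
    "induction",
    "follow_up_years",
] + EXCLUSION_ORDER[:-1]  # dsa_within_14d is derived from detections

DETECTION_COLUMNS = ["pair_id", "day", "specificity", "mfi"]


def write_outcomes_csv(records: list[CohortRecord], outcomes_path, detections_path) -> None:
    rows = []
    det_rows = []
    for r in records:
        row = {
            "pair_id": r.pair_id,
            "ethnicity": r.ethnicity,
            "donor_type": r.donor_type,
            "cni": r.cni,
            "antimetabolite": r.antimetabolite,
            "induction": r.induction,
            "follow_up_years": r.follow_up_years,
        }
        for flag in EXCLUSION_ORDER[:-1]:
            row[flag] = int(bool(r.flags.get(flag)))
        rows.append(row)
        for d in r.detections:
            det_rows.append(
                {
                    "pair_id": r.pair_id,
                    "day": d.day,
                    "specificity": d.specificity,
                    "mfi": "" if d.mfi is None else d.mfi,
                }
            )
    pd.DataFrame(rows, columns=OUTCOME_COLUMNS).to_csv(outcomes_path, index=False)
    pd.DataFrame(det_rows, columns=DETECTION_COLUMNS).to_csv(detections_path, index=False)


def load_cohort_records(outcomes_path, detections_path) -> list[CohortRecord]:
    out_df = pd.read_csv(outcomes_path, dtype={"pair_id": str}, keep_default_na=False)
    det_df = pd.read_csv(detections_path, dtype={"pair_id": str}, keep_default_na=False)
    dets: dict[str, list[Detection]] = {}
    for r in det_df.itertuples(index=False):
        mfi = None if str(r.mfi) == "" else float(r.mfi)
        dets.setdefault(r.pair_id, []).append(
            Detection(day=float(r.day), specificity=str(r.specificity), mfi=mfi)
        )
    records = []
    for r in out_df.itertuples(index=False):
        flags = {
            flag: bool(int(getattr(r, flag))) for flag in EXCLUSION_ORDER[:-1]
            if hasattr(r, flag)
        }
        records.append(
            CohortRecord(
                pair_id=str(r.pair_id),
                ethnicity=str(r.ethnicity),
                donor_type=str(r.donor_type),
                cni=str(r.cni),
                antimetabolite=str(r.antimetabolite),
                induction=str(r.induction),
                follow_up_years=float(r.follow_up_years),
                detections=sorted(dets.get(str(r.pair_id), []), key=lambda d: d.day),
                flags=flags,
            )
        )
    return records
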