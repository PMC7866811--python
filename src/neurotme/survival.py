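"""Cox proportional-hazards machinery for the cohort analysis.

The protocol mirrors a classical exploratory survival workup on overall
mortality: every candidate variable is screened in a univariate Cox model
adjusted for age, gender and BMI (relevant if p < 0.05); relevant variables
are checked for pairwise interactions at the 5% level; a multivariable
model with backward selection (removal threshold p ≥ 0.05, adjusters never
removed, interaction hierarchy enforced) yields the final model; and an
exploratory interaction model of lymphoid-aggregate burden (LA ≥ 5), nerve
fiber density (NFD high) and tumor cellularity (TC) reports the NFD × LA
interaction together with within-stratum NFD hazard ratios via the delta
method.

Partial-likelihood maximization, Kaplan–Meier curves and the log-rank test
are delegated to ``lifelines`` (Efron tie handling, Wald inference); this
module owns the protocol, the design-matrix handling (``"a:b"`` interaction
columns), the hierarchy rules and the delta-method subgroup contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import ConvergenceError, DegenerateDesignError, DomainError, HierarchyError

__all__ = [
    "ALWAYS_KEEP",
    "ModelSpec",
    "CoxResult",
    "ScreenResult",
    "SelectionResult",
    "InteractionModelResult",
    "KMResult",
    "fit_cox",
    "univariate_screen",
    "pairwise_interaction_screen",
    "backward_select",
    "interaction_model",
    "km_curves",
    "cox_score_test",
]

#: Adjustment covariates kept in every model.
ALWAYS_KEEP = ("age", "gender01", "bmi")

_Z95 = 1.96


def _split_interaction(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


@dataclass(frozen=True)
class ModelSpec:
    """A covariate list (with ``"a:b"`` interaction terms) plus the always-
    kept adjusters.  Construction enforces the hierarchy principle: an
    interaction may only appear together with both of its main effects."""

    covariates: tuple[str, ...]
    always_keep: tuple[str, ...] = ALWAYS_KEEP

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        all_terms = set(self.covariates) | set(self.always_keep)
        for term in self.covariates:
            if ":" in term:
                for parent in _split_interaction(term):
                    if parent not in all_terms:
                        raise HierarchyError(
                            f"interaction {term!r} requires main effect {parent!r} "
                            "in the model"
                        )

    @property
    def terms(self) -> tuple[str, ...]:
        seen = list(self.always_keep)
        for t in self.covariates:
            if t not in seen:
                seen.append(t)
        return tuple(seen)


def build_design(
    table: pd.DataFrame, terms: Sequence[str],
    duration_col: str = "time", event_col: str = "event",
) -> pd.DataFrame:
    """Design frame for lifelines: covariate columns (interactions expanded
    as products) plus duration and event columns."""
    df = pd.DataFrame(index=table.index)
    for term in terms:
        if ":" in term:
            a, b = _split_interaction(term)
            df[term] = table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float)
        else:
            df[term] = table[term].to_numpy(dtype=float)
    df[duration_col] = table[duration_col].to_numpy(dtype=float)
    df[event_col] = table[event_col].to_numpy(dtype=float)
    return df


@dataclass
class CoxResult:
    """Per-term estimates of one Cox fit plus fit-level metadata.

    ``summary`` is indexed by term with columns ``coef``, ``se``, ``hr``,
    ``hr_lower``, ``hr_upper`` (Wald 95% limits) and ``p``;
    ``covariance`` is the estimated covariance of the coefficients.
    """

    summary: pd.DataFrame
    covariance: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    terms: tuple[str, ...]

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def p(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])

    def coef(self, term: str) -> float:
        return float(self.summary.loc[term, "coef"])


def fit_cox(
    table: pd.DataFrame,
    terms: Sequence[str] | ModelSpec,
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxResult:
    """Fit a Cox proportional-hazards model by partial likelihood.

    Efron's approximation handles tied event times; inference is Wald
    (hr = exp(coef), 95% limits exp(coef ± 1.96·se)).  Raises
    :class:`DegenerateDesignError` for constant or collinear covariates and
    :class:`ConvergenceError` when the Newton iterations fail.
    """
    if isinstance(terms, ModelSpec):
        terms = terms.terms
    terms = tuple(terms)
    if not terms:
        raise DegenerateDesignError("no covariates to fit")
    df = build_design(table, terms, duration_col, event_col)
    n_events = int(df[event_col].sum())
    if n_events < 1:
        raise DegenerateDesignError("no events in the data; Cox model undefined")
    X = df[list(terms)].to_numpy(dtype=float)
    sds = X.std(axis=0)
    constant = [t for t, s in zip(terms, sds) if s == 0]
    if constant:
        raise DegenerateDesignError(f"constant covariate(s): {constant}")
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < len(terms):
        raise DegenerateDesignError(
            f"design matrix is rank-deficient over terms {list(terms)}"
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except _LLConvergenceError as exc:
        raise ConvergenceError(f"Cox fit did not converge: {exc}") from exc
    coefs = cph.params_.reindex(list(terms))
    ses = cph.standard_errors_.reindex(list(terms))
    summary = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "hr": np.exp(coefs),
            "hr_lower": np.exp(coefs - _Z95 * ses),
            "hr_upper": np.exp(coefs + _Z95 * ses),
            "p": [2 * stats.norm.sf(abs(c / s)) for c, s in zip(coefs, ses)],
        }
    )
    cov = cph.variance_matrix_.reindex(index=list(terms), columns=list(terms))
    return CoxResult(
        summary=summary,
        covariance=cov,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=n_events,
        terms=terms,
    )


# ---------------------------------------------------------------------------
# Screening and selection
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    table: pd.DataFrame                       # one row per candidate
    relevant: list[str]
    errors: dict[str, str] = field(default_factory=dict)


def univariate_screen(
    table: pd.DataFrame,
    candidates: Sequence[str],
    alpha: float = 0.05,
    adjusters: Sequence[str] = ALWAYS_KEEP,
) -> ScreenResult:
    """Screen each candidate in a Cox model adjusted for age/gender/BMI.

    A candidate is relevant if its Wald p-value is below ``alpha``.
    Per-candidate fit errors are recorded, not fatal.
    """
    rows, relevant, errors = [], [], {}
    for cand in candidates:
        try:
            res = fit_cox(table, tuple(adjusters) + (cand,))
        except Exception as exc:  # noqa: BLE001 - recorded per candidate
            errors[cand] = str(exc)
            continue
        row = res.summary.loc[cand]
        rows.append(
            {
                "candidate": cand, "hr": row["hr"], "hr_lower": row["hr_lower"],
                "hr_upper": row["hr_upper"], "p": row["p"],
                "relevant": bool(row["p"] < alpha),
            }
        )
        if row["p"] < alpha:
            relevant.append(cand)
    out = pd.DataFrame(
        rows, columns=["candidate", "hr", "hr_lower", "hr_upper", "p", "relevant"]
    )
    return ScreenResult(table=out, relevant=relevant, errors=errors)


def pairwise_interaction_screen(
    table: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.05,
    adjusters: Sequence[str] = ALWAYS_KEEP,
) -> list[str]:
    """Test each pair of variables for interaction (adjusted model with both
    mains + product); return the ``"a:b"`` terms significant at ``alpha``."""
    selected = []
    variables = list(variables)
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            term = f"{a}:{b}"
            try:
                res = fit_cox(table, tuple(adjusters) + (a, b, term))
            except Exception:  # noqa: BLE001 - screening is best-effort
                continue
            if res.p(term) < alpha:
                selected.append(term)
    return selected


@dataclass
class SelectionResult:
    final: CoxResult
    removed: list[tuple[str, float]]          # (term, p at removal)


def backward_select(
    table: pd.DataFrame,
    spec: ModelSpec,
    alpha_remove: float = 0.05,
) -> SelectionResult:
    """Backward elimination at ``alpha_remove`` with protected adjusters.

    Repeatedly removes the highest-p removable term with p ≥ alpha_remove
    and refits.  The adjusters are never removed, and a main effect is not
    removable while an interaction containing it remains (hierarchy).
    """
    current = list(spec.covariates)
    removed: list[tuple[str, float]] = []
    while True:
        res = fit_cox(table, tuple(spec.always_keep) + tuple(current))
        removable = []
        for term in current:
            if ":" not in term and any(
                ":" in t and term in _split_interaction(t) for t in current
            ):
                continue
            removable.append(term)
        if not removable:
            return SelectionResult(final=res, removed=removed)
        ps = {t: res.p(t) for t in removable}
        worst = max(ps, key=ps.get)
        if ps[worst] < alpha_remove:
            return SelectionResult(final=res, removed=removed)
        current.remove(worst)
        removed.append((worst, ps[worst]))


# ---------------------------------------------------------------------------
# Exploratory LA / NFD / TC interaction model
# ---------------------------------------------------------------------------

@dataclass
class InteractionModelResult:
    cox: CoxResult
    la_tc_dropped: bool
    la_nfd_p: float
    subgroups: pd.DataFrame    # stratum, hr, hr_lower, hr_upper (high vs low NFD)


def interaction_model(
    table: pd.DataFrame,
    la_col: str = "la_ge5",
    nfd_col: str = "nfd_high",
    tc_col: str = "tc",
    alpha: float = 0.05,
) -> InteractionModelResult:
    """Exploratory model {LA, NFD, TC, LA×NFD, LA×TC} on overall mortality.

    The LA×TC interaction is removed (and the model refitted) when its
    p-value is ≥ ``alpha``.  Reported subgroup hazard ratios of high- vs
    low-NFD are exp(β_nfd + β_int) within LA ≥ 5 and exp(β_nfd) within
    LA < 5, with delta-method Wald intervals from the coefficient
    covariance.
    """
    la_nfd = f"{la_col}:{nfd_col}"
    la_tc = f"{la_col}:{tc_col}"
    terms = (la_col, nfd_col, tc_col, la_nfd, la_tc)
    res = fit_cox(table, ALWAYS_KEEP + terms)
    dropped = False
    if res.p(la_tc) >= alpha:
        dropped = True
        res = fit_cox(table, ALWAYS_KEEP + (la_col, nfd_col, tc_col, la_nfd))

    b_nfd = res.coef(nfd_col)
    b_int = res.coef(la_nfd)
    v_nfd = float(res.covariance.loc[nfd_col, nfd_col])
    v_int = float(res.covariance.loc[la_nfd, la_nfd])
    cov = float(res.covariance.loc[nfd_col, la_nfd])
    rows = []
    for stratum, est, var in (
        ("la_ge5", b_nfd + b_int, v_nfd + v_int + 2 * cov),
        ("la_lt5", b_nfd, v_nfd),
    ):
        se = float(np.sqrt(var))
        rows.append(
            {
                "stratum": stratum,
                "hr": float(np.exp(est)),
                "hr_lower": float(np.exp(est - _Z95 * se)),
                "hr_upper": float(np.exp(est + _Z95 * se)),
            }
        )
    return InteractionModelResult(
        cox=res,
        la_tc_dropped=dropped,
        la_nfd_p=res.p(la_nfd),
        subgroups=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and the log-rank / score tests
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    curves: dict                    # group -> DataFrame(time, survival)
    logrank_stat: float
    logrank_p: float

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for group, curve in self.curves.items():
            ax.step(curve["time"], curve["survival"], where="post", label=str(group))
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend(title=f"log-rank p = {self.logrank_p:.4f}")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


def km_curves(
    table: pd.DataFrame,
    group_col: str,
    duration_col: str = "time",
    event_col: str = "event",
) -> KMResult:
    """Product-limit survival estimate per group plus the log-rank test."""
    groups = table[group_col].unique()
    if len(groups) == 0 or table.empty:
        raise DomainError("no subjects to estimate survival from")
    curves = {}
    for g in sorted(groups, key=str):
        sub = table[table[group_col] == g]
        if sub.empty:
            raise DomainError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    if len(groups) > 1:
        lr = multivariate_logrank_test(
            table[duration_col], table[group_col], table[event_col]
        )
        stat, p = float(lr.test_statistic), float(lr.p_value)
    else:
        stat, p = 0.0, 1.0
    return KMResult(curves=curves, logrank_stat=stat, logrank_p=p)


def cox_score_test(
    table: pd.DataFrame,
    covariate: str,
    duration_col: str = "time",
    event_col: str = "event",
) -> tuple[float, float]:
    """Cox partial-likelihood score test of H0: β = 0 for one covariate.

    Computed directly from the score and information at β = 0 (assumes
    untied event times); with a binary covariate and no ties this is
    algebraically the log-rank test.  Returns (chi², p).
    """
    df = table[[duration_col, event_col, covariate]].sort_values(
        duration_col, ascending=False
    )
    x = df[covariate].to_numpy(dtype=float)
    e = df[event_col].to_numpy(dtype=float)
    # risk sets accumulate as times decrease
    s0 = np.arange(1, len(x) + 1, dtype=float)
    s1 = np.cumsum(x)
    s2 = np.cumsum(x**2)
    ev = e == 1
    u = float((x[ev] - s1[ev] / s0[ev]).sum())
    info = float((s2[ev] / s0[ev] - (s1[ev] / s0[ev]) ** 2).sum())
    if info <= 0:
        raise DegenerateDesignError("zero information; covariate constant in risk sets")
    chi2 = u**2 / info
    return chi2, float(stats.chi2.sf(chi2, df=1))
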