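"""Disproportionality statistics for drug–event signal detection.

Implements the four estimators routinely used to mine spontaneous-report
databases — reporting odds ratio (ROR), proportional reporting ratio (PRR)
with a Yates-corrected chi-square, the BCPNN information component (IC), and
the DuMouchel multi-item gamma-Poisson shrinker (MGPS / EBGM) — together with
the conventional signal thresholds, a strong-signal classification, and
top-k ranking.

All statistics operate on a 2x2 contingency table built over deduplicated
cases:

    a  cases with the target drug (primary suspect) and the target event
    b  cases with the target drug, without the event
    c  cases with the event under any other drug
    d  cases with neither
    N  = a + b + c + d, the database case total

A (drug, event) pair is a *signal* when, simultaneously (the ``all``
policy):

    ROR:   95% CI lower bound > 1 and a >= 3
    PRR:   PRR >= 2, chi2 >= 4, a >= 3
    BCPNN: IC - 2SD > 0 and a >= 3
    MGPS:  EB05 (5th posterior percentile of the shrunken rate) > 2
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import optimize
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import gamma as gamma_dist

__all__ = [
    "ContingencyTable",
    "MgpsPrior",
    "DUMOUCHEL_START",
    "SignalStats",
    "SignalRow",
    "DatabaseResult",
    "build_tables",
    "compute_ror",
    "compute_prr",
    "compute_bcpnn",
    "fit_mgps_prior",
    "mgps_marginal_loglik",
    "compute_ebgm",
    "classify_signal",
    "SignalThresholds",
    "DEFAULT_THRESHOLDS",
    "strong_condition",
    "rank_top_k",
    "evaluate_database",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug–event table over deduplicated cases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count under row/column independence, E = (a+b)(a+c)/N."""
        if self.n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n


class RorResult(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float
    flags: tuple[str, ...] = ()


class PrrResult(NamedTuple):
    prr: float
    chi2: float
    flags: tuple[str, ...] = ()


class BcpnnResult(NamedTuple):
    ic: float
    ic_minus_2sd: float


class EbgmResult(NamedTuple):
    ebgm: float
    eb05: float
    flags: tuple[str, ...] = ()


def _corrected(t: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """Haldane–Anscombe +0.5 on all four cells when any of b, c, d is zero.

    a = 0 is handled upstream (short-circuits to a null statistic), so the
    correction here only fires for degenerate comparator/margin cells.
    """
    if t.b == 0 or t.c == 0 or t.d == 0:
        return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, True
    return float(t.a), float(t.b), float(t.c), float(t.d), False


def compute_ror(t: ContingencyTable) -> RorResult:
    """Reporting odds ratio (a·d)/(b·c) with the Woolf log-scale 95% CI.

    CI: exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d)).
    a=0 returns ROR 0 with an undefined CI (flag ``undefined_ci``); a zero
    b/c/d cell triggers the +0.5 continuity correction (flag
    ``continuity_corrected``).
    """
    if t.a == 0:
        return RorResult(0.0, math.nan, math.nan, ("undefined_ci",))
    a, b, c, d, corrected = _corrected(t)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = ror * math.exp(-Z_95 * se)
    hi = ror * math.exp(Z_95 * se)
    return RorResult(ror, lo, hi, ("continuity_corrected",) if corrected else ())


def compute_prr(t: ContingencyTable) -> PrrResult:
    """Proportional reporting ratio and Yates-corrected chi-square.

    PRR = [a/(a+b)] / [c/(c+d)] with the comparator excluding the drug's own
    cohort; chi2 = N(|ad−bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)], the continuity
    term capped at |ad−bc| so the numerator never goes negative.
    """
    if t.a == 0:
        return PrrResult(0.0, 0.0, ())
    a, b, c, d, corrected = _corrected(t)
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    dev = abs(a * d - b * c)
    num = max(dev - n / 2.0, 0.0)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = n * num * num / denom
    return PrrResult(prr, chi2, ("continuity_corrected",) if corrected else ())


def compute_bcpnn(t: ContingencyTable) -> BcpnnResult:
    """Information component of the BCPNN with its lower 2-SD bound.

    Closed-form posterior moments of IC = log2 of the Bayes-smoothed
    observed/expected ratio, with the standard constants gamma11 = 1,
    alpha1 = beta1 = 1, alpha = beta = 2 and the data-dependent
    gamma = (N+alpha)(N+beta) / [(a+b+alpha1)(a+c+beta1)].
    """
    if t.n <= 0:
        raise ValueError("empty table")
    a, n = float(t.a), float(t.n)
    ab = float(t.a + t.b)
    ac = float(t.a + t.c)
    g11, a1, b1, al, be = 1.0, 1.0, 1.0, 2.0, 2.0
    g = g11 * (n + al) * (n + be) / ((ab + a1) * (ac + b1))
    ic = math.log2((a + g11) * (n + al) * (n + be) / ((n + g) * (ab + a1) * (ac + b1)))
    var = (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - ab + al - a1) / ((ab + a1) * (1 + n + al))
        + (n - ac + be - b1) / ((ac + b1) * (1 + n + be))
    ) / math.log(2) ** 2
    return BcpnnResult(ic, ic - 2.0 * math.sqrt(var))


# ---------------------------------------------------------------------------
# MGPS — DuMouchel's gamma-Poisson shrinker


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the relative reporting rate.

    Component k has shape ``alphak`` and rate ``betak``; ``p_mix`` is the
    weight of component 1. Marginally each count a is negative-binomial.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    converged: bool = True

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.p_mix < 1:
            raise ValueError("p_mix must lie in (0, 1)")


DUMOUCHEL_START = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    """log NB(a; alpha, q) with q = beta/(beta+E): the gamma-Poisson marginal."""
    log_q = np.log(beta) - np.log(beta + e)
    log_1mq = np.log(e) - np.log(beta + e)
    return gammaln(alpha + a) - gammaln(alpha) - gammaln(a + 1) + alpha * log_q + a * log_1mq


def mgps_marginal_loglik(prior: MgpsPrior, a: np.ndarray, e: np.ndarray) -> float:
    """Marginal log likelihood of counts ``a`` at expecteds ``e`` under the prior."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    with np.errstate(divide="ignore"):  # a boundary mixture weight is a -inf term
        l1 = np.log(prior.p_mix) + _nb_logpmf(a, prior.alpha1, prior.beta1, e)
        l2 = np.log1p(-prior.p_mix) + _nb_logpmf(a, prior.alpha2, prior.beta2, e)
    return float(np.sum(logsumexp(np.stack([l1, l2]), axis=0)))


def fit_mgps_prior(
    tables: Sequence[ContingencyTable],
    start: MgpsPrior = DUMOUCHEL_START,
    min_tables: int = 50,
) -> MgpsPrior:
    """Maximum-marginal-likelihood fit of the five MGPS hyperparameters.

    Optimizes in (log alpha1, log beta1, log alpha2, log beta2, logit p) by
    L-BFGS-B from the DuMouchel starting point. Requires at least
    ``min_tables`` tables with E > 0. Non-convergence — or a degenerate
    all-zero count vector — falls back to the start values with
    ``converged=False``.
    """
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    keep = e > 0
    a, e = a[keep], e[keep]
    if a.size < min_tables:
        raise ValueError(f"need >= {min_tables} tables with E > 0, got {a.size}")
    if not np.any(a > 0):
        return replace(start, converged=False)

    def unpack(x: np.ndarray) -> tuple[float, float, float, float, float]:
        a1, b1, a2, b2 = np.exp(x[:4])
        p = 1.0 / (1.0 + np.exp(-x[4]))
        return a1, b1, a2, b2, p

    def nll(x: np.ndarray) -> float:
        a1, b1, a2, b2, p = unpack(x)
        with np.errstate(divide="ignore"):  # p can hit 0/1 during line search
            l1 = np.log(p) + _nb_logpmf(a, a1, b1, e)
            l2 = np.log1p(-p) + _nb_logpmf(a, a2, b2, e)
        return -float(np.sum(logsumexp(np.stack([l1, l2]), axis=0)))

    x0 = np.array(
        [
            math.log(start.alpha1),
            math.log(start.beta1),
            math.log(start.alpha2),
            math.log(start.beta2),
            math.log(start.p_mix / (1 - start.p_mix)),
        ]
    )
    res = optimize.minimize(nll, x0, method="L-BFGS-B")
    if not res.success or not np.all(np.isfinite(res.x)):
        return replace(start, converged=False)
    a1, b1, a2, b2, p = unpack(res.x)
    return MgpsPrior(a1, b1, a2, b2, p, converged=True)


def _posterior_q(t_a: float, e: float, prior: MgpsPrior) -> float:
    """Posterior weight of mixture component 1 given the observed count."""
    arr = np.array([t_a], dtype=float)
    earr = np.array([e], dtype=float)
    l1 = math.log(prior.p_mix) + float(_nb_logpmf(arr, prior.alpha1, prior.beta1, earr)[0])
    l2 = math.log1p(-prior.p_mix) + float(_nb_logpmf(arr, prior.alpha2, prior.beta2, earr)[0])
    m = max(l1, l2)
    w1 = math.exp(l1 - m)
    w2 = math.exp(l2 - m)
    return w1 / (w1 + w2)


def compute_ebgm(t: ContingencyTable, prior: MgpsPrior) -> EbgmResult:
    """Empirical-Bayes geometric mean (EBGM) and 5th percentile (EB05).

    Posterior on the relative reporting rate lambda is a two-component gamma
    mixture: weights Q and 1-Q (posterior component probabilities), shapes
    alphak + a, rates betak + E. EBGM = exp(E[ln lambda]); EB05 solves the
    mixture CDF at 0.05 by root finding to 1e-9 relative on lambda.
    """
    e = t.expected
    if e <= 0:
        return EbgmResult(math.nan, math.nan, ("undefined_expected",))
    q = _posterior_q(t.a, e, prior)
    s1, r1 = prior.alpha1 + t.a, prior.beta1 + e
    s2, r2 = prior.alpha2 + t.a, prior.beta2 + e
    ebgm = math.exp(q * (digamma(s1) - math.log(r1)) + (1 - q) * (digamma(s2) - math.log(r2)))

    def cdf(x: float) -> float:
        return q * gamma_dist.cdf(x, s1, scale=1 / r1) + (1 - q) * gamma_dist.cdf(
            x, s2, scale=1 / r2
        )

    lo = 0.5 * min(gamma_dist.ppf(0.05, s1, scale=1 / r1), gamma_dist.ppf(0.05, s2, scale=1 / r2))
    hi = 2.0 * max(gamma_dist.ppf(0.05, s1, scale=1 / r1), gamma_dist.ppf(0.05, s2, scale=1 / r2))
    lo = max(lo, 1e-300)
    eb05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, rtol=1e-9, xtol=1e-12)
    return EbgmResult(ebgm, float(eb05), ())


# ---------------------------------------------------------------------------
# Signal classification


class SignalFlags(NamedTuple):
    ror_sig: bool
    prr_sig: bool
    bcpnn_sig: bool
    mgps_sig: bool
    signal: bool


@dataclass
class SignalStats:
    """All four statistics for one (drug, event) pair plus their signal flags."""

    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ic: float
    ic_minus_2sd: float
    ebgm: float
    eb05: float
    flags: tuple[str, ...] = ()
    ror_sig: bool = False
    prr_sig: bool = False
    bcpnn_sig: bool = False
    mgps_sig: bool = False
    signal: bool = False
    strong_condition: str = "none"


@dataclass(frozen=True)
class SignalThresholds:
    """Per-method screening thresholds (defaults are the conventional ones)."""

    min_a: int = 3  # minimum case count for ROR/PRR/BCPNN
    ror_ci_low: float = 1.0  # strict >
    prr: float = 2.0  # inclusive >=
    chi2: float = 4.0  # inclusive >=
    ic_minus_2sd: float = 0.0  # strict >
    eb05: float = 2.0  # strict >

    def __post_init__(self) -> None:
        if self.min_a < 0 or min(self.ror_ci_low, self.prr, self.chi2, self.eb05) < 0:
            raise ValueError("thresholds must be non-negative")


DEFAULT_THRESHOLDS = SignalThresholds()


def classify_signal(
    s: SignalStats,
    a: int,
    policy: str = "all",
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
) -> SignalFlags:
    """Apply the per-method thresholds and the combination policy.

    Defaults (inclusive/exclusive exactly as conventional): ROR CI lower
    bound strictly > 1 with a >= 3; PRR >= 2 with chi2 >= 4 and a >= 3;
    IC − 2SD strictly > 0 with a >= 3; EB05 strictly > 2. ``policy`` is
    ``all`` (conjunction, default) or ``any``.
    """
    if policy not in ("all", "any"):
        raise ValueError(f"unknown policy {policy!r}")
    th = thresholds
    ror_sig = bool(
        not math.isnan(s.ror_ci_low) and s.ror_ci_low > th.ror_ci_low and a >= th.min_a
    )
    prr_sig = bool(s.prr >= th.prr and s.chi2 >= th.chi2 and a >= th.min_a)
    bcpnn_sig = bool(a >= th.min_a and s.ic_minus_2sd > th.ic_minus_2sd)
    mgps_sig = bool(not math.isnan(s.eb05) and s.eb05 > th.eb05)
    votes = (ror_sig, prr_sig, bcpnn_sig, mgps_sig)
    signal = all(votes) if policy == "all" else any(votes)
    return SignalFlags(ror_sig, prr_sig, bcpnn_sig, mgps_sig, signal)


class StrongResult(NamedTuple):
    label: str  # none | A | B | C | D
    cond_a: bool
    cond_b: bool
    cond_c: bool
    cond_d: bool


def strong_condition(
    s: SignalStats,
    other_ics: Iterable[float] = (),
    metric: str = "ic",
) -> StrongResult:
    """Strong-signal classification for a positive signal.

    A: ROR, PRR and EBGM all exceed 10. B: IC exceeds 3. C: A and B together.
    D: this drug's signal strength (IC by default, EBGM via ``metric``)
    strictly exceeds that of every other drug with a positive signal for the
    same event — vacuously true when no other drug signals it. The label is
    the highest-priority condition that holds, priority C > D > A > B.
    """
    cond_a = s.ror > 10 and s.prr > 10 and s.ebgm > 10
    cond_b = s.ic > 3
    cond_c = cond_a and cond_b
    own = s.ic if metric == "ic" else s.ebgm
    cond_d = all(own > o for o in other_ics)
    for label, hit in (("C", cond_c), ("D", cond_d), ("A", cond_a), ("B", cond_b)):
        if hit:
            return StrongResult(label, cond_a, cond_b, cond_c, cond_d)
    return StrongResult("none", cond_a, cond_b, cond_c, cond_d)


# ---------------------------------------------------------------------------
# Table construction and database-level evaluation


def build_tables(cases: Sequence, drug_group: str) -> dict[str, ContingencyTable]:
    """2x2 tables for one drug cohort against every event PT ever reported.

    A case belongs to the cohort iff it has at least one primary-suspect
    mention of ``drug_group``. For every PT: a = cohort cases reporting it,
    b = cohort remainder, c = non-cohort cases reporting it, d = the rest;
    a+b+c+d = N for every PT.
    """
    n = len(cases)
    if n == 0:
        return {}
    cohort = [case.in_cohort(drug_group) for case in cases]
    n_cohort = sum(cohort)
    a_counts: Counter[str] = Counter()
    pt_totals: Counter[str] = Counter()
    for case, is_in in zip(cases, cohort):
        for pt in case.events:
            pt_totals[pt] += 1
            if is_in:
                a_counts[pt] += 1
    tables = {}
    for pt, total in pt_totals.items():
        a = a_counts.get(pt, 0)
        c = total - a
        tables[pt] = ContingencyTable(a=a, b=n_cohort - a, c=c, d=n - n_cohort - c)
    return tables


@dataclass
class SignalRow:
    """One evaluated (drug, event) pair, flattened for tabular output."""

    drug: str
    pt: str
    a: int
    stats: SignalStats

    @property
    def ic(self) -> float:
        return self.stats.ic

    @property
    def signal(self) -> bool:
        return self.stats.signal

    def to_dict(self) -> dict:
        s = self.stats
        return {
            "drug": self.drug,
            "pt": self.pt,
            "a": self.a,
            "ror": s.ror,
            "ror_ci_low": s.ror_ci_low,
            "ror_ci_high": s.ror_ci_high,
            "prr": s.prr,
            "chi2": s.chi2,
            "ic": s.ic,
            "ic_minus_2sd": s.ic_minus_2sd,
            "ebgm": s.ebgm,
            "eb05": s.eb05,
            "ror_sig": s.ror_sig,
            "prr_sig": s.prr_sig,
            "bcpnn_sig": s.bcpnn_sig,
            "mgps_sig": s.mgps_sig,
            "signal": s.signal,
            "strong_condition": s.strong_condition,
            "flags": ";".join(s.flags),
        }


@dataclass
class DatabaseResult:
    """Full disproportionality evaluation of one deduplicated database."""

    n_cases: int
    cohort_sizes: dict[str, int]
    prior: MgpsPrior
    rows: dict[str, list[SignalRow]]  # drug -> evaluated pairs (a >= 1)

    def signals(self, drug: str) -> list[SignalRow]:
        return [r for r in self.rows.get(drug, []) if r.signal]


def _evaluate_table(
    t: ContingencyTable,
    prior: MgpsPrior,
    policy: str,
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
) -> SignalStats:
    ror = compute_ror(t)
    prr = compute_prr(t)
    bc = compute_bcpnn(t)
    eb = compute_ebgm(t, prior)
    s = SignalStats(
        ror=ror.ror,
        ror_ci_low=ror.ci_low,
        ror_ci_high=ror.ci_high,
        prr=prr.prr,
        chi2=prr.chi2,
        ic=bc.ic,
        ic_minus_2sd=bc.ic_minus_2sd,
        ebgm=eb.ebgm,
        eb05=eb.eb05,
        flags=tuple(dict.fromkeys(ror.flags + prr.flags + eb.flags)),
    )
    fl = classify_signal(s, t.a, policy=policy, thresholds=thresholds)
    s.ror_sig, s.prr_sig, s.bcpnn_sig, s.mgps_sig, s.signal = fl
    return s


def evaluate_database(
    cases: Sequence,
    drug_groups: Sequence[str],
    policy: str = "all",
    prior: MgpsPrior | None = None,
    strong_metric: str = "ic",
    thresholds: SignalThresholds = DEFAULT_THRESHOLDS,
) -> DatabaseResult:
    """Evaluate every (drug group, PT) pair with a >= 1 across the database.

    The MGPS prior is fitted once on the pooled a >= 1 tables of all drug
    groups (falling back to the DuMouchel start when fewer than 50 such
    tables exist), then applied per table. Strong-signal conditions compare
    IC across drugs with a positive signal for the same PT.
    """
    tables_by_drug = {g: build_tables(cases, g) for g in drug_groups}
    pooled = [t for tabs in tables_by_drug.values() for t in tabs.values() if t.a >= 1]
    if prior is None:
        try:
            prior = fit_mgps_prior(pooled)
        except ValueError:
            prior = replace(DUMOUCHEL_START, converged=False)
    rows: dict[str, list[SignalRow]] = {}
    for g, tabs in tables_by_drug.items():
        rows[g] = [
            SignalRow(g, pt, t.a, _evaluate_table(t, prior, policy, thresholds))
            for pt, t in sorted(tabs.items())
            if t.a >= 1
        ]
    # cross-drug strong-signal comparison among positive signals per PT
    ic_by_pt: dict[str, dict[str, float]] = {}
    for g, rlist in rows.items():
        for r in rlist:
            if r.signal:
                ic_by_pt.setdefault(r.pt, {})[g] = (
                    r.stats.ic if strong_metric == "ic" else r.stats.ebgm
                )
    for g, rlist in rows.items():
        for r in rlist:
            if r.signal:
                others = [v for d, v in ic_by_pt.get(r.pt, {}).items() if d != g]
                r.stats.strong_condition = strong_condition(
                    r.stats, others, metric=strong_metric
                ).label
    cohort_sizes = {
        g: (next(iter(tabs.values())).a + next(iter(tabs.values())).b) if tabs else 0
        for g, tabs in tables_by_drug.items()
    }
    return DatabaseResult(
        n_cases=len(cases), cohort_sizes=cohort_sizes, prior=prior, rows=rows
    )


def rank_top_k(signals: Sequence[SignalRow], k: int) -> list[SignalRow]:
    """Top-k signals by case count a (desc), ties by IC (desc) then PT name."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted(signals, key=lambda r: (-r.a, -r.ic, r.pt))[:k]
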