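"""Trial endpoint statistics: composite lesion response, ORR/DCR, survival, design.

Implements the composite response rule for patients with intrahepatic and
extrahepatic lesions, response-rate endpoints with exact binomial intervals,
Kaplan–Meier estimation, the log-rank test with an O/E hazard-ratio
approximation, and the Freedman log-rank sample-size formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
LESION_LEVELS = ("CR", "PR", "SD", "PD", "NE", "NONE")


# ---------------------------------------------------------------------------
# Composite response


def combine_lesion_responses(intrahepatic: str, extrahepatic: str) -> str:
    """Combine per-compartment lesion responses into an overall response.

    ``NONE`` marks a compartment with no lesion; at least one compartment
    must have a lesion.  Rules, in order of precedence:

    - PD in any compartment dominates (progression anywhere is progression);
    - otherwise NE in any assessed compartment makes the overall response NE;
    - CR requires CR in every assessed compartment;
    - PR requires every assessed compartment in {CR, PR} (not all CR);
    - SD otherwise (all assessed in {CR, PR, SD}, at least one SD).

    A single-compartment patient takes that compartment's response.
    """
    for name, level in (("intrahepatic", intrahepatic), ("extrahepatic", extrahepatic)):
        if level not in LESION_LEVELS:
            raise ValueError(f"invalid {name} lesion response: {level!r}")
    present = [r for r in (intrahepatic, extrahepatic) if r != "NONE"]
    if not present:
        raise ValueError("patient has no lesion in either compartment")
    if "PD" in present:
        return "PD"
    if "NE" in present:
        return "NE"
    if all(r == "CR" for r in present):
        return "CR"
    if all(r in ("CR", "PR") for r in present):
        return "PR"
    # remaining levels are all in {CR, PR, SD} with >=1 SD
    return "SD"


# ---------------------------------------------------------------------------
# Response rates


@dataclass
class ResponseTable:
    """Per-arm counts over the five response categories (ITT denominators)."""

    counts: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        for arm, cat_counts in self.counts.items():
            for cat in cat_counts:
                if cat not in RESPONSE_CATEGORIES:
                    raise ValueError(f"unknown response category {cat!r} in arm {arm!r}")
            if any(v < 0 for v in cat_counts.values()):
                raise ValueError(f"negative count in arm {arm!r}")

    @property
    def arms(self) -> list[str]:
        return list(self.counts)

    def arm_size(self, arm: str) -> int:
        return int(sum(self.counts[arm].values()))

    def count(self, arm: str, category: str) -> int:
        return int(self.counts[arm].get(category, 0))

    @classmethod
    def from_responses(cls, arms, responses) -> "ResponseTable":
        """Tabulate per-patient (arm, overall response) pairs."""
        counts: dict[str, dict[str, int]] = {}
        for arm, resp in zip(arms, responses, strict=True):
            if resp not in RESPONSE_CATEGORIES:
                raise ValueError(f"unknown response category {resp!r}")
            counts.setdefault(arm, {c: 0 for c in RESPONSE_CATEGORIES})[resp] += 1
        return cls(counts)


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def response_rates(table: ResponseTable, ci_level: float = 0.95) -> dict:
    """ORR = (CR+PR)/n and DCR = (CR+PR+SD)/n per arm, NE in the denominator.

    Returns per-arm dicts with proportions and exact (Clopper–Pearson)
    binomial confidence intervals.
    """
    out = {}
    for arm in table.arms:
        n = table.arm_size(arm)
        if n == 0:
            raise ValueError(f"arm {arm!r} has zero patients")
        resp = table.count(arm, "CR") + table.count(arm, "PR")
        ctrl = resp + table.count(arm, "SD")
        out[arm] = {
            "n": n,
            "orr": resp / n,
            "dcr": ctrl / n,
            "orr_ci": _clopper_pearson(resp, n, ci_level),
            "dcr_ci": _clopper_pearson(ctrl, n, ci_level),
        }
    return out


@dataclass
class RateComparison:
    statistic: float | None
    p_value: float
    method: str
    table: np.ndarray


def compare_rates(table: ResponseTable, endpoint: str = "orr") -> RateComparison:
    """Compare responder proportions between two arms.

    Collapses to a 2x2 responder/non-responder table and applies the
    chi-square test with continuity correction, falling back to Fisher's
    exact test when any expected cell count is below 5 or a margin is
    degenerate.
    """
    if endpoint not in ("orr", "dcr"):
        raise ValueError("endpoint must be 'orr' or 'dcr'")
    if len(table.arms) != 2:
        raise ValueError("compare_rates requires exactly two arms")
    cats = ("CR", "PR") if endpoint == "orr" else ("CR", "PR", "SD")
    rows = []
    for arm in table.arms:
        k = sum(table.count(arm, c) for c in cats)
        rows.append([k, table.arm_size(arm) - k])
    contingency = np.asarray(rows, dtype=float)
    degenerate = (contingency.sum(axis=0) == 0).any() or (
        contingency.sum(axis=1) == 0
    ).any()
    if not degenerate:
        expected = stats.contingency.expected_freq(contingency)
        # small expected counts, or an empty observed cell, route to the
        # exact test
        use_fisher = (expected < 5).any() or (contingency == 0).any()
    else:
        use_fisher = True
    if use_fisher:
        _, p = stats.fisher_exact(contingency.astype(int))
        return RateComparison(None, float(p), "fisher", contingency)
    chi2, p, _, _ = stats.chi2_contingency(contingency, correction=True)
    return RateComparison(float(chi2), float(p), "chi2_yates", contingency)


# ---------------------------------------------------------------------------
# Survival


@dataclass
class KMResult:
    """Product-limit estimate: right-continuous step function."""

    times: np.ndarray       # distinct event times, increasing
    survival: np.ndarray    # S(t) just after each event time
    median: float           # nan when the curve never reaches 0.5
    median_defined: bool
    n: int
    n_events: int

    def rate_at(self, t: float) -> float:
        """Survival probability read off the step function at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMResult:
    """Kaplan–Meier product-limit estimator.

    Median = earliest time at which the curve drops to <= 0.5; flagged as
    undefined (not an error) when no events occur or the curve stays above
    0.5 throughout.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape or times.ndim != 1 or times.size == 0:
        raise ValueError("times and events must be equal-length 1-d arrays")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")

    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    n = times.size
    event_times, surv = [], []
    s = 1.0
    i = 0
    while i < n:
        t = t_sorted[i]
        j = i
        d = 0
        while j < n and t_sorted[j] == t:
            d += int(e_sorted[j])
            j += 1
        at_risk = n - i
        if d > 0:
            s *= 1.0 - d / at_risk
            event_times.append(t)
            surv.append(s)
        i = j
    surv_arr = np.asarray(surv, dtype=float)
    t_arr = np.asarray(event_times, dtype=float)
    below = np.nonzero(surv_arr <= 0.5)[0]
    if below.size:
        median, defined = float(t_arr[below[0]]), True
    else:
        median, defined = float("nan"), False
    return KMResult(t_arr, surv_arr, median, defined, n, int(events.sum()))


@dataclass
class LogrankResult:
    observed: dict[str, float]
    expected: dict[str, float]
    statistic: float
    p_value: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    arms: tuple[str, str]


def logrank_and_hr(
    times, events, arms, arm_order: tuple[str, str] | None = None,
    ci_level: float = 0.95,
) -> LogrankResult:
    """Two-group log-rank test with the O/E hazard-ratio approximation.

    The statistic is the usual (O1-E1)^2 / V with the hypergeometric
    variance summed over event times; HR = (O1/E1)/(O2/E2) for
    ``arm_order[0]`` versus ``arm_order[1]`` with a log-scale confidence
    interval using se(log HR) = sqrt(1/E1 + 1/E2).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    arms = np.asarray(arms)
    labels = list(dict.fromkeys(arms.tolist()))
    if arm_order is None:
        arm_order = tuple(sorted(labels))  # type: ignore[assignment]
    if len(labels) != 2 or set(labels) != set(arm_order):
        raise ValueError("logrank_and_hr requires exactly two arms")
    g1 = arms == arm_order[0]
    if events[g1].sum() == 0 or events[~g1].sum() == 0:
        raise ValueError("each arm must have at least one event")

    o1 = e1 = v = 0.0
    event_times = np.unique(times[events])
    for t in event_times:
        at_risk = times >= t
        n_j = at_risk.sum()
        n1_j = (at_risk & g1).sum()
        dying = events & (times == t)
        d_j = dying.sum()
        d1_j = (dying & g1).sum()
        o1 += d1_j
        e1 += d_j * n1_j / n_j
        if n_j > 1:
            v += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    o_total = float(events.sum())
    o2, e2 = o_total - o1, o_total - e1
    statistic = (o1 - e1) ** 2 / v if v > 0 else 0.0
    p = float(stats.chi2.sf(statistic, df=1)) if v > 0 else 1.0
    hr = (o1 / e1) / (o2 / e2)
    se = math.sqrt(1.0 / e1 + 1.0 / e2)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    ci = (hr * math.exp(-z * se), hr * math.exp(z * se))
    return LogrankResult(
        observed={arm_order[0]: float(o1), arm_order[1]: float(o2)},
        expected={arm_order[0]: float(e1), arm_order[1]: float(e2)},
        statistic=float(statistic),
        p_value=p,
        hazard_ratio=float(hr),
        hr_ci=(float(ci[0]), float(ci[1])),
        arms=tuple(arm_order),
    )


def cox_hr(times, events, arms, arm_order: tuple[str, str] | None = None) -> dict:
    """Proportional-hazards regression HR (optional companion to the O/E value)."""
    from lifelines import CoxPHFitter

    arms = np.asarray(arms)
    if arm_order is None:
        arm_order = tuple(sorted(dict.fromkeys(arms.tolist())))  # type: ignore
    df = pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "group": (arms == arm_order[0]).astype(int),
        }
    )
    fitter = CoxPHFitter().fit(df, duration_col="time", event_col="event")
    summary = fitter.summary.loc["group"]
    return {
        "hazard_ratio": float(np.exp(summary["coef"])),
        "hr_ci": (
            float(np.exp(summary["coef lower 95%"])),
            float(np.exp(summary["coef upper 95%"])),
        ),
        "p_value": float(summary["p"]),
    }


# ---------------------------------------------------------------------------
# Design


@dataclass
class SampleSizeSpec:
    median_control: float
    median_treatment: float
    alpha: float = 0.05
    power: float = 0.80
    loss_fraction: float = 0.10
    event_probability: float = 1.0

    def __post_init__(self) -> None:
        if self.median_control <= 0 or self.median_treatment <= 0:
            raise ValueError("medians must be positive")
        if self.median_control == self.median_treatment:
            raise ValueError("design undefined for equal medians (HR = 1)")
        for name in ("alpha", "power", "loss_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.event_probability <= 1:
            raise ValueError("event_probability must be in (0, 1]")


@dataclass
class SampleSizeResult:
    hazard_ratio: float
    events_total: int
    n_per_group: int
    method: str


def freedman_sample_size(
    spec: SampleSizeSpec, method: str = "freedman"
) -> SampleSizeResult:
    """Log-rank sample size under exponential survival.

    HR = median_control / median_treatment.  Required events:

    - freedman:   d = (z_{1-a/2} + z_pow)^2 ((1+HR)/(1-HR))^2
    - schoenfeld: d = 4 (z_{1-a/2} + z_pow)^2 / (ln HR)^2

    Per-group size = ceil(ceil(d) / 2 / event_probability / (1 - loss)).
    """
    hr = spec.median_control / spec.median_treatment
    z = stats.norm.ppf(1 - spec.alpha / 2) + stats.norm.ppf(spec.power)
    if method == "freedman":
        d = z**2 * ((1 + hr) / (1 - hr)) ** 2
    elif method == "schoenfeld":
        d = 4 * z**2 / math.log(hr) ** 2
    else:
        raise ValueError("method must be 'freedman' or 'schoenfeld'")
    events_total = math.ceil(d)
    n_per_group = math.ceil(
        events_total / 2 / spec.event_probability / (1 - spec.loss_fraction)
    )
    return SampleSizeResult(float(hr), events_total, n_per_group, method)


def exponential_survival_times(median: float, size: int, rng: np.random.Generator):
    """Exponential times with the requested median."""
    if median <= 0:
        raise ValueError("median must be positive")
    return rng.exponential(scale=median / math.log(2), size=size)


def simulate_logrank_power(
    n_per_arm: int,
    median_a: float,
    median_b: float,
    n_sims: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Monte-Carlo power of the two-sided log-rank test, full follow-up."""
    rng = np.random.default_rng(seed)
    arms = np.repeat(["A", "B"], n_per_arm)
    events = np.ones(2 * n_per_arm, dtype=bool)
    rejections = 0
    for _ in range(n_sims):
        t = np.concatenate(
            [
                exponential_survival_times(median_a, n_per_arm, rng),
                exponential_survival_times(median_b, n_per_arm, rng),
            ]
        )
        res = logrank_and_hr(t, events, arms, arm_order=("A", "B"))
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_sims


# ---------------------------------------------------------------------------
# End-to-end endpoint report


def trial_endpoints(
    cohort: pd.DataFrame,
    arm_order: tuple[str, str] | None = None,
    milestone_months: tuple[float, ...] = (6.0, 12.0, 24.0),
) -> dict:
    """Full endpoint report for a cohort table.

    Expects columns patient, arm, intra_resp, extra_resp, os_months,
    os_event, pfs_months, pfs_event.  Overall responses are derived from the
    lesion pairs, rates and their comparison computed, and OS/PFS analyzed
    by Kaplan–Meier and log-rank.
    """
    required = {
        "patient", "arm", "intra_resp", "extra_resp",
        "os_months", "os_event", "pfs_months", "pfs_event",
    }
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    overall = [
        combine_lesion_responses(i, e)
        for i, e in zip(cohort["intra_resp"], cohort["extra_resp"])
    ]
    table = ResponseTable.from_responses(cohort["arm"], overall)
    arms = list(table.arms) if arm_order is None else list(arm_order)
    report: dict = {
        "response_table": {a: dict(table.counts[a]) for a in arms},
        "rates": response_rates(table),
        "orr_comparison": compare_rates(table, "orr").__dict__ | {"table": None},
        "dcr_comparison": compare_rates(table, "dcr").__dict__ | {"table": None},
        "survival": {},
    }
    for endpoint in ("os", "pfs"):
        times = cohort[f"{endpoint}_months"].to_numpy(dtype=float)
        events = cohort[f"{endpoint}_event"].to_numpy(dtype=bool)
        per_arm = {}
        for arm in arms:
            sel = (cohort["arm"] == arm).to_numpy()
            km = km_estimate(times[sel], events[sel])
            per_arm[arm] = {
                "median": km.median,
                "median_defined": km.median_defined,
                "rates": {m: km.rate_at(m) for m in milestone_months},
                "n": km.n,
                "n_events": km.n_events,
            }
        lr = logrank_and_hr(
            times, events, cohort["arm"].to_numpy(), arm_order=tuple(arms)
        )
        report["survival"][endpoint] = {
            "per_arm": per_arm,
            "logrank_p": lr.p_value,
            "logrank_statistic": lr.statistic,
            "hazard_ratio": lr.hazard_ratio,
            "hr_ci": lr.hr_ci,
        }
    return report
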