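"""Per-protein linear mixed models with contrast testing and FDR adjustment.

Model per protein: expression ~ response + arm + time fixed effects (with
configurable interaction terms) plus a per-patient random intercept, fit by
profiled REML.  Contrasts are linear combinations c'beta tested with the
large-sample z statistic; four contrast families cover pre-treatment
response differences, arm x response interactions, post-pre changes, and
arm x time interactions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

FULL_INTERACTIONS = (
    "arm:response",
    "arm:time",
    "time:response",
    "arm:time:response",
)

FAMILY_PAIRWISE_PRE = "pairwise_pre"
FAMILY_INTERACTION_ARM_RESPONSE = "interaction_arm_response"
FAMILY_PRE_POST = "pre_post_within"
FAMILY_INTERACTION_ARM_TIME = "interaction_arm_time"
ALL_FAMILIES = (
    FAMILY_PAIRWISE_PRE,
    FAMILY_INTERACTION_ARM_RESPONSE,
    FAMILY_PRE_POST,
    FAMILY_INTERACTION_ARM_TIME,
)

_CANONICAL_RESPONSE_ORDER = ("PD", "SD", "PR", "CR")


# ---------------------------------------------------------------------------
# Design


@dataclass
class Design:
    """Fixed-effect design matrix plus the patient grouping vector."""

    X: np.ndarray
    columns: list[str]
    groups: np.ndarray            # integer patient codes, aligned with rows
    group_labels: list
    sample_ids: list
    response_levels: tuple[str, ...]   # reference level first
    arm_levels: tuple[str, ...]
    time_levels: tuple[str, ...]
    interactions: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def _order_levels(observed, reference, canonical=None):
    observed = list(dict.fromkeys(observed))
    if reference not in observed:
        raise ValueError(f"reference level {reference!r} not present in data")
    rest = [x for x in observed if x != reference]
    if canonical:
        key = {lvl: i for i, lvl in enumerate(canonical)}
        rest.sort(key=lambda x: (key.get(x, len(key)), str(x)))
    else:
        rest.sort(key=str)
    return (reference, *rest)


def validate_annotation(annotation: pd.DataFrame) -> None:
    """Check the per-sample factor table invariants."""
    required = {"sample", "patient", "arm", "time", "response"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    dup = annotation.duplicated(subset=["patient", "time"])
    if dup.any():
        raise ValueError("each (patient, time) pair may occur at most once")
    for col in ("arm", "response"):
        per_patient = annotation.groupby("patient")[col].nunique()
        if (per_patient > 1).any():
            bad = per_patient[per_patient > 1].index.tolist()
            raise ValueError(f"patient(s) with inconsistent {col}: {bad}")


def build_design(
    annotation: pd.DataFrame,
    reference_levels: tuple[str, str, str] = ("PD", "placebo", "pre"),
    interactions: tuple[str, ...] | str = "full",
    exclude_ne: bool = True,
) -> Design:
    """Dummy-coded fixed-effect design with a patient grouping vector.

    ``reference_levels`` is (response, arm, time).  ``interactions`` is
    ``"full"``, ``"none"``, or a subset of
    ``("arm:response", "arm:time", "time:response", "arm:time:response")``;
    the full set saturates the response x arm x time cell means, which makes
    all four contrast families estimable as cell-mean differences.  NE
    samples are excluded before coding.
    """
    validate_annotation(annotation)
    if interactions == "full":
        interactions = FULL_INTERACTIONS
    elif interactions in ("none", None):
        interactions = ()
    else:
        interactions = tuple(interactions)
        unknown = set(interactions) - set(FULL_INTERACTIONS)
        if unknown:
            raise ValueError(f"unknown interaction terms: {sorted(unknown)}")

    ann = annotation.copy()
    if exclude_ne:
        ann = ann[ann["response"] != "NE"]
    ref_response, ref_arm, ref_time = reference_levels
    for col, ref in (("response", ref_response), ("arm", ref_arm), ("time", ref_time)):
        n_levels = ann[col].nunique()
        if n_levels < 2:
            raise ValueError(f"factor {col!r} has fewer than two levels")
    response_levels = _order_levels(
        ann["response"], ref_response, _CANONICAL_RESPONSE_ORDER
    )
    arm_levels = _order_levels(ann["arm"], ref_arm)
    time_levels = _order_levels(ann["time"], ref_time)
    if len(arm_levels) != 2 or len(time_levels) != 2:
        raise ValueError("arm and time must each have exactly two levels")

    n = len(ann)
    resp_d = {
        lvl: (ann["response"] == lvl).to_numpy(float) for lvl in response_levels[1:]
    }
    arm_d = (ann["arm"] == arm_levels[1]).to_numpy(float)
    time_d = (ann["time"] == time_levels[1]).to_numpy(float)

    cols: list[str] = ["Intercept"]
    mats: list[np.ndarray] = [np.ones(n)]
    for lvl in response_levels[1:]:
        cols.append(f"response[{lvl}]")
        mats.append(resp_d[lvl])
    cols.append(f"arm[{arm_levels[1]}]")
    mats.append(arm_d)
    cols.append(f"time[{time_levels[1]}]")
    mats.append(time_d)
    if "arm:response" in interactions:
        for lvl in response_levels[1:]:
            cols.append(f"arm[{arm_levels[1]}]:response[{lvl}]")
            mats.append(arm_d * resp_d[lvl])
    if "arm:time" in interactions:
        cols.append(f"arm[{arm_levels[1]}]:time[{time_levels[1]}]")
        mats.append(arm_d * time_d)
    if "time:response" in interactions:
        for lvl in response_levels[1:]:
            cols.append(f"time[{time_levels[1]}]:response[{lvl}]")
            mats.append(time_d * resp_d[lvl])
    if "arm:time:response" in interactions:
        if not {"arm:response", "arm:time", "time:response"} <= set(interactions):
            raise ValueError(
                "arm:time:response requires all two-way interactions"
            )
        for lvl in response_levels[1:]:
            cols.append(
                f"arm[{arm_levels[1]}]:time[{time_levels[1]}]:response[{lvl}]"
            )
            mats.append(arm_d * time_d * resp_d[lvl])

    patients = ann["patient"].tolist()
    group_labels = list(dict.fromkeys(patients))
    code = {p: i for i, p in enumerate(group_labels)}
    groups = np.asarray([code[p] for p in patients], dtype=np.intp)

    return Design(
        X=np.column_stack(mats),
        columns=cols,
        groups=groups,
        group_labels=group_labels,
        sample_ids=ann["sample"].tolist(),
        response_levels=response_levels,
        arm_levels=arm_levels,
        time_levels=time_levels,
        interactions=interactions,
    )


def cell_mean_vector(design: Design, response: str, arm: str, time: str) -> np.ndarray:
    """Coefficient vector c with c'beta = model-implied mean of one cell."""
    if response not in design.response_levels:
        raise ValueError(f"unknown response level {response!r}")
    if arm not in design.arm_levels or time not in design.time_levels:
        raise ValueError("unknown arm or time level")
    r = {lvl: float(response == lvl) for lvl in design.response_levels[1:]}
    a = float(arm == design.arm_levels[1])
    t = float(time == design.time_levels[1])
    c = []
    for col in design.columns:
        if col == "Intercept":
            c.append(1.0)
        elif col.startswith("response["):
            c.append(r[col[len("response["):-1]])
        elif col == f"arm[{design.arm_levels[1]}]":
            c.append(a)
        elif col == f"time[{design.time_levels[1]}]":
            c.append(t)
        elif ":" in col:
            v = 1.0
            for part in col.split(":"):
                name, lvl = part.split("[")
                lvl = lvl[:-1]
                if name == "response":
                    v *= r[lvl]
                elif name == "arm":
                    v *= a
                elif name == "time":
                    v *= t
            c.append(v)
        else:  # pragma: no cover - defensive
            raise RuntimeError(f"unrecognized design column {col!r}")
    return np.asarray(c)


@dataclass
class Contrast:
    vector: np.ndarray
    label: str
    family: str
    meta: dict = field(default_factory=dict)


def enumerate_contrasts(
    design: Design, families: tuple[str, ...] = ALL_FAMILIES
) -> list[Contrast]:
    """The four contrast families, built as cell-mean differences.

    1. ``pairwise_pre`` — every response pair, within each arm, at pre;
    2. ``interaction_arm_response`` — arm difference of each pre-treatment
       response-pair contrast (requires the arm:response term);
    3. ``pre_post_within`` — post minus pre within each response x arm cell;
    4. ``interaction_arm_time`` — arm difference of the post-pre change
       within each response (requires the arm:time term).

    Pair contrasts are oriented later-minus-earlier in the response level
    order (reference first), so e.g. "CR-PD" is positive when expression is
    higher in CR.
    """
    unknown = set(families) - set(ALL_FAMILIES)
    if unknown:
        raise ValueError(f"unknown contrast families: {sorted(unknown)}")
    if FAMILY_INTERACTION_ARM_RESPONSE in families and "arm:response" not in design.interactions:
        raise ValueError("interaction_arm_response requires the arm:response term")
    if FAMILY_INTERACTION_ARM_TIME in families and "arm:time" not in design.interactions:
        raise ValueError("interaction_arm_time requires the arm:time term")

    cell = lambda r, a, t: cell_mean_vector(design, r, a, t)
    pre, post = design.time_levels
    ref_arm, alt_arm = design.arm_levels
    levels = design.response_levels
    pairs = [(hi, lo) for lo, hi in itertools.combinations(levels, 2)]

    out: list[Contrast] = []
    if FAMILY_PAIRWISE_PRE in families:
        for arm in design.arm_levels:
            for hi, lo in pairs:
                out.append(
                    Contrast(
                        cell(hi, arm, pre) - cell(lo, arm, pre),
                        f"{hi}-{lo} | {arm}, {pre}",
                        FAMILY_PAIRWISE_PRE,
                        {"r_hi": hi, "r_lo": lo, "arm": arm},
                    )
                )
    if FAMILY_INTERACTION_ARM_RESPONSE in families:
        for hi, lo in pairs:
            v = (cell(hi, alt_arm, pre) - cell(lo, alt_arm, pre)) - (
                cell(hi, ref_arm, pre) - cell(lo, ref_arm, pre)
            )
            out.append(
                Contrast(
                    v,
                    f"({hi}-{lo}) x arm[{alt_arm}] | {pre}",
                    FAMILY_INTERACTION_ARM_RESPONSE,
                    {"r_hi": hi, "r_lo": lo},
                )
            )
    if FAMILY_PRE_POST in families:
        for arm in design.arm_levels:
            for r in levels:
                out.append(
                    Contrast(
                        cell(r, arm, post) - cell(r, arm, pre),
                        f"{post}-{pre} | {r}, {arm}",
                        FAMILY_PRE_POST,
                        {"response": r, "arm": arm},
                    )
                )
    if FAMILY_INTERACTION_ARM_TIME in families:
        for r in levels:
            v = (cell(r, alt_arm, post) - cell(r, alt_arm, pre)) - (
                cell(r, ref_arm, post) - cell(r, ref_arm, pre)
            )
            out.append(
                Contrast(
                    v,
                    f"({post}-{pre}) x arm[{alt_arm}] | {r}",
                    FAMILY_INTERACTION_ARM_TIME,
                    {"response": r},
                )
            )
    labels = [c.label for c in out]
    assert len(labels) == len(set(labels))
    return out


# ---------------------------------------------------------------------------
# REML fitting


@dataclass
class LMMFit:
    """Random-intercept mixed-model fit for one protein."""

    protein: str | None
    beta: np.ndarray
    cov_beta: np.ndarray
    columns: list[str]
    var_random: float
    var_residual: float
    converged: bool
    boundary: bool          # random-intercept variance on the zero boundary
    n_obs: int
    n_groups: int
    message: str = ""


def _failed_fit(protein, columns, n_obs, n_groups, message) -> LMMFit:
    p = len(columns)
    return LMMFit(
        protein=protein,
        beta=np.full(p, np.nan),
        cov_beta=np.full((p, p), np.nan),
        columns=list(columns),
        var_random=float("nan"),
        var_residual=float("nan"),
        converged=False,
        boundary=False,
        n_obs=n_obs,
        n_groups=n_groups,
        message=message,
    )


def fit_protein_lmm(
    y, design: Design, protein: str | None = None
) -> LMMFit:
    """Profiled-REML fit of a random-intercept linear mixed model.

    Missing responses are dropped.  With V = sigma2_e (I + lam Z Z') the GLS
    solution and the REML criterion are profiled over lam = sigma2_b /
    sigma2_e via block-wise Woodbury identities, leaving a one-dimensional
    optimization.  Rank deficiency or insufficient data yields a failed
    (non-converged) fit rather than an exception; a zero-boundary random
    variance falls back to the ordinary least-squares covariance with the
    ``boundary`` flag set.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.X.shape[0]:
        raise ValueError("response vector length does not match the design")
    mask = np.isfinite(y)
    X = design.X[mask]
    yv = y[mask]
    g = design.groups[mask]
    n, p = X.shape
    n_groups = len(np.unique(g))
    if n < p + 2:
        return _failed_fit(protein, design.columns, n, n_groups, "too few observations")
    if n_groups < 2:
        return _failed_fit(protein, design.columns, n, n_groups, "fewer than two patients")
    if np.linalg.matrix_rank(X) < p:
        return _failed_fit(
            protein, design.columns, n, n_groups,
            "rank-deficient design after missing-data dropout",
        )

    # per-group row sums of X and y
    _, g_codes = np.unique(g, return_inverse=True)
    m = g_codes.max() + 1
    n_i = np.bincount(g_codes, minlength=m).astype(float)
    Sx = np.zeros((m, p))
    np.add.at(Sx, g_codes, X)
    Sy = np.bincount(g_codes, weights=yv, minlength=m)
    XtX = X.T @ X
    Xty = X.T @ yv
    yty = float(yv @ yv)

    def profile(lam: float):
        shrink = lam / (1.0 + lam * n_i)
        XtWX = XtX - (Sx * shrink[:, None]).T @ Sx
        XtWy = Xty - (Sx * shrink[:, None]).T @ Sy
        ytWy = yty - float(shrink @ (Sy**2))
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - float(XtWy @ beta), 0.0)
        return beta, XtWX, rss

    def criterion(lam: float) -> float:
        _, XtWX, rss = profile(lam)
        sigma2 = rss / (n - p)
        if sigma2 <= 0:
            return -np.inf
        _, logdet_xwx = np.linalg.slogdet(XtWX)
        logdet_v = float(np.sum(np.log1p(lam * n_i)))
        return (n - p) * math.log(sigma2) + logdet_v + logdet_xwx

    # degenerate: exact fit at lam = 0 (e.g. constant response)
    beta0, XtWX0, rss0 = profile(0.0)
    if rss0 <= 1e-12 * max(yty, 1.0):
        return LMMFit(
            protein, beta0, np.zeros((p, p)), list(design.columns),
            0.0, 0.0, True, True, n, n_groups, "degenerate exact fit",
        )

    crit0 = criterion(0.0)
    try:
        res = optimize.minimize_scalar(
            lambda u: criterion(math.exp(u)),
            bounds=(-12.0, 12.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = math.exp(res.x)
        converged = bool(res.success)
        if crit0 <= res.fun + 1e-9:
            lam_hat = 0.0
    except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
        return _failed_fit(protein, design.columns, n, n_groups, str(exc))

    beta, XtWX, rss = profile(lam_hat)
    sigma2_e = rss / (n - p)
    sigma2_b = lam_hat * sigma2_e
    cov = sigma2_e * np.linalg.inv(XtWX)
    boundary = lam_hat <= 1e-8
    return LMMFit(
        protein=protein,
        beta=beta,
        cov_beta=cov,
        columns=list(design.columns),
        var_random=float(sigma2_b),
        var_residual=float(sigma2_e),
        converged=converged,
        boundary=boundary,
        n_obs=n,
        n_groups=n_groups,
        message="" if converged else "optimizer did not converge",
    )


# ---------------------------------------------------------------------------
# Contrast testing and FDR


@dataclass
class ContrastResult:
    protein: str | None
    family: str
    label: str
    estimate: float
    se: float
    z: float
    p_raw: float
    p_adj: float | None = None
    degenerate: bool = False
    meta: dict = field(default_factory=dict)


def test_contrast(
    fit: LMMFit, vector, label: str, family: str, meta: dict | None = None
) -> ContrastResult:
    """Wald z test of the linear combination c'beta.

    SE = sqrt(c' Cov(beta) c); a zero SE yields p = 1 for a zero estimate
    and p = 0 (flagged degenerate) otherwise.
    """
    c = np.asarray(vector, dtype=float)
    if c.shape != fit.beta.shape:
        raise ValueError("contrast vector length does not match the coefficients")
    est = float(c @ fit.beta)
    var = float(c @ fit.cov_beta @ c)
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        if est == 0.0:
            return ContrastResult(fit.protein, family, label, 0.0, 0.0, 0.0, 1.0,
                                  meta=dict(meta or {}))
        return ContrastResult(fit.protein, family, label, est, 0.0,
                              math.copysign(math.inf, est), 0.0,
                              degenerate=True, meta=dict(meta or {}))
    z = est / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return ContrastResult(fit.protein, family, label, est, se, z, p,
                          meta=dict(meta or {}))


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def run_contrast_suite(
    matrix,
    annotation: pd.DataFrame,
    reference_levels: tuple[str, str, str] = ("PD", "placebo", "pre"),
    families: tuple[str, ...] = ALL_FAMILIES,
    bh_scope: str = "family",
) -> pd.DataFrame:
    """Fit every protein and evaluate all contrast families.

    ``matrix`` is a normalized :class:`~trialomics.preprocess.ProteinMatrix`
    whose columns cover the annotation's sample ids.  Returns a tidy frame
    with one row per (protein, contrast) and BH-adjusted p values computed
    per contrast family across proteins (``bh_scope="family"``), per
    individual contrast (``"contrast"``), or globally (``"global"``).
    """
    if bh_scope not in ("family", "contrast", "global"):
        raise ValueError("bh_scope must be 'family', 'contrast' or 'global'")
    design = build_design(annotation, reference_levels=reference_levels)
    contrasts = enumerate_contrasts(design, families=families)
    values = matrix.values[design.sample_ids]

    rows = []
    for protein in matrix.proteins:
        y = values.loc[protein].to_numpy(dtype=float)
        fit = fit_protein_lmm(y, design, protein=str(protein))
        if not fit.converged:
            for con in contrasts:
                rows.append(
                    {
                        "protein": str(protein), "family": con.family,
                        "label": con.label, "estimate": np.nan, "se": np.nan,
                        "z": np.nan, "p_raw": np.nan, "converged": False,
                        "boundary": False, **con.meta,
                    }
                )
            continue
        for con in contrasts:
            r = test_contrast(fit, con.vector, con.label, con.family, con.meta)
            rows.append(
                {
                    "protein": str(protein), "family": con.family,
                    "label": con.label, "estimate": r.estimate, "se": r.se,
                    "z": r.z, "p_raw": r.p_raw, "converged": True,
                    "boundary": fit.boundary, **con.meta,
                }
            )
    results = pd.DataFrame(rows)
    for col in ("r_hi", "r_lo", "arm", "response"):
        if col not in results.columns:
            results[col] = pd.NA

    results["p_adj"] = np.nan
    if bh_scope == "global":
        grouper = [np.ones(len(results), dtype=bool)]
    elif bh_scope == "family":
        grouper = [
            (results["family"] == fam).to_numpy() for fam in results["family"].unique()
        ]
    else:
        grouper = [
            (results["label"] == lab).to_numpy() for lab in results["label"].unique()
        ]
    for sel in grouper:
        ok = sel & np.isfinite(results["p_raw"].to_numpy())
        if ok.any():
            results.loc[ok, "p_adj"] = adjust_bh(results.loc[ok, "p_raw"].to_numpy())
    return results
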