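"""Single-protein and multi-protein panel response predictors with ROC/AUC.

Missing cells of panel proteins are imputed to 0 before scoring (undetected
means no measurable abundance for prediction purposes).  Panel scores
average per-protein z scores; AUC is the tie-aware pairwise concordance
probability, equivalent to the rank-sum statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from trialomics.preprocess import ProteinMatrix


@dataclass
class PanelSpec:
    proteins: list[str]
    positive_class: str
    combination: str = "mean_z"   # or "single"

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("panel must contain at least one protein")
        if self.combination not in ("mean_z", "single"):
            raise ValueError("combination must be 'mean_z' or 'single'")
        if self.combination == "single" and len(self.proteins) != 1:
            raise ValueError("'single' combination requires exactly one protein")


def impute_zero(matrix: ProteinMatrix, proteins) -> pd.DataFrame:
    """Slice out ``proteins`` with missing cells replaced by 0.

    Only the requested rows are returned; other cells of the matrix are
    never touched.  Unknown protein ids raise.
    """
    proteins = list(proteins)
    unknown = [p for p in proteins if p not in matrix.proteins]
    if unknown:
        raise KeyError(f"unknown protein id(s): {unknown}")
    return matrix.values.loc[proteins].fillna(0.0)


def panel_score(values: pd.DataFrame, spec: PanelSpec) -> pd.Series:
    """Per-sample panel score from a proteins x samples slice.

    ``mean_z`` standardizes each protein over the scored samples and
    averages; a zero-variance protein contributes z = 0 (with a warning).
    ``single`` returns the protein's values unchanged (AUC is invariant to
    standardization).
    """
    missing = [p for p in spec.proteins if p not in values.index]
    if missing:
        raise KeyError(f"panel protein(s) absent from the slice: {missing}")
    sub = values.loc[spec.proteins]
    if sub.isna().any().any():
        raise ValueError("panel slice contains missing cells; impute first")
    if spec.combination == "single":
        return sub.iloc[0].astype(float)
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance panel protein(s) {list(sub.index[flat])}; "
            "their z scores are set to 0",
            stacklevel=2,
        )
    z = sub.sub(mean, axis=0).div(sd.where(~flat, 1.0), axis=0)
    z[flat] = 0.0
    return z.mean(axis=0)


@dataclass
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC with ties counted one half.

    AUC equals the Mann–Whitney concordance P(score_pos > score_neg) +
    0.5 P(tie), computed from midranks; the curve is a descending
    threshold sweep starting at (0, 0) and ending at (1, 1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both a positive and a negative sample are required")

    ranks = stats.rankdata(s)  # midranks handle ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # keep only the last point of each tied-score block
    last_of_block = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[last_of_block] / n_pos]
    fpr = np.r_[0.0, fp[last_of_block] / n_neg]
    return RocResult(float(auc), n_pos, n_neg, fpr, tpr)


def predict_response(
    matrix: ProteinMatrix,
    annotation: pd.DataFrame,
    spec: PanelSpec,
    time: str = "pre",
    exclude_ne: bool = True,
) -> tuple[pd.Series, RocResult]:
    """Score pre-treatment samples with a panel and evaluate against response.

    Returns the per-sample scores and the ROC result for
    ``response == spec.positive_class`` versus the rest.
    """
    ann = annotation[annotation["time"] == time]
    if exclude_ne:
        ann = ann[ann["response"] != "NE"]
    samples = [s for s in ann["sample"] if s in matrix.samples]
    ann = ann[ann["sample"].isin(samples)]
    values = impute_zero(matrix, spec.proteins)[samples]
    scores = panel_score(values, spec)
    labels = (ann.set_index("sample").loc[samples, "response"]
              == spec.positive_class).to_numpy()
    return scores, roc_auc(scores.to_numpy(), labels)
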