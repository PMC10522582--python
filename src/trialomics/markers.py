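"""Compound decision rules for differential proteins and arm-unique calls.

A protein is differential when any contrast in the relevant family has raw
p below threshold.  It is an arm-unique response marker when, on a
pre-treatment response contrast within the arm of interest, raw p < 0.05
AND (adjusted p < 0.05 OR |coefficient| > 1.5), AND the matching
arm x response interaction contrast has raw p < 0.05.  Unique treatment
targets use the same structure on post-pre contrasts with coefficient
threshold 1.2 and the arm x time interaction gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from trialomics.lmm import (
    FAMILY_INTERACTION_ARM_RESPONSE,
    FAMILY_INTERACTION_ARM_TIME,
    FAMILY_PAIRWISE_PRE,
    FAMILY_PRE_POST,
)

CALL_COLUMNS = [
    "protein", "call_type", "family", "label", "cell", "arm",
    "estimate", "direction", "p_raw", "p_adj", "p_interaction",
    "fired_raw_p", "fired_adj_p", "fired_coef", "fired_interaction_p",
]


@dataclass
class MarkerCallConfig:
    """Thresholds of the compound calling rules."""

    raw_p_threshold: float = 0.05
    adj_p_threshold: float = 0.05
    coef_threshold_markers: float = 1.5
    coef_threshold_targets: float = 1.2
    interaction_p_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("raw_p_threshold", "adj_p_threshold", "interaction_p_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.coef_threshold_markers <= 0 or self.coef_threshold_targets <= 0:
            raise ValueError("coefficient thresholds must be positive")


_DIFFERENTIAL_TYPE = {
    FAMILY_PAIRWISE_PRE: "differential_pre",
    FAMILY_PRE_POST: "differential_prepost",
}


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(columns=CALL_COLUMNS)


def _cell_and_direction(row) -> tuple[str, str]:
    """Response cell a call refers to, always reported as the up side."""
    if row["family"] == FAMILY_PAIRWISE_PRE:
        up = row["estimate"] > 0
        return (row["r_hi"] if up else row["r_lo"]), "up"
    direction = "up" if row["estimate"] > 0 else "down"
    return row["response"], direction


def call_differential(
    results: pd.DataFrame,
    family: str,
    config: MarkerCallConfig | None = None,
) -> pd.DataFrame:
    """Proteins with any raw p below threshold in ``family``.

    One output row per triggering contrast; empty input yields an empty
    call table.
    """
    config = config or MarkerCallConfig()
    if family not in _DIFFERENTIAL_TYPE:
        raise ValueError(
            f"differential calls are defined for families {list(_DIFFERENTIAL_TYPE)}"
        )
    sub = results[results["family"] == family]
    hits = sub[
        sub["converged"].fillna(False)
        & (sub["p_raw"] < config.raw_p_threshold)
    ]
    if hits.empty:
        return _empty_calls()
    rows = []
    for _, row in hits.iterrows():
        cell, direction = _cell_and_direction(row)
        rows.append(
            {
                "protein": row["protein"],
                "call_type": _DIFFERENTIAL_TYPE[family],
                "family": family,
                "label": row["label"],
                "cell": cell,
                "arm": row["arm"],
                "estimate": row["estimate"],
                "direction": direction,
                "p_raw": row["p_raw"],
                "p_adj": row["p_adj"],
                "p_interaction": np.nan,
                "fired_raw_p": True,
                "fired_adj_p": bool(row["p_adj"] < config.adj_p_threshold),
                "fired_coef": False,
                "fired_interaction_p": False,
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def _call_unique(
    results: pd.DataFrame,
    config: MarkerCallConfig,
    arm: str,
    main_family: str,
    interaction_family: str,
    join_keys: list[str],
    coef_threshold: float,
    call_type: str,
) -> pd.DataFrame:
    main = results[
        (results["family"] == main_family)
        & (results["arm"] == arm)
        & results["converged"].fillna(False)
    ]
    inter = results[
        (results["family"] == interaction_family)
        & results["converged"].fillna(False)
    ]
    if results[results["family"] == interaction_family].empty:
        raise ValueError(
            f"results lack the {interaction_family!r} family needed as the"
            " arm-uniqueness gate"
        )
    merged = main.merge(
        inter[["protein", *join_keys, "p_raw"]].rename(
            columns={"p_raw": "p_interaction"}
        ),
        on=["protein", *join_keys],
        how="inner",
    )
    fired_raw = merged["p_raw"] < config.raw_p_threshold
    fired_adj = merged["p_adj"] < config.adj_p_threshold
    fired_coef = merged["estimate"].abs() > coef_threshold
    fired_inter = merged["p_interaction"] < config.interaction_p_threshold
    keep = fired_raw & (fired_adj | fired_coef) & fired_inter
    if not keep.any():
        return _empty_calls()
    rows = []
    for (_, row), adj, coef in zip(
        merged[keep].iterrows(), fired_adj[keep], fired_coef[keep]
    ):
        cell, direction = _cell_and_direction(row)
        rows.append(
            {
                "protein": row["protein"],
                "call_type": call_type,
                "family": main_family,
                "label": row["label"],
                "cell": cell,
                "arm": arm,
                "estimate": row["estimate"],
                "direction": direction,
                "p_raw": row["p_raw"],
                "p_adj": row["p_adj"],
                "p_interaction": row["p_interaction"],
                "fired_raw_p": True,
                "fired_adj_p": bool(adj),
                "fired_coef": bool(coef),
                "fired_interaction_p": True,
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def call_unique_markers(
    results: pd.DataFrame,
    config: MarkerCallConfig | None = None,
    arm: str = "ATRA",
) -> pd.DataFrame:
    """Arm-unique pre-treatment response markers.

    Each pre-treatment pairwise contrast within ``arm`` is gated by the
    arm x response interaction contrast of the same response pair, at raw
    p scale.  The reported cell is the response level with the higher
    pre-treatment expression.
    """
    return _call_unique(
        results,
        config or MarkerCallConfig(),
        arm,
        FAMILY_PAIRWISE_PRE,
        FAMILY_INTERACTION_ARM_RESPONSE,
        ["r_hi", "r_lo"],
        (config or MarkerCallConfig()).coef_threshold_markers,
        "unique_marker",
    )


def call_unique_targets(
    results: pd.DataFrame,
    config: MarkerCallConfig | None = None,
    arm: str = "ATRA",
) -> pd.DataFrame:
    """Arm-unique pre/post treatment targets.

    Post-pre contrasts within ``arm`` are gated by the arm x time
    interaction contrast of the same response level; the coefficient branch
    uses the looser 1.2 threshold.
    """
    return _call_unique(
        results,
        config or MarkerCallConfig(),
        arm,
        FAMILY_PRE_POST,
        FAMILY_INTERACTION_ARM_TIME,
        ["response"],
        (config or MarkerCallConfig()).coef_threshold_targets,
        "unique_target",
    )
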