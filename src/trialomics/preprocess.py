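"""Protein abundance matrix: detection filtering, normalization, log transform.

The matrix is proteins x samples.  A missing cell means the protein was not
detected in that sample; detected-but-zero counts are observed zeros and are
kept (a switch lets zeros be reclassified as undetected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW = "raw_counts"
NORMALIZED = "normalized_log"

DEFAULT_PSEUDOCOUNT = 1e-6


@dataclass
class ProteinMatrix:
    """Proteins x samples abundance grid with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with sample ids as columns.
        ``NaN`` encodes an undetected (missing) cell.
    state
        ``"raw_counts"`` or ``"normalized_log"``.
    log_base, pseudocount
        Recorded on normalized matrices; ``None`` while raw.
    """

    values: pd.DataFrame
    state: str = RAW
    log_base: float | None = None
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        if self.state not in (RAW, NORMALIZED):
            raise ValueError(f"unknown matrix state: {self.state!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.state == RAW:
            observed = self.values.to_numpy(dtype=float)
            if np.nanmin(observed, initial=0.0) < 0:
                raise ValueError("raw matrix contains negative abundances")
        else:
            if self.log_base is None or self.pseudocount is None:
                raise ValueError(
                    "normalized matrix must record log_base and pseudocount"
                )

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where a cell is undetected."""
        return self.values.isna()

    @property
    def n_missing_per_protein(self) -> pd.Series:
        return self.values.isna().sum(axis=1)

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            self.values.copy(),
            state=self.state,
            log_base=self.log_base,
            pseudocount=self.pseudocount,
        )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="protein", na_rep="")

    @classmethod
    def from_tsv(cls, path, state: str = RAW, **kwargs) -> "ProteinMatrix":
        values = pd.read_csv(path, sep="\t", index_col="protein")
        return cls(values, state=state, **kwargs)


def filter_undetected(
    matrix: ProteinMatrix,
    max_missing_samples: int = 40,
    zeros_as_undetected: bool = False,
) -> ProteinMatrix:
    """Drop proteins undetected in more than ``max_missing_samples`` samples.

    A protein is retained iff its count of missing cells is
    ``<= max_missing_samples``.  Row order of retained proteins is preserved.
    With ``zeros_as_undetected`` observed zero counts also count as missing
    for the purpose of the filter (the cells themselves are not altered).
    """
    if max_missing_samples < 0:
        raise ValueError("max_missing_samples must be non-negative")
    if matrix.state != RAW:
        raise ValueError("filter_undetected expects a raw-count matrix")
    missing = matrix.values.isna()
    if zeros_as_undetected:
        missing = missing | (matrix.values == 0)
    keep = missing.sum(axis=1) <= max_missing_samples
    return ProteinMatrix(matrix.values.loc[keep].copy(), state=RAW)


def normalize_and_log(
    matrix: ProteinMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_base: float = 2.0,
) -> ProteinMatrix:
    """Total-count normalize each sample, then log-transform.

    Each observed cell is divided by its sample's total over observed cells,
    then ``log(x + pseudocount)`` in the requested base is applied.  Missing
    cells stay missing.
    """
    if matrix.state != RAW:
        raise ValueError("normalize_and_log expects a raw-count matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    totals = matrix.values.sum(axis=0, skipna=True)
    n_observed = matrix.values.notna().sum(axis=0)
    bad = (n_observed == 0) | (totals <= 0)
    if bad.any():
        names = ", ".join(map(str, matrix.samples[bad]))
        raise ValueError(
            f"sample(s) with no observed counts or zero total: {names}"
        )
    fractions = matrix.values.div(totals, axis=1)
    logged = np.log(fractions + pseudocount) / np.log(log_base)
    return ProteinMatrix(
        logged, state=NORMALIZED, log_base=log_base, pseudocount=pseudocount
    )
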