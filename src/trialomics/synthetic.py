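"""Synthetic trial cohorts and paired pre/post proteomes with known truth.

The cohort generator draws per-arm response categories from configurable
multinomial frequencies, lesion-level responses consistent with the overall
category, and exponential OS/PFS with configured medians.  The proteome
generator produces a spectral-count-like matrix: per-protein log2 baselines,
per-(patient, protein) random intercepts shared across the patient's two
samples, spike-in effects restricted to one arm and one of four archetypes,
Gaussian residual noise, per-sample library-size scaling, rounding to
non-negative integers, and detection dropout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trialomics.trial import LESION_LEVELS, RESPONSE_CATEGORIES, combine_lesion_responses

ARCHETYPES = ("pre_CR_up", "pre_PR_up", "post_CR_up", "post_responder_down")

#: Response-category frequencies of the default two-arm configuration,
#: in RESPONSE_CATEGORIES order (CR, PR, SD, PD, NE).
DEFAULT_RESPONSE_COUNTS = {
    "ATRA": (4, 9, 14, 19, 7),
    "placebo": (1, 4, 12, 31, 7),
}


def _default_probs() -> dict[str, tuple[float, ...]]:
    return {
        arm: tuple(c / sum(counts) for c in counts)
        for arm, counts in DEFAULT_RESPONSE_COUNTS.items()
    }


@dataclass
class CohortConfig:
    """Two-arm cohort simulation parameters."""

    n_per_arm: tuple[int, int] = (53, 55)
    arms: tuple[str, str] = ("ATRA", "placebo")
    response_probs: dict[str, tuple[float, ...]] = field(default_factory=_default_probs)
    median_os_months: dict[str, float] = field(
        default_factory=lambda: {"ATRA": 16.2, "placebo": 10.7}
    )
    median_pfs_months: dict[str, float] = field(
        default_factory=lambda: {"ATRA": 7.1, "placebo": 4.2}
    )
    censor_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_arm) != 2 or any(n <= 0 for n in self.n_per_arm):
            raise ValueError("n_per_arm must be two positive integers")
        for arm in self.arms:
            probs = self.response_probs[arm]
            if len(probs) != len(RESPONSE_CATEGORIES):
                raise ValueError(
                    f"response_probs[{arm!r}] must have "
                    f"{len(RESPONSE_CATEGORIES)} entries (CR, PR, SD, PD, NE)"
                )
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(
                    f"response_probs[{arm!r}] must be non-negative and sum to 1"
                )
            if self.median_os_months[arm] <= 0 or self.median_pfs_months[arm] <= 0:
                raise ValueError("survival medians must be positive")
            if self.median_pfs_months[arm] > self.median_os_months[arm]:
                raise ValueError(
                    "median PFS cannot exceed median OS (PFS is capped at OS)"
                )
        if not 0 <= self.censor_prob <= 1:
            raise ValueError("censor_prob must be in [0, 1]")


def _lesion_preimage() -> dict[str, list[tuple[str, str]]]:
    """Lesion pairs mapping to each overall response (extrahepatic always present)."""
    preimage: dict[str, list[tuple[str, str]]] = {c: [] for c in RESPONSE_CATEGORIES}
    for intra in LESION_LEVELS:
        for extra in LESION_LEVELS[:-1]:  # metastatic patients: extra != NONE
            preimage[combine_lesion_responses(intra, extra)].append((intra, extra))
    return preimage


_PREIMAGE = _lesion_preimage()


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a two-arm trial cohort.

    Returns one row per patient with columns patient, arm, response,
    intra_resp, extra_resp, os_months, os_event, pfs_months, pfs_event.
    Lesion-level responses are drawn uniformly from the pairs consistent
    with the sampled overall response; OS/PFS are exponential with the
    configured medians (PFS capped at OS); censoring is independent with
    probability ``censor_prob``, at a uniform fraction of the true OS time.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for arm, n in zip(config.arms, config.n_per_arm):
        probs = np.asarray(config.response_probs[arm], dtype=float)
        responses = rng.choice(RESPONSE_CATEGORIES, size=n, p=probs)
        os_true = rng.exponential(config.median_os_months[arm] / math.log(2), size=n)
        # progression hazard chosen so min(OS, progression) has exactly the
        # configured PFS median (exponential competing risks)
        prog_rate = math.log(2) * (
            1.0 / config.median_pfs_months[arm] - 1.0 / config.median_os_months[arm]
        )
        if prog_rate > 0:
            prog = rng.exponential(1.0 / prog_rate, size=n)
            pfs_true = np.minimum(os_true, prog)
        else:
            pfs_true = os_true.copy()
        censored = rng.random(n) < config.censor_prob
        censor_frac = rng.random(n)
        for i in range(n):
            resp = str(responses[i])
            intra, extra = _PREIMAGE[resp][rng.integers(len(_PREIMAGE[resp]))]
            if censored[i]:
                c_time = censor_frac[i] * os_true[i]
                os_months, os_event = c_time, 0
                if pfs_true[i] <= c_time:
                    pfs_months, pfs_event = pfs_true[i], 1
                else:
                    pfs_months, pfs_event = c_time, 0
            else:
                os_months, os_event = os_true[i], 1
                pfs_months, pfs_event = pfs_true[i], 1
            rows.append(
                {
                    "patient": f"{arm}-{i + 1:03d}",
                    "arm": arm,
                    "response": resp,
                    "intra_resp": intra,
                    "extra_resp": extra,
                    "os_months": float(os_months),
                    "os_event": int(os_event),
                    "pfs_months": float(pfs_months),
                    "pfs_event": int(pfs_event),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ProteomeConfig:
    """Paired pre/post proteome simulation parameters (log2 effect scale)."""

    n_proteins: int = 300
    n_spiked_per_archetype: int = 5
    effect_size: float = 2.0
    patient_sd: float = 0.5
    residual_sd: float = 0.5
    dropout_prob: float = 0.05
    library_size_range: tuple[float, float] = (5e4, 1.5e5)
    seed: int = 0
    spike_arm: str = "ATRA"
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    dropout_mode: str = "bernoulli"      # or "intensity"
    dropout_steepness: float = 1.0
    n_proteome_patients: int | None = None   # subset size; None = whole cohort

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.n_spiked_per_archetype < 0:
            raise ValueError("n_spiked_per_archetype must be non-negative")
        if self.n_spiked_per_archetype * len(ARCHETYPES) > self.n_proteins:
            raise ValueError("more spiked proteins requested than proteins")
        if self.patient_sd <= 0 or self.residual_sd <= 0:
            raise ValueError("patient_sd and residual_sd must be positive")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")
        if self.dropout_mode not in ("bernoulli", "intensity"):
            raise ValueError("dropout_mode must be 'bernoulli' or 'intensity'")


def _spike_effect_mask(
    archetype: str, arm: str, annotation: pd.DataFrame
) -> np.ndarray:
    in_arm = (annotation["arm"] == arm).to_numpy()
    resp = annotation["response"].to_numpy()
    time = annotation["time"].to_numpy()
    if archetype == "pre_CR_up":
        return in_arm & (resp == "CR") & (time == "pre")
    if archetype == "pre_PR_up":
        return in_arm & (resp == "PR") & (time == "pre")
    if archetype == "post_CR_up":
        return in_arm & (resp == "CR") & (time == "post")
    if archetype == "post_responder_down":
        return in_arm & np.isin(resp, ("CR", "PR")) & (time == "post")
    raise ValueError(f"unknown archetype {archetype!r}")


def _intensity_dropout(log2_counts: np.ndarray, target: float, steepness: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Logistic-in-abundance missingness calibrated to an overall rate."""
    from scipy.optimize import brentq

    x = log2_counts.ravel()

    def mean_rate(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a - steepness * x))))) - target

    lo, hi = -50.0, steepness * float(x.max()) + 50.0
    a = brentq(mean_rate, lo, hi)
    probs = 1.0 / (1.0 + np.exp(-(a - steepness * log2_counts)))
    return rng.random(log2_counts.shape) < probs


def generate_proteome(
    cohort: pd.DataFrame, config: ProteomeConfig
) -> tuple["object", pd.DataFrame, pd.DataFrame]:
    """Simulate a raw-count protein matrix with annotation and spike truth.

    Returns ``(matrix, annotation, truth)`` where ``matrix`` is a raw
    :class:`~trialomics.preprocess.ProteinMatrix` (NaN = undetected),
    ``annotation`` has one row per sample (sample, patient, arm, time,
    response), and ``truth`` lists every spiked protein with its archetype
    and target arm.
    """
    from trialomics.preprocess import ProteinMatrix

    if cohort.empty:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(config.seed)

    patients = cohort[["patient", "arm", "response"]].reset_index(drop=True)
    if config.n_proteome_patients is not None:
        if config.n_proteome_patients > len(patients):
            raise ValueError("n_proteome_patients exceeds the cohort size")
        idx = rng.choice(len(patients), size=config.n_proteome_patients, replace=False)
        patients = patients.iloc[np.sort(idx)].reset_index(drop=True)

    annotation = pd.DataFrame(
        [
            {
                "sample": f"{row.patient}-{time}",
                "patient": row.patient,
                "arm": row.arm,
                "time": time,
                "response": row.response,
            }
            for row in patients.itertuples()
            for time in ("pre", "post")
        ]
    )
    n_samples = len(annotation)
    n_patients = len(patients)

    protein_ids = [f"P{j + 1:04d}" for j in range(config.n_proteins)]
    # a zero effect size means nothing is actually spiked
    k = config.n_spiked_per_archetype if config.effect_size != 0 else 0
    truth_rows = []
    for a_idx, archetype in enumerate(ARCHETYPES):
        for j in range(a_idx * k, (a_idx + 1) * k):
            truth_rows.append(
                {
                    "protein": protein_ids[j],
                    "archetype": archetype,
                    "arm": config.spike_arm,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["protein", "archetype", "arm"])

    baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_proteins
    )
    intercepts = rng.normal(0.0, config.patient_sd, size=(config.n_proteins, n_patients))
    patient_of_sample = annotation["patient"].map(
        {p: i for i, p in enumerate(patients["patient"])}
    ).to_numpy()

    log2x = baseline[:, None] + intercepts[:, patient_of_sample]
    for a_idx, archetype in enumerate(ARCHETYPES):
        mask = _spike_effect_mask(archetype, config.spike_arm, annotation)
        sign = -1.0 if archetype == "post_responder_down" else 1.0
        for j in range(a_idx * k, (a_idx + 1) * k):
            log2x[j, mask] += sign * config.effect_size
    log2x += rng.normal(0.0, config.residual_sd, size=log2x.shape)

    intensity = np.exp2(log2x)
    library = rng.uniform(*config.library_size_range, size=n_samples)
    counts = intensity / intensity.sum(axis=0) * library
    counts = np.rint(counts)
    np.maximum(counts, 0.0, out=counts)

    if config.dropout_prob > 0:
        if config.dropout_mode == "bernoulli":
            missing = rng.random(counts.shape) < config.dropout_prob
        else:
            missing = _intensity_dropout(
                np.log2(counts + 1.0), config.dropout_prob,
                config.dropout_steepness, rng,
            )
        counts[missing] = np.nan

    matrix = ProteinMatrix(
        pd.DataFrame(counts, index=protein_ids, columns=annotation["sample"].tolist())
    )
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# Config file and dataset I/O


def load_configs(path) -> tuple[CohortConfig, ProteomeConfig]:
    """Read a YAML file with top-level ``cohort:`` and ``proteome:`` maps."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_kwargs = dict(raw.get("cohort", {}))
    if "n_per_arm" in cohort_kwargs:
        cohort_kwargs["n_per_arm"] = tuple(cohort_kwargs["n_per_arm"])
    if "arms" in cohort_kwargs:
        cohort_kwargs["arms"] = tuple(cohort_kwargs["arms"])
    if "response_probs" in cohort_kwargs:
        cohort_kwargs["response_probs"] = {
            arm: tuple(v) for arm, v in cohort_kwargs["response_probs"].items()
        }
    proteome_kwargs = dict(raw.get("proteome", {}))
    if "library_size_range" in proteome_kwargs:
        proteome_kwargs["library_size_range"] = tuple(
            proteome_kwargs["library_size_range"]
        )
    return CohortConfig(**cohort_kwargs), ProteomeConfig(**proteome_kwargs)


def write_dataset(out_dir, cohort, matrix, annotation, truth) -> None:
    """Write cohort.csv, matrix.tsv, annotation.csv and truth.csv."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv", index=False)
    matrix.to_tsv(out / "matrix.tsv")
    annotation.to_csv(out / "annotation.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
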