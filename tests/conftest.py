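import numpy as np
import pandas as pd
import pytest

from trialomics.lmm import build_design

RESPONSES = ("PD", "SD", "PR", "CR")


def make_annotation(n_patients=60, seed=0, arms=("ATRA", "placebo"),
                    responses=RESPONSES):
    """Paired pre/post annotation; every arm x response cell is populated."""
    rng = np.random.default_rng(seed)
    combos = [(a, r) for a in arms for r in responses]
    assignment = [combos[i % len(combos)] for i in range(n_patients)]
    rng.shuffle(assignment)
    rows = []
    for i in range(n_patients):
        arm, resp = assignment[i]
        for time in ("pre", "post"):
            rows.append(
                {
                    "sample": f"p{i:03d}-{time}",
                    "patient": f"p{i:03d}",
                    "arm": arm,
                    "time": time,
                    "response": resp,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def annotation():
    return make_annotation()


@pytest.fixture(scope="session")
def design(annotation):
    return build_design(annotation)


def simulate_response(design, beta, patient_sd, residual_sd, rng):
    """Draw one response vector from the random-intercept model."""
    u = rng.normal(0.0, patient_sd, size=len(design.group_labels))
    eps = rng.normal(0.0, residual_sd, size=design.X.shape[0])
    return design.X @ beta + u[design.groups] + eps
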