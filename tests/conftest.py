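import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fast",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture
def labeled_evidence():
    """Small, perfectly separable labeled evidence table."""
    rows = []
    for i in range(20):
        rows.append(("viral", 10 + i % 3, 1))
    for cls in ("bacterial", "archaeal", "eukaryotic"):
        for i in range(20):
            rows.append((cls, 0, 30 + i))
    df = pd.DataFrame(rows, columns=["truth_class", "viral_orf_count", "cellular_match_count"])
    df.insert(0, "scaffold_id", [f"sc{i}" for i in range(len(df))])
    return df


def random_labeled_evidence(seed: int, n: int = 500) -> pd.DataFrame:
    """Random labeled evidence with overlapping classes, for calibration
    oracle checks."""
    rng = np.random.default_rng(seed)
    classes = rng.choice(
        ["viral", "bacterial", "archaeal", "eukaryotic"],
        size=n,
        p=[0.4, 0.25, 0.15, 0.2],
    )
    is_viral = classes == "viral"
    v = np.where(is_viral, rng.poisson(8, n), rng.poisson(0.5, n))
    c = np.where(is_viral, rng.poisson(2, n), rng.poisson(12, n))
    return pd.DataFrame(
        {"truth_class": classes, "viral_orf_count": v, "cellular_match_count": c}
    )


def brute_force_calibrate(evidence, slopes, intercepts, max_euk_fp=0.01):
    """Exhaustive reference search: returns (sensitivity, intercept, slope)
    of the optimum under the strict eukaryotic FP cap, or None."""
    v = evidence["viral_orf_count"].to_numpy(dtype=float)
    c = evidence["cellular_match_count"].to_numpy(dtype=float)
    viral = (evidence["truth_class"] == "viral").to_numpy()
    euk = (evidence["truth_class"] == "eukaryotic").to_numpy()
    best = None
    for s in slopes:
        for i in intercepts:
            pred = v > s * c + i
            if pred[euk].sum() / euk.sum() >= max_euk_fp:
                continue
            key = (pred[viral].sum() / viral.sum(), i, s)
            if best is None or key > best:
                best = key
    return best
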