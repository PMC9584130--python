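import numpy as np
import pandas as pd
import pytest

import phenoblocks as pb


def exact_corr_pair(r: float, n: int = 200, seed: int = 0) -> pd.DataFrame:
    """Two columns whose sample Pearson correlation is exactly r.

    Built by orthonormalizing two random vectors (QR) and mixing them, so
    the empirical correlation hits the target to machine precision.
    """
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, 2))
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    q1, q2 = Q[:, 0], Q[:, 1]
    x1 = q1
    x2 = r * q1 + np.sqrt(1 - r**2) * q2
    return pd.DataFrame({"x1": x1, "x2": x2})


def one_factor_block(
    loadings: list[float], n: int, rng: np.random.Generator, prefix: str = "m"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Reflective block: m_j = lam_j * f + sqrt(1 - lam_j^2) * eps."""
    f = rng.standard_normal(n)
    cols = {
        f"{prefix}{j + 1}": lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        for j, lam in enumerate(loadings)
    }
    return pd.DataFrame(cols), f


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded default-structure cohort at reduced n for fast tests."""
    cfg = pb.default_config(n_subjects=300, seed=7)
    baseline, chronic, blocks, groups = pb.generate_cohort(cfg)
    return cfg, baseline, chronic, blocks, groups


@pytest.fixture(scope="session")
def small_delta(small_cohort):
    _, baseline, chronic, _, _ = small_cohort
    return pb.compute_changes(baseline, chronic)


@pytest.fixture(scope="session")
def cohort_scores():
    """Full-size cohort scored by the PLSPM star model.

    The weakly coupled star inner model needs the full cohort scale for
    stable mode-A weights, so subgroup-detection tests run at n = 883.
    """
    cfg = pb.default_config(seed=7)
    baseline, chronic, blocks, groups = pb.generate_cohort(cfg)
    delta = pb.compute_changes(baseline, chronic)
    aligned, _ = pb.align_signs(delta, blocks)
    fit = pb.fit_plspm(aligned, pb.build_default_path_model(blocks, "SPO2"))
    return fit.lv_scores, groups
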