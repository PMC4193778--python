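import numpy as np
import pandas as pd
import pytest

from scallopsize import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_camera():
    return sim.TrueCameraModel()


@pytest.fixture
def pincushion_camera():
    return sim.TrueCameraModel.with_pincushion()


@pytest.fixture
def tiny_nested():
    """2 surveys x 2 transects x 2 frames x 2 obs = 16 observations."""
    return sim.simulate_nested_heights(
        mu=6.0,
        sigma2_survey=0.2, sigma2_transect=0.05,
        sigma2_frame=0.3, sigma2_resid=0.8,
        n_surveys=2, transects_per_survey=2,
        frames_per_transect=2, obs_per_frame=2,
        rng=42,
    )


def dense_nested_loglik(records: pd.DataFrame, mu, s2_s, s2_t, s2_f, s2_e):
    """Brute-force oracle: build the full nested covariance matrix and
    evaluate the dense multivariate-normal log-density."""
    from scipy.stats import multivariate_normal

    s = records["survey_id"].astype(str).to_numpy()
    t = np.char.add(s, records["transect_id"].astype(str).to_numpy())
    f = np.char.add(t, records["frame_id"].astype(str).to_numpy())
    y = records["height_cm"].to_numpy(float)
    n = len(y)
    cov = (
        s2_e * np.eye(n)
        + s2_f * (f[:, None] == f[None, :])
        + s2_t * (t[:, None] == t[None, :])
        + s2_s * (s[:, None] == s[None, :])
    )
    return float(
        multivariate_normal.logpdf(y, mean=np.full(n, mu), cov=cov)
    )


def grid_refine_oracle(records: pd.DataFrame) -> float:
    """Brute-force maximum of the dense nested likelihood: coarse grid
    over (boundary-inclusive) log variances, Nelder-Mead polish with
    chained restarts from the best grid points."""
    from scipy import optimize

    def neg(p):
        v = np.exp(np.clip(p[1:], -30.0, 8.0))
        try:
            return -dense_nested_loglik(records, p[0], *v)
        except np.linalg.LinAlgError:
            return 1e12

    grid = np.log([1e-10, 0.01, 0.1, 0.5, 1.5])
    ybar = float(records["height_cm"].mean())
    pts = [
        [ybar, a, b, c, d]
        for a in grid for b in grid for c in grid for d in grid
    ]
    scores = np.array([neg(p) for p in pts])
    best = -np.inf
    for i in np.argsort(scores)[:10]:
        x = np.array(pts[i])
        for _ in range(3):
            res = optimize.minimize(
                neg, x, method="Nelder-Mead",
                options={"fatol": 1e-12, "xatol": 1e-10, "maxiter": 8000},
            )
            x = res.x
        best = max(best, -float(res.fun))
    return best
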