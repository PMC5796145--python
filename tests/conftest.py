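import numpy as np
import pandas as pd
import pytest

import pairdissect as pdx


@pytest.fixture(scope="session")
def default_cohort():
    """The default three-class simulated cohort (shared across tests)."""
    return pdx.simulate_cohort(pdx.default_config(seed=42))


@pytest.fixture()
def tiny_matrix():
    """3 probes x 4 samples with symbols and detection p-values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0], [2.0, 8.0, 4.0, 6.0]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    symbols = pd.Series(["ESR1", "GAPDH", "ESR1"], index=values.index)
    detp = pd.DataFrame(0.0, index=values.index, columns=values.columns)
    return pdx.ExpressionMatrix(values=values, symbols=symbols, detection_p=detp)


def pingouin_agreement_icc(x: np.ndarray) -> float:
    """Independent oracle: single-rater absolute-agreement ICC via pingouin."""
    import warnings

    import pingouin as pg

    x = np.asarray(x, dtype=float)
    n, k = x.shape
    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": x.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        )
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    return float(row["ICC"].iloc[0])


def direct_mean_squares_icc(x: np.ndarray) -> float:
    """Second oracle: agreement ICC by naive elementwise loops."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_p = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_m = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_r = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    ms_p = ss_p / (n - 1)
    ms_m = ss_m / (k - 1)
    ms_r = ss_r / ((n - 1) * (k - 1))
    s_p = (ms_p - ms_r) / k
    s_m = (ms_m - ms_r) / n
    return s_p / (s_p + s_m + ms_r)
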