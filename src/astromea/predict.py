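"""Autoregressive random-forest predictability of the downsampled signal.

Each channel (after the prediction preprocessing chain: 300 Hz low-pass,
250 Hz sample rate) is framed as a one-step-ahead autoregression: the
regressor sees the previous ``n_lags`` samples (default 20, i.e. 80 ms
of history) and predicts the next one.  A random forest is trained on
the first 70% of the samples (contiguous) and evaluated on the last
30%, predicting each test sample from its true lagged values.  The
score is Pearson's correlation r between predicted and actual test
values: strongly patterned signals are predictable (r near 1) while
noise-like signals are not (r near 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, substream_seed
from .recording import RawRecording

__all__ = [
    "PredictionResult",
    "build_lagged_design",
    "fit_predict_rf",
    "pearson_r",
    "predict_recording",
]


@dataclass
class PredictionResult:
    """Predictability score of one channel."""

    channel_id: str
    r: float                 # Pearson correlation, test segment; NaN if undefined
    predicted: np.ndarray    # one-step-ahead predictions on the test segment
    actual: np.ndarray
    split_index: int         # first test-sample index in the lagged design
    flagged: bool = False    # True when r is undefined (constant segment)


def build_lagged_design(x: np.ndarray, n_lags: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design matrix and one-step-ahead targets.

    Row ``i`` holds ``x[i] .. x[i + n_lags - 1]`` and its target is
    ``x[i + n_lags]``; there are ``len(x) - n_lags`` rows.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if n_lags <= 0:
        raise ValueError(f"n_lags must be >= 1, got {n_lags}")
    if x.size <= n_lags:
        raise ValueError(f"need more than {n_lags} samples, got {x.size}")
    n = x.size - n_lags
    X = np.lib.stride_tricks.sliding_window_view(x, n_lags)[:n]
    y = x[n_lags:]
    return np.ascontiguousarray(X), y


def pearson_r(a, b) -> float:
    """Product-moment correlation of two equal-length samples."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def fit_predict_rf(x: np.ndarray, config: AnalysisConfig | None = None,
                   channel_id: str = "", seed: int | None = None
                   ) -> PredictionResult:
    """Train/test a one-step-ahead random-forest autoregression on ``x``.

    The first ``train_fraction`` of the samples (default 70%) trains the
    forest; the remainder is predicted one step ahead from true lags and
    scored with Pearson's r.  A constant test or training segment makes
    the correlation undefined: the result is flagged and ``r`` is NaN.
    """
    from sklearn.ensemble import RandomForestRegressor

    config = config or AnalysisConfig()
    if config.predict_horizon != 1:
        raise NotImplementedError("only one-step-ahead prediction is implemented")
    x = np.asarray(x, dtype=np.float64).ravel()
    X, y = build_lagged_design(x, config.n_lags)
    split = int(np.floor(config.train_fraction * X.shape[0]))
    if split < 1 or split >= X.shape[0]:
        raise ValueError("train fraction leaves an empty train or test segment")
    if seed is None:
        seed = substream_seed(config.seed, f"rf:{channel_id}")
    rf = RandomForestRegressor(n_estimators=config.n_trees, random_state=seed,
                               n_jobs=1)
    if np.ptp(y[:split]) == 0 or np.ptp(y[split:]) == 0:
        return PredictionResult(channel_id=channel_id, r=float("nan"),
                                predicted=np.array([]), actual=y[split:],
                                split_index=split, flagged=True)
    rf.fit(X[:split], y[:split])
    pred = rf.predict(X[split:])
    if pred.std() == 0:
        return PredictionResult(channel_id=channel_id, r=float("nan"),
                                predicted=pred, actual=y[split:],
                                split_index=split, flagged=True)
    r = pearson_r(pred, y[split:])
    return PredictionResult(channel_id=channel_id, r=r, predicted=pred,
                            actual=y[split:], split_index=split)


def predict_recording(rec: RawRecording, config: AnalysisConfig | None = None
                      ) -> pd.DataFrame:
    """Per-channel predictability table of a prediction-chain recording."""
    config = config or AnalysisConfig()
    rows = []
    for ch in range(rec.n_channels):
        res = fit_predict_rf(rec.data[ch], config, rec.channel_ids[ch])
        rows.append((res.channel_id, res.r, res.flagged))
    return pd.DataFrame(rows, columns=["channel", "pearson_r", "flagged"])
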