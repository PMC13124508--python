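"""Query-time prediction head, horizon-weighted loss, and error metrics.

Predictions at arbitrary future times come from the state of the *last*
canonical interval: the context vector is passed together with the
normalized future time t_fut = (tau - T) / H through a time-aware
Fourier-analysis output layer (cos/sin/GELU three-block concatenation) and
a final linear projection.

Training minimizes a horizon-weighted squared error: each scored query is
weighted by w = 1 + alpha * (tau - T), so farther-future queries — the ones
that matter for proactive planning — receive linearly increasing emphasis.
With alpha = 0 the loss is exactly the unweighted masked MSE.  Queries
without ground truth are excluded from both the sum and the normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gelu

__all__ = [
    "PredictionHeadParams",
    "LossConfig",
    "ForecastSet",
    "predict_queries",
    "merge_forecasts",
    "mta_loss",
    "evaluate",
]


class PredictionHeadParams:
    """Time-aware output layer plus the final projection to the value dim."""

    def __init__(self, d_context: int, d_p: int = 8, d_pbar: int = 16,
                 d_value: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        s = 1 / np.sqrt(d_context)
        self.Wp = Tensor(rng.normal(0, s, (d_context, d_p)),
                         requires_grad=True)
        # paired channels near one cycle per horizon: same-frequency
        # cos/sin pairs let the context modulate amplitude as well as
        # phase, and frequencies must start near plausible oscillation
        # rates because they move too slowly under gradient descent to be
        # found from a zero-centered init
        reps = int(np.ceil(d_p / 4))
        up0 = 2 * np.pi * np.tile([0.8, 1.0, 1.0, 1.25], reps)[:d_p] \
            + rng.normal(0, 0.05, d_p)
        self.Up = Tensor(up0, requires_grad=True)
        self.Wpbar = Tensor(rng.normal(0, s, (d_context, d_pbar)),
                            requires_grad=True)
        self.Vpbar = Tensor(rng.normal(0, 1.0, d_pbar), requires_grad=True)
        self.Bpbar = Tensor(np.zeros(d_pbar), requires_grad=True)
        d_z = 2 * d_p + d_pbar
        # zero-initialized output projection: the untrained forecaster
        # predicts the (standardized) mean instead of arbitrary-phase
        # oscillations, which keeps early training stable
        self.W_out = Tensor(np.zeros((d_z, d_value)), requires_grad=True)
        self.b_out = Tensor(np.zeros(d_value), requires_grad=True)

    def params(self) -> dict[str, Tensor]:
        return {"Wp": self.Wp, "Up": self.Up, "Wpbar": self.Wpbar,
                "Vpbar": self.Vpbar, "Bpbar": self.Bpbar,
                "W_out": self.W_out, "b_out": self.b_out}


@dataclass(frozen=True)
class LossConfig:
    """Horizon-weight slope alpha (per hour of forecast distance)."""

    alpha: float = 0.1

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass
class ForecastSet:
    """Predictions at query times with matched targets where available.

    ``variable_index`` holds the position of each query's variable in the
    episode's series list; ``horizons`` are tau - T in hours.  ``scored``
    marks queries with known ground truth; only those enter loss/metrics.
    """

    predictions: Tensor                  # (Q,) in standardized space
    targets: np.ndarray                  # (Q,), NaN where unknown
    scored: np.ndarray                   # (Q,) bool
    variable_index: np.ndarray           # (Q,) int
    horizons: np.ndarray                 # (Q,) float, tau - T
    query_times: np.ndarray              # (Q,) float, absolute tau
    episode_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def n_scored(self) -> int:
        return int(self.scored.sum())


def head_features(context: Tensor, t_fut: np.ndarray,
                  p: PredictionHeadParams) -> Tensor:
    """z = [cos(Wp c + Up t) || sin(Wp c + Up t) || GELU(B + Wpbar c + Vpbar t)].

    ``context`` is [Q, d_context]; ``t_fut`` is the normalized future time
    in (0, 1], one per query.
    """
    t = Tensor(np.asarray(t_fut, dtype=float)[:, None])
    u = context @ p.Wp + t * p.Up
    g = gelu(p.Bpbar + context @ p.Wpbar + t * p.Vpbar)
    return concat([u.cos(), u.sin(), g], axis=-1)


def predict_queries(contexts: Tensor, episode, p: PredictionHeadParams,
                    series_index: dict[int, int] | None = None
                    ) -> ForecastSet:
    """Forecast every query of an episode from per-variable contexts.

    ``contexts`` is [N, d_context] — the last-canonical-interval state of
    each variable.  Queries may be empty or unevenly spread over variables;
    each query's time must lie in (T, T + H].
    """
    T, H = episode.window_end, episode.horizon
    if series_index is None:
        series_index = {vid: i for i, vid in enumerate(episode.variable_ids())}
    times = np.array([q.time for q in episode.queries], dtype=float)
    if len(times) and (times.min() <= T or times.max() > T + H + 1e-9):
        raise ValueError("query outside (T, T + H]")
    var_idx = np.array([series_index[q.variable_id]
                        for q in episode.queries], dtype=int)
    targets = np.array([np.nan if q.target is None else q.target
                        for q in episode.queries], dtype=float)
    if len(times) == 0:
        return ForecastSet(Tensor(np.zeros(0)), targets,
                           np.zeros(0, dtype=bool), var_idx, times, times,
                           [episode.episode_id] * 0)
    t_fut = (times - T) / H
    ctx = contexts[var_idx]
    z = head_features(ctx, t_fut, p)
    yhat = (z @ p.W_out + p.b_out)[:, 0]
    return ForecastSet(yhat, targets, ~np.isnan(targets), var_idx,
                       times - T, times, [episode.episode_id] * len(times))


def merge_forecasts(sets: list[ForecastSet]) -> ForecastSet:
    """Concatenate per-episode forecast sets (variable indices preserved)."""
    return ForecastSet(
        predictions=concat([s.predictions for s in sets], axis=0),
        targets=np.concatenate([s.targets for s in sets]),
        scored=np.concatenate([s.scored for s in sets]),
        variable_index=np.concatenate([s.variable_index for s in sets]),
        horizons=np.concatenate([s.horizons for s in sets]),
        query_times=np.concatenate([s.query_times for s in sets]),
        episode_ids=[e for s in sets for e in s.episode_ids],
    )


def mta_loss(forecasts: ForecastSet, config: LossConfig = LossConfig()
             ) -> Tensor:
    """Horizon-weighted masked squared error (differentiable scalar).

    L = (1/Q) * sum_q w_q * (yhat_q - y_q)^2 over scored queries, with
    w_q = 1 + alpha * (tau_q - T) and Q the scored count.  alpha = 0 gives
    the plain masked MSE.
    """
    scored = forecasts.scored
    if not scored.any():
        raise ValueError("no scored queries")
    idx = np.flatnonzero(scored)
    resid = forecasts.predictions[idx] - forecasts.targets[idx]
    w = 1.0 + config.alpha * forecasts.horizons[idx]
    return (resid * resid * w).sum() * (1.0 / len(idx))


def evaluate(forecasts: ForecastSet, mape_eps: float = 1e-8
             ) -> dict[str, float]:
    """MSE/MAE/RMSE/MRE/MAPE over scored queries.

    MSE and MAE average per variable first (over that variable's scored
    queries) and then across variables, so densely queried variables do not
    dominate.  MRE is the aggregate relative error sum|e| / sum|y|; MAPE
    excludes |y| < eps queries (their count is reported).
    """
    scored = forecasts.scored
    if not scored.any():
        raise ValueError("no scored queries")
    yhat = forecasts.predictions.data[scored]
    y = forecasts.targets[scored]
    vidx = forecasts.variable_index[scored]
    err = yhat - y
    per_var_mse, per_var_mae = [], []
    for v in np.unique(vidx):
        e = err[vidx == v]
        per_var_mse.append(np.mean(e ** 2))
        per_var_mae.append(np.mean(np.abs(e)))
    mse = float(np.mean(per_var_mse))
    mae = float(np.mean(per_var_mae))
    denom = np.abs(y)
    ok = denom >= mape_eps
    mape = float(np.mean(np.abs(err[ok]) / denom[ok])) if ok.any() \
        else float("nan")
    return {
        "MSE": mse,
        "MAE": mae,
        "RMSE": float(np.sqrt(mse)),
        "MRE": float(np.sum(np.abs(err)) / max(np.sum(denom), mape_eps)),
        "MAPE": mape,
        "n_scored": int(scored.sum()),
        "n_mape_excluded": int((~ok).sum()),
    }
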