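"""Data model and I/O for irregular multivariate time-series (IMTS) episodes.

An *episode* is one patient record: for each of N physiological variables, a
time-ordered sequence of (time, value) observations over an observation
window [0, T], plus a set of future query times in (T, T + H] at which the
forecaster is scored.  Missingness is represented purely by absence — there
is no sentinel value anywhere in the pipeline.

The canonical on-disk format is a long-format CSV with one row per
observation (``episode_id, variable_id, time_hours, value``) and an optional
companion query table (``episode_id, variable_id, query_time_hours,
target_value``).  This matches the shape of typical EHR extracts and keeps
fixtures diffable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Observation",
    "IrregularSeries",
    "Query",
    "IMTSEpisode",
    "Standardizer",
    "read_long_table",
    "write_long_table",
    "split_episodes",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
    "perturb_pointwise_mcar",
    "perturb_blockwise",
]


@dataclass(frozen=True)
class Observation:
    """A single measurement: hours since episode start and its value."""

    time: float
    value: float

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"observation time must be finite and >= 0, "
                             f"got {self.time}")
        if not np.isfinite(self.value):
            raise ValueError("observation value must be finite")


@dataclass(frozen=True)
class IrregularSeries:
    """All observations of one variable within an episode, strictly ordered."""

    variable_id: int
    observations: tuple[Observation, ...]

    def __post_init__(self):
        times = [o.time for o in self.observations]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"variable {self.variable_id}: observation times must be "
                f"strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([o.value for o in self.observations], dtype=float)

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class Query:
    """A forecast request: predict variable ``variable_id`` at ``time``.

    ``target`` is the ground-truth value when known (for training /
    evaluation) and None for pure inference queries.
    """

    variable_id: int
    time: float
    target: float | None = None


@dataclass(frozen=True)
class IMTSEpisode:
    """One patient's irregular multivariate record plus its forecast queries."""

    episode_id: str
    series: tuple[IrregularSeries, ...]
    window_end: float
    horizon: float
    queries: tuple[Query, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.series) < 2:
            raise ValueError("an episode needs at least 2 variables")
        for s in self.series:
            if len(s) and s.times[-1] > self.window_end + 1e-12:
                raise ValueError(
                    f"episode {self.episode_id}, variable {s.variable_id}: "
                    f"observation beyond the window end T={self.window_end}")
        lo, hi = self.window_end, self.window_end + self.horizon
        for q in self.queries:
            if not (lo < q.time <= hi + 1e-12):
                raise ValueError(
                    f"episode {self.episode_id}: query time {q.time} outside "
                    f"(T, T+H] = ({lo}, {hi}]")

    @property
    def n_variables(self) -> int:
        return len(self.series)

    def n_observations(self) -> int:
        return sum(len(s) for s in self.series)

    def variable_ids(self) -> list[int]:
        return [s.variable_id for s in self.series]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_OBS_COLS = ["episode_id", "variable_id", "time_hours", "value"]
_QRY_COLS = ["episode_id", "variable_id", "query_time_hours", "target_value"]


def read_long_table(path: str | Path,
                    query_path: str | Path | None = None,
                    window_end: float | None = None,
                    horizon: float | None = None) -> list[IMTSEpisode]:
    """Read a long-format observation CSV (and optional query CSV).

    ``window_end``/``horizon`` default to the maximum observation time and
    the span needed to cover the latest query, respectively, when not given.
    Duplicate (episode, variable, time) rows are rejected.
    """
    path = Path(path)
    try:
        obs = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _OBS_COLS if c not in obs.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = obs[~np.isfinite(pd.to_numeric(obs["time_hours"], errors="coerce"))]
    if len(bad):
        raise ValueError(
            f"{path}: malformed time_hours at line {bad.index[0] + 2}")
    bad = obs[~np.isfinite(pd.to_numeric(obs["value"], errors="coerce"))]
    if len(bad):
        raise ValueError(f"{path}: malformed value at line {bad.index[0] + 2}")
    dup = obs.duplicated(subset=["episode_id", "variable_id", "time_hours"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (episode, variable, time) at line "
            f"{int(np.flatnonzero(dup.to_numpy())[0]) + 2}")

    queries = pd.DataFrame(columns=_QRY_COLS)
    if query_path is not None:
        queries = pd.read_csv(query_path)
        missing = [c for c in _QRY_COLS if c not in queries.columns]
        if missing:
            raise ValueError(f"{query_path}: missing columns {missing}")

    episodes: list[IMTSEpisode] = []
    for eid, grp in obs.groupby("episode_id", sort=True):
        var_ids = sorted(set(grp["variable_id"].astype(int)))
        qgrp = queries[queries["episode_id"] == eid]
        qvars = sorted(set(qgrp["variable_id"].astype(int))) if len(qgrp) else []
        var_ids = sorted(set(var_ids) | set(qvars))
        series = []
        for vid in var_ids:
            rows = grp[grp["variable_id"] == vid].sort_values("time_hours")
            series.append(IrregularSeries(
                variable_id=vid,
                observations=tuple(Observation(float(t), float(v))
                                   for t, v in zip(rows["time_hours"],
                                                   rows["value"]))))
        T = window_end if window_end is not None else (
            float(grp["time_hours"].max()) if len(grp) else 0.0)
        qs = tuple(Query(int(r.variable_id), float(r.query_time_hours),
                         None if pd.isna(r.target_value)
                         else float(r.target_value))
                   for r in qgrp.itertuples())
        H = horizon if horizon is not None else (
            max((q.time for q in qs), default=T + 1.0) - T)
        episodes.append(IMTSEpisode(str(eid), tuple(series), T, H, qs))
    return episodes


def write_long_table(episodes: list[IMTSEpisode], path: str | Path,
                     query_path: str | Path | None = None) -> None:
    """Write episodes back to the long-format CSVs (inverse of read)."""
    rows = [(e.episode_id, s.variable_id, o.time, o.value)
            for e in episodes for s in e.series for o in s.observations]
    pd.DataFrame(rows, columns=_OBS_COLS).to_csv(path, index=False)
    if query_path is not None:
        qrows = [(e.episode_id, q.variable_id, q.time,
                  "" if q.target is None else q.target)
                 for e in episodes for q in e.queries]
        pd.DataFrame(qrows, columns=_QRY_COLS).to_csv(query_path, index=False)


# ---------------------------------------------------------------------------
# Episode-level split
# ---------------------------------------------------------------------------

def split_episodes(episodes: list[IMTSEpisode],
                   fractions: tuple[float, ...] = (0.6, 0.2, 0.2),
                   seed: int = 0) -> tuple[list[IMTSEpisode], ...]:
    """Partition episodes into disjoint subsets at the patient level.

    Each episode lands in exactly one subset; the split is deterministic for
    a given seed.  Subset sizes are the rounded fractions with the remainder
    given to the first subsets.
    """
    if not episodes:
        raise ValueError("no episodes to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_nonzero = sum(f > 0 for f in fractions)
    if len(episodes) < n_nonzero:
        raise ValueError(
            f"cannot split {len(episodes)} episodes into {n_nonzero} "
            f"non-empty subsets")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(episodes))
    n = len(episodes)
    sizes = [int(np.floor(f * n)) for f in fractions]
    i = 0
    while sum(sizes) < n:
        if fractions[i % len(fractions)] > 0:
            sizes[i % len(sizes)] += 1
        i += 1
    out, start = [], 0
    for size in sizes:
        out.append([episodes[j] for j in order[start:start + size]])
        start += size
    return tuple(out)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardizer:
    """Per-variable mean/std estimated on training episodes.

    Uses the population convention (divide by n).  Variables with zero
    variance or no training observations get std 1 (with a warning for the
    zero-variance case) so that the transform is always invertible.
    """

    means: dict[int, float]
    stds: dict[int, float]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"means": {str(k): v for k, v in self.means.items()},
             "stds": {str(k): v for k, v in self.stds.items()}}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Standardizer":
        d = json.loads(Path(path).read_text())
        return cls(means={int(k): v for k, v in d["means"].items()},
                   stds={int(k): v for k, v in d["stds"].items()})


def fit_standardizer(train_episodes: list[IMTSEpisode]) -> Standardizer:
    pooled: dict[int, list[float]] = {}
    for ep in train_episodes:
        for s in ep.series:
            pooled.setdefault(s.variable_id, []).extend(s.values)
        for q in ep.queries:
            pooled.setdefault(q.variable_id, [])
    means, stds = {}, {}
    for vid, vals in pooled.items():
        if not vals:
            means[vid], stds[vid] = 0.0, 1.0
            continue
        arr = np.asarray(vals)
        means[vid] = float(arr.mean())
        std = float(arr.std())  # population convention
        if std <= 0:
            warnings.warn(f"variable {vid} has zero variance in training "
                          f"data; std forced to 1", stacklevel=2)
            std = 1.0
        stds[vid] = std
    return Standardizer(means, stds)


def _transform_episode(episode: IMTSEpisode, std: Standardizer,
                       invert: bool) -> IMTSEpisode:
    series = []
    for s in episode.series:
        mu = std.means.get(s.variable_id, 0.0)
        sd = std.stds.get(s.variable_id, 1.0)
        obs = tuple(
            Observation(o.time,
                        o.value * sd + mu if invert else (o.value - mu) / sd)
            for o in s.observations)
        series.append(IrregularSeries(s.variable_id, obs))
    queries = tuple(
        replace(q, target=None if q.target is None else
                (q.target * std.stds.get(q.variable_id, 1.0)
                 + std.means.get(q.variable_id, 0.0)) if invert else
                (q.target - std.means.get(q.variable_id, 0.0))
                / std.stds.get(q.variable_id, 1.0))
        for q in episode.queries)
    return replace(episode, series=tuple(series), queries=queries)


def apply_standardizer(episode: IMTSEpisode,
                       std: Standardizer) -> IMTSEpisode:
    """Map observation values and query targets to standardized space."""
    return _transform_episode(episode, std, invert=False)


def invert_standardizer(episode: IMTSEpisode,
                        std: Standardizer) -> IMTSEpisode:
    """Map a standardized episode back to raw value space."""
    return _transform_episode(episode, std, invert=True)


# ---------------------------------------------------------------------------
# Test-time missingness perturbations
# ---------------------------------------------------------------------------

def perturb_pointwise_mcar(episode: IMTSEpisode, rho: float,
                           seed: int) -> IMTSEpisode:
    """Remove each observation independently with probability ``rho``.

    Queries and targets are never touched; only the observed history is
    thinned.  Deterministic for a given seed.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if rho == 0.0:
        return episode
    rng = np.random.default_rng(seed)
    series = []
    for s in episode.series:
        keep = rng.random(len(s)) >= rho
        series.append(IrregularSeries(
            s.variable_id,
            tuple(o for o, k in zip(s.observations, keep) if k)))
    return replace(episode, series=tuple(series))


def perturb_blockwise(episode: IMTSEpisode, rho: float, seed: int,
                      block_fraction: float = 0.1,
                      min_block: int = 2,
                      block_length: int | None = None) -> IMTSEpisode:
    """Remove contiguous runs of observed indices per variable.

    For each variable with ``n`` observations, blocks of ``block_length``
    consecutive observation indices (default ``max(min_block,
    round(block_fraction * n))``) are removed at random non-overlapping
    starts until the total removed count reaches approximately ``rho * n``
    (within one block length).  Emulates interrupted monitoring or delayed
    lab panels.  Queries are never touched.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if rho == 0.0:
        return episode
    rng = np.random.default_rng(seed)
    series = []
    for s in episode.series:
        n = len(s)
        if n == 0:
            series.append(s)
            continue
        block = (block_length if block_length is not None
                 else max(min_block, int(round(block_fraction * n))))
        block = min(block, n)
        target = rho * n
        removed = np.zeros(n, dtype=bool)
        attempts = 0
        while removed.sum() < target - 1e-9 and attempts < 50 * n:
            attempts += 1
            start = int(rng.integers(0, n - block + 1))
            if removed[start:start + block].any():
                continue
            removed[start:start + block] = True
        series.append(IrregularSeries(
            s.variable_id,
            tuple(o for o, r in zip(s.observations, removed) if not r)))
    return replace(episode, series=tuple(series))
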