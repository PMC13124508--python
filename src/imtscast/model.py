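"""End-to-end forecaster: patching -> dual-domain encoding -> scale fusion
-> [transformer -> dynamic graph -> GCN] x K -> query prediction.

The model operates on *prepared* episodes: padded per-scale patch arrays,
precomputed Lomb-Scargle node features, and flattened query metadata.
Preparation is pure numpy and cacheable; the differentiable forward pass
consumes a collated batch so that all episodes, variables and patches of a
scale run through each neural stage in a single vectorized call.

Ablation switches (mirroring the component study the architecture was
designed around):

* ``no_patching``   — one token per union timestamp (pre-aligned
                      representation) instead of duration patches;
* ``single_scale``  — finest scale only;
* ``no_frequency``  — drop the IFAN branch and the spectral node features;
* ``no_transformer``— identity in place of the temporal transformer;
* ``no_graph``      — skip graph construction and GCN (variables stay
                      independent end to end).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .core import IMTSEpisode
from .encoder import DualDomainEncoder, pad_patches
from .forecast import (ForecastSet, LossConfig, PredictionHeadParams,
                       head_features)
from .fusion import (ScaleFusionParams, TransformerConfig, TransformerEncoder,
                     align_to_canonical, fuse_scales)
from .graph import (GraphParams, build_interval_graph, gcn_aggregate,
                    lomb_scargle_power, spectral_features)
from .patching import PatchSpec, build_patch_grid

__all__ = ["ModelConfig", "Forecaster", "prepare_episode", "collate"]


@dataclass(frozen=True)
class ModelConfig:
    """All architectural and training-relevant hyperparameters.

    Defaults follow the reference configuration: scale set {1,2,4,8,24} h
    over a 24 h window, hidden width 64, time embedding 10, variable
    embedding 10, one transformer head/layer and one block.
    """

    scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 24.0)
    window_end: float = 24.0
    horizon: float = 24.0
    d_value: int = 1
    d_time_embed: int = 10
    d_time: int = 32
    d_freq: int = 32
    d_fused: int = 64
    d_hidden: int = 32
    n_ifan_layers: int = 2
    d_model: int = 64
    n_heads: int = 1
    n_tf_layers: int = 1
    d_ff: int | None = None
    dropout: float = 0.1
    d_fourier: int = 10
    d_graph: int = 10
    n_blocks: int = 1
    alpha: float = 0.1
    seed: int = 0
    # ablation switches
    no_patching: bool = False
    single_scale: bool = False
    no_frequency: bool = False
    no_transformer: bool = False
    no_graph: bool = False

    def patch_spec(self) -> PatchSpec:
        scales = (self.scales[:1] if self.single_scale else self.scales)
        return PatchSpec(scales=tuple(scales), window_end=self.window_end)

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Compact configuration for desk-scale cohorts (CPU training)."""
        params = dict(d_time=8, d_freq=16, d_fused=32, d_hidden=8,
                      d_model=32, d_ff=64, n_ifan_layers=1, dropout=0.0)
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        d["scales"] = list(d["scales"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["scales"] = tuple(d["scales"])
        return cls(**d)


@dataclass
class EpisodePrep:
    """Numpy-only prepared form of one episode."""

    episode: IMTSEpisode
    # per scale: (values [N*P_s, L, 1], times [N*P_s, L], valid [N*P_s, L])
    scale_arrays: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    spectral: np.ndarray | None          # (N, P1, d_fourier)
    n_canonical: int
    query_var: np.ndarray                # positions in the series list
    query_times: np.ndarray
    query_targets: np.ndarray            # NaN where unknown


def prepare_episode(episode: IMTSEpisode, config: ModelConfig,
                    probe_frequencies: np.ndarray | None) -> EpisodePrep:
    """Patch, pad and feature-extract one episode (no parameters involved)."""
    series_index = {vid: i for i, vid in enumerate(episode.variable_ids())}
    qvar = np.array([series_index[q.variable_id] for q in episode.queries],
                    dtype=int)
    qt = np.array([q.time for q in episode.queries], dtype=float)
    qy = np.array([np.nan if q.target is None else q.target
                   for q in episode.queries], dtype=float)

    if config.no_patching:
        return _prepare_prealigned(episode, config, probe_frequencies,
                                   qvar, qt, qy)

    spec = config.patch_spec()
    grid = build_patch_grid(episode, spec)
    arrays = []
    for s in range(spec.n_scales):
        patch_lists = grid.patches_at_scale(s)
        arrays.append(pad_patches(patch_lists, config.d_value))
    spectral = None
    if not config.no_frequency:
        if probe_frequencies is None:
            raise ValueError("probe frequencies required unless the "
                             "frequency pathway is ablated")
        spectral, _ = spectral_features(grid, spec, probe_frequencies)
    return EpisodePrep(episode, arrays, spectral, spec.n_canonical,
                       qvar, qt, qy)


def _prepare_prealigned(episode, config, probe_frequencies, qvar, qt, qy
                        ) -> EpisodePrep:
    """Pre-aligned representation: one singleton token per union timestamp."""
    union = sorted({o.time for s in episode.series for o in s.observations})
    if not union:
        union = [0.0]
    n_tok = len(union)
    N = episode.n_variables
    pos = {t: j for j, t in enumerate(union)}
    values = np.zeros((N * n_tok, 1, config.d_value))
    times = np.zeros((N * n_tok, 1))
    valid = np.zeros((N * n_tok, 1), dtype=bool)
    for i, s in enumerate(episode.series):
        for o in s.observations:
            j = pos[o.time]
            row = i * n_tok + j
            values[row, 0, 0] = o.value
            valid[row, 0] = True
    spectral = None
    if not config.no_frequency:
        per_var = np.zeros((N, len(probe_frequencies)))
        for i, s in enumerate(episode.series):
            if len(s) >= 3:
                per_var[i] = lomb_scargle_power(s.times, s.values,
                                                probe_frequencies)
        spectral = np.repeat(per_var[:, None, :], n_tok, axis=1)
    return EpisodePrep(episode, [(values, times, valid)], spectral, n_tok,
                       qvar, qt, qy)


@dataclass
class ScaleBatch:
    """Compacted patches of one scale, bucketed by padded length.

    Empty patches are dropped entirely; the remaining patches are grouped
    into power-of-two length buckets so the encoder never pads a sparse
    patch to the longest patch in the batch.  ``inverse_index`` maps every
    (episode, variable, interval) grid slot to its row in the concatenation
    of the bucket outputs, with the sentinel last row standing for "use the
    learned empty-patch token".
    """

    buckets: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    inverse_index: np.ndarray
    n_slots: int


@dataclass
class Batch:
    """Collated episodes ready for the differentiable forward pass."""

    preps: list[EpisodePrep]
    scale_arrays: list[ScaleBatch]
    spectral: np.ndarray | None          # (B, N, P1, d_fourier)
    n_variables: int
    n_canonical: int
    query_episode: np.ndarray
    query_var: np.ndarray
    query_t_fut: np.ndarray              # normalized (tau - T) / H
    query_horizons: np.ndarray           # tau - T in hours
    query_times: np.ndarray
    query_targets: np.ndarray
    episode_ids: list[str]


def collate(preps: list[EpisodePrep]) -> Batch:
    """Stack prepared episodes, padding patch lengths to the batch maximum."""
    B = len(preps)
    n_scales = len(preps[0].scale_arrays)
    N = preps[0].episode.n_variables
    P1 = preps[0].n_canonical
    if any(p.n_canonical != P1 or p.episode.n_variables != N
           for p in preps):
        raise ValueError("episodes in one batch must share the canonical "
                         "timeline; use batch size 1 for the pre-aligned "
                         "(no_patching) representation")
    scale_arrays = []
    for s in range(n_scales):
        rows = preps[0].scale_arrays[s][0].shape[0]
        L = max(p.scale_arrays[s][0].shape[1] for p in preps)
        dv = preps[0].scale_arrays[s][0].shape[2]
        values = np.zeros((B * rows, L, dv))
        times = np.zeros((B * rows, L))
        valid = np.zeros((B * rows, L), dtype=bool)
        for b, p in enumerate(preps):
            v, t, m = p.scale_arrays[s]
            sl = slice(b * rows, b * rows + rows)
            values[sl, :v.shape[1]] = v
            times[sl, :t.shape[1]] = t
            valid[sl, :m.shape[1]] = m
        # compact away empty patches and bucket the rest by padded length
        lengths = valid.sum(axis=1)
        n_ne = int((lengths > 0).sum())
        inverse = np.full(B * rows, n_ne, dtype=int)  # sentinel: empty token
        caps, c = [], 1
        while True:
            caps.append(min(c, L))
            if c >= L:
                break
            c *= 2
        buckets = []
        offset = 0
        prev = 0
        for cap in caps:
            in_bucket = (lengths > prev) & (lengths <= cap)
            prev = cap
            if in_bucket.any():
                rows_idx = np.flatnonzero(in_bucket)
                inverse[rows_idx] = offset + np.arange(len(rows_idx))
                offset += len(rows_idx)
                buckets.append((values[rows_idx, :cap],
                                times[rows_idx, :cap],
                                valid[rows_idx, :cap]))
        scale_arrays.append(ScaleBatch(buckets, inverse, B * rows))
    spectral = None
    if preps[0].spectral is not None:
        spectral = np.stack([p.spectral for p in preps])
    qep, qvar, qfut, qhor, qtimes, qtgt, eids = [], [], [], [], [], [], []
    for b, p in enumerate(preps):
        T, H = p.episode.window_end, p.episode.horizon
        qep.append(np.full(len(p.query_var), b))
        qvar.append(p.query_var)
        qfut.append((p.query_times - T) / H)
        qhor.append(p.query_times - T)
        qtimes.append(p.query_times)
        qtgt.append(p.query_targets)
        eids.extend([p.episode.episode_id] * len(p.query_var))
    return Batch(
        preps=preps, scale_arrays=scale_arrays, spectral=spectral,
        n_variables=N, n_canonical=P1,
        query_episode=np.concatenate(qep).astype(int),
        query_var=np.concatenate(qvar).astype(int),
        query_t_fut=np.concatenate(qfut),
        query_horizons=np.concatenate(qhor),
        query_times=np.concatenate(qtimes),
        query_targets=np.concatenate(qtgt),
        episode_ids=eids,
    )


class Forecaster:
    """The assembled model with its parameters."""

    def __init__(self, config: ModelConfig,
                 probe_frequencies: np.ndarray | None = None):
        self.config = config
        spec = None if config.no_patching else config.patch_spec()
        self.spec = spec
        n_scales = 1 if config.no_patching else spec.n_scales
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        self.encoder = DualDomainEncoder(
            n_scales=n_scales, d_time_embed=config.d_time_embed,
            d_value=config.d_value, d_time=config.d_time,
            d_freq=config.d_freq, d_fused=config.d_fused,
            d_hidden=config.d_hidden, n_ifan_layers=config.n_ifan_layers,
            use_frequency=not config.no_frequency, rng=rng)
        self.scale_fusion = ScaleFusionParams(
            n_scales, config.d_fused, config.d_model, rng)
        self.transformer = TransformerEncoder(
            TransformerConfig(config.d_model, config.n_heads,
                              config.n_tf_layers, config.d_ff,
                              config.dropout), rng)
        d_fourier = 0 if config.no_frequency else config.d_fourier
        self.graph = GraphParams(config.d_model + d_fourier, config.d_model,
                                 config.d_graph, rng)
        d_p = int(np.ceil(config.d_freq / 4))
        self.head = PredictionHeadParams(
            config.d_model, d_p=d_p, d_pbar=config.d_freq - 2 * d_p,
            d_value=config.d_value, rng=rng)
        if config.no_frequency:
            probe_frequencies = None
        elif probe_frequencies is None:
            probe_frequencies = np.linspace(
                0.05, 0.5, config.d_fourier)  # generic hourly-vitals grid
        self.probe_frequencies = probe_frequencies
        self.loss_config = LossConfig(config.alpha)

    # -- parameters -----------------------------------------------------------
    def params(self) -> dict[str, Tensor]:
        out = {f"encoder.{k}": v for k, v in self.encoder.params().items()}
        out.update({f"scale_fusion.{k}": v
                    for k, v in self.scale_fusion.params().items()})
        if not self.config.no_transformer:
            out.update({f"transformer.{k}": v
                        for k, v in self.transformer.params().items()})
        if not self.config.no_graph:
            out.update({f"graph.{k}": v
                        for k, v in self.graph.params().items()})
        out.update({f"head.{k}": v for k, v in self.head.params().items()})
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params().values())

    # -- data preparation -----------------------------------------------------
    def prepare(self, episodes: list[IMTSEpisode]) -> list[EpisodePrep]:
        return [prepare_episode(ep, self.config, self.probe_frequencies)
                for ep in episodes]

    # -- forward --------------------------------------------------------------
    def forward_batch(self, batch: Batch,
                      rng: np.random.Generator | None = None,
                      return_graphs: bool = False):
        """Run the full pipeline on a collated batch.

        Returns a ForecastSet (and, optionally, the per-interval adjacency
        stack [B, P1, N, N]).  Pass ``rng`` to enable dropout (training
        mode); without it evaluation is fully deterministic.
        """
        cfg = self.config
        B = len(batch.preps)
        N, P1 = batch.n_variables, batch.n_canonical
        # 1. dual-domain patch encoding per scale (non-empty patches only,
        #    in length buckets; empty grid slots resolve to the learned
        #    per-scale token)
        per_scale = []
        for s, sb in enumerate(batch.scale_arrays):
            pieces = [self.encoder.encode_padded(v, t, m, s)
                      for v, t, m in sb.buckets]
            pieces.append(self.encoder.empty_tokens[s].reshape(
                1, cfg.d_fused))
            h = concat(pieces, axis=0)[sb.inverse_index]
            P_s = sb.n_slots // (B * N)
            per_scale.append(h.reshape(B, N, P_s, cfg.d_fused))
        # 2. canonical alignment + scale fusion
        if self.spec is not None:
            h_ms = align_to_canonical(per_scale, self.spec)
        else:
            h_ms = per_scale[0]
        m = fuse_scales(h_ms, self.scale_fusion)        # (B, N, P1, d_model)
        # 3. K blocks of intra-series and inter-series modeling
        adjacency = None
        for _ in range(cfg.n_blocks):
            if cfg.no_transformer:
                m_tilde = m
            else:
                flat = m.reshape(B * N, P1, cfg.d_model)
                m_tilde = self.transformer.forward(flat, rng=rng).reshape(
                    B, N, P1, cfg.d_model)
            if cfg.no_graph:
                m = m_tilde
            else:
                mt = m_tilde.transpose(0, 2, 1, 3)      # (B, P1, N, d)
                sp = None
                if batch.spectral is not None:
                    sp = np.transpose(batch.spectral, (0, 2, 1, 3))
                g = build_interval_graph(mt, sp, self.graph)
                adjacency = g.adjacency.data            # (B, P1, N, N)
                m = gcn_aggregate(g, mt, self.graph).transpose(0, 2, 1, 3)
        # 4. prediction from the last canonical interval
        contexts = m[:, :, P1 - 1, :]                   # (B, N, d_model)
        ctx_q = contexts[batch.query_episode, batch.query_var]
        z = head_features(ctx_q, batch.query_t_fut, self.head)
        yhat = (z @ self.head.W_out + self.head.b_out)[:, 0]
        forecasts = ForecastSet(
            predictions=yhat,
            targets=batch.query_targets,
            scored=~np.isnan(batch.query_targets),
            variable_index=batch.query_var,
            horizons=batch.query_horizons,
            query_times=batch.query_times,
            episode_ids=batch.episode_ids,
        )
        if return_graphs:
            return forecasts, adjacency
        return forecasts

    def forward_episode(self, episode: IMTSEpisode,
                        return_graphs: bool = False):
        """Convenience single-episode forward in evaluation mode."""
        batch = collate(self.prepare([episode]))
        return self.forward_batch(batch, rng=None,
                                  return_graphs=return_graphs)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write parameters (.npz) with the config embedded as JSON."""
        arrays = {k: p.data for k, p in self.params().items()}
        meta = {"config": self.config.to_dict(),
                "probe_frequencies":
                    None if self.probe_frequencies is None
                    else list(map(float, self.probe_frequencies))}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Forecaster":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            model = cls(ModelConfig.from_dict(meta["config"]),
                        None if meta["probe_frequencies"] is None
                        else np.array(meta["probe_frequencies"]))
            params = model.params()
            for k, p in params.items():
                p.data = data[k].copy()
        return model
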