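"""Dual-domain patch encoding: time-aware convolution + Fourier analysis.

Each non-empty patch is encoded twice and the two codes are fused:

* **Time branch (TTCN)** — every observation is augmented with a learnable
  continuous time embedding of its within-patch rescaled timestamp, a shared
  two-layer meta-network scores each augmented observation per output
  channel, the scores are softmax-normalized *over the observations* per
  feature channel, and the patch code is the filter-weighted sum.  Because
  the filter is generated from the data, the parameter count is independent
  of how many observations a patch happens to contain.

* **Frequency branch (IFAN)** — a stack of time-aware Fourier-analysis
  layers applied point-wise: each layer concatenates cos/sin of a
  value-and-time modulated linear map with a GELU-gated nonlinear branch,
  and the patch code is the mean over observations (hence permutation
  invariant).

* **Fusion** — concatenation followed by a linear projection.

Empty patches (inevitable at ICU-level missingness) are represented by a
learned per-scale embedding token instead of the encoder output.

All operations run on padded batches ``[n_patches, L_max, ...]`` with a
validity mask; a padded slot never influences any output.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, gelu, softmax, where

__all__ = [
    "TimeEmbeddingParams",
    "TTCNParams",
    "IFANParams",
    "FusionParams",
    "DualDomainEncoder",
    "time_embed",
    "ttcn_encode",
    "ifan_encode",
    "fuse_patch",
    "pad_patches",
]


def _init(rng: np.random.Generator, *shape: int, fan_in: int | None = None
          ) -> Tensor:
    fan = fan_in if fan_in is not None else (shape[-2] if len(shape) > 1
                                             else shape[0])
    return Tensor(rng.normal(0, 1.0 / np.sqrt(max(fan, 1)), shape),
                  requires_grad=True)


class TimeEmbeddingParams:
    """Learnable frequencies/phases of the continuous time embedding.

    Channel 0 is linear (omega_0 * t + alpha_0); channels d > 0 are
    sin(omega_d * t + alpha_d).  Initialized to the identity line plus
    integer harmonics of the unit patch interval.
    """

    def __init__(self, d_time_embed: int = 10):
        self.d_time_embed = d_time_embed
        omega = 2 * np.pi * np.arange(d_time_embed, dtype=float)
        omega[0] = 1.0
        self.omega = Tensor(omega, requires_grad=True)
        self.alpha = Tensor(np.zeros(d_time_embed), requires_grad=True)

    def params(self) -> dict[str, Tensor]:
        return {"omega": self.omega, "alpha": self.alpha}


def time_embed(t: np.ndarray, p: TimeEmbeddingParams) -> Tensor:
    """Embed rescaled times ``t`` (any shape) to shape ``t.shape + (D_t,)``."""
    tt = Tensor(np.asarray(t, dtype=float)[..., None])
    ang = tt * p.omega + p.alpha
    periodic_mask = np.arange(p.d_time_embed) > 0
    return where(periodic_mask, ang.sin(), ang)


class TTCNParams:
    """Shared two-layer meta-network generating per-observation filters."""

    def __init__(self, d_in: int, d_time: int, d_hidden: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.d_in, self.d_time, self.d_hidden = d_in, d_time, d_hidden
        self.W1 = _init(rng, d_time, d_in, d_hidden)       # per channel k
        self.b1 = Tensor(np.zeros((d_time, 1, 1, d_hidden)),
                         requires_grad=True)
        self.W2 = _init(rng, d_time, d_hidden, d_in)
        self.b2 = Tensor(np.zeros((d_time, 1, 1, d_in)), requires_grad=True)

    def params(self) -> dict[str, Tensor]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}


def ttcn_scores(z: Tensor, p: TTCNParams) -> Tensor:
    """Meta-network scores s_k[j] for a batch: [K, B, L, D_in].

    The per-channel first layers are fused into one wide GEMM
    (z @ [W_{1,1} ... W_{K,1}]) before splitting back per channel for the
    second layer — algebraically identical to applying each channel's
    two-layer MLP separately, but orders of magnitude faster than batching
    K tiny matrix products.
    """
    B, L, d_in = z.shape
    K, dh = p.d_time, p.d_hidden
    z2 = z.reshape(B * L, d_in)
    W1_wide = p.W1.transpose(1, 0, 2).reshape(d_in, K * dh)
    h = gelu(z2 @ W1_wide + p.b1.reshape(K * dh))        # (B*L, K*dh)
    h3 = h.reshape(B * L, K, dh).transpose(1, 0, 2)      # (K, B*L, dh)
    s = h3 @ p.W2 + p.b2.reshape(K, 1, d_in)             # (K, B*L, Din)
    return s.reshape(K, B, L, d_in)


def ttcn_filters(z: Tensor, valid: np.ndarray, p: TTCNParams) -> Tensor:
    """Softmax-normalized filters f_k[j, d]: sums to 1 over j per (k, d)."""
    s = ttcn_scores(z, p)
    return softmax(s, axis=2, mask=valid[None, :, :, None])


def ttcn_encode_batch(z: Tensor, valid: np.ndarray, p: TTCNParams) -> Tensor:
    """Batched TTCN patch codes: z [B, L, D_in] -> [B, D_time].

    ``valid`` marks real observations; padded slots receive ~0 filter weight
    and contribute zero because their z rows are zero-padded.
    """
    f = ttcn_filters(z, valid, p)                    # (K, B, L, Din)
    zz = z.reshape(1, *z.shape)
    h = (f * zz).sum(axis=(2, 3))                    # (K, B)
    return h.transpose(1, 0)


def ttcn_encode(rescaled_times: np.ndarray, values: np.ndarray,
                tp: TimeEmbeddingParams, p: TTCNParams) -> Tensor:
    """Single-patch TTCN code (non-empty patch): -> vector [D_time]."""
    L = len(rescaled_times)
    if L == 0:
        raise ValueError("TTCN is defined for non-empty patches only; "
                         "empty patches use the learned empty token")
    phi = time_embed(np.asarray(rescaled_times), tp)       # (L, Dt)
    v = Tensor(np.asarray(values, dtype=float).reshape(L, -1))
    z = concat([phi, v], axis=-1).reshape(1, L, -1)
    return ttcn_encode_batch(z, np.ones((1, L), dtype=bool), p)[0]


class IFANParams:
    """Stack of time-aware Fourier-analysis layers.

    Layer output dim is 2*d_p + d_pbar; layer 1 consumes the raw value
    (dimension d_value), deeper layers consume the previous output.
    """

    def __init__(self, d_value: int = 1, d_p: int = 8, d_pbar: int = 16,
                 n_layers: int = 2, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.d_p, self.d_pbar, self.n_layers = d_p, d_pbar, n_layers
        self.d_out = 2 * d_p + d_pbar
        self.layers: list[dict[str, Tensor]] = []
        d_in = d_value
        for _ in range(n_layers):
            # spread the timestamp frequencies over plausible within-patch
            # cycle counts at init: gradient descent adjusts frequencies far
            # too slowly to discover them from scratch
            up0 = 2 * np.pi * np.linspace(0.25, 4.0, d_p) \
                + rng.normal(0, 0.1, d_p)
            self.layers.append({
                "Wp": _init(rng, d_in, d_p),
                "Up": Tensor(up0, requires_grad=True),
                "Wpbar": _init(rng, d_in, d_pbar),
                "Vpbar": _init(rng, d_pbar, fan_in=1),
                "Bpbar": Tensor(np.zeros(d_pbar), requires_grad=True),
            })
            d_in = self.d_out

    def params(self) -> dict[str, Tensor]:
        out = {}
        for l, layer in enumerate(self.layers):
            for name, t in layer.items():
                out[f"layer{l}.{name}"] = t
        return out


def ifan_point_features(values: Tensor, t: Tensor, p: IFANParams) -> Tensor:
    """Apply the layer stack point-wise: [..., D_v] -> [..., 2*d_p+d_pbar].

    ``t`` must broadcast against the leading axes of ``values`` with a
    trailing singleton feature axis.
    """
    x = values
    lead = x.shape[:-1]
    n = int(np.prod(lead)) if lead else 1
    x = x.reshape(n, x.shape[-1])
    t2 = t.reshape(n, 1)
    for layer in p.layers:
        u = x @ layer["Wp"] + t2 * layer["Up"]
        g = gelu(layer["Bpbar"] + x @ layer["Wpbar"] + t2 * layer["Vpbar"])
        x = concat([u.cos(), u.sin(), g], axis=-1)
    return x.reshape(*lead, x.shape[-1])


def ifan_encode_batch(values: Tensor, t: np.ndarray, valid: np.ndarray,
                      p: IFANParams) -> Tensor:
    """Batched IFAN patch codes: values [B, L, D_v] -> [B, 2*d_p+d_pbar].

    Mean pooling runs over valid observations only; an all-invalid row
    yields zeros (replaced by the empty token downstream).
    """
    tt = Tensor(np.asarray(t, dtype=float)[..., None])
    x = ifan_point_features(values, tt, p)
    m = valid[..., None].astype(float)
    counts = np.maximum(valid.sum(axis=1, keepdims=True), 1).astype(float)
    return (x * m).sum(axis=1) / counts


def ifan_encode(rescaled_times: np.ndarray, values: np.ndarray,
                p: IFANParams) -> Tensor:
    """Single-patch IFAN code (non-empty patch): -> vector [2*d_p+d_pbar]."""
    L = len(rescaled_times)
    if L == 0:
        raise ValueError("IFAN is defined for non-empty patches only")
    v = Tensor(np.asarray(values, dtype=float).reshape(1, L, -1))
    t = np.asarray(rescaled_times, dtype=float).reshape(1, L)
    return ifan_encode_batch(v, t, np.ones((1, L), dtype=bool), p)[0]


class FusionParams:
    """Linear projection of the concatenated dual-domain code."""

    def __init__(self, d_time: int, d_freq: int, d_fused: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.d_fused = d_fused
        self.W = _init(rng, d_time + d_freq, d_fused)
        self.b = Tensor(np.zeros(d_fused), requires_grad=True)

    def params(self) -> dict[str, Tensor]:
        return {"W": self.W, "b": self.b}


def fuse_patch(h_time: Tensor, h_freq: Tensor | None,
               p: FusionParams) -> Tensor:
    """h = W [h_time || h_freq] + b, batched over leading axes."""
    h = h_time if h_freq is None else concat([h_time, h_freq], axis=-1)
    return h @ p.W + p.b


def pad_patches(patch_lists: list[list], d_value: int = 1
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad a nested list of patches to arrays.

    Returns ``(values [B, L, d_value], rescaled_times [B, L],
    valid [B, L])`` where B is the flattened patch count and L the longest
    patch (at least 1 so empty batches stay well-formed).
    """
    flat = [pch for row in patch_lists for pch in row]
    B = len(flat)
    L = max((len(p) for p in flat), default=0) or 1
    values = np.zeros((B, L, d_value))
    times = np.zeros((B, L))
    valid = np.zeros((B, L), dtype=bool)
    for b, pch in enumerate(flat):
        n = len(pch)
        if n:
            values[b, :n, 0] = pch.values
            times[b, :n] = pch.rescaled_times
            valid[b, :n] = True
    return values, times, valid


class DualDomainEncoder:
    """TTCN + IFAN + fusion with per-scale learned empty-patch tokens."""

    def __init__(self, n_scales: int, d_time_embed: int = 10,
                 d_value: int = 1, d_time: int = 32, d_freq: int = 32,
                 d_fused: int = 64, d_hidden: int = 32, n_ifan_layers: int = 2,
                 use_frequency: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        d_p = int(np.ceil(d_freq / 4))
        d_pbar = d_freq - 2 * d_p
        self.use_frequency = use_frequency
        self.time_embedding = TimeEmbeddingParams(d_time_embed)
        self.ttcn = TTCNParams(d_time_embed + d_value, d_time, d_hidden, rng)
        self.ifan = (IFANParams(d_value, d_p, d_pbar, n_ifan_layers, rng)
                     if use_frequency else None)
        d_freq_eff = self.ifan.d_out if use_frequency else 0
        self.fusion = FusionParams(d_time, d_freq_eff, d_fused, rng)
        self.empty_tokens = Tensor(
            rng.normal(0, 0.1, (n_scales, d_fused)), requires_grad=True)
        self.d_fused = d_fused
        self.d_value = d_value

    def params(self) -> dict[str, Tensor]:
        out = {f"time.{k}": v for k, v in self.time_embedding.params().items()}
        out.update({f"ttcn.{k}": v for k, v in self.ttcn.params().items()})
        if self.ifan is not None:
            out.update({f"ifan.{k}": v for k, v in self.ifan.params().items()})
        out.update({f"fusion.{k}": v for k, v in self.fusion.params().items()})
        out["empty_tokens"] = self.empty_tokens
        return out

    def encode_padded(self, values: np.ndarray, times: np.ndarray,
                      valid: np.ndarray, scale_index: int) -> Tensor:
        """Encode padded patch arrays -> [B, d_fused] with empty-token fill."""
        phi = time_embed(times, self.time_embedding)        # (B, L, Dt)
        v = Tensor(values)
        z = concat([phi, v], axis=-1)
        h_time = ttcn_encode_batch(z, valid, self.ttcn)
        h_freq = (ifan_encode_batch(v, times, valid, self.ifan)
                  if self.use_frequency else None)
        h = fuse_patch(h_time, h_freq, self.fusion)
        nonempty = valid.any(axis=1)[:, None]
        return where(nonempty, h, self.empty_tokens[scale_index])
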