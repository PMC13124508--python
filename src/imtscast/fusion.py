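"""Scale alignment, per-interval scale fusion, and temporal contextualization.

Patch embeddings from all S scales are aligned onto the canonical timeline
defined by the finest scale: canonical interval k (1-based) takes, from each
scale s, the unique patch p = ceil(k * L_1 / L_s) whose span covers it, so a
coarse patch is replicated across every canonical interval it covers.  The
S aligned embeddings are concatenated and projected with a GELU to one token
per (variable, canonical interval), and each variable's token sequence is
contextualized independently by a standard pre-norm transformer encoder with
fixed sinusoidal positional encodings.  Cross-variable information flow is
deliberately absent here; it happens only in the dynamic-graph stage.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, gelu, layer_norm, softmax
from .patching import PatchSpec, canonical_representative

__all__ = [
    "ScaleFusionParams",
    "alignment_indices",
    "align_to_canonical",
    "fuse_scales",
    "TransformerConfig",
    "TransformerEncoder",
    "sinusoidal_positions",
]


class ScaleFusionParams:
    """Linear + GELU projection of the S concatenated scale embeddings."""

    def __init__(self, n_scales: int, d_fused: int, d_model: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.d_model = d_model
        self.W = Tensor(rng.normal(0, 1 / np.sqrt(n_scales * d_fused),
                                   (n_scales * d_fused, d_model)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_model), requires_grad=True)

    def params(self) -> dict[str, Tensor]:
        return {"W": self.W, "b": self.b}


def alignment_indices(spec: PatchSpec) -> list[np.ndarray]:
    """Per scale: 0-based patch index covering each canonical interval."""
    P1 = spec.n_canonical
    return [np.array([canonical_representative(k, s, spec) - 1
                      for k in range(1, P1 + 1)], dtype=int)
            for s in range(spec.n_scales)]


def align_to_canonical(per_scale: list[Tensor], spec: PatchSpec) -> Tensor:
    """Replicate and concatenate scale embeddings on the canonical timeline.

    ``per_scale[s]`` has shape [..., P_s, d_fused]; the result is
    [..., P_1, S * d_fused] with scales concatenated in ascending order.
    """
    idx = alignment_indices(spec)
    picked = []
    for s, h in enumerate(per_scale):
        sl = (slice(None),) * (h.ndim - 2) + (idx[s], slice(None))
        picked.append(h[sl])
    return concat(picked, axis=-1)


def fuse_scales(h_ms_concat: Tensor, p: ScaleFusionParams) -> Tensor:
    """m = GELU(W h + b): [..., S*d_fused] -> [..., d_model]."""
    return gelu(h_ms_concat @ p.W + p.b)


def sinusoidal_positions(n_positions: int, d_model: int) -> np.ndarray:
    """Fixed sine/cosine positional table (deterministic, no parameters)."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


class TransformerConfig:
    def __init__(self, d_model: int = 64, n_heads: int = 1,
                 n_layers: int = 1, d_ff: int | None = None,
                 dropout: float = 0.1):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff if d_ff is not None else 4 * d_model
        self.dropout = dropout


def _dropout(x: Tensor, rate: float,
             rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(float) / (1.0 - rate)
    return x * Tensor(keep)


class TransformerEncoder:
    """Pre-norm encoder stack applied per variable over canonical intervals."""

    def __init__(self, config: TransformerConfig,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        d, ff = config.d_model, config.d_ff
        s = 1 / np.sqrt(d)
        self.layers = []
        for _ in range(config.n_layers):
            self.layers.append({
                "Wq": Tensor(rng.normal(0, s, (d, d)), requires_grad=True),
                "Wk": Tensor(rng.normal(0, s, (d, d)), requires_grad=True),
                "Wv": Tensor(rng.normal(0, s, (d, d)), requires_grad=True),
                "Wo": Tensor(rng.normal(0, s, (d, d)), requires_grad=True),
                "ln1_g": Tensor(np.ones(d), requires_grad=True),
                "ln1_b": Tensor(np.zeros(d), requires_grad=True),
                "W_ff1": Tensor(rng.normal(0, s, (d, ff)),
                                requires_grad=True),
                "b_ff1": Tensor(np.zeros(ff), requires_grad=True),
                "W_ff2": Tensor(rng.normal(0, 1 / np.sqrt(ff), (ff, d)),
                                requires_grad=True),
                "b_ff2": Tensor(np.zeros(d), requires_grad=True),
                "ln2_g": Tensor(np.ones(d), requires_grad=True),
                "ln2_b": Tensor(np.zeros(d), requires_grad=True),
            })
        self.last_attention: np.ndarray | None = None

    def params(self) -> dict[str, Tensor]:
        out = {}
        for l, layer in enumerate(self.layers):
            for name, t in layer.items():
                out[f"layer{l}.{name}"] = t
        return out

    def _attend(self, x: Tensor, layer: dict[str, Tensor]) -> Tensor:
        cfg = self.config
        B, P, D = x.shape
        H, dh = cfg.n_heads, cfg.d_model // cfg.n_heads
        q = (x @ layer["Wq"]).reshape(B, P, H, dh).transpose(0, 2, 1, 3)
        k = (x @ layer["Wk"]).reshape(B, P, H, dh).transpose(0, 2, 1, 3)
        v = (x @ layer["Wv"]).reshape(B, P, H, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1)          # rows sum to 1
        self.last_attention = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, P, D)
        return out @ layer["Wo"]

    def forward(self, x: Tensor, rng: np.random.Generator | None = None
                ) -> Tensor:
        """Contextualize token sequences x [B, P, d_model].

        Positional encodings are added here; pass ``rng`` to enable dropout
        (training mode), omit it for deterministic evaluation.
        """
        cfg = self.config
        pe = sinusoidal_positions(x.shape[-2], cfg.d_model)
        x = x + Tensor(pe)
        for layer in self.layers:
            h = layer_norm(x, layer["ln1_g"], layer["ln1_b"])
            x = x + _dropout(self._attend(h, layer), cfg.dropout, rng)
            h = layer_norm(x, layer["ln2_g"], layer["ln2_b"])
            h = gelu(h @ layer["W_ff1"] + layer["b_ff1"]) @ layer["W_ff2"] \
                + layer["b_ff2"]
            x = x + _dropout(h, cfg.dropout, rng)
        return x
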