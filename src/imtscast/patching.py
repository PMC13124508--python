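"""Multi-scale temporal patching of irregular series.

Each univariate irregular series is partitioned into non-overlapping patches
at S duration scales L_1 < ... < L_S (hours).  At scale s the window [0, T)
splits into P_s = floor(T / L_s) half-open intervals [(p-1)L_s, pL_s); a
patch holds every observation of one variable falling in one interval.
Patches with equal interval index share the exact same span across
variables, which is what gives the downstream modules patch-level temporal
alignment without interpolation.

Boundary closure: an observation exactly at t = T belongs to the history, so
the final patch at every scale is closed on the right.  Its rescaled
within-patch time is clamped to 1 - 1e-9 to preserve the [0, 1) contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import IMTSEpisode

__all__ = ["PatchSpec", "Patch", "PatchGrid", "build_patch_grid",
           "rescale_times", "canonical_representative", "DEFAULT_SCALES"]

DEFAULT_SCALES = (1.0, 2.0, 4.0, 8.0, 24.0)

_BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class PatchSpec:
    """Scale set and observation-window end defining the patch layout."""

    scales: tuple[float, ...] = DEFAULT_SCALES
    window_end: float = 24.0

    def __post_init__(self):
        if not self.scales:
            raise ValueError("need at least one scale")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be strictly increasing")
        L1 = self.scales[0]
        for L in self.scales:
            if abs(L / L1 - round(L / L1)) > 1e-9:
                raise ValueError(
                    f"every scale must be an integer multiple of the finest "
                    f"scale {L1}; got {L}")
        LS = self.scales[-1]
        if abs(self.window_end / LS - round(self.window_end / LS)) > 1e-9:
            raise ValueError(
                f"window end {self.window_end} must be an integer multiple "
                f"of the coarsest scale {LS}")

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def n_patches(self, s: int) -> int:
        """P_s = floor(T / L_s) for scale index s (0-based)."""
        return int(np.floor(self.window_end / self.scales[s] + 1e-9))

    @property
    def n_canonical(self) -> int:
        """Number of canonical (finest-scale) intervals P_1."""
        return self.n_patches(0)


@dataclass(frozen=True)
class Patch:
    """Observations of one variable in one interval of one scale."""

    variable: int          # position in the episode's series list
    scale_index: int
    interval_index: int    # p, 1-based as in the interval arithmetic
    span: tuple[float, float]
    times: np.ndarray      # original timestamps
    values: np.ndarray
    rescaled_times: np.ndarray  # within-patch times in [0, 1)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def is_empty(self) -> bool:
        return len(self.times) == 0


class PatchGrid:
    """All patches of one episode, indexed (variable, scale, interval)."""

    def __init__(self, spec: PatchSpec, patches: dict[tuple[int, int, int],
                                                      Patch],
                 n_variables: int):
        self.spec = spec
        self._patches = patches
        self.n_variables = n_variables

    def patch(self, variable: int, scale: int, interval: int) -> Patch:
        """Look up a patch; ``interval`` is 1-based like the index p."""
        return self._patches[(variable, scale, interval)]

    def patches_at_scale(self, scale: int) -> list[list[Patch]]:
        """Per-variable list of the P_s patches at one scale, in order."""
        return [[self.patch(i, scale, p + 1)
                 for p in range(self.spec.n_patches(scale))]
                for i in range(self.n_variables)]

    def dump_json(self, path: str | Path) -> None:
        """Debug dump of spans and counts (no values)."""
        out = [{"variable": k[0], "scale": k[1], "interval": k[2],
                "span": list(v.span), "count": len(v)}
               for k, v in sorted(self._patches.items())]
        Path(path).write_text(json.dumps(out, indent=1))


def rescale_times(times: np.ndarray, span: tuple[float, float]
                  ) -> np.ndarray:
    """Linearly map timestamps in ``span`` to [0, 1).

    The right edge only occurs for the boundary-closed final patch; it is
    clamped just below 1 so the within-patch time stays in [0, 1).
    """
    lo, hi = span
    t = (np.asarray(times, dtype=float) - lo) / (hi - lo)
    return np.minimum(t, 1.0 - _BOUNDARY_EPS)


def build_patch_grid(episode: IMTSEpisode, spec: PatchSpec) -> PatchGrid:
    """Assign every observation with t <= T to exactly one patch per scale."""
    patches: dict[tuple[int, int, int], Patch] = {}
    T = spec.window_end
    for i, series in enumerate(episode.series):
        times = series.times
        values = series.values
        in_window = times <= T + 1e-12
        times, values = times[in_window], values[in_window]
        for s, L in enumerate(spec.scales):
            P = spec.n_patches(s)
            # half-open assignment, final patch closed at T
            idx = np.floor(times / L).astype(int)
            idx = np.minimum(idx, P - 1)
            for p in range(1, P + 1):
                mask = idx == p - 1
                span = ((p - 1) * L, p * L)
                tt = times[mask]
                patches[(i, s, p)] = Patch(
                    variable=i, scale_index=s, interval_index=p,
                    span=span, times=tt, values=values[mask],
                    rescaled_times=rescale_times(tt, span))
    return PatchGrid(spec, patches, episode.n_variables)


def canonical_representative(k: int, scale_index: int,
                             spec: PatchSpec) -> int:
    """Scale-s patch index p whose span covers canonical interval k.

    Both k and the result are 1-based: p = ceil(k * L_1 / L_s).
    """
    L1, Ls = spec.scales[0], spec.scales[scale_index]
    return int(np.ceil(k * L1 / Ls - 1e-9))
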