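"""Small shared helpers: seeded substreams and the synthetic channel layout."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "circular_layout", "smooth_field"]


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return an independent named random substream derived from a master seed.

    Substreams are keyed by name (via CRC32), so adding a new consumer of
    randomness never perturbs the draws of an existing one, and the same
    (seed, names) always yields the same stream.
    """
    keys = [zlib.crc32(n.encode("utf-8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


def circular_layout(n_channels: int, radius: float = 1.0) -> np.ndarray:
    """Synthetic 2-D electrode layout: channels equally spaced on a circle.

    Real electrode geometry is not needed for testing the pipeline; a circle
    provides well-defined neighbour distances for smoothing and interpolation.
    """
    theta = 2.0 * np.pi * np.arange(n_channels) / n_channels
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])


def smooth_field(rng: np.random.Generator, n_channels: int, smoothness: int,
                 size: tuple[int, ...] | int = ()) -> np.ndarray:
    """Draw unit-variance spatially correlated random fields over channels.

    White noise indexed by channel position on a circular layout is smoothed
    with a circular moving average of width ``smoothness`` and rescaled by
    sqrt(smoothness) so the marginal variance stays exactly 1.  smoothness <= 1
    returns plain white noise. The channel axis is last.
    """
    if isinstance(size, int):
        size = (size,)
    shape = tuple(size) + (n_channels,)
    z = rng.standard_normal(shape)
    m = int(smoothness)
    if m <= 1:
        return z
    if m > n_channels:
        raise ValueError("smoothness cannot exceed the number of channels")
    # circular moving average over the channel axis
    idx = (np.arange(n_channels)[:, None] + np.arange(m)[None, :]) % n_channels
    out = z[..., idx].mean(axis=-1) * np.sqrt(m)
    return out
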