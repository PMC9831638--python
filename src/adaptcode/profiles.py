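"""Problem-size profiles.

``FULL`` mirrors the full-scale study conditions (32x32 patches reduced
to 512 PCA dimensions, 512 neurons, 32 belief bins / 5x5 position grid,
10^4 or 10^3 training images per belief point).  ``SCALED`` is the
default working profile for tests and examples: the same pipeline at
16x16 / 128 dimensions / 128 neurons with 8 bins, a 3x3 grid, and 300
Monte-Carlo samples per belief point, which preserves every qualitative
property at a fraction of the runtime.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Profile:
    W: int
    d: int
    N: int
    k_bins: int
    grid_side: int
    n_mc_binary: int
    n_mc_localization: int
    corpus_size: int


SCALED = Profile(
    W=16, d=128, N=128, k_bins=8, grid_side=3,
    n_mc_binary=300, n_mc_localization=300, corpus_size=4000,
)

FULL = Profile(
    W=32, d=512, N=512, k_bins=32, grid_side=5,
    n_mc_binary=10_000, n_mc_localization=1_000, corpus_size=50_000,
)
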