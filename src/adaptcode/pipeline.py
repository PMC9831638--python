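"""End-to-end model construction helpers.

Convenience wrappers that chain the standard steps — draw a patch corpus,
PCA-reduce it, learn the sparse dictionary — at a given problem-size
profile, so tests, scripts, and the CLI share one seeded build path.
"""

from __future__ import annotations

import numpy as np

from .profiles import SCALED, Profile
from .sparse import Dictionary, SparseConfig, attach_pca, learn_dictionary
from .stimuli import generate_patches, preprocess_corpus


def build_model(
    profile: Profile = SCALED,
    seed: int = 0,
    epochs: int = 12,
    corpus_size: int | None = None,
    lam: float = 1.0,
    sigma2: float = 0.5,
    spectral_exponent: float = 2.0,
    patch_kind: str = "dead_leaves",
) -> tuple[Dictionary, np.ndarray]:
    """Learn a dictionary on a fresh synthetic corpus.

    The default corpus is the dead-leaves (occluding disks) family: its
    edge structure is what gives the learned features spatial
    localization and orientation, which the spatial-attention analyses
    rely on.  Returns the dictionary (with PCA map attached) and the
    corpus images, which downstream task builders reuse (e.g. the
    orientation-category discovery).  Deterministic given ``seed``.
    """
    n = corpus_size or profile.corpus_size
    images = generate_patches(n, profile.W, spectral_exponent, seed, kind=patch_kind)
    pmap, coords = preprocess_corpus(images, profile.d)
    cfg = SparseConfig(lam=lam, sigma2=sigma2)
    dct, trace = learn_dictionary(coords, profile.N, cfg, epochs=epochs, seed=seed + 1)
    dct = attach_pca(dct, pmap)
    dct.meta["energy_trace"] = trace
    return dct, images
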