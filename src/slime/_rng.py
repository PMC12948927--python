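"""Deterministic seed derivation.

All randomness in the package flows through one root integer seed. Child
generators are derived from stable string labels (experiment ids, pair
labels, stage names) hashed with CRC32, so adding an experiment or a pair
never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed_sequence"]


def child_seed_sequence(root_seed: int, *labels: object) -> np.random.SeedSequence:
    """SeedSequence keyed by ``root_seed`` and a stable hash of ``labels``."""
    key = tuple(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)
    return np.random.SeedSequence(int(root_seed), spawn_key=key)


def child_rng(root_seed: int, *labels: object) -> np.random.Generator:
    """Generator seeded independently per label path (label-hashed children)."""
    return np.random.default_rng(child_seed_sequence(root_seed, *labels))
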