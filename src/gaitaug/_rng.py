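"""Deterministic seed fan-out.

A single master seed is expanded into independent named substreams
(cohort generation, fold shuffling, per-window augmentation, model
initialisation, ...) so that changing how one stage consumes randomness
never perturbs another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) % (2**32)
    return zlib.crc32(str(key).encode("utf-8"))


def substream(master_seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys``.

    The same (master_seed, keys) always yields the same stream; distinct
    key tuples yield statistically independent streams (SeedSequence).
    """
    entropy = [int(master_seed) % (2**32)] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(master_seed: int, *keys: object) -> int:
    """A 31-bit integer seed derived from the named substream."""
    return int(substream(master_seed, *keys).integers(0, 2**31))
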