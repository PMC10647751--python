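"""Deterministic seed fan-out.

A single master seed drives every random component of an experiment grid
(fold shuffles, hyperparameter search, forest bootstraps, oracle noise).
Sub-seeds are derived from the master seed plus a string/integer path so
that each component gets an independent, reproducible stream and adding a
new component never shifts the seeds of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def derive(seed: int, *path: str | int) -> int:
    """Derive a sub-seed (< 2**31) from ``seed`` and a component path.

    Deterministic across processes and platforms: the path is hashed with
    CRC32 (stable, unlike Python's ``hash``) and fed to a SeedSequence.
    """
    tokens = [int(seed) & _MOD]
    for p in path:
        if isinstance(p, int):
            tokens.append(p & _MOD)
        else:
            tokens.append(zlib.crc32(str(p).encode()) & _MOD)
    return int(np.random.SeedSequence(tokens).generate_state(1)[0] % _MOD)


def rng_for(seed: int, *path: str | int) -> np.random.Generator:
    """A numpy Generator seeded from :func:`derive`."""
    return np.random.default_rng(derive(seed, *path))
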