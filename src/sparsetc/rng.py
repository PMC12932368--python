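"""Hierarchical random-number streams.

Every stochastic stage of the simulator draws from its own child stream of a
single root seed, keyed by a stable string path such as ``("rep3", "genome")``.
Changing how one stage consumes randomness therefore never perturbs the draws
seen by any other stage, and the whole experiment is reproducible from one
integer.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng", "derive_int", "msprime_seed"]


def _key_to_ints(key: tuple[str | int, ...]) -> tuple[int, ...]:
    out = []
    for part in key:
        if isinstance(part, (int, np.integer)):
            out.append(int(part) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(part).encode()))
    return tuple(out)


def child_seed(root_seed: int, *key: str | int) -> np.random.SeedSequence:
    """Seed sequence for the stage identified by ``key`` under ``root_seed``."""
    return np.random.SeedSequence(int(root_seed), spawn_key=_key_to_ints(tuple(key)))


def child_rng(root_seed: int, *key: str | int) -> np.random.Generator:
    """Generator for the stage identified by ``key`` under ``root_seed``."""
    return np.random.default_rng(child_seed(root_seed, *key))


def derive_int(root_seed: int, *key: str | int) -> int:
    """A 31-bit integer seed for the stage identified by ``key``."""
    return int(child_seed(root_seed, *key).generate_state(1)[0] % (2**31))


def msprime_seed(root_seed: int, *key: str | int) -> int:
    """A strictly positive 31-bit integer seed derived from a stream key."""
    state = child_seed(root_seed, *key).generate_state(1)[0]
    return int(state % (2**31 - 2)) + 1
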