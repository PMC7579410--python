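"""Counter-based seed splitting.

Every stochastic operation in the package derives its generator from a single
user seed plus a tuple of string/int keys identifying the sub-stream.  Streams
are independent of one another and of how many other streams exist, so adding
proteins (or peptides, or fish) to a simulation never perturbs the draws made
for existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _key_to_int(key: object) -> int:
    digest = hashlib.blake2b(repr(key).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big")


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """A Generator for the sub-stream identified by ``keys`` under ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key_to_int(k) for k in keys))
    return np.random.default_rng(ss)


def child_seed(seed: int, *keys: object) -> int:
    """A 31-bit integer seed for libraries that take plain ints."""
    return int(child_rng(seed, *keys).integers(0, 2**31 - 1))
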