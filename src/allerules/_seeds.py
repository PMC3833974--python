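"""Named substreams from a single master seed.

Every stochastic stage of the pipeline draws from a generator keyed by the
master seed plus a tuple of names/indices, so stages are independently
reproducible: re-running one stage with the same seed gives the same stream
regardless of what ran before it.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _key_word(part: object) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    digest = hashlib.blake2s(str(part).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def seed_sequence(seed: int, *names: object) -> np.random.SeedSequence:
    """SeedSequence for the substream identified by ``names``."""
    return np.random.SeedSequence(int(seed), spawn_key=tuple(_key_word(n) for n in names))


def substream(seed: int, *names: object) -> np.random.Generator:
    """A fresh Generator for the substream identified by ``names``."""
    return np.random.default_rng(seed_sequence(seed, *names))
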