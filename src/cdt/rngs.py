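"""Named, reproducible random streams derived from one master seed.

Every stochastic operation in the package draws from a stream obtained
here, so adding a new task or component never perturbs existing streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(master_seed: int, *names) -> np.random.Generator:
    """Generator for the child stream identified by `names`.

    The same (master_seed, names) pair always yields an identically
    seeded generator; distinct name tuples yield independent streams.
    """
    key = tuple(zlib.crc32(str(n).encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(master_seed), spawn_key=key))
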