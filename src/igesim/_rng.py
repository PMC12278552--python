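"""Named, independent random-number streams.

Every stochastic component of a replicate (pedigree, breeding values,
environment, herd effects, network topology, contact intensities,
measurement noise, trace probes) draws from its own generator, spawned
from a single replicate seed.  Turning a feature off (e.g. intensities)
therefore never perturbs the draws of the other components.
"""

from __future__ import annotations

import numpy as np

#: Fixed stream order; append only, never reorder.
STREAMS = (
    "pedigree",
    "breeding_values",
    "environment",
    "herd",
    "network",
    "intensity",
    "noise",
    "probes",
)


def rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """Spawn one independent :class:`numpy.random.Generator` per named stream."""
    children = np.random.SeedSequence(seed).spawn(len(STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(STREAMS, children)}


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Derive a per-replicate seed below 2**31 from a base seed."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(replicate,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
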