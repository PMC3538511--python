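"""Hierarchical random-number streams.

A single global integer seed is split into independent per-stage streams via
:class:`numpy.random.SeedSequence` spawn keys, so any pipeline stage can be
re-run in isolation and still reproduce its draws bit-for-bit.
"""

from __future__ import annotations

import numpy as np

# Fixed stage indices: changing these changes every downstream draw.
STREAMS = {
    "panel": 0,
    "sample": 1,
    "exposure": 2,
    "noise": 3,
    "gender": 4,
    "status": 5,
    "subsample": 6,
}


def rng_for(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Return the generator for one named sub-stream of a global seed.

    ``index`` distinguishes parallel draws inside a stage (noise variables,
    subsample replicates).
    """
    if stream not in STREAMS:
        raise KeyError(f"unknown RNG stream {stream!r}")
    ss = np.random.SeedSequence(int(seed), spawn_key=(STREAMS[stream], int(index)))
    return np.random.Generator(np.random.PCG64(ss))
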