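"""Named, independent random-number streams.

A single run seed is fanned out into one substream per source of randomness
(substrate wiring, background-proximity noise, degree preferences, initial
dispositions, interaction sampling, behaviour switching, forcing noise,
bootstrap resampling).  Keeping the streams separate lets partial-model
variants that share a run index consume *identical* substrate, background
proximity and disposition-forcing realisations while their dynamics diverge.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np


class Stream(IntEnum):
    SUBSTRATE = 0
    BACKGROUND = 1
    DEGREE_PREFERENCE = 2
    DISPOSITION = 3
    INTERACTION = 4
    SWITCHING = 5
    FORCING = 6
    BOOTSTRAP = 7


def stream_rng(seed: int, stream: Stream) -> np.random.Generator:
    """Generator for the named substream of ``seed``."""
    ss = np.random.SeedSequence(seed, spawn_key=(int(stream),))
    return np.random.Generator(np.random.PCG64(ss))


def stream_seed(seed: int, stream: Stream) -> int:
    """31-bit integer seed for libraries that take plain ints (networkx)."""
    ss = np.random.SeedSequence(seed, spawn_key=(int(stream),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
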