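"""Shared helpers: seed handling and validation."""

from __future__ import annotations

import numpy as np

# Named sub-streams of the global seed, so each synthetic stream is
# independently reproducible.  sub-seed = SeedSequence(seed, spawn_key=(k,)).
_STREAMS = {
    "accel": 0,
    "depth": 1,
    "diel": 2,
    "track": 3,
    "labels": 4,
    "classifier": 5,
    "zib": 6,
}


def spawn_rng(seed: int, stream: str | int = 0) -> np.random.Generator:
    """Derive a reproducible per-stream generator from one global seed."""
    key = _STREAMS[stream] if isinstance(stream, str) else int(stream)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def spawn_int(seed: int, stream: str | int = 0) -> int:
    """A derived 31-bit integer seed (safe to hand to sklearn)."""
    return int(spawn_rng(seed, stream).integers(0, 2**31 - 1))


def check_positive(value, name: str):
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value!r}")
    return value
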