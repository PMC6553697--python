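"""Deterministic seed derivation.

A single master seed expands into independent per-trial, per-stream,
per-pass substreams through :class:`numpy.random.SeedSequence` spawn keys.
Any single trial of a large experiment can therefore be regenerated in
isolation from ``(master_seed, condition_index, repetition, role, pass)``
without running everything that preceded it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "child_rng"]

#: role tags used by the experiment layer; kept stable so that published
#: run manifests remain reproducible across versions.
ROLES = {
    "external_left": 0,
    "external_right": 1,
    "internal_left": 2,
    "internal_right": 3,
    "internal_shared": 4,
}


def child_seed(master_seed: int, *key: int) -> int:
    """Derive a 31-bit integer seed from a master seed and an index key.

    The mapping is a pure function of ``(master_seed, key)``: equal inputs
    give equal outputs, and distinct keys give statistically independent
    streams (SeedSequence spawn-key semantics).
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the derived substream."""
    return np.random.default_rng(child_seed(master_seed, *key))
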