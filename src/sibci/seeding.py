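"""Deterministic seed fan-out.

A single global seed must drive every stochastic stage (session plan,
signal synthesis, fold shuffling, permutations, random trial removal)
without any two stages sharing a stream.  Seeds are derived by hashing
the global seed together with a tuple of string/int tags identifying the
stage, so adding a participant or scenario never perturbs the streams of
the others.
"""

from __future__ import annotations

import hashlib


def derive_seed(global_seed: int, *tags: object) -> int:
    """Derive a sub-stream seed < 2**31 from a global seed and stage tags.

    Stable across platforms and Python versions (SHA-256 of the decimal
    seed and repr of each tag, joined with '/').
    """
    key = "/".join([str(int(global_seed))] + [repr(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
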