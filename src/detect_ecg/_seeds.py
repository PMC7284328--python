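"""Deterministic seed derivation.

One run-level seed drives every random stage (cohort synthesis, window
augmentation, train/test split, forest construction).  Each stage derives its
own sub-seed from the run seed plus a stable string tag, so a stage can be
re-run in isolation and per-subject draws do not depend on cohort ordering.
"""

import hashlib

_MOD = 2**31


def derive_seed(seed: int, *tags) -> int:
    """Map (seed, tags...) to a stable 31-bit sub-seed.

    The mapping is a SHA-256 hash of the textual concatenation, so it is
    independent of Python's randomized ``hash()`` and identical across
    platforms and processes.
    """
    key = "|".join([str(int(seed)), *map(str, tags)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") % _MOD
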