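"""Deterministic seed derivation.

A single master seed drives every stochastic stage. Stage seeds are derived by
hashing ``"<master>/<label>/<label>/..."`` with SHA-256 and taking the first
four bytes, so adding a new stage never perturbs the seeds of existing ones
(unlike positional ``SeedSequence.spawn`` chains). Derived seeds are always in
``[0, 2**31 - 2]`` and therefore safe for every scikit-learn / xgboost
``random_state`` argument.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *labels: object) -> int:
    """Derive a stage seed from a master seed and a label path.

    Parameters
    ----------
    master
        Master seed (any Python int).
    *labels
        Arbitrary hashable path components naming the stage, e.g.
        ``derive_seed(seed, "cv", repeat, fold)``.
    """
    key = "/".join([str(master), *map(str, labels)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)
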