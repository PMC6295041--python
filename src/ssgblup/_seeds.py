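"""Deterministic seed derivation.

Every stochastic stage draws its seed from a single master seed combined
with a stage label, so replicates are mutually independent but every run
is exactly reproducible from one integer.
"""

import hashlib


def derive_seed(master_seed: int, *labels) -> int:
    """Derive a child seed (< 2**31) from a master seed and stage labels."""
    key = ":".join([str(int(master_seed))] + [str(l) for l in labels])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31)
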