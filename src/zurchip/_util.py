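"""Small shared helpers: circular-coordinate arithmetic and sequence ops."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def circ_signed_delta(pos, ref, length=None):
    """Signed displacement pos - ref, wrapped to (-length/2, length/2] if circular."""
    d = np.asarray(pos) - ref
    if length is None:
        return d
    d = np.mod(d, length)
    return np.where(d > length / 2, d - length, d)


def circ_distance(pos, ref, length=None):
    """Unsigned distance between coordinates, around the circle if a length is given."""
    d = np.abs(np.asarray(pos) - ref)
    if length is None:
        return d
    d = np.mod(d, length)
    return np.minimum(d, length - d)
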