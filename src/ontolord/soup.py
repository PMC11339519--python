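"""Phase 3 — uniform "model soup" weight averaging.

Several students distilled with different projection-head seeds end up as
slightly different models; averaging their parameters elementwise yields a
single model that is typically at least as good as the best member, at no
inference cost.  Only the uniform soup is implemented (no greedy member
selection), and projection heads are excluded — they are seed-specific and
already discarded at export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import HashingNgramEncoder
from .exceptions import IncompatibilityError


@dataclass
class ParameterSnapshot:
    arrays: dict[str, np.ndarray]
    architecture_tag: str


def snapshot_from_encoder(enc) -> ParameterSnapshot:
    return ParameterSnapshot(
        {k: np.array(v, copy=True) for k, v in enc.parameters().items()},
        enc.architecture_tag,
    )


def soup_average(
    snapshots: list[ParameterSnapshot],
    exclude: tuple[str, ...] = (),
) -> ParameterSnapshot:
    """Elementwise uniform mean of shape-compatible snapshots.

    Array names prefixed by anything in ``exclude`` are dropped from the soup.
    Mismatched names, shapes, or architecture tags raise
    :class:`IncompatibilityError` naming the offending array.
    """
    if not snapshots:
        raise IncompatibilityError("need at least one snapshot")
    first = snapshots[0]
    keep = [k for k in first.arrays if not any(k.startswith(p) for p in exclude)]
    for snap in snapshots[1:]:
        if snap.architecture_tag != first.architecture_tag:
            raise IncompatibilityError(
                f"architecture tags differ: {snap.architecture_tag!r} vs {first.architecture_tag!r}"
            )
        snap_keys = {k for k in snap.arrays if not any(k.startswith(p) for p in exclude)}
        if snap_keys != set(keep):
            raise IncompatibilityError(f"array names differ: {sorted(snap_keys ^ set(keep))}")
        for k in keep:
            if snap.arrays[k].shape != first.arrays[k].shape:
                raise IncompatibilityError(f"shape mismatch for array {k!r}")
    # mean as anchor + mean of differences: exact when all members coincide
    averaged = {}
    for k in keep:
        anchor = first.arrays[k]
        deltas = np.stack([snap.arrays[k] - anchor for snap in snapshots])
        averaged[k] = anchor + deltas.mean(axis=0)
    return ParameterSnapshot(averaged, first.architecture_tag)


def soup_encoders(encoders: list[HashingNgramEncoder]) -> HashingNgramEncoder:
    """Convenience: average trained reference encoders into a new encoder."""
    snap = soup_average([snapshot_from_encoder(e) for e in encoders])
    souped = encoders[0].copy()
    souped.set_parameters(snap.arrays)
    return souped
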