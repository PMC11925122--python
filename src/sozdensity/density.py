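"""HD -> LD electrode decimation, the core experimental manipulation.

Lower-density (LD) recordings are made from higher-density (HD) hardware by
dropping contacts, never by interpolating: grids lose every other row and
column (4 mm -> 8 mm spacing) and depth probes every other contact
(5 mm -> 10 mm). The retained LD contact set is always a strict subset of
the HD set, which is what later guarantees pointwise heatmap dominance of
the HD condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import ArrayKind, ElectrodeArray, GeometryError
from .preprocess import PreprocessError, Recording

__all__ = [
    "DensityCondition",
    "subsample_grid",
    "subsample_linear",
    "subsample_array",
    "subsample_recording",
]


@dataclass(frozen=True)
class DensityCondition:
    """Which contacts of a parent HD array a condition retains."""

    label: str  # "HD" | "LD"
    parent_array_id: str
    retained_contact_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.retained_contact_indices))
        if not idx:
            raise GeometryError("retained contact set must be nonempty")
        object.__setattr__(self, "retained_contact_indices", idx)


def subsample_grid(
    arr: ElectrodeArray, anchor: int = 0
) -> tuple[ElectrodeArray, DensityCondition]:
    """Omit every other row and column of a grid; spacing doubles.

    ``anchor`` selects which parity of row/column indices is kept
    (default 0: keep row 0, column 0).
    """
    if arr.kind is not ArrayKind.GRID:
        raise GeometryError("subsample_grid requires a grid array")
    rows, cols = arr.grid_shape
    keep_r = np.arange(anchor % 2, rows, 2)
    keep_c = np.arange(anchor % 2, cols, 2)
    flat = (keep_r[:, None] * cols + keep_c[None, :]).ravel()
    sub = ElectrodeArray(
        arr.array_id,
        ArrayKind.GRID,
        arr.contacts[flat],
        arr.spacing_mm * 2 if (len(keep_r) > 1 or len(keep_c) > 1) else arr.spacing_mm,
        (len(keep_r), len(keep_c)),
        tuple(np.array(arr.channel_labels)[flat]),
    )
    return sub, DensityCondition("LD", arr.array_id, tuple(int(i) for i in flat))


def subsample_linear(
    arr: ElectrodeArray, anchor: int = 0
) -> tuple[ElectrodeArray, DensityCondition]:
    """Omit every other contact of a depth or strip; spacing doubles."""
    if arr.kind is ArrayKind.GRID:
        raise GeometryError("subsample_linear requires a depth or strip array")
    flat = np.arange(anchor % 2, arr.n_contacts, 2)
    sub = ElectrodeArray(
        arr.array_id,
        arr.kind,
        arr.contacts[flat],
        arr.spacing_mm * 2 if len(flat) > 1 else arr.spacing_mm,
        (len(flat), 1),
        tuple(np.array(arr.channel_labels)[flat]),
    )
    return sub, DensityCondition("LD", arr.array_id, tuple(int(i) for i in flat))


def subsample_array(
    arr: ElectrodeArray, anchor: int = 0, decimate_strips: bool = False
) -> tuple[ElectrodeArray, DensityCondition]:
    """Dispatch on array kind.

    Strips were recorded at the same 10 mm spacing on both systems in the
    motivating setting, so they are passed through unchanged unless
    ``decimate_strips`` is set.
    """
    if arr.kind is ArrayKind.GRID:
        return subsample_grid(arr, anchor)
    if arr.kind is ArrayKind.STRIP and not decimate_strips:
        cond = DensityCondition("LD", arr.array_id, tuple(range(arr.n_contacts)))
        return arr, cond
    return subsample_linear(arr, anchor)


def subsample_recording(
    rec: Recording, conds: list[DensityCondition],
    arrays: list[ElectrodeArray],
) -> Recording:
    """Restrict a recording to the channels a set of conditions retains.

    Samples on shared channels are bit-identical to the HD recording — the
    LD condition removes channels, nothing else.
    """
    by_id = {a.array_id: a for a in arrays}
    keep_labels: list[str] = []
    for cond in conds:
        arr = by_id.get(cond.parent_array_id)
        if arr is None:
            raise PreprocessError(f"no array {cond.parent_array_id!r} supplied")
        for i in cond.retained_contact_indices:
            keep_labels.append(arr.channel_labels[i])
    idx = [rec.channel_index(lab) for lab in keep_labels]
    return replace(
        rec,
        data=rec.data[idx],
        channel_labels=tuple(keep_labels),
    )
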