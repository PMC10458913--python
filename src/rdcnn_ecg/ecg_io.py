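"""Read/write fixed-length beat datasets in the delimited corpus layout.

The on-disk dialect matches the widely used pre-segmented heartbeat CSV
layout: one row per beat, no header, sample values followed by an integer
class label in the final column.  Class codes are fixed:
0=N, 1=S, 2=V, 3=F, 4=Q.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

CLASS_NAMES: dict[int, str] = {0: "N", 1: "S", 2: "V", 3: "F", 4: "Q"}

#: numeric formatting used by write_beats; round-trips float64 to < 1e-9
_SAMPLE_FMT = "%.10g"


class FormatError(ValueError):
    """Raised for malformed beat files (ragged rows, non-integral labels)."""


class PairingError(ValueError):
    """Raised when a beat matrix and label vector disagree in length."""


def read_beats(path, delimiter: str = ",") -> tuple[np.ndarray, np.ndarray]:
    """Read a beat file into a (beats, labels) pair.

    The last column becomes the integer label vector; the remaining columns
    become the beat matrix.  Row order is preserved.
    """
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        line = _find_ragged_line(path, delimiter)
        if line is not None:
            raise FormatError(
                f"{path}: row {line} has a different number of columns"
            ) from exc
        raise FormatError(f"{path}: {exc}") from exc
    if data.size == 0:
        return np.empty((0, 0)), np.empty(0, dtype=int)
    if data.shape[1] < 2:
        raise FormatError(f"{path}: rows need at least one sample and a label")
    raw_labels = data[:, -1]
    if not np.all(raw_labels == np.round(raw_labels)):
        bad = int(np.nonzero(raw_labels != np.round(raw_labels))[0][0]) + 1
        raise FormatError(f"{path}: row {bad} has a non-integral label")
    return data[:, :-1], raw_labels.astype(int)


def write_beats(beats, labels, path, delimiter: str = ",") -> None:
    """Write a beat matrix and its labels as delimited rows (samples, label)."""
    beats = np.asarray(beats, dtype=float)
    labels = np.asarray(labels)
    if beats.ndim != 2:
        raise PairingError(f"beat matrix must be 2-D, got shape {beats.shape}")
    if beats.shape[0] != labels.shape[0]:
        raise PairingError(
            f"{beats.shape[0]} beats but {labels.shape[0]} labels"
        )
    path = Path(path)
    if beats.shape[0] == 0:
        path.write_text("")
        return
    table = np.column_stack([beats, labels.astype(float)])
    fmt = [_SAMPLE_FMT] * beats.shape[1] + ["%d"]
    np.savetxt(path, table, fmt=fmt, delimiter=delimiter)


def write_masks(masks, path, delimiter: str = ",") -> None:
    """Write contact-loss masks as a 0/1 sidecar in the same row layout."""
    masks = np.asarray(masks, dtype=int)
    np.savetxt(path, masks, fmt="%d", delimiter=delimiter)


def read_masks(path, delimiter: str = ",") -> np.ndarray:
    """Read a 0/1 mask sidecar written by :func:`write_masks`."""
    data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return data.astype(bool)


def summarize_dataset(labels) -> dict:
    """Per-class beat counts plus the total, in the corpus-table layout.

    Returns a dict ``{"per_class": {class_id: count}, "total": n}`` where
    the per-class counts always sum to the total.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot summarize an empty label vector")
    values, counts = np.unique(labels, return_counts=True)
    per_class = {int(v): int(c) for v, c in zip(values, counts)}
    return {"per_class": per_class, "total": int(labels.size)}


def summary_table(summary: dict) -> str:
    """Human-readable rendering of a :func:`summarize_dataset` result."""
    lines = ["class  name  count"]
    for class_id, count in sorted(summary["per_class"].items()):
        name = CLASS_NAMES.get(class_id, "?")
        lines.append(f"{class_id:>5}  {name:>4}  {count}")
    lines.append(f"total        {summary['total']}")
    return "\n".join(lines)


def write_summary(summary: dict, path) -> None:
    """Write a dataset summary as JSON."""
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")


def _find_ragged_line(path: Path, delimiter: str) -> int | None:
    """Return the 1-based line number of the first row with a deviant width."""
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            ncols = len(line.strip().split(delimiter))
            if width is None:
                width = ncols
            elif ncols != width:
                return lineno
    return None
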