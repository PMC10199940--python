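"""Plain-text storage for EEG records and cohort directories.

A record file is a commented header followed by a whitespace-delimited
numeric table (samples x channels)::

    # eegmarkers record
    # subject_id=A000
    # group=A
    # eye_condition=open
    # fs=128
    # channels=Fp1 Fp2 ... O2
    -0.123456 0.654321 ...

A cohort lives in a directory with one subdirectory per group
(``root/{A,B,C,D}/*.txt``); group membership is assigned by directory.
Values are written with 6 significant digits, so write/read roundtrips
preserve samples to that precision and all metadata exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import GROUP_EYE_CONDITION, GROUPS, EEGRecord

__all__ = ["CohortIndex", "read_record", "write_record", "load_cohort", "write_cohort"]


@dataclass
class CohortIndex:
    """Files of a cohort directory, grouped by label A-D."""

    root: Path
    files: dict[str, list[Path]] = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self.files.values())

    def eye_condition(self, group: str) -> str:
        return GROUP_EYE_CONDITION[group]


def write_record(record: EEGRecord, path: str | os.PathLike) -> None:
    """Write one record to ``path`` in the native plain-text format."""
    path = Path(path)
    header = (
        "eegmarkers record\n"
        f"subject_id={record.subject_id}\n"
        f"group={record.group}\n"
        f"eye_condition={record.eye_condition}\n"
        f"fs={record.fs:g}\n"
        f"channels={' '.join(record.channel_names)}"
    )
    np.savetxt(path, record.signal.T, fmt="%.6g", header=header, comments="# ")


def read_record(path: str | os.PathLike) -> EEGRecord:
    """Parse one record file; raises ValueError on malformed content."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line.lstrip("#").strip()
            if "=" in text:
                key, _, value = text.partition("=")
                meta[key.strip()] = value.strip()
    for key in ("fs", "group", "channels"):
        if key not in meta:
            raise ValueError(f"{path}: missing header field {key!r}")
    channels = tuple(meta["channels"].split())
    try:
        body = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric data ({exc})") from exc
    if body.shape[1] != len(channels):
        raise ValueError(
            f"{path}: {body.shape[1]} data columns but header lists "
            f"{len(channels)} channels"
        )
    try:
        return EEGRecord(
            subject_id=meta.get("subject_id", path.stem),
            group=meta["group"],
            channel_names=channels,
            signal=body.T,
            fs=float(meta["fs"]),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_cohort(records: list[EEGRecord], root: str | os.PathLike) -> CohortIndex:
    """Write records into ``root/<group>/<subject_id>.txt``."""
    root = Path(root)
    index = CohortIndex(root=root, files={g: [] for g in GROUPS})
    for record in records:
        gdir = root / record.group
        gdir.mkdir(parents=True, exist_ok=True)
        target = gdir / f"{record.subject_id}.txt"
        write_record(record, target)
        index.files[record.group].append(target)
    return index


def load_cohort(root: str | os.PathLike) -> tuple[CohortIndex, list[EEGRecord]]:
    """Load every record under ``root/{A,B,C,D}``.

    Group labels are assigned by directory. An empty or absent group
    directory is allowed; a malformed file or a record whose channel
    set differs from the rest of the cohort is an error naming the file.
    """
    root = Path(root)
    index = CohortIndex(root=root, files={g: [] for g in GROUPS})
    records: list[EEGRecord] = []
    channel_set: tuple[str, ...] | None = None
    for group in GROUPS:
        gdir = root / group
        if not gdir.is_dir():
            continue
        for path in sorted(gdir.glob("*.txt")):
            record = read_record(path)
            record.group = group
            record.eye_condition = GROUP_EYE_CONDITION[group]
            if channel_set is None:
                channel_set = record.channel_names
            elif record.channel_names != channel_set:
                raise ValueError(
                    f"{path}: channel set differs from the rest of the cohort"
                )
            index.files[group].append(path)
            records.append(record)
    return index, records
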