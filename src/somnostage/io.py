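"""Readers and writers: EDF nights, hypnogram sidecars, curve tables.

Generated nights are exported as standard EDF (two signals, physical unit
microvolts) plus a plain-text hypnogram sidecar with one line per 30-s
epoch, ``epoch_index<TAB>stage_name``.  Real or re-read polysomnography
comes back in through MNE's EDF reader and is segmented into consecutive
non-overlapping 30-s epochs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from ._edf import write_edf
from .stages import StageLabel
from .synth import CHANNEL_NAMES, EPOCH_SECONDS, EpochRecord

__all__ = [
    "export_night_edf",
    "read_psg_edf",
    "write_hypnogram",
    "read_hypnogram",
    "attach_hypnogram",
    "export_dataset",
    "load_dataset",
]

logger = logging.getLogger(__name__)

HYPNOGRAM_SUFFIX = ".hyp.tsv"


def export_night_edf(records: Sequence[EpochRecord], path: str | Path) -> None:
    """Write one night's consecutive epochs as EDF + hypnogram sidecar."""
    if not records:
        raise ValueError("no epochs to export")
    night_ids = {r.night_id for r in records}
    if len(night_ids) != 1:
        raise ValueError(f"records span several nights: {sorted(night_ids)}")
    ordered = sorted(records, key=lambda r: r.epoch_index)
    signals = np.concatenate([r.samples for r in ordered], axis=0)
    write_edf(path, signals, ordered[0].fs_hz, list(CHANNEL_NAMES))
    sidecar = Path(str(path)[:-4] + HYPNOGRAM_SUFFIX) \
        if str(path).endswith(".edf") else Path(str(path) + HYPNOGRAM_SUFFIX)
    write_hypnogram(sidecar, [r.stage for r in ordered])


def read_psg_edf(
    path: str | Path,
    channel_names: Sequence[str] = CHANNEL_NAMES,
    *,
    subject_id: str | None = None,
    night_id: str | None = None,
) -> list[EpochRecord]:
    """Read an EDF recording and segment it into unlabelled 30-s epochs.

    Requested channels must be present; a missing channel raises
    ``ValueError`` naming the channels the file does contain.  A partial
    trailing epoch is dropped with a logged count.  Samples are returned in
    microvolts at the file's sampling rate; stages are ``None`` until a
    hypnogram is attached.
    """
    import mne  # deferred: import is slow and only this entry point needs it

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises several types for malformed files
        raise ValueError(f"cannot read {path} as EDF: {exc}") from exc
    missing = [ch for ch in channel_names if ch not in raw.ch_names]
    if missing:
        raise ValueError(
            f"channel(s) {missing} not in {path.name}; available: {raw.ch_names}"
        )
    fs = float(raw.info["sfreq"])
    data = raw.get_data(picks=list(channel_names)) * 1e6  # volts -> uV
    samples = data.T  # (n_samples, n_channels)
    n_per_epoch = int(round(fs * EPOCH_SECONDS))
    n_epochs = samples.shape[0] // n_per_epoch
    remainder = samples.shape[0] - n_epochs * n_per_epoch
    if remainder:
        logger.info("%s: dropped partial trailing epoch of %d samples (%.1f s)",
                    path.name, remainder, remainder / fs)
    subject = subject_id if subject_id is not None else path.stem.split("_")[0]
    night = night_id if night_id is not None else path.stem
    records = []
    for i in range(n_epochs):
        records.append(
            EpochRecord(
                samples=samples[i * n_per_epoch:(i + 1) * n_per_epoch],
                fs_hz=fs,
                stage=None,
                subject_id=subject,
                night_id=night,
                epoch_index=i,
            )
        )
    return records


def write_hypnogram(path: str | Path, labels: Sequence[StageLabel]) -> None:
    """One line per epoch: ``epoch_index<TAB>stage_name``."""
    with open(path, "w") as fh:
        for i, label in enumerate(labels):
            fh.write(f"{i}\t{label.name}\n")


def read_hypnogram(path: str | Path) -> list[StageLabel]:
    """Parse a hypnogram sidecar back into stage labels.

    Unknown stage tokens raise ``ValueError`` with their line number
    (five-stage AASM scheme only); out-of-order indices are re-sorted with
    a warning; gaps or duplicate indices are rejected.
    """
    entries: list[tuple[int, StageLabel]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}, line {lineno}: expected 'index<TAB>stage'"
                )
            try:
                idx = int(parts[0])
            except ValueError:
                raise ValueError(
                    f"{path}, line {lineno}: bad epoch index {parts[0]!r}"
                ) from None
            try:
                stage = StageLabel.from_name(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
            entries.append((idx, stage))
    if not entries:
        raise ValueError(f"{path}: empty hypnogram")
    indices = [i for i, _ in entries]
    if indices != sorted(indices):
        logger.warning("%s: epoch indices out of order; re-sorting", path)
        entries.sort(key=lambda e: e[0])
        indices = [i for i, _ in entries]
    if indices != list(range(len(indices))):
        raise ValueError(
            f"{path}: epoch indices must be 0..n-1 without gaps or duplicates"
        )
    return [stage for _, stage in entries]


def attach_hypnogram(
    records: Sequence[EpochRecord], labels: Sequence[StageLabel]
) -> list[EpochRecord]:
    """Label epochs in place from a hypnogram, aligned by epoch index."""
    if len(records) != len(labels):
        raise ValueError(
            f"{len(records)} epochs vs {len(labels)} hypnogram entries"
        )
    for rec in records:
        rec.stage = labels[rec.epoch_index]
    return list(records)


def export_dataset(records: Sequence[EpochRecord], out_dir: str | Path) -> list[Path]:
    """Write every night in a record list as EDF + sidecar; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nights: dict[str, list[EpochRecord]] = {}
    for rec in records:
        nights.setdefault(rec.night_id, []).append(rec)
    paths = []
    for night_id, night_records in nights.items():
        path = out_dir / f"{night_id}.edf"
        export_night_edf(night_records, path)
        paths.append(path)
    return paths


def load_dataset(data_dir: str | Path) -> list[EpochRecord]:
    """Read every EDF night (with its hypnogram sidecar) from a directory."""
    data_dir = Path(data_dir)
    edf_paths = sorted(data_dir.glob("*.edf"))
    if not edf_paths:
        raise ValueError(f"no .edf files in {data_dir}")
    records: list[EpochRecord] = []
    for path in edf_paths:
        night = read_psg_edf(path)
        sidecar = Path(str(path)[:-4] + HYPNOGRAM_SUFFIX)
        if sidecar.exists():
            attach_hypnogram(night, read_hypnogram(sidecar))
        records.extend(night)
    return records
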