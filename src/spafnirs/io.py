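"""On-disk formats: SNIRF (HDF5), physiology CSV, BIDS-style events TSV.

The SNIRF writer/reader covers the subset of the continuous-wave format
this pipeline needs (``dataTimeSeries``/``time``/``measurementList``/
``probe``/``metaDataTags``).  ROI labels, which SNIRF itself does not
carry, live in a ``*_channels.tsv`` sidecar next to each file.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (
    PHYSIO_CSV_COLUMNS,
    PHYSIO_SIGNALS,
    EventSchedule,
    PhysioRecord,
    RawScan,
)
from .errors import InvalidInputError
from .simulate import GroundTruth, SessionBundle

_STR = h5py.string_dtype(encoding="utf-8")


def _channels_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + "_channels.tsv")


def write_snirf(path, scan: RawScan) -> Path:
    """Write a RawScan as SNIRF v1.0 plus a channel-table sidecar."""
    path = Path(path)
    table = scan.channel_table
    n_ch, _, n_t = scan.intensity.shape
    # measurement list: channel-major, wavelength-minor
    data = np.empty((n_t, n_ch * 2))
    for c in range(n_ch):
        for w in range(2):
            data[:, 2 * c + w] = scan.intensity[c, w]
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=_STR)
        nirs = f.create_group("/nirs")
        meta = nirs.create_group("metaDataTags")
        for key, value in {
            "SubjectID": "sim",
            "MeasurementDate": "2000-01-01",
            "MeasurementTime": "00:00:00",
            "LengthUnit": "mm",
            "TimeUnit": "s",
            "FrequencyUnit": "Hz",
        }.items():
            meta.create_dataset(key, data=value, dtype=_STR)
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=scan.times)
        for c in range(n_ch):
            for w in range(2):
                ml = d1.create_group(f"measurementList{2 * c + w + 1}")
                ml.create_dataset("sourceIndex", data=int(table.loc[c, "source"]))
                ml.create_dataset("detectorIndex", data=int(table.loc[c, "detector"]))
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(scan.wavelengths))
        n_src = int(table["source"].max())
        n_det = int(table["detector"].max())
        # synthetic planar layout; separations are recorded in the sidecar
        probe.create_dataset(
            "sourcePos2D",
            data=np.column_stack([np.arange(n_src) * 30.0, np.zeros(n_src)]),
        )
        probe.create_dataset(
            "detectorPos2D",
            data=np.column_stack([np.arange(n_det) * 30.0, np.full(n_det, 30.0)]),
        )
    table.to_csv(_channels_sidecar(path), sep="\t", index=False)
    return path


def read_snirf(path) -> RawScan:
    """Read a SNIRF file written by :func:`write_snirf` (or compatible)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        nirs = f["/nirs"] if "nirs" in f else f["/nirs1"]
        d1 = nirs["data1"]
        data = d1["dataTimeSeries"][()]
        time = d1["time"][()]
        wavelengths = tuple(float(w) for w in nirs["probe"]["wavelengths"][()])
        ml_names = sorted(
            (k for k in d1.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        entries = []
        for name in ml_names:
            g = d1[name]
            entries.append(
                (
                    int(np.array(g["sourceIndex"])),
                    int(np.array(g["detectorIndex"])),
                    int(np.array(g["wavelengthIndex"])),
                )
            )
    if len(time) > 1:
        rate = 1.0 / float(np.median(np.diff(time)))
    else:
        raise InvalidInputError("SNIRF time axis too short")
    sidecar = _channels_sidecar(path)
    if not sidecar.exists():
        raise InvalidInputError(f"channel sidecar {sidecar} not found")
    table = pd.read_csv(sidecar, sep="\t")
    table["is_short"] = table["is_short"].astype(bool)
    n_ch = len(table)
    intensity = np.empty((n_ch, 2, data.shape[0]))
    # map measurement-list entries back onto (channel, wavelength)
    pair_rows: dict[tuple[int, int], int] = {
        (int(row.source), int(row.detector)): i for i, row in table.iterrows()
    }
    for col, (src, det, wl) in enumerate(entries):
        ch = pair_rows[(src, det)]
        intensity[ch, wl - 1] = data[:, col]
    return RawScan(
        intensity=intensity,
        sample_rate=rate,
        wavelengths=wavelengths,
        channel_table=table,
    )


def write_physio_csv(path, record: PhysioRecord) -> Path:
    path = Path(path)
    frame = pd.DataFrame({"time_s": record.times})
    for name in PHYSIO_SIGNALS:
        frame[PHYSIO_CSV_COLUMNS[name]] = record.signals[name]
    frame.to_csv(path, index=False, float_format="%.6f")
    return path


def read_physio_csv(path) -> PhysioRecord:
    frame = pd.read_csv(path)
    t = frame["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise InvalidInputError("physiology CSV too short")
    rate = 1.0 / float(np.median(np.diff(t)))
    signals = {
        name: frame[col].to_numpy(dtype=float)
        for name, col in PHYSIO_CSV_COLUMNS.items()
    }
    return PhysioRecord(signals=signals, sample_rate=rate)


def write_events_tsv(path, schedule: EventSchedule) -> Path:
    path = Path(path)
    schedule.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path) -> EventSchedule:
    return EventSchedule.from_frame(pd.read_csv(path, sep="\t"))


def write_ground_truth_json(path, truth: GroundTruth) -> Path:
    path = Path(path)
    payload = {
        "roi_amplitudes": {k: float(v) for k, v in truth.roi_amplitudes.items()},
        "lags_s": {k: float(v) for k, v in truth.lags.items()},
        "channel_betas": truth.channel_betas.tolist(),
        "superficial_gains": truth.superficial_gains.tolist(),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def write_session(outdir, bundle: SessionBundle) -> dict[str, str]:
    """Write one session bundle; returns the artifact manifest entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"ses-{bundle.session_index + 1:02d}"
    paths = {
        "snirf": write_snirf(outdir / f"{stem}.snirf", bundle.raw),
        "physio": write_physio_csv(outdir / f"{stem}_physio.csv", bundle.physio),
        "events": write_events_tsv(outdir / f"{stem}_events.tsv", bundle.schedule),
        "truth": write_ground_truth_json(outdir / f"{stem}_truth.json", bundle.truth),
    }
    return {k: str(v) for k, v in paths.items()}


def discover_sessions(directory) -> list[dict[str, Path]]:
    """Find ``ses-*`` bundles (SNIRF + physio CSV + events TSV) in a directory."""
    directory = Path(directory)
    sessions = []
    for snirf in sorted(directory.glob("ses-*.snirf")):
        stem = snirf.stem
        entry = {
            "snirf": snirf,
            "physio": directory / f"{stem}_physio.csv",
            "events": directory / f"{stem}_events.tsv",
        }
        if entry["physio"].exists() and entry["events"].exists():
            sessions.append(entry)
    return sessions


def read_session(entry: dict[str, Path]) -> tuple[RawScan, PhysioRecord, EventSchedule]:
    return (
        read_snirf(entry["snirf"]),
        read_physio_csv(entry["physio"]),
        read_events_tsv(entry["events"]),
    )
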