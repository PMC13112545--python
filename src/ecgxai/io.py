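"""Readers and writers for ECG records, labels and analysis outputs.

Records travel as single-column CSV (one sample per row, millivolts,
UTF-8, '.' decimal separator) with optional ``# key: value`` comment
headers carrying metadata, or as WFDB header/signal pairs (format-16
binary or CinC2017-style ``.mat`` files).  Labels are two-column CSV;
any label other than normal/afib is reported and excluded rather than
crashing, mirroring a two-class study design.

Importances, interval scores, CAM maps and ground truth all serialize to
plain CSV with 0-based sample indices and seconds to three decimals.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aggregate import AggregationReport
from .gradcam import CamMap
from .records import EcgRecord, GroundTruth, Rhythm
from .xai import ImportanceVector

logger = logging.getLogger("ecgxai")

__all__ = [
    "read_record",
    "write_record",
    "read_labels",
    "write_labels",
    "write_importance",
    "write_rpeaks",
    "write_interval_scores",
    "write_cam",
    "write_ground_truth",
    "read_ground_truth",
]


# -- records ----------------------------------------------------------------

def _read_csv_record(path: Path, fs: float, record_id: Optional[str]) -> EcgRecord:
    meta: Dict[str, str] = {}
    samples: List[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if text.startswith("#"):
                if ":" in text:
                    key, _, value = text.lstrip("#").partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if text == "":
                # a trailing newline is fine; an interior blank line is not
                rest = fh.read()
                if rest.strip():
                    raise ValueError(f"{path}: blank line at line {lineno}")
                break
            try:
                samples.append(float(text))
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(
                    f"{path}: non-numeric sample {text!r} at row {lineno}"
                ) from None
    label = Rhythm.parse(meta["label"]) if meta.get("label") else None
    return EcgRecord(
        record_id=record_id or meta.get("record_id", path.stem),
        samples=np.asarray(samples),
        fs=float(meta.get("fs", fs)),
        label=label,
    )


def _read_wfdb_record(path: Path, record_id: Optional[str]) -> EcgRecord:
    """Minimal WFDB reader: header plus format-16 .dat or .mat signal."""
    header = path.with_suffix(".hea")
    if not header.exists():
        raise FileNotFoundError(f"missing WFDB header {header}")
    lines = [
        ln.strip() for ln in header.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    fields = lines[0].split()
    name, n_sig = fields[0], int(fields[1])
    fs = float(fields[2]) if len(fields) > 2 else 250.0
    if n_sig < 1:
        raise ValueError(f"{header}: no signals declared")
    sig = lines[1].split()
    sig_file, fmt = sig[0], sig[1]
    gain, baseline = 200.0, 0.0
    if len(sig) > 2:
        gain_field = sig[2].split("/")[0]
        if "(" in gain_field:
            gain_s, base_s = gain_field.rstrip(")").split("(")
            gain, baseline = float(gain_s), float(base_s)
        else:
            gain = float(gain_field)
        if gain == 0:
            gain = 200.0
    data_path = path.parent / sig_file
    if data_path.suffix == ".mat":
        from scipy.io import loadmat

        mat = loadmat(data_path)
        key = "val" if "val" in mat else next(
            k for k in mat if not k.startswith("__")
        )
        raw = np.asarray(mat[key], dtype=float).reshape(n_sig, -1)[0]
    elif fmt.startswith("16"):
        raw = np.fromfile(data_path, dtype="<i2").astype(float)
        raw = raw.reshape(-1, n_sig)[:, 0]
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt!r}")
    samples = (raw - baseline) / gain
    return EcgRecord(record_id=record_id or name, samples=samples, fs=fs)


def read_record(
    path: str | Path,
    format: Optional[str] = None,
    fs: float = 300.0,
    record_id: Optional[str] = None,
) -> EcgRecord:
    """Read one record from CSV or WFDB.

    ``format`` is inferred from the extension when omitted (``.hea``/
    ``.dat``/``.mat`` → wfdb, anything else → csv).  For CSV the sampling
    rate comes from a ``# fs:`` header line or the ``fs`` argument.
    """
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in (".hea", ".dat", ".mat") else "csv"
    if format == "wfdb":
        return _read_wfdb_record(path, record_id)
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_csv_record(path, fs, record_id)
    raise ValueError(f"unknown record format {format!r}")


def write_record(record: EcgRecord, path: str | Path) -> Path:
    """Write a record as single-column CSV with metadata comment headers."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# record_id: {record.record_id}\n")
        fh.write(f"# fs: {record.fs:g}\n")
        if record.label is not None:
            fh.write(f"# label: {record.label.value}\n")
        for v in record.samples:
            fh.write(f"{v:.12g}\n")
    return path


# -- labels -----------------------------------------------------------------

def read_labels(path: str | Path) -> Dict[str, Rhythm]:
    """Two-column CSV (record_id, label) to a mapping.

    Labels outside {normal, afib} (e.g. 'alternative rhythm', 'noisy') are
    excluded with a warning; duplicate ids are an error.
    """
    labels: Dict[str, Rhythm] = {}
    excluded = 0
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: malformed label row {row!r}")
            rid, token = row[0].strip(), row[1].strip()
            if rid.lower() == "record_id":
                continue  # header
            if rid in labels:
                raise ValueError(f"{path}: duplicate record_id {rid!r}")
            try:
                labels[rid] = Rhythm.parse(token)
            except ValueError:
                excluded += 1
                warnings.warn(
                    f"excluding record {rid!r} with out-of-scope label {token!r}"
                )
    if excluded:
        logger.info("read_labels: kept %d records, excluded %d", len(labels), excluded)
    return labels


def write_labels(labels: Dict[str, Rhythm], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("record_id,label\n")
        for rid in sorted(labels):
            fh.write(f"{rid},{labels[rid].value}\n")
    return path


# -- analysis outputs -------------------------------------------------------

def write_importance(imp: ImportanceVector, record_id: str, path: str | Path) -> Path:
    """Importance CSV; positive values are evidence for the target class."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# sign convention: positive = evidence for target_class\n")
        fh.write("record_id,sample_index,value,method,target_class,seed\n")
        seed = imp.meta.get("seed", "")
        for i, v in enumerate(imp.values):
            fh.write(
                f"{record_id},{i},{v:.10g},{imp.method},{imp.target_class.value},{seed}\n"
            )
    return path


def write_interval_scores(
    report: AggregationReport, record_id: str, fs: float, method: str, path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "record_id,start_index,end_index,duration_s,raw_score,"
            "normalized_score,rank,method\n"
        )
        for s in report.scores:
            fh.write(
                f"{record_id},{s.interval.start},{s.interval.end},"
                f"{s.interval.duration:.3f},{s.raw_score:.10g},"
                f"{s.normalized_score:.6f},{s.rank},{method}\n"
            )
    return path


def write_cam(cam: CamMap, record_id: str, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("record_id,sample_index,activation,highlighted\n")
        for i, (a, h) in enumerate(zip(cam.activation, cam.highlight_mask)):
            fh.write(f"{record_id},{i},{a:.6f},{int(h)}\n")
    return path


def write_rpeaks(rpeaks, record_id: str, path: str | Path) -> Path:
    """Annotation-style CSV: one row per detected R-peak."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("record_id,sample_index,symbol\n")
        for idx in rpeaks.indices:
            fh.write(f"{record_id},{int(idx)},R\n")
    return path


def write_ground_truth(
    truths: Sequence[Tuple[str, GroundTruth]], path: str | Path
) -> Path:
    """Ground-truth CSV: r_times and p_windows as ';'-joined second values."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("record_id,rhythm,r_times,p_windows\n")
        for rid, truth in truths:
            rts = ";".join(f"{t:.3f}" for t in truth.r_times)
            pws = ";".join(f"{s:.3f}:{e:.3f}" for s, e in truth.p_windows)
            fh.write(f"{rid},{truth.rhythm.value},{rts},{pws}\n")
    return path


def read_ground_truth(path: str | Path) -> Dict[str, GroundTruth]:
    out: Dict[str, GroundTruth] = {}
    frame = pd.read_csv(path, dtype=str).fillna("")
    for _, row in frame.iterrows():
        r_times = tuple(float(v) for v in row["r_times"].split(";") if v)
        p_windows = tuple(
            tuple(float(x) for x in pair.split(":"))
            for pair in row["p_windows"].split(";")
            if pair
        )
        out[row["record_id"]] = GroundTruth(
            r_times=r_times,
            p_windows=p_windows,  # type: ignore[arg-type]
            rhythm=Rhythm.parse(row["rhythm"]),
        )
    return out
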