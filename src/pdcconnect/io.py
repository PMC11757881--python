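"""Reading and writing recordings, cohorts, feature tables and reports.

Cohorts are stored as one delimited matrix per subject (samples × channels,
tab-separated, header row of channel labels) plus a JSON manifest carrying
subject IDs, class labels, sampling rate and units.  EDF reading is
supported through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EEGRecording
from .synthetic import Cohort

MANIFEST_NAME = "cohort_manifest.json"


def write_recording(rec: EEGRecording, path) -> None:
    """Samples × channels TSV with a channel-label header."""
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_recording(path, fs: float, unit: str = "uV", subject_id: str = "",
                   class_label: str | None = None) -> EEGRecording:
    df = pd.read_csv(path, sep="\t")
    return EEGRecording(data=df.to_numpy(dtype=float).T, fs=fs,
                        channel_labels=tuple(df.columns), subject_id=subject_id,
                        class_label=class_label, unit=unit)


def read_edf(path, subject_id: str = "", class_label: str | None = None) -> EEGRecording:
    """Read an EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("EDF input requires the 'mne' package "
                          "(pip install pdcconnect[edf])") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(data=raw.get_data() * 1e6,  # mne holds volts
                        fs=float(raw.info["sfreq"]),
                        channel_labels=tuple(ch.upper() for ch in raw.ch_names),
                        subject_id=subject_id, class_label=class_label, unit="uV")


def write_cohort(cohort: Cohort, outdir) -> Path:
    """One TSV per subject plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort.recordings:
        fname = f"{rec.subject_id}.tsv"
        write_recording(rec, outdir / fname)
        entries.append({"subject_id": rec.subject_id, "class_label": rec.class_label,
                        "file": fname, "fs": rec.fs, "unit": rec.unit})
    manifest = {"seed": cohort.config.seed,
                "n_subjects_per_class": cohort.config.n_subjects_per_class,
                "duration_s": cohort.config.duration_s,
                "subjects": entries}
    path = outdir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_cohort(manifest_path) -> list[EEGRecording]:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    manifest = json.loads(manifest_path.read_text())
    recs = []
    for entry in manifest["subjects"]:
        recs.append(read_recording(manifest_path.parent / entry["file"],
                                   fs=entry["fs"], unit=entry.get("unit", "uV"),
                                   subject_id=entry["subject_id"],
                                   class_label=entry.get("class_label")))
    return recs


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report_json(report, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))
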