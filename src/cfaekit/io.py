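"""Delimited-text persistence for recordings, manifests and ground truth.

Signal files are two-column CSV (time s, amplitude mV) preceded by ``#``
header lines carrying patient/site/af_type/fs metadata. The cohort manifest
is a CSV of (patient_id, af_type, site, path); ground truth (activation times,
artifact intervals) goes to a companion CSV. Everything is plain text for
diffability.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import FS, N_SAMPLES, Recording


def write_recording(rec: Recording, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(N_SAMPLES) / FS
    with open(path, "w") as fh:
        fh.write(f"# patient_id={rec.patient_id}\n")
        fh.write(f"# af_type={rec.af_type}\n")
        fh.write(f"# site={rec.site}\n")
        fh.write(f"# fs={rec.fs}\n")
        fh.write("time_s,amplitude_mv\n")
        for ti, xi in zip(t, rec.samples):
            fh.write(f"{ti:.3f},{float(xi)!r}\n")


def read_recording(path: Path) -> Recording:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    fs = int(meta.get("fs", FS))
    samples = df["amplitude_mv"].to_numpy(dtype=float)
    if fs != FS:
        raise ValueError(f"{path}: fs={fs}, expected {FS} Hz")
    if len(samples) != N_SAMPLES:
        raise ValueError(f"{path}: {len(samples)} samples, expected {N_SAMPLES} (16 s)")
    return Recording(
        patient_id=meta.get("patient_id", path.stem),
        af_type=meta.get("af_type", "ParAF"),
        site=meta.get("site", "LSPV"),
        samples=samples,
        fs=fs,
    )


def write_cohort(cohort: list[Recording], outdir: Path) -> Path:
    """Write one signal file per recording plus manifest and truth tables;
    returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows, truth_rows = [], []
    for rec in cohort:
        fname = f"{rec.patient_id}_{rec.site}.csv"
        write_recording(rec, outdir / fname)
        manifest_rows.append(
            {"patient_id": rec.patient_id, "af_type": rec.af_type, "site": rec.site, "path": fname}
        )
        for t_ms in rec.truth.get("activation_times_ms", []):
            truth_rows.append(
                {"patient_id": rec.patient_id, "site": rec.site, "kind": "activation", "value_ms": t_ms}
            )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    if truth_rows:
        pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
    return manifest


def read_recordings(manifest_path: Path) -> tuple[list[Recording], list[dict]]:
    """Load a cohort from a manifest; malformed rows are reported, not fatal.

    Returns (recordings, problems) where each problem dict carries the
    manifest line number and the diagnostic.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    recs, problems = [], []
    for i, row in df.iterrows():
        path = manifest_path.parent / row["path"]
        try:
            rec = read_recording(path)
            rec.patient_id = str(row["patient_id"])
            rec.af_type = str(row["af_type"])
            rec.site = str(row["site"])
            recs.append(rec)
        except (OSError, ValueError, KeyError) as exc:
            problems.append({"line": int(i) + 2, "path": str(path), "error": str(exc)})
    return recs, problems
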