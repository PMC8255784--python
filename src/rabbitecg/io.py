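"""CSV / JSON input-output for beat tables, waveforms and cohorts.

All files are plain text: beat tables as CSV with columns
``time_s, rr_ms, qt_ms, label, phase``; waveforms as CSV with
``time_s, mV``; fiducials as CSV; cohort manifests and ground truth as
JSON.  Optional ``# key=value`` comment headers carry provenance (e.g. the
run-config hash) and are ignored on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import BeatSeries, Cohort, EcgWaveform


def _write_csv(frame: pd.DataFrame, path, header_comment: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def write_beat_series(series: BeatSeries, path,
                      header_comment: str | None = None) -> None:
    _write_csv(series.to_frame(), path, header_comment)


def read_beat_series(path) -> BeatSeries:
    frame = pd.read_csv(path, comment="#")
    return BeatSeries.from_frame(frame)


def write_waveform(waveform: EcgWaveform, path,
                   header_comment: str | None = None) -> None:
    frame = pd.DataFrame({"time_s": waveform.time_s(),
                          "mV": waveform.samples})
    _write_csv(frame, path, header_comment)


def read_waveform(path, fs_hz: float | None = None,
                  fiducials_path=None) -> EcgWaveform:
    frame = pd.read_csv(path, comment="#")
    t = frame["time_s"].to_numpy(dtype=float)
    x = frame["mV"].to_numpy(dtype=float)
    if fs_hz is None:
        if t.size < 2:
            raise ValueError("cannot infer sampling rate from < 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("waveform CSV is not uniformly sampled")
        fs_hz = 1.0 / float(np.mean(dt))
    fid = None
    if fiducials_path is not None and Path(fiducials_path).exists():
        fid = pd.read_csv(fiducials_path, comment="#")
    return EcgWaveform(fs_hz=float(fs_hz), samples=x, fiducials=fid)


def write_fiducials(waveform: EcgWaveform, path,
                    header_comment: str | None = None) -> None:
    if waveform.fiducials is None:
        raise ValueError("waveform carries no fiducials")
    _write_csv(waveform.fiducials, path, header_comment)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_cohort(cohort: Cohort, outdir, header_comment: str | None = None,
                 ) -> Path:
    """Write a cohort: observed data under ``animals/``, ground truth
    (responder status, injected events, fiducials) under ``truth/``, and a
    ``manifest.json``.  Returns the manifest path."""
    outdir = Path(outdir)
    animals_dir = outdir / "animals"
    truth_dir = outdir / "truth"
    manifest = cohort.manifest()
    for animal, entry in zip(cohort.animals, manifest["animals"]):
        beats_path = animals_dir / f"{animal.animal_id}_beats.csv"
        write_beat_series(animal.series, beats_path, header_comment)
        entry["beats_file"] = str(beats_path.relative_to(outdir))
        if animal.waveform is not None:
            wf_path = animals_dir / f"{animal.animal_id}_waveform.csv"
            write_waveform(animal.waveform, wf_path, header_comment)
            entry["waveform_file"] = str(wf_path.relative_to(outdir))
            entry["fs_hz"] = animal.waveform.fs_hz
            if animal.waveform.fiducials is not None:
                fp = truth_dir / f"{animal.animal_id}_fiducials.csv"
                write_fiducials(animal.waveform, fp, header_comment)
        write_json(animal.truth, truth_dir / f"{animal.animal_id}.json")
    manifest_path = outdir / "manifest.json"
    write_json(manifest, manifest_path)
    return manifest_path
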