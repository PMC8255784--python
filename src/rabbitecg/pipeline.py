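"""Four-stage pipeline: simulate -> analyze -> stratify -> report.

Each stage reads and writes plain-text files (CSV/JSON) so runs are
inspectable and re-runnable; every output carries the run-config hash.
Per-animal failures (missing or corrupt recordings, too-short entropy
segments) exclude the animal with a logged reason instead of aborting the
run, mirroring how analyzable-animal counts are reported in practice.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import beats as beats_mod
from . import events as events_mod
from . import hrv as hrv_mod
from . import io as io_mod
from . import repol as repol_mod
from . import riskstats as risk_mod
from .config import RunConfig
from .entropy import SegmentTooShort, entropy_for_animal
from .synth import LABEL_NORMAL, generate_cohort

log = logging.getLogger("rabbitecg")


def simulate(config: RunConfig, outdir) -> Path:
    """Generate the synthetic cohort and write it to ``outdir``."""
    t0 = time.perf_counter()
    cohort = generate_cohort(
        config.profiles, config.n_per_group, config.seed,
        protocol=config.protocol, fs_hz=config.fs_hz,
        waveform_seconds=config.waveform_seconds,
        noise_sd_mv=config.noise_sd_mv,
        responder_amp_jitter=config.responder_amp_jitter)
    manifest = io_mod.write_cohort(cohort, outdir,
                                   header_comment=f"config={config.config_hash()}")
    config.to_json(Path(outdir) / "config.json")
    log.info("simulate: %d animals in %.1f s -> %s",
             len(cohort.animals), time.perf_counter() - t0, outdir)
    return manifest


def _analyze_animal(entry: dict, cohort_dir: Path, config: RunConfig) -> dict:
    series = io_mod.read_beat_series(cohort_dir / entry["beats_file"])
    row: dict = {"animal": entry["id"], "group": entry["group"]}

    normal = series.label == LABEL_NORMAL
    qtc = np.full(series.n_beats, np.nan)
    ok = normal & np.isfinite(series.qt_ms)
    qtc[ok] = repol_mod.qtc_rabbit(series.qt_ms[ok], series.rr_ms[ok])
    for phase in pd.unique(series.phase):
        sel = (series.phase == phase) & np.isfinite(qtc)
        row[f"rr_{phase}"] = float(series.rr_ms[series.phase == phase].mean())
        row[f"qtc_{phase}"] = float(np.nanmean(qtc[series.phase == phase]))
        try:
            row[f"stv_{phase}"] = repol_mod.stv(
                qtc[sel], n_diffs=config.stv.n_diffs,
                denominator=config.stv.denominator)
        except ValueError:
            row[f"stv_{phase}"] = np.nan

    win = hrv_mod.baseline_window(series, minutes=config.hrv_minutes)
    cleaned = beats_mod.clean_rr(win.rr_ms)
    lo, hi, step = config.freq_grid
    metrics = hrv_mod.hrv_metrics(win.beat_time_s, cleaned.rr_ms,
                                  bands=config.bands,
                                  freq_grid=np.arange(lo, hi + step / 2, step))
    row.update(lf=metrics["lf"], hf=metrics["hf"], lf_hf=metrics["lf_hf"],
               rr_cleaned=cleaned.n_replaced)

    row.update(aape=np.nan, iein_sigma=np.nan, entropy_excluded="")
    wf_file = entry.get("waveform_file")
    if wf_file:
        waveform = io_mod.read_waveform(cohort_dir / wf_file,
                                        fs_hz=entry.get("fs_hz"))
        try:
            res = entropy_for_animal(
                waveform, ordinal=config.ordinal, iein=config.iein,
                decimate_to_hz=config.entropy_decimate_hz,
                min_seconds=config.entropy_min_seconds)
            row.update(aape=res.aape, iein_sigma=res.iein_sigma)
        except SegmentTooShort as exc:
            row["entropy_excluded"] = str(exc)
    else:
        row["entropy_excluded"] = "no waveform recorded"

    episodes = events_mod.classify_runs(series.label, series.beat_time_s)
    outcome = events_mod.outcome_category(episodes, animal_id=entry["id"])
    row.update(category=outcome.category, inducible=outcome.inducible,
               seb_present=outcome.seb_present,
               meb_present=outcome.meb_present,
               n_episodes=len(episodes))
    row["_episodes"] = episodes
    return row


def analyze(cohort_dir, config: RunConfig, outdir=None) -> Path:
    """Per-animal metrics: intervals/QTc/STV, HRV, entropy, episodes."""
    cohort_dir = Path(cohort_dir)
    outdir = Path(outdir) if outdir else cohort_dir / "metrics"
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = io_mod.read_json(cohort_dir / "manifest.json")
    rows, exclusions = [], {}
    for entry in manifest["animals"]:
        t0 = time.perf_counter()
        try:
            row = _analyze_animal(entry, cohort_dir, config)
        except (OSError, ValueError, KeyError) as exc:
            exclusions[entry["id"]] = f"{type(exc).__name__}: {exc}"
            log.warning("analyze: skipping %s (%s)", entry["id"], exc)
            continue
        episodes = row.pop("_episodes")
        ep_frame = pd.DataFrame(
            [{"animal": entry["id"], "kind": e.kind,
              "start_time_s": e.start_time_s, "end_time_s": e.end_time_s,
              "n_beats": e.n_beats} for e in episodes])
        io_mod._write_csv(ep_frame, outdir / f"{entry['id']}_episodes.csv",
                          f"config={config.config_hash()}")
        rows.append(row)
        log.info("analyze: %s done in %.2f s", entry["id"],
                 time.perf_counter() - t0)
    if not rows:
        raise ValueError("no analyzable animals in cohort")
    io_mod._write_csv(pd.DataFrame(rows), outdir / "metrics.csv",
                      f"config={config.config_hash()}")
    io_mod.write_json(exclusions, outdir / "exclusions.json")
    return outdir / "metrics.csv"


def stratify_report(metrics_dir, config: RunConfig, cohort_dir=None,
                    outdir=None, fmt: str = "md") -> Path:
    """Cohort report: interval summary, incidences, outcome regrouping,
    predictor confusion tables and the entropy quadrant."""
    metrics_dir = Path(metrics_dir)
    outdir = Path(outdir) if outdir else metrics_dir / "report"
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = pd.read_csv(metrics_dir / "metrics.csv", comment="#")
    hdr = f"config={config.config_hash()}"

    # interval summary shaped like the group table
    summary = None
    cohort_dir = Path(cohort_dir) if cohort_dir else metrics_dir.parent
    manifest_path = cohort_dir / "manifest.json"
    if manifest_path.exists():
        frames = []
        for entry in io_mod.read_json(manifest_path)["animals"]:
            try:
                s = io_mod.read_beat_series(cohort_dir / entry["beats_file"])
            except (OSError, ValueError):
                continue
            f = s.to_frame()
            f = f[f["label"] == LABEL_NORMAL].copy()
            f["qtc_ms"] = repol_mod.qtc_rabbit(f["qt_ms"], f["rr_ms"])
            f["animal"] = entry["id"]
            f["group"] = entry["group"]
            frames.append(f)
        if frames:
            allbeats = pd.concat(frames, ignore_index=True)
            summary = repol_mod.phase_summary(allbeats,
                                             stv_n_diffs=config.stv.n_diffs)
            io_mod._write_csv(summary.reset_index(), outdir / "summary.csv", hdr)

    # incidence per group + pairwise proportion tests
    groups = list(pd.unique(metrics["group"]))
    inc_rows = []
    for g in groups:
        sub = metrics[metrics["group"] == g]
        k, n, pct = events_mod.incidence_from_counts(
            int(sub["inducible"].sum()), len(sub))
        k2, _, pct2 = events_mod.incidence_from_counts(
            int((sub["n_episodes"] > 0).sum()), len(sub))
        inc_rows.append({"group": g, "tdp_k": k, "n": n, "tdp_percent": pct,
                         "any_arrhythmia_k": k2, "any_arrhythmia_percent": pct2})
    inc = pd.DataFrame(inc_rows)
    io_mod._write_csv(inc, outdir / "incidence.csv", hdr)

    prop_rows = []
    if len(groups) >= 2:
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                r1 = inc[inc["group"] == g1].iloc[0]
                r2 = inc[inc["group"] == g2].iloc[0]
                z, p = risk_mod.two_sample_proportion_test(
                    int(r1["tdp_k"]), int(r1["n"]),
                    int(r2["tdp_k"]), int(r2["n"]))
                prop_rows.append({"group_1": g1, "group_2": g2,
                                  "z": z, "p_two_sided": p})
        io_mod._write_csv(pd.DataFrame(prop_rows),
                          outdir / "proportion_tests.csv", hdr)

    # ectopy predictors of TdP
    confusion = {}
    for flag in ("seb_present", "meb_present"):
        cc = risk_mod.ConfusionCounts(
            tp=int((metrics[flag] & metrics["inducible"]).sum()),
            fp=int((metrics[flag] & ~metrics["inducible"]).sum()),
            tn=int((~metrics[flag] & ~metrics["inducible"]).sum()),
            fn=int((~metrics[flag] & metrics["inducible"]).sum()))
        se, sp = risk_mod.sensitivity_specificity(cc)
        confusion[flag] = {"tp": cc.tp, "fp": cc.fp, "tn": cc.tn, "fn": cc.fn,
                           "sensitivity": se, "specificity": sp}
    io_mod.write_json(confusion, outdir / "confusion.json")

    # entropy quadrant
    quad = metrics[["animal", "group", "category", "aape",
                    "iein_sigma"]].copy()
    with_entropy = np.isfinite(quad["aape"]) & np.isfinite(quad["iein_sigma"])
    quad["low_risk"] = [
        risk_mod.quadrant_low_risk(a, s, config.thresholds) if ok else None
        for a, s, ok in zip(quad["aape"], quad["iein_sigma"], with_entropy)]
    io_mod._write_csv(quad, outdir / "quadrant.csv", hdr)

    report = outdir / f"report.{fmt}"
    if fmt == "md":
        lines = [f"# Cohort report (config {config.config_hash()})", ""]
        if summary is not None:
            lines += ["## Interval summary", "",
                      summary.reset_index()[
                          ["group", "phase", "rr_fmt", "qtc_fmt",
                           "stv_fmt"]].to_string(index=False), ""]
        lines += ["## Incidence", "", inc.to_string(index=False), ""]
        if prop_rows:
            lines += ["## Proportion tests (TdP incidence)", "",
                      pd.DataFrame(prop_rows).to_string(index=False), ""]
        lines += ["## Ectopy predictors of TdP", ""]
        for flag, c in confusion.items():
            lines.append(f"- {flag}: sensitivity "
                         f"{c['sensitivity']:.2f}, specificity "
                         f"{c['specificity']:.2f} "
                         f"(tp={c['tp']} fp={c['fp']} tn={c['tn']} fn={c['fn']})")
        lines += ["", "## Entropy quadrant", "",
                  quad.to_string(index=False), ""]
        report.write_text("\n".join(lines), encoding="utf-8")
    else:
        io_mod.write_json({
            "incidence": inc_rows, "proportion_tests": prop_rows,
            "confusion": confusion,
            "quadrant": quad.to_dict(orient="records")}, report)
    return report
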