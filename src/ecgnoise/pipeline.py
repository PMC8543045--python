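"""End-to-end study orchestration and external-format adapters.

``run_study`` drives simulate -> clean -> inject -> transform -> train ->
evaluate -> report from one config with a single master seed; every stage
seed is derived deterministically from it.  Artefacts (signal CSVs, image
PNG/NPZ pairs, manifests, SNR report, metrics tables, Markdown report) land
in a predictable directory tree so any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import evaluate as ev
from .classify import TrainConfig, make_folds
from .cohort import (
    CohortConfig,
    ECGRecord,
    NoiseParams,
    generate_cohort,
    generate_noise_bank,
    stable_seed,
)
from .noise import build_datasets
from .preprocess import FilterConfig
from .transforms import (
    ScalogramConfig,
    SPARConfig,
    cwt_scalogram,
    spar_attractor,
)

log = logging.getLogger("ecgnoise")

KINDS = ("attractor", "scalogram")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    spar: SPARConfig = field(default_factory=SPARConfig)
    scalogram: ScalogramConfig = field(default_factory=ScalogramConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0
    out_dir: str = "ecgnoise_run"
    variations: tuple = ev.VARIATIONS
    n_folds: int = 5
    write_images: bool = False  # PNG/NPZ emission is optional (large trees)


def transform_datasets(datasets: dict, spar_cfg=None, scal_cfg=None) -> dict:
    """All 12 image datasets: {(variant, kind): {record_id: TransformImage}}."""
    images = {}
    for variant, records in datasets.items():
        images[(variant, "attractor")] = {
            rid: spar_attractor(r, spar_cfg) for rid, r in records.items()
        }
        images[(variant, "scalogram")] = {
            rid: cwt_scalogram(r, scal_cfg) for rid, r in records.items()
        }
    return images


def _write_image(img, path_base: Path) -> None:
    arr8 = np.round(img.pixels * 255).astype(np.uint8)
    Image.fromarray(arr8, mode="L").save(path_base.with_suffix(".png"))
    np.savez_compressed(path_base.with_suffix(".npz"), pixels=img.pixels)


def run_study(cfg: RunConfig) -> dict:
    """Run the whole study; returns a dict of in-memory results and paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        cfg.cohort.seed = stable_seed(cfg.seed, "cohort")
        cohort = generate_cohort(cfg.cohort)
        bank = generate_noise_bank(
            cfg.cohort.fs, stable_seed(cfg.seed, "noise_bank"), cfg.noise
        )
        manifest = pd.DataFrame(
            {
                "record_id": [r.record_id for r in cohort],
                "class_label": [r.class_label for r in cohort],
                "duration_s": [r.duration_s for r in cohort],
                "variant": [r.variant for r in cohort],
                "seed": cfg.cohort.seed,
            }
        )
        manifest.to_csv(out / "cohort_manifest.csv", index=False)
        log.info("simulate: %d records", len(cohort))

        stage = "inject"
        from .preprocess import clean_record

        datasets, snr_table = build_datasets(
            cohort, bank, stable_seed(cfg.seed, "inject"),
            clean_fn=lambda r: clean_record(r, cfg.filters),
        )
        snr_table.to_csv(out / "snr_report.csv", index=False)

        stage = "transform"
        images = transform_datasets(datasets, cfg.spar, cfg.scalogram)
        ids = [r.record_id for r in cohort]
        labels = np.asarray([r.class_label for r in cohort])
        man_rows = []
        for (variant, kind), imgs in images.items():
            img_dir = out / "images" / variant / kind
            if cfg.write_images:
                img_dir.mkdir(parents=True, exist_ok=True)
            for rid in ids:
                if cfg.write_images:
                    _write_image(imgs[rid], img_dir / rid)
                man_rows.append(
                    {"record_id": rid, "variant": variant, "kind": kind,
                     "path": str(img_dir / f"{rid}.png")}
                )
        pd.DataFrame(man_rows).to_csv(out / "image_manifest.csv", index=False)
        log.info("transform: %d image datasets", len(images))

        stage = "train/evaluate"
        folds = make_folds(ids, labels, k=cfg.n_folds, seed=stable_seed(cfg.seed, "folds"))
        ordered = {
            key: [imgs[rid] for rid in ids] for key, imgs in images.items()
        }
        tables = []
        for variation in cfg.variations:
            t = ev.run_variation(variation, ordered, labels, folds, cfg.train)
            tables.append(t)
        if tables:
            table = pd.concat(tables, ignore_index=True)
            table.to_csv(out / "metrics_per_fold.csv", index=False)
            agg = ev.aggregate(table)
            agg.to_csv(out / "metrics_aggregated.csv", index=False)
        else:
            table = agg = pd.DataFrame()

        stage = "report"
        report = ev.render_report(agg) if len(agg) else "# Robustness results\n\n(no variations run)\n"
        (out / "report.md").write_text(report)
        (out / "run_config.json").write_text(
            json.dumps({"seed": cfg.seed, "n_records": len(cohort),
                        "n_folds": cfg.n_folds}, indent=2)
        )
    except Exception as exc:
        raise RuntimeError(f"study failed at stage {stage!r}: {exc}") from exc

    return {
        "cohort": cohort, "bank": bank, "datasets": datasets, "images": images,
        "folds": folds, "snr_table": snr_table, "metrics": table,
        "aggregated": agg, "report": report, "out_dir": out,
    }


# ---------------------------------------------------------------------------
# external-format adapters

def write_record_csv(record: ECGRecord, path) -> None:
    t = np.arange(record.n_samples) / record.fs
    pd.DataFrame({"time_s": t, "amplitude_mv": record.signal}).to_csv(path, index=False)


def _read_csv_record(path: Path) -> ECGRecord:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected time and amplitude columns")
    t = df.iloc[:, 0].to_numpy(float)
    sig = df.iloc[:, 1].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: too few samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return ECGRecord(Path(path).stem, "Normal", round(fs, 6), sig, len(sig) / round(fs, 6), "raw")


def _read_wfdb_record(path: Path) -> ECGRecord:
    """Minimal WFDB-style reader: text ``.hea`` header plus a format-16
    little-endian binary ``.dat`` or a CSV signal file.  Selects lead II."""
    hea = Path(path).with_suffix(".hea")
    if not hea.exists():
        raise ValueError(f"header file {hea} not found")
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_sig, fs = int(head[1]), float(head[2])
    n_samp = int(head[3]) if len(head) > 3 else None
    sig_lines = lines[1 : 1 + n_sig]
    names, gains, files = [], [], []
    for ln in sig_lines:
        parts = ln.split()
        files.append(parts[0])
        gain_part = parts[2].split("/")[0].split("(")[0]
        gains.append(float(gain_part) if float(gain_part) != 0 else 200.0)
        names.append(parts[-1])
    if "II" not in names:
        raise ValueError(f"lead II not present; available leads: {names}")
    lead = names.index("II")
    dat = Path(path).parent / files[lead]
    if dat.suffix == ".csv":
        raw = pd.read_csv(dat, header=None).to_numpy(float)
        col = raw[:, lead] if raw.shape[1] > lead else raw[:, 0]
    else:
        flat = np.fromfile(dat, dtype="<i2").astype(float)
        col = flat[lead::n_sig]
    if n_samp is not None:
        col = col[:n_samp]
    sig = col / gains[lead]  # ADC units -> mV
    return ECGRecord(Path(path).stem, "Normal", fs, sig, len(sig) / fs, "raw")


def read_external_record(path, fmt: str = "csv") -> ECGRecord:
    """Read a raw-variant record from a CSV or WFDB-style file pair."""
    path = Path(path)
    if fmt == "csv":
        return _read_csv_record(path)
    if fmt == "wfdb":
        return _read_wfdb_record(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'wfdb'")
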