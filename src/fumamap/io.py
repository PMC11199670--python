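"""File formats, run configuration, logging and the end-to-end pipeline.

Spectra travel as two-column delimited text (wavenumber, counts) with
'#'-prefixed metadata header lines; hyperspectral maps as a .npz
container (axis + counts cube) with a JSON sidecar carrying step, dwell
and provenance.  Every output embeds the configuration hash and seed so
re-running a configuration reproduces outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .calibrate import (
    CalibrationModel,
    estimate_lod,
    fit_calibration,
)
from .compartments import (
    anova_compartments,
    assign_compartments,
    background_correct,
    compartment_concentrations,
    kmeans_manhattan,
)
from .core import SpectralMap, Spectrum
from .preprocess import BaselineParams, despike_map, mean_center_scan
from .quantify import concentration_histogram, concentration_map_auc

log = logging.getLogger("fumamap")

__all__ = [
    "read_spectrum", "write_spectrum", "read_map", "write_map",
    "RunConfig", "run_pipeline", "read_calibration_model",
    "write_calibration_model",
]


# ---------------------------------------------------------------------------
# Spectrum text format
# ---------------------------------------------------------------------------

def write_spectrum(spec: Spectrum, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# dwell: {spec.dwell!r}\n")
        if spec.power is not None:
            fh.write(f"# power: {spec.power!r}\n")
        for key, val in sorted(spec.meta.items()):
            fh.write(f"# {key}: {val}\n")
        for wn, ct in zip(spec.wavenumbers, spec.counts):
            fh.write(f"{float(wn)!r}\t{float(ct)!r}\n")


def read_spectrum(path) -> Spectrum:
    """Read a two-column (wavenumber, counts) text spectrum.

    Header lines start with '#'; 'dwell' is required for unit
    correctness, unknown header keys are preserved in ``meta``.  A
    descending axis is reversed on read with a logged notice.
    """
    path = Path(path)
    header: dict[str, str] = {}
    wns, cts = [], []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("#").partition(":")
                header[key.strip()] = val.strip()
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                wns.append(float(parts[0]))
                cts.append(float(parts[1]))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
    if "dwell" not in header:
        raise ValueError(
            f"{path}: missing required 'dwell' header (seconds); intensities "
            "cannot be dwell-normalised without it")
    dwell = float(header.pop("dwell"))
    power = float(header.pop("power")) if "power" in header else None
    wn = np.asarray(wns)
    ct = np.asarray(cts)
    if wn.size >= 2 and np.all(np.diff(wn) < 0):
        log.info("axis of %s is descending; reversing on read", path)
        wn, ct = wn[::-1], ct[::-1]
    return Spectrum(wn, ct, dwell=dwell, power=power, meta=dict(header))


# ---------------------------------------------------------------------------
# Map container (.npz + JSON sidecar)
# ---------------------------------------------------------------------------

def write_map(smap: SpectralMap, path) -> None:
    path = Path(path)
    np.savez_compressed(path, wavenumbers=smap.wavenumbers,
                        counts=smap.counts)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {"step_um": smap.step_um, "dwell": smap.dwell,
            "meta": {k: v for k, v in smap.meta.items()
                     if isinstance(v, (str, int, float, bool, list))}}
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_map(path) -> SpectralMap:
    path = Path(path)
    with np.load(path) as data:
        wn = data["wavenumbers"]
        counts = data["counts"]
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return SpectralMap(wn, counts, step_um=float(meta["step_um"]),
                       dwell=float(meta["dwell"]),
                       meta=dict(meta.get("meta", {})))


def write_calibration_model(model: CalibrationModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2,
                                     sort_keys=True))


def read_calibration_model(path) -> CalibrationModel:
    return CalibrationModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Defaults carry the processing constants of the protocol: baseline
    window 1324-1379 cm^-1, integration window 1399-1419 cm^-1,
    polynomial baseline order 4 / 7 iterations / tolerance 15 counts,
    5 mM histogram bins, LOD test level 0.05.
    """

    out_dir: str = "fumamap_out"
    seed: int = 0
    preset: str = "KO19"
    control_preset: str = "WT"
    k: int = 6
    control_k: int = 8
    baseline_order: int = 4
    baseline_iterations: int = 7
    baseline_tolerance: float = 15.0
    bin_width_mm: float = 5.0
    lod_alpha: float = 0.05
    calibration_concs: tuple = tuple(range(0, 110, 10))
    calibration_replicates: int = 3
    calibration_dwell: float = 5.0
    dwell: float = 0.3
    method: str = "auc"

    def __post_init__(self) -> None:
        if self.method not in ("auc", "gauss"):
            raise ValueError("method must be 'auc' or 'gauss'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "calibration_concs" in raw:
            raw["calibration_concs"] = tuple(raw["calibration_concs"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["calibration_concs"] = list(self.calibration_concs)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in sorted(self.__dict__.items())}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(cfg: RunConfig) -> str:
    return f"# config: {cfg.digest()} seed: {cfg.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig,
               index: bool = True) -> None:
    with path.open("w") as fh:
        fh.write(_stamp(cfg))
        df.to_csv(fh, index=index)


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> calibrate -> quantify -> segment -> report.

    Generates a KO phantom and its FH-proficient control, fits the
    calibration and LOD from a synthetic dilution series, quantifies
    both maps, segments them, and writes the compartment table and its
    background-corrected variant plus histogram CSVs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    baseline = BaselineParams(config.baseline_order,
                              config.baseline_iterations,
                              config.baseline_tolerance)
    log.info("stage=calibrate concs=%s replicates=%d dwell=%.3g seed=%d",
             list(config.calibration_concs), config.calibration_replicates,
             config.dwell, config.seed)
    series = synth.generate_calibration_series(
        config.calibration_concs, replicates=config.calibration_replicates,
        dwell=config.calibration_dwell, seed=config.seed)
    model = fit_calibration(series, alpha=config.lod_alpha)
    model.lod = estimate_lod(series, alpha=config.lod_alpha)
    write_calibration_model(model, out / "calibration_model.json")

    tables = {}
    for tag, preset, k in (("control", config.control_preset,
                            config.control_k),
                           ("case", config.preset, config.k)):
        log.info("stage=simulate preset=%s seed=%d", preset, config.seed)
        cfg = synth.cell_phantom_config(preset, seed=config.seed,
                                        dwell=config.dwell)
        smap, truth = synth.generate_cell_phantom(cfg)
        smap = despike_map(smap)   # cosmic-ray removal precedes everything
        write_map(smap, out / f"{tag}_map.npz")
        log.info("stage=quantify method=%s baseline=%s", config.method,
                 baseline)
        cmap = concentration_map_auc(smap, model, baseline=baseline,
                                     despike=False)
        hist = concentration_histogram(cmap, bin_width=config.bin_width_mm,
                                       scan_id=tag)
        _write_csv(hist.to_frame(), out / f"{tag}_histogram.csv", config,
                   index=False)
        log.info("stage=segment k=%d seed=%d metric=manhattan", k,
                 config.seed)
        centered = mean_center_scan(smap)
        clusters = kmeans_manhattan(centered, k=k, seed=config.seed,
                                    original=smap)
        assignment = assign_compartments(clusters)
        _write_csv(assignment.scores.assign(
            compartment=[assignment.mapping[j]
                         for j in assignment.scores.index]),
            out / f"{tag}_assignment.csv", config)
        table = compartment_concentrations(cmap, assignment, clusters.labels,
                                           cell_line=preset)
        _write_csv(table.table, out / f"{tag}_compartments.csv", config)
        tables[tag] = (table, cmap, clusters, assignment)

    ko_table = tables["case"][0]
    wt_table = tables["control"][0]
    try:
        corrected = background_correct(ko_table, wt_table)
        _write_csv(corrected.table, out / "case_compartments_corrected.csv",
                   config)
    except ValueError as err:
        log.warning("stage=report background correction skipped: %s", err)
        corrected = None
    table, cmap, clusters, assignment = tables["case"]
    present = set(assignment.mapping.values())
    groups = tuple(g for g in ("membrane", "cytoplasm", "mitochondria")
                   if g in present)
    f_stat = p_val = None
    if len(groups) >= 2:
        f_stat, p_val = anova_compartments(cmap, clusters.labels,
                                           assignment, groups)
        log.info("stage=report anova groups=%s F=%.3g p=%.3g", groups,
                 f_stat, p_val)
    summary = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "sensitivity": model.sensitivity,
        "r_squared": model.r_squared,
        "lod_mM": model.lod,
        "anova_F": f_stat,
        "anova_p": p_val,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    return {"model": model, "tables": tables, "corrected": corrected,
            "summary": summary}
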