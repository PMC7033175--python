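"""End-to-end driver: simulate presets, process traces, gate, count, report.

Each stage writes its outputs plus a JSON run manifest recording the
configuration snapshot, seeds, package version, file checksums and per-stage
event counts, so a run can be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .circuit import InvalidParameterError
from .gating import (
    AGGREGATE_THRESHOLD_UV,
    snr_points,
    GateError,
    build_gate,
    classify_events,
    compare_populations,
    fit_amplitude_mixture,
    select_n_components,
    threshold_classify,
)
from .sigproc import FilterConfig, process_trace, read_events_csv, write_events_csv
from .synth import (
    REFERENCE_FREQUENCY_HZ,
    TraceConfig,
    amp_column,
    preset_config,
    preset_sample,
    read_trace_csv,
    read_trace_hdf5,
    write_event_log,
    write_trace_csv,
    write_trace_hdf5,
)

# scale (in bead-gate standard deviations) beyond which a mixture event is
# treated as clearly non-bead when estimating the aggregate cluster
BEAD_EXCLUSION_SCALE = 3.0


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_manifest(path: str | Path, manifest: dict) -> None:
    manifest = dict(manifest)
    manifest["impedcyto_version"] = __version__
    files = manifest.get("files", {})
    manifest["checksums"] = {
        name: file_sha256(p) for name, p in files.items() if Path(p).exists()
    }
    Path(path).write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True) + "\n")


def simulate_preset(
    preset: str,
    seed: int,
    out_dir: str | Path,
    fmt: str = "hdf5",
    config: TraceConfig | None = None,
) -> dict[str, Path]:
    """Simulate one preset sample; write trace, truth log and manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace, log = preset_sample(preset, seed, config)
    if fmt == "hdf5":
        trace_path = out_dir / f"{preset}_trace.h5"
        write_trace_hdf5(trace, trace_path)
    elif fmt == "csv":
        trace_path = out_dir / f"{preset}_trace.csv"
        write_trace_csv(trace, trace_path)
    else:
        raise InvalidParameterError(f"unknown trace format {fmt!r}")
    log_path = out_dir / f"{preset}_events_truth.csv"
    write_event_log(log, log_path)
    paths = {"trace": trace_path, "event_log": log_path}
    cfg = config if config is not None else preset_config(preset, seed)
    write_manifest(
        out_dir / f"{preset}_simulate_manifest.json",
        {
            "stage": "simulate",
            "preset": preset,
            "seed": seed,
            "config": dataclasses.asdict(cfg),
            "n_events": len(log),
            "files": {k: str(v) for k, v in paths.items()},
        },
    )
    return paths


def read_trace_any(path: str | Path):
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return read_trace_hdf5(path)
    return read_trace_csv(path)


def process_file(
    trace_path: str | Path,
    out_csv: str | Path,
    cfg: FilterConfig | None = None,
    reference_frequency_hz: float = REFERENCE_FREQUENCY_HZ,
) -> pd.DataFrame:
    """Filter a stored trace, detect events, write events CSV + manifest."""
    cfg = cfg or FilterConfig()
    trace = read_trace_any(trace_path)
    events, _, sigmas = process_trace(trace, cfg, reference_frequency_hz)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    write_events_csv(events, out_csv)
    write_manifest(
        out_csv.with_name(out_csv.stem + "_manifest.json"),
        {
            "stage": "process",
            "trace": str(trace_path),
            "filter": dataclasses.asdict(cfg),
            "reference_frequency_hz": reference_frequency_hz,
            "noise_sigma_uv": {f"{f:g}": s for f, s in sigmas.items()},
            "n_events": len(events),
            "files": {"events": str(out_csv)},
        },
    )
    return events


def analyze(
    bead_events: pd.DataFrame,
    cell_events: pd.DataFrame,
    mixture_events: pd.DataFrame,
    f_low_hz: float = REFERENCE_FREQUENCY_HZ,
    f_high_hz: float = 20e6,
    gate_scale: float = 1.0,
    threshold_uv: float = AGGREGATE_THRESHOLD_UV,
    seed: int = 0,
) -> dict:
    """Build gates from the calibration samples and count mixture aggregates.

    The bead and cell gates come from the pure calibration runs; the
    aggregate gate is fitted to the mixture events that are clearly outside
    the bead cluster (Mahalanobis distance above ``BEAD_EXCLUSION_SCALE``).
    """
    for name, ev in (("bead", bead_events), ("cell", cell_events), ("mixture", mixture_events)):
        if len(ev) == 0:
            raise GateError(f"{name} event set is empty; cannot analyze")

    bead_gate = build_gate(bead_events, f_low_hz, f_high_hz, gate_scale, name="beads")
    cell_gate = build_gate(cell_events, f_low_hz, f_high_hz, gate_scale, name="cells")

    d_bead = bead_gate.mahalanobis(snr_points(mixture_events, f_low_hz, f_high_hz))
    non_bead = mixture_events.loc[d_bead > BEAD_EXCLUSION_SCALE]
    if len(non_bead) < 3:
        raise GateError(
            "fewer than 3 mixture events fall outside the bead cluster; cannot "
            "estimate an aggregate gate"
        )
    aggregate_gate = build_gate(
        non_bead, f_low_hz, f_high_hz, gate_scale, name="mixture-aggregates"
    )

    labelled, gate_counts = classify_events(
        mixture_events, bead_gate, cell_gate, aggregate_gate
    )
    _, threshold_counts = threshold_classify(mixture_events, threshold_uv, f_low_hz)

    amp_col = amp_column(f_low_hz)
    bead_amps = bead_events[amp_col].to_numpy()
    cell_amps = cell_events[amp_col].to_numpy()
    mixture_amps = mixture_events[amp_col].to_numpy()

    comparison = compare_populations(bead_amps, cell_amps)
    fits = {
        "beads": fit_amplitude_mixture(bead_amps, 2, seed=seed, sample_name="beads").to_dict(),
        "cells": select_n_components(cell_amps, (1, 2), seed=seed, sample_name="cells").to_dict(),
        "mixture": fit_amplitude_mixture(
            mixture_amps, 2, seed=seed, sample_name="mixture"
        ).to_dict(),
    }
    bimodality = {
        name: {
            "bic_1": fit_amplitude_mixture(a, 1, seed=seed).bic,
            "bic_2": fit_amplitude_mixture(a, 2, seed=seed).bic,
        }
        for name, a in (("beads", bead_amps), ("mixture", mixture_amps))
    }

    return {
        "n_events": {
            "beads": len(bead_events),
            "cells": len(cell_events),
            "mixture": len(mixture_events),
        },
        "gates": {
            g.name: g.to_dict() for g in (bead_gate, cell_gate, aggregate_gate)
        },
        "gate_counts": gate_counts,
        "threshold_counts": threshold_counts,
        "threshold_uv": threshold_uv,
        "aggregate_count": gate_counts.get("aggregate", 0),
        "mixture_fits": fits,
        "bimodality_bic": bimodality,
        "bead_vs_cell": dataclasses.asdict(comparison),
        "labelled_mixture": labelled,
    }


def analyze_files(
    bead_csv: str | Path,
    cell_csv: str | Path,
    mixture_csv: str | Path,
    out_dir: str | Path,
    figures: bool = False,
    seed: int = 0,
    gate_scale: float = 1.0,
) -> dict:
    """File-level wrapper around :func:`analyze`; writes the report bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bead_events = read_events_csv(bead_csv)
    cell_events = read_events_csv(cell_csv)
    mixture_events = read_events_csv(mixture_csv)
    report = analyze(
        bead_events, cell_events, mixture_events, gate_scale=gate_scale, seed=seed
    )
    labelled = report.pop("labelled_mixture")

    labelled_path = out_dir / "mixture_events_labelled.csv"
    labelled.to_csv(labelled_path, index=False, float_format="%.8g")
    counts = pd.DataFrame(
        [
            {"method": "ellipse_gate", "label": k, "count": v}
            for k, v in report["gate_counts"].items()
        ]
        + [
            {"method": "threshold", "label": k, "count": v}
            for k, v in report["threshold_counts"].items()
        ]
    )
    counts_path = out_dir / "counts_summary.csv"
    counts.to_csv(counts_path, index=False)
    gates_path = out_dir / "gates.json"
    gates_path.write_text(json.dumps(_jsonable(report["gates"]), indent=2) + "\n")
    fits_path = out_dir / "mixture_fits.json"
    fits_path.write_text(json.dumps(_jsonable(report["mixture_fits"]), indent=2) + "\n")
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")

    files = {
        "labelled_mixture": labelled_path,
        "counts_summary": counts_path,
        "gates": gates_path,
        "mixture_fits": fits_path,
        "report": report_path,
    }
    if figures:
        files.update(
            make_figures(bead_events, cell_events, mixture_events, report, out_dir)
        )
    write_manifest(
        out_dir / "analyze_manifest.json",
        {
            "stage": "analyze",
            "inputs": {
                "beads": str(bead_csv),
                "cells": str(cell_csv),
                "mixture": str(mixture_csv),
            },
            "seed": seed,
            "gate_scale": gate_scale,
            "counts": report["gate_counts"],
            "files": {k: str(v) for k, v in files.items()},
        },
    )
    report["files"] = {k: str(v) for k, v in files.items()}
    return report


def make_figures(
    bead_events: pd.DataFrame,
    cell_events: pd.DataFrame,
    mixture_events: pd.DataFrame,
    report: dict,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Amplitude histogram and SNR scatter with 1-SD gate ellipses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    out_dir = Path(out_dir)
    amp_col = amp_column(REFERENCE_FREQUENCY_HZ)

    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(0, 40, 81)
    for ev, label, color in (
        (bead_events, "beads", "tab:red"),
        (cell_events, "cells", "tab:blue"),
        (mixture_events, "mixture", "black"),
    ):
        ax.hist(
            ev[amp_col], bins=bins, histtype="step", density=True, label=label, color=color
        )
    ax.axvline(report["threshold_uv"], ls="--", color="gray", lw=1)
    ax.set_xlabel("peak amplitude at 500 kHz (µV)")
    ax.set_ylabel("density")
    ax.legend()
    hist_path = out_dir / "amplitude_distributions.png"
    fig.tight_layout()
    fig.savefig(hist_path, dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 5))
    lo = f"snr_{int(REFERENCE_FREQUENCY_HZ)}"
    hi = "snr_20000000"
    for ev, label, color in (
        (bead_events, "beads", "tab:red"),
        (cell_events, "cells", "tab:green"),
        (mixture_events, "mixture", "tab:blue"),
    ):
        ax.scatter(ev[lo], ev[hi], s=8, alpha=0.5, label=label, color=color)
    for gate in report["gates"].values():
        mean = np.array(gate["mean"])
        cov = np.array(gate["covariance"])
        vals, vecs = np.linalg.eigh(cov)
        angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
        ell = Ellipse(
            mean,
            2 * gate["scale"] * np.sqrt(vals[-1]),
            2 * gate["scale"] * np.sqrt(vals[0]),
            angle=angle,
            fill=False,
            color="black",
            lw=1,
        )
        ax.add_patch(ell)
    ax.set_xlabel("SNR at 500 kHz")
    ax.set_ylabel("SNR at 20 MHz")
    ax.legend()
    scatter_path = out_dir / "snr_scatter.png"
    fig.tight_layout()
    fig.savefig(scatter_path, dpi=150)
    plt.close(fig)
    return {"amplitude_histogram": hist_path, "snr_scatter": scatter_path}


def run_full_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    figures: bool = False,
) -> dict:
    """Simulate all three presets, process each trace, and analyze.

    Per-stage seeds are derived from ``seed`` so the whole run reproduces
    byte-for-byte.
    """
    out_dir = Path(out_dir)
    seeds = derive_seeds(seed, len(("pure_beads", "pure_cells", "mixture")))
    event_paths = {}
    for preset, s in zip(("pure_beads", "pure_cells", "mixture"), seeds):
        paths = simulate_preset(preset, s, out_dir)
        out_csv = out_dir / f"{preset}_events.csv"
        process_file(paths["trace"], out_csv)
        event_paths[preset] = out_csv
    return analyze_files(
        event_paths["pure_beads"],
        event_paths["pure_cells"],
        event_paths["mixture"],
        out_dir / "analysis",
        figures=figures,
        seed=seed,
    )


def derive_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage seeds (< 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
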