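"""Plain-text readers and writers for the pipeline's tabular formats.

All writers emit deterministic output (sorted keys, fixed float formats) so
that identical inputs and seeds give byte-identical files.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml

from foldonkinetics.free_energy import FreeEnergyTable, WindowSamples
from foldonkinetics.flux import FluxMatrix
from foldonkinetics.network import ChevronCurve, RateMatrix

FLOAT_FMT = "{:.10g}"


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "nan"
    return FLOAT_FMT.format(float(x))


# -- frame observable tables -------------------------------------------------

def write_frames_tsv(window: WindowSamples) -> str:
    """window_id, frame, energy, global_q, q_1..q_N (one row per frame)."""
    if window.foldon_q is None:
        raise ValueError("window carries no per-foldon q values")
    n_fold = window.foldon_q.shape[1]
    header = ["window_id", "frame", "energy", "global_q"] + [
        f"q_{k + 1}" for k in range(n_fold)
    ]
    lines = ["\t".join(header)]
    for k in range(window.n_frames):
        row = [window.window_id, str(k), _fmt(window.energy[k]),
               _fmt(window.global_q[k])]
        row += [_fmt(q) for q in window.foldon_q[k]]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def read_frames_tsv(
    text: str,
    window_id: str,
    bias_center: float,
    bias_strength: float,
    temperature: float,
    threshold: float | None = None,
) -> WindowSamples:
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    n_fold = sum(1 for h in header if h.startswith("q_"))
    rows = [ln.split("\t") for ln in lines[1:]]
    energy = np.array([float(r[2]) for r in rows])
    global_q = np.array([float(r[3]) for r in rows])
    foldon_q = np.array([[float(x) for x in r[4 : 4 + n_fold]] for r in rows])
    labels = None
    if threshold is not None:
        labels = tuple(
            "".join("1" if q > threshold else "0" for q in row)
            for row in foldon_q
        )
    return WindowSamples(
        window_id=window_id,
        bias_center=bias_center,
        bias_strength=bias_strength,
        temperature=temperature,
        energy=energy,
        global_q=global_q,
        foldon_q=foldon_q,
        labels=labels,
    )


# -- window manifest ---------------------------------------------------------

def write_window_manifest(entries: list[dict]) -> str:
    """YAML manifest: list of {window_id, file, kappa, center, temperature}."""
    return yaml.safe_dump(
        {"windows": entries}, sort_keys=True, default_flow_style=False
    )


def read_window_manifest(text: str) -> list[dict]:
    data = yaml.safe_load(text)
    return data["windows"]


def load_windows(
    manifest_path: Path, threshold: float | None = None
) -> list[WindowSamples]:
    manifest_path = Path(manifest_path)
    entries = read_window_manifest(manifest_path.read_text())
    windows = []
    for e in entries:
        path = manifest_path.parent / e["file"]
        windows.append(
            read_frames_tsv(
                path.read_text(),
                window_id=str(e["window_id"]),
                bias_center=float(e["center"]),
                bias_strength=float(e["kappa"]),
                temperature=float(e["temperature"]),
                threshold=threshold,
            )
        )
    return windows


# -- labels ------------------------------------------------------------------

def write_labels_tsv(window_id: str, labels: list[str]) -> str:
    lines = ["window_id\tframe\tlabel"]
    for k, lab in enumerate(labels):
        lines.append(f"{window_id}\t{k}\t{lab}")
    return "\n".join(lines) + "\n"


# -- free-energy tables ------------------------------------------------------

def write_free_energy_tsv(table: FreeEnergyTable) -> str:
    lines = ["temperature\tlabel\tF_kT\tstderr_kT"]
    for lab in sorted(table.entries):
        err = table.stderr.get(lab) if table.stderr else None
        lines.append(
            f"{_fmt(table.temperature)}\t{lab}\t"
            f"{_fmt(table.entries[lab])}\t{_fmt(err)}"
        )
    return "\n".join(lines) + "\n"


def read_free_energy_tsv(text: str) -> FreeEnergyTable:
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    temperature = float(rows[0][0])
    entries = {r[1]: float(r[2]) for r in rows}
    stderr = {
        r[1]: float(r[3]) for r in rows if r[3] != "nan"
    } or None
    zeros = "0" * len(rows[0][1])
    gauge = zeros if zeros in entries and abs(entries[zeros]) < 1e-12 else min(
        entries, key=lambda a: entries[a]
    )
    # restore the stored gauge exactly
    if abs(entries[gauge]) > 1e-12:
        shift = entries[gauge]
        entries = {lab: v - shift for lab, v in entries.items()}
        entries[gauge] = 0.0
    return FreeEnergyTable(
        temperature=temperature, entries=entries, gauge=gauge, stderr=stderr
    )


# -- rate matrix, chevron, flux ----------------------------------------------

def write_rate_matrix_tsv(K: RateMatrix) -> str:
    lines = ["from_label\tto_label\trate_per_s"]
    for i, a in enumerate(K.labels):
        for j, b in enumerate(K.labels):
            if i == j or K.matrix[j, i] == 0.0:
                continue
            lines.append(f"{a}\t{b}\t{_fmt(K.matrix[j, i])}")
    return "\n".join(lines) + "\n"


def write_chevron_tsv(curve: ChevronCurve) -> str:
    lines = ["temperature\tstability_kT\tlog10_rate"]
    for (x, y), t in zip(curve.points, curve.temperatures):
        lines.append(f"{_fmt(t)}\t{_fmt(x)}\t{_fmt(y)}")
    return "\n".join(lines) + "\n"


def write_flux_tsv(J: FluxMatrix) -> str:
    """Positive net fluxes only (the antisymmetric partner is implied)."""
    lines = ["from_label\tto_label\tnet_flux"]
    for b in sorted(J.labels):
        for a in sorted(J.labels):
            if a == b:
                continue
            val = J.net(a, b)
            if val > 0:
                lines.append(f"{b}\t{a}\t{_fmt(val)}")
    return "\n".join(lines) + "\n"
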