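"""Readers and writers for the plain-text formats of the pipeline.

Formats
-------
* Sparky-style peak lists: whitespace table with header
  ``Assignment  w1  w2`` and rows like ``V35CG1-HG1  21.300  0.850``
  (w1 = indirect nucleus, w2 = 1H).  ``#`` lines are comments.
* Curve tables: TSV with columns residue_id, point_index, ligand_total_M,
  csp_ppm.
* 1D traces: two-column text (ppm, intensity) with ``#`` headers, plus a
  TSV manifest (file, ratio, receptor_total_M).
* EMSA lanes: TSV with columns lane_id, equivalents, density_free,
  density_b1, density_b2; a JSON config supplies nucleosome pmol and load
  volume.
* Fit reports: one JSON schema for every fitter (estimates, intervals,
  flags, diagnostics, seed, config digest).
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .csp import CspCurve, ShiftRecord
from .emsa import LaneDensities
from .lineshape import AcquisitionParams, SpectrumTrace
from .units import pmol_in_volume_to_molar

__all__ = [
    "read_peak_list",
    "write_peak_list",
    "read_curves",
    "write_curves",
    "read_trace",
    "write_trace",
    "read_trace_manifest",
    "write_lineshape_dataset",
    "read_lanes",
    "write_lanes",
    "write_report",
    "sha256_of_file",
]

_AA1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_AA3TO1 = {v: k for k, v in _AA1TO3.items()}

_ASSIGNMENT_RE = re.compile(r"^([A-Z])(\d+)([A-Z][A-Z0-9]*)-([A-Z][A-Z0-9]*)$")


def parse_assignment(token: str) -> tuple[int, str, str, str]:
    """Parse a Sparky assignment like ``V35CG1-HG1`` or ``G46N-H``.

    Returns (residue_id, residue_name, atom_x, atom_h).
    """
    m = _ASSIGNMENT_RE.match(token)
    if not m:
        raise ValueError(f"unparseable assignment token {token!r}")
    one, num, atom_x, atom_h = m.groups()
    if one not in _AA1TO3:
        raise ValueError(f"unknown residue code in assignment token {token!r}")
    return int(num), _AA1TO3[one], atom_x, atom_h


def read_peak_list(path, titration_index: int = 0) -> list[ShiftRecord]:
    """Read a Sparky-style peak list (``assignment w1 w2``) into records."""
    path = Path(path)
    records: list[ShiftRecord] = []
    seen: set[str] = set()
    lines = path.read_text().splitlines()
    body = [
        (n, ln) for n, ln in enumerate(lines, start=1)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not body:
        raise ValueError(f"{path}: empty peak list")
    start = 1 if body[0][1].split()[0].lower() == "assignment" else 0
    if not body[start:]:
        raise ValueError(f"{path}: peak list has a header but no rows")
    for n, ln in body[start:]:
        fields = ln.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{n}: expected 'assignment w1 w2', got {ln!r}")
        token = fields[0]
        if token in seen:
            raise ValueError(f"{path}:{n}: duplicate assignment {token!r}")
        seen.add(token)
        try:
            rid, rname, _, _ = parse_assignment(token)
        except ValueError as exc:
            raise ValueError(f"{path}:{n}: {exc}") from None
        try:
            w1, w2 = float(fields[1]), float(fields[2])
        except ValueError:
            raise ValueError(f"{path}:{n}: non-numeric shift in {ln!r}") from None
        records.append(ShiftRecord(rid, rname, shift_h=w2, shift_x=w1, titration_index=titration_index))
    return records


def write_peak_list(records: list[ShiftRecord], path, header_comment: str = "") -> None:
    """Write records as a Sparky-style peak list (amide N-H assignments)."""
    path = Path(path)
    out = []
    if header_comment:
        for line in header_comment.splitlines():
            out.append(f"# {line}")
    out.append(f"{'Assignment':<16s} {'w1':>10s} {'w2':>10s}")
    for r in records:
        one = _AA3TO1.get(r.residue_name, "X")
        out.append(f"{one}{r.residue_id}N-H".ljust(16) + f" {r.shift_x:10.4f} {r.shift_h:10.4f}")
    path.write_text("\n".join(out) + "\n")


def write_curves(curves: list[CspCurve], path) -> None:
    rows = []
    for c in curves:
        for i, (l0, y) in enumerate(zip(c.ligand_total, c.csp)):
            rows.append((c.residue_id, i, l0, y))
    df = pd.DataFrame(rows, columns=["residue_id", "point_index", "ligand_total_M", "csp_ppm"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_curves(path, receptor_total: float) -> list[CspCurve]:
    df = pd.read_csv(path, sep="\t")
    curves = []
    for rid, grp in df.groupby("residue_id"):
        grp = grp.sort_values("point_index")
        curves.append(
            CspCurve(int(rid), grp["csp_ppm"].to_numpy(), grp["ligand_total_M"].to_numpy(), receptor_total)
        )
    return curves


def write_trace(trace: SpectrumTrace, path, header_comment: str = "") -> None:
    path = Path(path)
    out = []
    if header_comment:
        for line in header_comment.splitlines():
            out.append(f"# {line}")
    for x, y in zip(trace.ppm, trace.intensity):
        out.append(f"{x:.8f}\t{y:.10e}")
    path.write_text("\n".join(out) + "\n")


def read_trace(path, acquisition: AcquisitionParams | None = None) -> SpectrumTrace:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return SpectrumTrace(data[:, 0], data[:, 1], acquisition)


def write_lineshape_dataset(traces, manifest: dict, out_dir) -> Path:
    """Write one trace file per titration point and the TSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (tr, ratio) in enumerate(zip(traces, manifest["ratios"])):
        name = f"trace_{i:02d}.xy"
        write_trace(
            tr, out_dir / name,
            header_comment=f"ratio={ratio} receptor_total_M={manifest['receptor_total_M']} seed={manifest.get('seed')}",
        )
        rows.append((name, ratio, manifest["receptor_total_M"]))
    df = pd.DataFrame(rows, columns=["file", "ratio", "receptor_total_M"])
    manifest_path = out_dir / "manifest.tsv"
    df.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_trace_manifest(manifest_path, acquisition: AcquisitionParams | None = None):
    """Read a manifest and its traces; returns (traces, ratios, receptor_total)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    traces, ratios = [], []
    for row in df.itertuples(index=False):
        tr = read_trace(manifest_path.parent / row.file, acquisition)
        tr.ratio = float(row.ratio)
        traces.append(tr)
        ratios.append(float(row.ratio))
    receptor = float(df["receptor_total_M"].iloc[0])
    return traces, ratios, receptor


def write_lanes(lanes: list[LaneDensities], path) -> None:
    df = pd.DataFrame(
        [
            (l.lane_id, l.equivalents, l.density_free, l.density_b1, l.density_b2)
            for l in lanes
        ],
        columns=["lane_id", "equivalents", "density_free", "density_b1", "density_b2"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_lanes(path, config: dict | None = None, receptor_total: float | None = None) -> list[LaneDensities]:
    """Read a lane TSV; receptor concentration from config {nucleosome_pmol, load_volume_ul} or given directly."""
    if receptor_total is None:
        if config is None:
            raise ValueError("provide receptor_total or a config with nucleosome_pmol and load_volume_ul")
        receptor_total = pmol_in_volume_to_molar(config["nucleosome_pmol"], config["load_volume_ul"])
    df = pd.read_csv(path, sep="\t")
    return [
        LaneDensities(
            equivalents=float(r.equivalents),
            density_free=float(r.density_free),
            density_b1=float(r.density_b1),
            density_b2=float(r.density_b2),
            receptor_total=receptor_total,
            lane_id=str(r.lane_id),
        )
        for r in df.itertuples(index=False)
    ]


def sha256_of_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(path, analysis: str, estimates: dict, intervals: dict | None = None,
                 flags: dict | None = None, diagnostics: dict | None = None,
                 seed: int | None = None, inputs: list | None = None) -> dict:
    """Write the uniform JSON fit report; returns the report dict."""

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            obj = obj.item()
        if isinstance(obj, float) and not np.isfinite(obj):
            return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
        return obj

    report = {
        "analysis": analysis,
        "estimates": _clean(estimates),
        "intervals": _clean(intervals or {}),
        "flags": _clean(flags or {}),
        "diagnostics": _clean(diagnostics or {}),
        "seed": seed,
        "inputs": [
            {"path": str(p), "sha256": sha256_of_file(p)} for p in (inputs or [])
        ],
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
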