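"""File formats and result provenance.

Conventions: trace coordinates and scattering curves are in nm / nm^-1,
imaging in um.  Traces travel as CSV with columns (molecule_id, point_index,
x_nm, y_nm); scattering curves as whitespace 3-column text (q_nm^-1, I,
sigma) with a ``# d2o_fraction: x`` header line; image stacks as multi-page
TIFF with pixel size supplied alongside; configs as YAML.  Result JSON files
carry a provenance block (package version, seed, SHA-256 of the
configuration) so a run can be reproduced from its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .buffers import BufferSpec, Species
from .channels import ExtensionRecord
from .gyration import Frame
from .sans import ScatteringCurve
from .wlc import ContourTrace

__all__ = [
    "read_traces",
    "write_traces",
    "read_scattering",
    "write_scattering",
    "read_buffer_spec",
    "read_records",
    "write_records",
    "read_stack",
    "write_stack",
    "write_result",
]

TRACE_COLUMNS = ["molecule_id", "point_index", "x_nm", "y_nm"]


def read_traces(path) -> list[ContourTrace]:
    """Read an ensemble of traced contours from CSV.

    Rows are grouped by ``molecule_id`` and ordered by ``point_index``
    (0-based); duplicate (id, index) pairs are rejected with their line
    numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; expected {TRACE_COLUMNS}")
    dup = df.duplicated(subset=["molecule_id", "point_index"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # 1-based + header
        raise ValueError(f"{path}: duplicate (molecule_id, point_index) at lines {lines}")
    bad = df[df[["x_nm", "y_nm", "point_index"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed rows at lines {(bad.index + 2).tolist()}")
    traces = []
    for mol, g in df.groupby("molecule_id", sort=True):
        g = g.sort_values("point_index")
        traces.append(ContourTrace(str(mol), g[["x_nm", "y_nm"]].to_numpy(dtype=float)))
    return traces


def write_traces(path, traces: Sequence[ContourTrace]) -> None:
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(t.points):
            rows.append((t.id, i, x, y))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_scattering(path) -> ScatteringCurve:
    """Read a (q, I, sigma) curve; the D2O fraction rides in a header line."""
    path = Path(path)
    d2o = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("d2o_fraction"):
                    d2o = float(body.split(":", 1)[1])
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            q, I, s = map(float, parts)
            if s <= 0:
                raise ValueError(f"{path}:{lineno}: sigma must be positive")
            rows.append((q, I, s))
    if d2o is None:
        raise ValueError(f"{path}: missing required header '# d2o_fraction: <x>'")
    arr = np.asarray(rows)
    if len(arr) == 0:
        raise ValueError(f"{path}: no data rows")
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], d2o_fraction=d2o)


def write_scattering(path, curve: ScatteringCurve) -> None:
    with open(path, "w") as fh:
        fh.write(f"# d2o_fraction: {curve.d2o_fraction!r}\n")
        fh.write("# q_nm^-1 I sigma\n")
        for q, I, s in zip(curve.q, curve.I, curve.sigma):
            fh.write(f"{float(q)!r} {float(I)!r} {float(s)!r}\n")


def read_buffer_spec(path) -> BufferSpec:
    """Buffer composition from YAML: {pH: x, species: [{name, conc_mM, charge, pK?}]}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "pH" not in doc or "species" not in doc:
        raise ValueError(f"{path}: buffer spec needs 'pH' and 'species' keys")
    species = [
        Species(
            name=s["name"],
            conc_mM=float(s["conc_mM"]),
            charge=int(s.get("charge", 1)),
            pK=float(s["pK"]) if "pK" in s and s["pK"] is not None else None,
        )
        for s in doc["species"]
    ]
    return BufferSpec(species, pH=float(doc["pH"]))


RECORD_COLUMNS = ["id", "extension_um", "peak_to_background", "condensed", "concentration_uM"]


def write_records(path, records: Sequence[ExtensionRecord], ids: Optional[Sequence] = None) -> None:
    if ids is None:
        ids = [f"mol{i:04d}" for i in range(len(records))]
    rows = [
        (i, r.extension_um, r.peak_to_background, r.condensed, r.concentration_uM)
        for i, r in zip(ids, records)
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records(path) -> list[ExtensionRecord]:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ExtensionRecord(
                extension_um=float(row.extension_um),
                peak_to_background=float(row.peak_to_background),
                condensed=None if pd.isna(row.condensed) else bool(row.condensed),
                concentration_uM=None
                if pd.isna(row.concentration_uM)
                else float(row.concentration_uM),
            )
        )
    return out


def write_stack(path, frames: Sequence[Frame]) -> None:
    data = np.stack([f.intensity for f in frames]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_stack(path, pixel_size_um: float) -> list[Frame]:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return [Frame(np.asarray(img, dtype=float), pixel_size_um) for img in data]


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_result(path, payload: dict, config: dict, seed: Optional[int] = None) -> dict:
    """Write a result JSON with a provenance block; returns the document."""
    from . import __version__

    doc = dict(payload)
    doc["provenance"] = {
        "package": "nucleocompact",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": _config_hash(config),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return doc


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
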