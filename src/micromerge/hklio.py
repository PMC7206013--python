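"""Reading and writing SHELX-style reflection files and metadata sidecars.

The reflection format is the fixed-width SHELX HKLF record::

    3I4, 2F8.2, optional I4 batch column

i.e. ``h k l I sigI [batch]`` with 4-character index fields and 8-character
intensity fields.  The optional batch column carries the frame id.  Per-crystal
metadata (unit cell, wedge geometry, wavelength, space group) travels in a
YAML sidecar, one document per crystal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
import yaml

from .datasets import OBS_COLUMNS, CrystalDataset, validate_observation_table
from .symmetry import SpaceGroup, UnitCell

__all__ = ["read_hkl", "write_hkl", "read_metadata", "write_metadata", "HklParseError"]


class HklParseError(ValueError):
    """Raised when an hkl file yields no usable observations."""


@dataclass(frozen=True)
class LineDiagnostic:
    line_number: int
    message: str
    text: str

    def __str__(self) -> str:
        return f"line {self.line_number}: {self.message}: {self.text!r}"


def read_hkl(
    path: str | os.PathLike,
    crystal_id: str | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, list[LineDiagnostic]]:
    """Parse a SHELX-style hkl file into an observation table.

    Malformed lines are collected as diagnostics with their line numbers;
    with ``strict=True`` any diagnostic raises instead.  The all-zero
    ``0 0 0`` terminator record conventionally ending SHELX files is ignored.
    """
    if crystal_id is None:
        crystal_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    rows: list[tuple] = []
    diagnostics: list[LineDiagnostic] = []
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parsed = _parse_line(line)
            if isinstance(parsed, str):
                diagnostics.append(LineDiagnostic(lineno, parsed, line))
                continue
            h, k, l, intensity, sigma, frame = parsed
            if (h, k, l) == (0, 0, 0):
                continue  # terminator record
            if sigma <= 0:
                diagnostics.append(LineDiagnostic(lineno, "sigma must be > 0", line))
                continue
            rows.append((h, k, l, intensity, sigma, frame, crystal_id))
    if strict and diagnostics:
        raise HklParseError("; ".join(str(d) for d in diagnostics))
    table = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
    if len(table):
        table = validate_observation_table(table)
    return table, diagnostics


def _parse_line(line: str) -> tuple[int, int, int, float, float, int] | str:
    # whitespace tokens cover both free-format fixtures and fixed-width
    # records whose fields keep their separators; fall back to strict
    # 3I4,2F8.2,I4 slicing when full-width values run fields together
    fields = line.split()
    if not 5 <= len(fields) <= 6 and len(line) >= 28:
        fields = [line[0:4], line[4:8], line[8:12], line[12:20], line[20:28]]
        batch = line[28:32]
        if batch.strip():
            fields.append(batch)
    if len(fields) < 5:
        return "expected at least 5 fields (h k l I sigI)"
    try:
        h, k, l = (int(f) for f in fields[:3])
    except ValueError:
        return "non-integer Miller index"
    try:
        intensity = float(fields[3])
        sigma = float(fields[4])
    except ValueError:
        return "non-numeric intensity or sigma"
    frame = 0
    if len(fields) > 5 and fields[5].strip():
        try:
            frame = int(fields[5])
        except ValueError:
            return "non-integer batch number"
    return h, k, l, intensity, sigma, frame


def write_hkl(table: pd.DataFrame, path: str | os.PathLike, batch_column: bool = True) -> None:
    """Write an observation table (or merged intensities) as SHELX records."""
    table = table.copy()
    with open(path, "w", encoding="ascii") as fh:
        for row in table.itertuples(index=False):
            h, k, l = int(row.h), int(row.k), int(row.l)
            if not all(-999 <= x <= 9999 for x in (h, k, l)):
                raise ValueError(f"Miller index {(h, k, l)} overflows the I4 field")
            rec = f"{h:4d}{k:4d}{l:4d}{row.intensity:8.2f}{row.sigma:8.2f}"
            if batch_column and hasattr(row, "frame"):
                rec += f"{int(row.frame):4d}"
            fh.write(rec + "\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


def write_metadata(datasets: Sequence[CrystalDataset], path: str | os.PathLike, space_group: SpaceGroup | None = None) -> None:
    docs = []
    for ds in datasets:
        docs.append(
            {
                "crystal_id": ds.crystal_id,
                "cell": [float(x) for x in ds.cell.parameters()],
                "wedge_start": float(ds.wedge_start),
                "wedge_width": float(ds.wedge_width),
                "wavelength": float(ds.wavelength),
            }
        )
    payload: dict = {"crystals": docs}
    if space_group is not None:
        payload["space_group"] = {
            "symbol": space_group.symbol,
            "operators": [str(op) for op in space_group.ops],
            "friedel_merged": space_group.friedel_merged,
        }
    with open(path, "w", encoding="ascii") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_metadata(path: str | os.PathLike) -> tuple[list[dict], SpaceGroup | None]:
    with open(path, "r", encoding="ascii") as fh:
        payload = yaml.safe_load(fh)
    crystals = payload.get("crystals", [])
    sg = None
    if "space_group" in payload:
        sgd = payload["space_group"]
        sg = SpaceGroup(
            sgd.get("symbol", "custom"),
            ops=sgd.get("operators"),
            friedel_merged=bool(sgd.get("friedel_merged", True)),
        )
    for c in crystals:
        c["cell"] = UnitCell(*c["cell"])
    return crystals, sg
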