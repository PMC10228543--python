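"""Plain-text peak-table formats, manifests, and convenience readers."""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from .simulate import COLUMNS


class FormatError(ValueError):
    """A peak table does not conform to the expected schema."""


def write_peak_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a peak table as TSV with the fixed column header."""
    table = table.loc[:, list(COLUMNS)]
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a peak-table TSV, validating the header and basic invariants."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if (df["noise"].dropna() <= 0).any():
        bad = df.index[df["noise"] <= 0][0]
        raise FormatError(f"{path}: non-positive noise at line {bad + 2}")
    return df.astype({"salt_mM": int, "residue": int, "peak_id": int})


def write_manifest(path: str | Path, **fields) -> None:
    """Record generator parameters and seeds for byte-reproducible reruns."""
    from dataclasses import asdict, is_dataclass

    def default(obj):
        if is_dataclass(obj):
            return asdict(obj)
        if hasattr(obj, "tolist"):
            return obj.tolist()
        return str(obj)

    Path(path).write_text(json.dumps(fields, indent=2, default=default, sort_keys=True))


_SPARKY_ASSIGNMENT = re.compile(r"^([A-Za-z])(\d+)N-?H$", re.IGNORECASE)


def read_sparky_peaks(path: str | Path) -> pd.DataFrame:
    """Import a Sparky-style amide peak list (assignment, w1, w2[, height]).

    Assignments like ``T22N-H``; w1 is the 15N shift and w2 the 1H shift.
    Returns residue/dN_ppm/dH_ppm/intensity columns matching the HSQC rows of
    the native schema.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected assignment w1 w2 [height]")
        m = _SPARKY_ASSIGNMENT.match(parts[0])
        if not m:
            raise FormatError(f"{path}:{lineno}: unrecognized assignment {parts[0]!r}")
        rows.append(
            dict(
                residue=int(m.group(2)),
                peak_id=1,
                dN_ppm=float(parts[1]),
                dH_ppm=float(parts[2]),
                intensity=float(parts[3]) if len(parts) > 3 else float("nan"),
                experiment="HSQC",
            )
        )
    return pd.DataFrame(rows)
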