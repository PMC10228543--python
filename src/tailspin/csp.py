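"""Chemical shift perturbations between WT and mutant amide peak tables.

CSPs use the standard weighted combination of amide 1H and 15N shift
differences, delta = sqrt(dH^2 + 0.154*dN^2).  Doublet peaks (NCP-asymmetry
splittings seen at 0 mM KCl) follow the rule that when one side of the
comparison is a singlet, both peaks of the other side are compared against it
and both values are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence import TAIL_LENGTH, construct_mutations

#: Weight applied to the 15N shift difference (amide 1H/15N shift-range scaling).
N_WEIGHT = 0.154


class CSPError(ValueError):
    """Invalid CSP input."""


@dataclass(frozen=True)
class ShiftEntry:
    residue: int
    peak_id: int
    dH: float
    dN: float


def compute_csp(delta_H: float, delta_N: float, n_weight: float = N_WEIGHT) -> float:
    """Weighted CSP: sqrt(dH^2 + 0.154*dN^2); symmetric under sign flips."""
    if not (math.isfinite(delta_H) and math.isfinite(delta_N)):
        raise CSPError("shift differences must be finite")
    return math.sqrt(delta_H**2 + n_weight * delta_N**2)


def pair_peaks(
    wt: list[ShiftEntry] | None, mut: list[ShiftEntry] | None
) -> list[tuple[ShiftEntry, ShiftEntry, str]]:
    """Pairing plan for one residue's WT and mutant peaks.

    singlet-singlet: one pair; singlet(WT)-doublet(mut): both mutant peaks
    against the WT peak; doublet-doublet: matched by peak id; doublet(WT)-
    singlet(mut): both WT peaks against the mutant peak (mirror rule).
    Returns (wt_entry, mut_entry, pairing label) tuples; empty when the
    residue is absent on either side.
    """
    if not wt or not mut:
        return []
    if len(wt) > 2 or len(mut) > 2:
        raise CSPError(
            f"residue {max(wt or mut, key=lambda e: e.residue).residue}: "
            ">2 peaks per residue"
        )
    if len(wt) == 1 and len(mut) == 1:
        return [(wt[0], mut[0], "1:1")]
    if len(wt) == 1:
        return [(wt[0], m, f"1:{m.peak_id}") for m in sorted(mut, key=lambda e: e.peak_id)]
    if len(mut) == 1:
        return [(w, mut[0], f"{w.peak_id}:1") for w in sorted(wt, key=lambda e: e.peak_id)]
    by_id = {m.peak_id: m for m in mut}
    pairs = []
    for w in sorted(wt, key=lambda e: e.peak_id):
        if w.peak_id in by_id:
            pairs.append((w, by_id[w.peak_id], f"{w.peak_id}:{w.peak_id}"))
    return pairs


@dataclass(frozen=True)
class CSPValue:
    pairing: str
    csp: float
    mutated_site: bool


@dataclass
class CSPProfile:
    """Per-residue CSPs with missing bookkeeping; mutated positions flagged."""

    construct: str
    salt_mM: int
    values: dict[int, list[CSPValue]] = field(default_factory=dict)
    missing: dict[int, str] = field(default_factory=dict)

    def residue_max(self, position: int) -> float:
        return max(v.csp for v in self.values[position])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in range(1, TAIL_LENGTH + 1):
            if pos in self.values:
                for v in self.values[pos]:
                    rows.append(
                        dict(
                            residue=pos,
                            pairing=v.pairing,
                            csp_ppm=v.csp,
                            flag="mutated" if v.mutated_site else "",
                            status="ok",
                        )
                    )
            else:
                rows.append(
                    dict(
                        residue=pos,
                        pairing="",
                        csp_ppm=np.nan,
                        flag="",
                        status=self.missing.get(pos, "not observed"),
                    )
                )
        return pd.DataFrame(rows)


def _entries_by_residue(table: pd.DataFrame) -> dict[int, list[ShiftEntry]]:
    sub = table[table["experiment"] == "HSQC"]
    out: dict[int, list[ShiftEntry]] = {}
    for row in sub.itertuples():
        out.setdefault(int(row.residue), []).append(
            ShiftEntry(int(row.residue), int(row.peak_id), float(row.dH_ppm), float(row.dN_ppm))
        )
    for entries in out.values():
        entries.sort(key=lambda e: e.peak_id)
    return out


def csp_profile(
    wt_table: pd.DataFrame, mut_table: pd.DataFrame, n_weight: float = N_WEIGHT
) -> CSPProfile:
    """CSP profile of a mutant against WT (same salt condition).

    CSPs at mutated positions reflect the residue-type change itself; they are
    reported but flagged so aggregate statements can exclude them.
    """
    wt_salt = int(wt_table["salt_mM"].iloc[0])
    mut_salt = int(mut_table["salt_mM"].iloc[0])
    if wt_salt != mut_salt:
        raise CSPError(f"salt mismatch: WT at {wt_salt} mM, mutant at {mut_salt} mM")
    construct = str(mut_table["construct"].iloc[0])
    mutated = {
        int(lbl[1:-1]) for lbl in construct_mutations(construct)
    } if construct.upper() != "WT" else set()
    wt_entries = _entries_by_residue(wt_table)
    mut_entries = _entries_by_residue(mut_table)
    values: dict[int, list[CSPValue]] = {}
    missing: dict[int, str] = {}
    for pos in range(1, TAIL_LENGTH + 1):
        pairs = pair_peaks(wt_entries.get(pos), mut_entries.get(pos))
        if not pairs:
            missing[pos] = "not observed"
            continue
        values[pos] = [
            CSPValue(
                label,
                compute_csp(w.dH - m.dH, w.dN - m.dN, n_weight),
                pos in mutated,
            )
            for w, m, label in pairs
        ]
    return CSPProfile(construct, wt_salt, values, missing)
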