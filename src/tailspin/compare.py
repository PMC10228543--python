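"""WT-vs-mutant difference profiles, ranking, region detection, additivity.

The difference convention is Delta = WT - mutant, so a positive DeltahnNOE or
Delta(R2/R1) means the mutant tail is more mobile on the ps-ns timescale.
The breadth of a mutation's effect is the inclusive residue span of a run of
at least three residues whose difference exceeds the combined error bar, with
single-residue interruptions tolerated; invisible residues inside a run are
spanned without breaking it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relaxation import PeakValue, ResidueProfile
from .sequence import ResidueID, TAIL_LENGTH, count_residue_range, construct_sequence


class CompareError(ValueError):
    """Invalid profile comparison."""


@dataclass(frozen=True)
class DeltaEntry:
    pairing: str
    delta: float
    error: float  # quadrature of the two sides
    error_wt: float
    error_mut: float


@dataclass
class DeltaProfile:
    """Per-residue WT-minus-mutant differences with combined errors."""

    construct: str
    observable: str
    salt_mM: int
    values: dict[int, list[DeltaEntry]] = field(default_factory=dict)
    missing: dict[int, str] = field(default_factory=dict)

    def residue_delta(self, position: int) -> float:
        """Pairing-mean difference at a residue."""
        return float(np.mean([e.delta for e in self.values[position]]))

    def residue_error(self, position: int) -> float:
        entries = self.values[position]
        return float(np.sqrt(sum(e.error**2 for e in entries)) / len(entries))

    def residue_error_wt(self, position: int) -> float:
        entries = self.values[position]
        return float(np.sqrt(sum(e.error_wt**2 for e in entries)) / len(entries))

    def residue_error_mut(self, position: int) -> float:
        entries = self.values[position]
        return float(np.sqrt(sum(e.error_mut**2 for e in entries)) / len(entries))

    @property
    def positions(self) -> list[int]:
        return sorted(self.values)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in range(1, TAIL_LENGTH + 1):
            if pos in self.values:
                for e in self.values[pos]:
                    rows.append(
                        dict(
                            residue=pos,
                            pairing=e.pairing,
                            observable=self.observable,
                            delta=e.delta,
                            error=e.error,
                            status="ok",
                        )
                    )
            else:
                rows.append(
                    dict(
                        residue=pos,
                        pairing="",
                        observable=self.observable,
                        delta=np.nan,
                        error=np.nan,
                        status=self.missing.get(pos, "not observed"),
                    )
                )
        return pd.DataFrame(rows)


def _pair_peak_values(
    wt: list[PeakValue], mut: list[PeakValue]
) -> list[tuple[PeakValue, PeakValue, str]]:
    """Doublet pairing rules applied to per-peak observable values."""
    if len(wt) > 2 or len(mut) > 2:
        raise CompareError(">2 peaks per residue")
    if len(wt) == 1 and len(mut) == 1:
        return [(wt[0], mut[0], "1:1")]
    if len(wt) == 1:
        return [(wt[0], m, f"1:{m.peak_id}") for m in sorted(mut, key=lambda v: v.peak_id)]
    if len(mut) == 1:
        return [(w, mut[0], f"{w.peak_id}:1") for w in sorted(wt, key=lambda v: v.peak_id)]
    by_id = {m.peak_id: m for m in mut}
    return [
        (w, by_id[w.peak_id], f"{w.peak_id}:{w.peak_id}")
        for w in sorted(wt, key=lambda v: v.peak_id)
        if w.peak_id in by_id
    ]


def delta_profile(wt: ResidueProfile, mut: ResidueProfile) -> DeltaProfile:
    """Delta = WT - mutant per pairing, errors combined in quadrature."""
    if wt.kind != mut.kind:
        raise CompareError(f"observable mismatch: {wt.kind} vs {mut.kind}")
    if wt.salt_mM != mut.salt_mM:
        raise CompareError(f"salt mismatch: {wt.salt_mM} vs {mut.salt_mM} mM")
    values: dict[int, list[DeltaEntry]] = {}
    missing: dict[int, str] = {}
    for pos in range(1, TAIL_LENGTH + 1):
        if pos in wt.values and pos in mut.values:
            entries = []
            for w, m, label in _pair_peak_values(wt.values[pos], mut.values[pos]):
                entries.append(
                    DeltaEntry(
                        label,
                        w.value - m.value,
                        math.sqrt(w.error**2 + m.error**2),
                        w.error,
                        m.error,
                    )
                )
            if entries:
                values[pos] = entries
            else:
                missing[pos] = "no matching peaks"
        else:
            missing[pos] = wt.missing.get(pos) or mut.missing.get(pos) or "not observed"
    return DeltaProfile(mut.construct, wt.kind, wt.salt_mM, values, missing)


def summed_delta(profile: DeltaProfile) -> float:
    """Sum of per-residue differences across the tail.

    Doublet residues contribute the mean of their pairings; missing residues
    contribute nothing.  This is the area between the WT and mutant profiles
    and captures both magnitude and breadth of the effect.
    """
    return float(sum(profile.residue_delta(p) for p in profile.positions))


@dataclass(frozen=True)
class RankedMutant:
    construct: str
    summed_delta: float
    tied_with: tuple[str, ...] = ()


def rank_mutants(profiles: dict[str, DeltaProfile]) -> list[RankedMutant]:
    """Order constructs by descending summed difference; ties flagged."""
    if not profiles:
        raise CompareError("no profiles to rank")
    kinds = {p.observable for p in profiles.values()}
    salts = {p.salt_mM for p in profiles.values()}
    if len(kinds) > 1 or len(salts) > 1:
        raise CompareError(f"mixed observables/salts: {kinds}, {salts}")
    sums = {name: summed_delta(p) for name, p in profiles.items()}
    ordered = sorted(sums, key=lambda name: (-sums[name], name))
    out = []
    for name in ordered:
        ties = tuple(
            other
            for other in ordered
            if other != name and math.isclose(sums[other], sums[name], rel_tol=0, abs_tol=1e-12)
        )
        out.append(RankedMutant(name, sums[name], ties))
    return out


# --- affected-region detection ---------------------------------------------


@dataclass(frozen=True)
class AffectedRegion:
    start: ResidueID
    end: ResidueID
    residue_count: int
    interrupted_positions: tuple[int, ...] = ()

    @property
    def label(self) -> str:
        return f"{self.start.label}-{self.end.label}"


def _qualifies(profile: DeltaProfile, pos: int, k: float, criterion: str) -> bool:
    """A residue qualifies when any pairing clears its error bar."""
    for e in profile.values[pos]:
        err = e.error if criterion == "quadrature" else e.error_wt + e.error_mut
        if abs(e.delta) > k * err:
            return True
    return False


def detect_affected_regions(
    profile: DeltaProfile,
    k: float = 1.0,
    criterion: str = "quadrature",
    min_qualifying: int = 3,
) -> list[AffectedRegion]:
    """Find runs of at least ``min_qualifying`` residues clearing their errors.

    A residue qualifies when |Delta| strictly exceeds k times the combined
    error (``criterion="quadrature"``: errors combined in quadrature;
    ``"sum"``: sum of the two half-widths) for at least one of its pairings.
    Missing residues are skipped without breaking a run but are counted in the
    inclusive span; a run tolerates interruptions of at most one consecutive
    observed non-qualifying residue; run endpoints must qualify.  Maximal
    runs are returned N-terminus first.
    """
    if criterion not in ("quadrature", "sum"):
        raise CompareError(f"unknown overlap criterion {criterion!r}")
    seq = construct_sequence("WT")
    observed = profile.positions
    qual = {p: _qualifies(profile, p, k, criterion) for p in observed}
    # split the observed sequence wherever two consecutive observed residues
    # both fail to qualify; within each segment trim to qualifying endpoints
    segments: list[list[int]] = []
    current: list[int] = []
    for i, pos in enumerate(observed):
        if (
            current
            and not qual[pos]
            and not qual[current[-1]]
        ):
            segments.append(current)
            current = [pos]
        else:
            current.append(pos)
    if current:
        segments.append(current)
    regions = []
    for seg in segments:
        qual_positions = [p for p in seg if qual[p]]
        if len(qual_positions) < min_qualifying:
            continue
        start, end = qual_positions[0], qual_positions[-1]
        interruptions = tuple(
            p for p in seg if start < p < end and not qual[p]
        )
        rid_start = ResidueID(start, seq.code_at(start))
        rid_end = ResidueID(end, seq.code_at(end))
        regions.append(
            AffectedRegion(
                rid_start,
                rid_end,
                count_residue_range(rid_start, rid_end),
                interruptions,
            )
        )
    return regions


def region_breadth(regions: list[AffectedRegion]) -> int:
    """Total inclusive residue count over all detected regions."""
    return sum(r.residue_count for r in regions)


# --- additivity -------------------------------------------------------------


@dataclass
class AdditivityResult:
    """Per-residue discrepancy between summed single-mutant and quadruple deltas.

    ``discrepancy`` = sum of the four single-mutant deltas minus the quadruple
    delta; ``error`` is its standard error from full propagation (the shared
    WT profile enters the sum four times and the quadruple delta once, leaving
    WT multiplicity three in the discrepancy).  ``consistent`` marks residues
    where the error bars of the two compared curves (the summed-singles curve
    and the quadruple-delta curve) overlap.
    """

    frame: pd.DataFrame
    mean_abs_discrepancy: float
    fraction_consistent: float


def additivity_discrepancy(
    singles: dict[str, DeltaProfile], quadruple: DeltaProfile
) -> AdditivityResult:
    """Test whether single-arginine effects add up to the quadruple effect."""
    if len(singles) != 4:
        raise CompareError(f"expected four single-mutant profiles, got {len(singles)}")
    profiles = list(singles.values()) + [quadruple]
    kinds = {p.observable for p in profiles}
    salts = {p.salt_mM for p in profiles}
    if len(kinds) > 1 or len(salts) > 1:
        raise CompareError(f"mixed observables/salts: {kinds}, {salts}")
    shared = sorted(
        set(quadruple.positions).intersection(*(p.positions for p in singles.values()))
    )
    rows = []
    for pos in shared:
        s_deltas = [p.residue_delta(pos) for p in singles.values()]
        s_mut_vars = [p.residue_error_mut(pos) ** 2 for p in singles.values()]
        wt_var = quadruple.residue_error_wt(pos) ** 2
        q_mut_var = quadruple.residue_error_mut(pos) ** 2
        sum_singles = float(np.sum(s_deltas))
        d = sum_singles - quadruple.residue_delta(pos)
        # full propagation: D = 3*WT - sum(mut_i) + quad
        err = math.sqrt(9 * wt_var + sum(s_mut_vars) + q_mut_var)
        # error bars of the two compared curves
        err_sum_curve = math.sqrt(16 * wt_var + sum(s_mut_vars))
        err_quad_curve = math.sqrt(wt_var + q_mut_var)
        rows.append(
            dict(
                residue=pos,
                sum_singles=sum_singles,
                quadruple=quadruple.residue_delta(pos),
                discrepancy=d,
                error=err,
                consistent=abs(d) < err_sum_curve + err_quad_curve,
            )
        )
    frame = pd.DataFrame(rows)
    return AdditivityResult(
        frame,
        float(frame["discrepancy"].abs().mean()) if len(frame) else math.nan,
        float(frame["consistent"].mean()) if len(frame) else math.nan,
    )


# --- percent change ---------------------------------------------------------


def percent_change(reference: float, new: float) -> float:
    """Signed, unrounded percent change 100*(new - reference)/reference."""
    if reference == 0:
        raise CompareError("reference value is zero; percent change undefined")
    return 100.0 * (new - reference) / reference


def render_percent_change(reference: float, new: float) -> str:
    """Nearest-integer magnitude with direction, e.g. "17% increase"."""
    pct = percent_change(reference, new)
    direction = "increase" if pct > 0 else "decrease" if pct < 0 else "no change"
    if direction == "no change":
        return "no change"
    return f"{round(abs(pct))}% {direction}"
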