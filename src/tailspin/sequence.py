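"""H3 tail sequence, residue labels, mutations, and observability rules.

The first 36 residues of human histone H3 form the intrinsically disordered
N-terminal tail that protrudes from the nucleosome core particle (NCP).
Everything downstream of this module works in the tail's native 1-based
numbering (A1 .. K36); ranges are inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: The H3 tail, positions 1-36 (human H3.2/H3.3 N-terminus).
H3_TAIL = "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVK"

#: Arginine anchor positions in the WT tail.
ARGININE_POSITIONS = (2, 8, 17, 26)

#: Positions that are never visible in amide spectra: the N-terminal residue
#: (no observable amide after Met cleavage) and the two prolines.
NEVER_VISIBLE = frozenset({1, 16, 30})

TAIL_LENGTH = len(H3_TAIL)
assert TAIL_LENGTH == 36

_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)$")
_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class SequenceError(ValueError):
    """Malformed residue label, mutation, or construct specification."""


@dataclass(frozen=True, order=True)
class ResidueID:
    """A residue position with its one-letter code, e.g. T22."""

    position: int
    code: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SequenceError(f"position must be >= 1, got {self.position}")
        if len(self.code) != 1 or not self.code.isalpha():
            raise SequenceError(f"invalid residue code {self.code!r}")

    @property
    def label(self) -> str:
        return f"{self.code}{self.position}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class Mutation:
    """A point substitution such as R26Q."""

    position: int
    from_code: str
    to_code: str

    @property
    def label(self) -> str:
        return f"{self.from_code}{self.position}{self.to_code}"


@dataclass(frozen=True)
class TailSequence:
    """The (possibly mutated) 36-residue H3 tail.

    ``residues`` is the current sequence; ``mutations`` records the
    substitutions applied to the WT tail, in application order.
    """

    residues: str = H3_TAIL
    mutations: tuple[Mutation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.residues) != TAIL_LENGTH:
            raise SequenceError(
                f"tail must have {TAIL_LENGTH} residues, got {len(self.residues)}"
            )

    def code_at(self, position: int) -> str:
        if not 1 <= position <= TAIL_LENGTH:
            raise SequenceError(f"position {position} outside 1..{TAIL_LENGTH}")
        return self.residues[position - 1]

    def residue(self, position: int) -> ResidueID:
        return ResidueID(position, self.code_at(position))

    @property
    def mutated_positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)

    def apply_mutations(self, labels: list[str] | tuple[str, ...]) -> "TailSequence":
        """Return a new sequence with the given substitutions applied.

        Each label is from-code + position + to-code (e.g. ``"R26Q"``); the
        from-code must match the current sequence at that position.
        """
        residues = list(self.residues)
        applied = list(self.mutations)
        for label in labels:
            m = _MUTATION_RE.match(label)
            if not m:
                raise SequenceError(f"malformed mutation label {label!r}")
            from_code, position, to_code = m.group(1), int(m.group(2)), m.group(3)
            if not 1 <= position <= TAIL_LENGTH:
                raise SequenceError(f"mutation {label!r} outside tail 1..{TAIL_LENGTH}")
            current = residues[position - 1]
            if current != from_code:
                raise SequenceError(
                    f"mutation {label!r}: sequence has {current} at position "
                    f"{position}, not {from_code}"
                )
            residues[position - 1] = to_code
            applied.append(Mutation(position, from_code, to_code))
        return TailSequence("".join(residues), tuple(applied))


def parse_residue_label(label: str, sequence: TailSequence | None = None) -> ResidueID:
    """Parse a label like ``"T22"`` into a :class:`ResidueID`.

    If ``sequence`` is given, the code is validated against it.
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise SequenceError(f"malformed residue label {label!r}")
    rid = ResidueID(int(m.group(2)), m.group(1).upper())
    if sequence is not None:
        expected = sequence.code_at(rid.position)
        if expected != rid.code:
            raise SequenceError(
                f"label {label!r} does not match sequence: position "
                f"{rid.position} is {expected}"
            )
    return rid


def count_residue_range(start: ResidueID, end: ResidueID) -> int:
    """Inclusive positional count of a residue span.

    Invisible residues inside the span (e.g. P30 within T22-V35) are counted;
    the span T22-V35 therefore covers 14 residues.
    """
    if start.position > end.position:
        raise SequenceError(
            f"range start {start.label} after end {end.label}"
        )
    return end.position - start.position + 1


# --- constructs -------------------------------------------------------------

#: The six constructs studied: WT, four single-arginine neutralizations, and
#: the quadruple mutant.
DEFAULT_CONSTRUCTS = ("WT", "R2Q", "R8Q", "R17Q", "R26Q", "R2/8/17/26Q")

_COMPACT_RE = re.compile(r"^([A-Za-z])((?:\d+/)*\d+)([A-Za-z])$")


def construct_mutations(name: str) -> tuple[str, ...]:
    """Expand a construct name into mutation labels.

    ``"WT"`` -> (); ``"R26Q"`` -> ("R26Q",); the compact quadruple form
    ``"R2/8/17/26Q"`` -> ("R2Q", "R8Q", "R17Q", "R26Q").
    """
    name = name.strip()
    if name.upper() == "WT":
        return ()
    m = _COMPACT_RE.match(name)
    if not m:
        raise SequenceError(f"unrecognized construct name {name!r}")
    from_code, positions, to_code = m.group(1), m.group(2), m.group(3)
    return tuple(f"{from_code}{p}{to_code}" for p in positions.split("/"))


def construct_sequence(name: str) -> TailSequence:
    """Build the tail sequence for a named construct, validating mutations."""
    return TailSequence().apply_mutations(list(construct_mutations(name)))


def safe_construct_name(name: str) -> str:
    """Filesystem-safe variant of a construct name (slashes become dashes)."""
    return name.replace("/", "-")


# --- observability ----------------------------------------------------------

# Residues omitted from relaxation analysis per construct and salt condition,
# on top of the never-visible set. L20 is too weak in several samples, R2 is
# too weak at 0 mM KCl and invisible at 150 mM, K36 is not analyzable at
# 150 mM in any sample.
_RELAXATION_OMITTED_0MM: dict[str, frozenset[int]] = {
    "WT": frozenset({2, 20}),
    "R2Q": frozenset({2, 20}),
    "R8Q": frozenset({2, 20}),
    "R17Q": frozenset({2}),
    "R26Q": frozenset({2, 20}),
    "R2/8/17/26Q": frozenset({2}),
}
_RELAXATION_OMITTED_150MM: dict[str, frozenset[int]] = {
    "WT": frozenset({2, 20, 36}),
    "R2Q": frozenset({2, 36}),
    "R8Q": frozenset({2, 36}),
    "R17Q": frozenset({2, 36}),
    "R26Q": frozenset({2, 36}),
    "R2/8/17/26Q": frozenset({2, 36}),
}


@dataclass(frozen=True)
class ObservabilityRules:
    """Which tail residues are visible/analyzable per construct and salt."""

    never_visible: frozenset[int] = NEVER_VISIBLE

    def omitted(self, construct: str, salt_mM: int, experiment: str = "relaxation") -> frozenset[int]:
        """Positions omitted from analysis beyond the never-visible set.

        ``experiment`` is "relaxation" (R1/R2/hnNOE) or "hsqc" (shift tables,
        where R2 remains visible at 0 mM KCl).
        """
        if experiment == "hsqc":
            return frozenset({2}) if salt_mM >= 150 else frozenset()
        table = _RELAXATION_OMITTED_150MM if salt_mM >= 150 else _RELAXATION_OMITTED_0MM
        if construct not in table:
            raise SequenceError(f"unknown construct {construct!r}")
        return table[construct]

    def observable_positions(
        self, construct: str, salt_mM: int, experiment: str = "relaxation"
    ) -> tuple[int, ...]:
        dropped = self.never_visible | self.omitted(construct, salt_mM, experiment)
        return tuple(p for p in range(1, TAIL_LENGTH + 1) if p not in dropped)


DEFAULT_RULES = ObservabilityRules()

#: Positions visible in principle (excludes only A1 and the prolines).
VISIBLE_POSITIONS = tuple(p for p in range(1, TAIL_LENGTH + 1) if p not in NEVER_VISIBLE)

#: The flexible "hinge" where the tail exits the DNA gyres.
HINGE_SPAN = (28, 36)
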