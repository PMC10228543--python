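"""Exhaustive run-enumeration oracle for affected-region detection.

Independent of the production scan: enumerates every contiguous candidate
span, checks the run rule directly, and keeps maximal valid spans.
"""

from __future__ import annotations


def qualifying_status(profile, k: float = 1.0, criterion: str = "quadrature") -> dict[int, str]:
    """Map each position to 'Q' (qualifies), 'N' (observed, not qualifying),
    or 'M' (missing), re-deriving qualification from the raw entries."""
    status = {}
    for pos in range(1, 37):
        if pos not in profile.values:
            status[pos] = "M"
            continue
        qual = False
        for e in profile.values[pos]:
            err = e.error if criterion == "quadrature" else e.error_wt + e.error_mut
            if abs(e.delta) > k * err:
                qual = True
        status[pos] = "Q" if qual else "N"
    return status


def oracle_regions(status: dict[int, str], min_qualifying: int = 3) -> list[tuple[int, int]]:
    positions = sorted(status)
    valid = []
    for s in positions:
        if status[s] != "Q":
            continue
        for e in positions:
            if e < s or status[e] != "Q":
                continue
            obs = [p for p in positions if s <= p <= e and status[p] != "M"]
            if sum(1 for p in obs if status[p] == "Q") < min_qualifying:
                continue
            if any(
                status[obs[i]] == "N" and status[obs[i + 1]] == "N"
                for i in range(len(obs) - 1)
            ):
                continue
            valid.append((s, e))
    return sorted(
        (s, e)
        for (s, e) in valid
        if not any(
            s2 <= s and e <= e2 and (s2, e2) != (s, e) for (s2, e2) in valid
        )
    )
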