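"""Synthetic peak tables: relaxation decay series, hnNOE pairs, shift tables.

Emulates the structure of the deposited experiments: the relaxation delay
schedules actually acquired, doublet peaks at 0 mM KCl that merge at 150 mM,
per-spectrum Gaussian noise at a fixed fraction of each residue's reference
intensity, and the per-construct omission lists, so the analysis stages face
realistic missing data without any experimental download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AnchorModelParams, SyntheticTruth, default_params, generate_truth, _construct_key
from .sequence import DEFAULT_RULES, ObservabilityRules, TAIL_LENGTH, construct_sequence

#: Total relaxation loop lengths (s).  Duplicated delays are real repeats.
R1_DELAYS = (0.033, 0.195, 0.390, 0.390, 0.813, 0.813, 1.301, 1.951)
R2_DELAYS = (0.0088, 0.031, 0.031, 0.053, 0.079, 0.110, 0.110, 0.150)
#: Shorter CPMG schedule used for the WT sample at 150 mM KCl.
R2_DELAYS_WT_150 = (0.0044, 0.018, 0.018, 0.040, 0.062, 0.084, 0.084, 0.110)

#: Residues observed as two peaks at 0 mM KCl, per construct (attributed to
#: NCP asymmetry; all peaks are singlets at 150 mM KCl).
DOUBLETS_0MM: dict[str, tuple[int, ...]] = {
    "WT": (2, 36),
    "R2Q": (36,),
    "R8Q": (2, 3, 5, 36),
    "R17Q": (2, 5, 6, 8, 9, 20, 36),
    "R26Q": (2, 5, 6, 8),
    "R2/8/17/26Q": (),
}

DEFAULT_NOISE_FRACTION = 0.02

#: Fixed doublet splitting (full separation, ppm); within the spectral ranges
#: where such splittings are resolved.
DOUBLET_SPLIT_DH = 0.02
DOUBLET_SPLIT_DN = 0.10

COLUMNS = (
    "construct",
    "salt_mM",
    "experiment",
    "residue",
    "peak_id",
    "delay_s",
    "intensity",
    "noise",
    "dH_ppm",
    "dN_ppm",
)


class SimulationError(ValueError):
    """Invalid simulation settings."""


def _rng(seed: int, stream: int, construct: str, salt_mM: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), stream, int(salt_mM), _construct_key(construct)])
    )


def _doublets(construct: str, salt_mM: int, doublets: dict | None) -> frozenset[int]:
    if salt_mM >= 150:
        return frozenset()
    table = DOUBLETS_0MM if doublets is None else doublets
    return frozenset(table.get(construct, ()))


def _peaks_for(position: int, doublet_set: frozenset[int]):
    """(peak_id, intensity fraction) tuples; doublets split ~55/45."""
    if position in doublet_set:
        return ((1, 0.55), (2, 0.45))
    return ((1, 1.0),)


def _empty_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return df.astype({"salt_mM": int, "residue": int, "peak_id": int})


def simulate_relaxation_series(
    truth: SyntheticTruth,
    experiment: str,
    delays: tuple[float, ...] | None = None,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    seed: int | None = None,
    doublets: dict | None = None,
    rules: ObservabilityRules | None = DEFAULT_RULES,
) -> pd.DataFrame:
    """Simulate an R1 or R2 decay series for every analyzable residue.

    Each row is one (residue, peak, delay) measurement with intensity
    I0*exp(-R*t) + N(0, noise_fraction*I0); the noise column carries the
    per-spectrum noise figure noise_fraction*I0.  ``rules=None`` keeps
    residues that the corresponding experiment would omit.
    """
    if experiment not in ("R1", "R2"):
        raise SimulationError(f"experiment must be R1 or R2, got {experiment!r}")
    if noise_fraction < 0:
        raise SimulationError("noise_fraction must be >= 0")
    if delays is None:
        if experiment == "R1":
            delays = R1_DELAYS
        elif truth.construct == "WT" and truth.salt_mM >= 150:
            delays = R2_DELAYS_WT_150
        else:
            delays = R2_DELAYS
    if any(d <= 0 for d in delays):
        raise SimulationError("delays must be positive")
    seed = truth.seed if seed is None else seed
    rng = _rng(seed, 0x1 if experiment == "R1" else 0x2, truth.construct, truth.salt_mM)
    omitted = (
        rules.never_visible | rules.omitted(truth.construct, truth.salt_mM)
        if rules is not None
        else frozenset()
    )
    doublet_set = _doublets(truth.construct, truth.salt_mM, doublets)
    rates = truth.r1 if experiment == "R1" else truth.r2
    rows: list[dict] = []
    t = np.asarray(delays, dtype=float)
    for i, pos in enumerate(truth.positions):
        if pos in omitted:
            continue
        for peak_id, frac in _peaks_for(pos, doublet_set):
            i0 = frac * truth.reference_intensity[i]
            sigma = noise_fraction * i0
            clean = i0 * np.exp(-rates[i] * t)
            noisy = clean + rng.normal(0.0, sigma, size=t.size) if sigma > 0 else clean
            for delay, intensity in zip(delays, noisy):
                rows.append(
                    dict(
                        construct=truth.construct,
                        salt_mM=truth.salt_mM,
                        experiment=experiment,
                        residue=pos,
                        peak_id=peak_id,
                        delay_s=delay,
                        intensity=float(intensity),
                        noise=float(sigma),
                        dH_ppm=np.nan,
                        dN_ppm=np.nan,
                    )
                )
    return _empty_table(rows)


def simulate_noe_pair(
    truth: SyntheticTruth,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    seed: int | None = None,
    doublets: dict | None = None,
    rules: ObservabilityRules | None = DEFAULT_RULES,
) -> pd.DataFrame:
    """Simulate the interleaved saturated/reference hnNOE spectrum pair.

    Reference intensity I0 + noise; saturated intensity hnNOE*I0 + noise; both
    rows carry the same per-spectrum noise value noise_fraction*I0.
    """
    if noise_fraction < 0:
        raise SimulationError("noise_fraction must be >= 0")
    seed = truth.seed if seed is None else seed
    rng = _rng(seed, 0x3, truth.construct, truth.salt_mM)
    omitted = (
        rules.never_visible | rules.omitted(truth.construct, truth.salt_mM)
        if rules is not None
        else frozenset()
    )
    doublet_set = _doublets(truth.construct, truth.salt_mM, doublets)
    rows: list[dict] = []
    for i, pos in enumerate(truth.positions):
        if pos in omitted:
            continue
        for peak_id, frac in _peaks_for(pos, doublet_set):
            i0 = frac * truth.reference_intensity[i]
            sigma = noise_fraction * i0
            ref = i0 + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            sat = truth.noe[i] * i0 + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            for tag, intensity in (("hnNOE-sat", sat), ("hnNOE-ref", ref)):
                rows.append(
                    dict(
                        construct=truth.construct,
                        salt_mM=truth.salt_mM,
                        experiment=tag,
                        residue=pos,
                        peak_id=peak_id,
                        delay_s=np.nan,
                        intensity=float(intensity),
                        noise=float(sigma),
                        dH_ppm=np.nan,
                        dN_ppm=np.nan,
                    )
                )
    return _empty_table(rows)


# --- chemical shift tables --------------------------------------------------

#: Decay of the shift perturbation away from a mutated site (residues) and its
#: amplitudes at the site itself and at the nearest neighbour.
CSP_SITE_MAGNITUDE = 0.25
CSP_NEIGHBOR_MAGNITUDE = 0.085
CSP_DECAY_LENGTH = 2.0

_NWEIGHT = 0.154  # amide 15N scaling used in the weighted CSP


def _wt_shifts(params: AnchorModelParams, seed: int) -> np.ndarray:
    """WT amide shifts (dH, dN) per position, drawn once per seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5]))
    seq = construct_sequence("WT")
    shifts = np.zeros((TAIL_LENGTH, 2))
    for pos in range(1, TAIL_LENGTH + 1):
        code = seq.code_at(pos)
        dh = rng.uniform(7.9, 8.6)
        dn = rng.uniform(105.0, 112.0) if code == "G" else rng.uniform(115.0, 127.0)
        shifts[pos - 1] = (dh, dn)
    return shifts


def _site_perturbation(site: int, seed: int) -> np.ndarray:
    """Shift perturbation vectors (dH, dN) from neutralizing one arginine.

    Magnitude decays exponentially from the site; the direction in the
    (dH, sqrt(0.154)*dN) plane is a fixed random angle per residue, so the
    weighted CSP of the perturbation equals the chosen magnitude exactly.
    Perturbations from multiple sites add vectorially (additive ensemble
    shifts), keeping the quadruple mutant the sum of the singles.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6, site]))
    theta = rng.uniform(0.0, 2 * np.pi, size=TAIL_LENGTH)
    out = np.zeros((TAIL_LENGTH, 2))
    for pos in range(1, TAIL_LENGTH + 1):
        d = abs(pos - site)
        if d == 0:
            mag = CSP_SITE_MAGNITUDE
        else:
            mag = CSP_NEIGHBOR_MAGNITUDE * np.exp(-(d - 1) / CSP_DECAY_LENGTH)
        i = pos - 1
        out[i, 0] = mag * np.cos(theta[i])
        out[i, 1] = mag * np.sin(theta[i]) / np.sqrt(_NWEIGHT)
    return out


def simulate_shift_table(
    construct: str,
    salt_mM: int = 0,
    params: AnchorModelParams | None = None,
    seed: int = 0,
    doublets: dict | None = None,
    rules: ObservabilityRules | None = DEFAULT_RULES,
) -> pd.DataFrame:
    """Simulate a 1H-15N HSQC peak table for one construct/salt condition.

    Mutant shifts are WT shifts plus perturbation vectors decaying from each
    mutated site; doublet residues at 0 mM KCl are emitted as two peaks with a
    fixed small splitting.
    """
    params = params or default_params()
    seq = construct_sequence(construct)
    base = _wt_shifts(params, seed)
    shifts = base.copy()
    for m in seq.mutations:
        shifts = shifts + _site_perturbation(m.position, seed)
    omitted = (
        rules.never_visible | rules.omitted(construct, salt_mM, experiment="hsqc")
        if rules is not None
        else frozenset()
    )
    doublet_set = _doublets(construct, salt_mM, doublets)
    rows: list[dict] = []
    for pos in range(1, TAIL_LENGTH + 1):
        if pos in omitted:
            continue
        dh, dn = shifts[pos - 1]
        if pos in doublet_set:
            peaks = (
                (1, dh - DOUBLET_SPLIT_DH / 2, dn - DOUBLET_SPLIT_DN / 2),
                (2, dh + DOUBLET_SPLIT_DH / 2, dn + DOUBLET_SPLIT_DN / 2),
            )
        else:
            peaks = ((1, dh, dn),)
        for peak_id, ph, pn in peaks:
            rows.append(
                dict(
                    construct=construct,
                    salt_mM=salt_mM,
                    experiment="HSQC",
                    residue=pos,
                    peak_id=peak_id,
                    delay_s=np.nan,
                    intensity=np.nan,
                    noise=np.nan,
                    dH_ppm=float(ph),
                    dN_ppm=float(pn),
                )
            )
    return _empty_table(rows)


def simulate_construct_tables(
    construct: str,
    salt_mM: int = 0,
    params: AnchorModelParams | None = None,
    seed: int = 0,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    doublets: dict | None = None,
    rules: ObservabilityRules | None = DEFAULT_RULES,
) -> pd.DataFrame:
    """All experiments (R1, R2, hnNOE pair, HSQC) for one construct/salt."""
    params = params or default_params()
    truth = generate_truth(construct, salt_mM, params, seed)
    frames = [
        simulate_relaxation_series(
            truth, "R1", noise_fraction=noise_fraction, doublets=doublets, rules=rules
        ),
        simulate_relaxation_series(
            truth, "R2", noise_fraction=noise_fraction, doublets=doublets, rules=rules
        ),
        simulate_noe_pair(
            truth, noise_fraction=noise_fraction, doublets=doublets, rules=rules
        ),
        simulate_shift_table(
            construct, salt_mM, params, seed, doublets=doublets, rules=rules
        ),
    ]
    return pd.concat(frames, ignore_index=True)
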