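"""End-to-end orchestration: simulate -> fit -> CSP -> compare -> report.

Everything here is a thin composition of the library stages, shared by the
command-line interface and the example scripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import compare, csp, relaxation
from .io import read_peak_table, write_manifest, write_peak_table
from .model import AnchorModelParams, default_params
from .sequence import DEFAULT_CONSTRUCTS, construct_sequence, safe_construct_name
from .simulate import DEFAULT_NOISE_FRACTION, simulate_construct_tables

log = logging.getLogger("tailspin")

SINGLE_MUTANTS = ("R2Q", "R8Q", "R17Q", "R26Q")
QUADRUPLE = "R2/8/17/26Q"


@dataclass(frozen=True)
class RunConfig:
    """A reproducible pipeline run: constructs, conditions, seeds, options."""

    constructs: tuple[str, ...] = DEFAULT_CONSTRUCTS
    salts_mM: tuple[int, ...] = (0, 150)
    noise_fraction: float = DEFAULT_NOISE_FRACTION
    seed: int = 0
    overlap_criterion: str = "quadrature"
    params: AnchorModelParams | None = None

    def __post_init__(self) -> None:
        for c in self.constructs:
            construct_sequence(c)  # raises on unknown constructs
        for s in self.salts_mM:
            if s not in (0, 150):
                raise ValueError(f"salt condition must be 0 or 150 mM, got {s}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("constructs", "salts_mM"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("noise_fraction", "seed", "overlap_criterion"):
            if key in raw:
                kwargs[key] = raw[key]
        if "params" in raw:
            kwargs["params"] = AnchorModelParams.calibrated(**raw["params"])
        return cls(**kwargs)

    def model_params(self) -> AnchorModelParams:
        return self.params or default_params()


def simulate_dataset(config: RunConfig, outdir: str | Path) -> list[Path]:
    """One peak table per (construct, salt) plus a manifest; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.model_params()
    paths = []
    for construct in config.constructs:
        for salt in config.salts_mM:
            table = simulate_construct_tables(
                construct,
                salt,
                params,
                seed=config.seed,
                noise_fraction=config.noise_fraction,
            )
            path = outdir / f"peaks_{safe_construct_name(construct)}_{salt}mM.tsv"
            write_peak_table(table, path)
            paths.append(path)
            log.info("wrote %s (%d rows)", path, len(table))
    write_manifest(
        outdir / "manifest.json",
        seed=config.seed,
        constructs=list(config.constructs),
        salts_mM=list(config.salts_mM),
        noise_fraction=config.noise_fraction,
        params=params,
        tool="tailspin 0.1.0",
    )
    return paths


@dataclass
class ConditionAnalysis:
    """Fitted profiles and comparisons for one salt condition."""

    salt_mM: int
    profiles: dict[str, dict[str, relaxation.ResidueProfile]] = field(default_factory=dict)
    csp_profiles: dict[str, csp.CSPProfile] = field(default_factory=dict)
    deltas: dict[str, dict[str, compare.DeltaProfile]] = field(default_factory=dict)
    regions: pd.DataFrame | None = None
    ranking: dict[str, list[compare.RankedMutant]] = field(default_factory=dict)
    additivity: dict[str, compare.AdditivityResult] = field(default_factory=dict)


def analyze_tables(
    tables: dict[str, pd.DataFrame],
    salt_mM: int,
    overlap_criterion: str = "quadrature",
) -> ConditionAnalysis:
    """Run every analysis stage for one salt condition.

    ``tables`` maps construct name to its peak table.  Comparison stages are
    skipped (with a logged notice) unless both WT and mutants are present.
    """
    result = ConditionAnalysis(salt_mM)
    for construct, table in tables.items():
        r1 = relaxation.rate_profile(table, "R1", construct, salt_mM)
        r2 = relaxation.rate_profile(table, "R2", construct, salt_mM)
        result.profiles[construct] = {
            "R1": r1,
            "R2": r2,
            "R2R1": relaxation.r2r1_profile(r1, r2),
            "hnNOE": relaxation.noe_profile(table, construct, salt_mM),
        }
    if "WT" not in tables:
        log.warning("no WT table at %d mM; comparison stages skipped", salt_mM)
        return result
    mutants = [c for c in tables if c != "WT"]
    if not mutants:
        log.info("WT-only input at %d mM; comparison stages skipped", salt_mM)
        return result
    for construct in mutants:
        result.csp_profiles[construct] = csp.csp_profile(
            tables["WT"], tables[construct]
        )
    region_rows = []
    for kind in ("hnNOE", "R2R1"):
        result.deltas[kind] = {
            c: compare.delta_profile(
                result.profiles["WT"][kind], result.profiles[c][kind]
            )
            for c in mutants
        }
        for c, dp in result.deltas[kind].items():
            for region in compare.detect_affected_regions(
                dp, criterion=overlap_criterion
            ):
                region_rows.append(
                    dict(
                        construct=c,
                        observable=kind,
                        salt_mM=salt_mM,
                        start=region.start.label,
                        end=region.end.label,
                        count=region.residue_count,
                        interruptions=",".join(map(str, region.interrupted_positions)),
                    )
                )
        single_deltas = {
            c: result.deltas[kind][c] for c in SINGLE_MUTANTS if c in result.deltas[kind]
        }
        if len(single_deltas) >= 2:
            result.ranking[kind] = compare.rank_mutants(single_deltas)
        if len(single_deltas) == 4 and QUADRUPLE in result.deltas[kind]:
            result.additivity[kind] = compare.additivity_discrepancy(
                single_deltas, result.deltas[kind][QUADRUPLE]
            )
    result.regions = pd.DataFrame(
        region_rows,
        columns=["construct", "observable", "salt_mM", "start", "end", "count", "interruptions"],
    )
    return result


def analyze_directory(
    indir: str | Path, config: RunConfig | None = None
) -> dict[int, ConditionAnalysis]:
    """Analyze every peak table in a directory, grouped by salt condition."""
    config = config or RunConfig()
    indir = Path(indir)
    by_salt: dict[int, dict[str, pd.DataFrame]] = {}
    for path in sorted(indir.glob("peaks_*.tsv")):
        table = read_peak_table(path)
        salt = int(table["salt_mM"].iloc[0])
        construct = str(table["construct"].iloc[0])
        by_salt.setdefault(salt, {})[construct] = table
    return {
        salt: analyze_tables(tables, salt, config.overlap_criterion)
        for salt, tables in sorted(by_salt.items())
    }


def write_reports(results: dict[int, ConditionAnalysis], outdir: str | Path) -> None:
    """Emit the CSV reports and a plain-text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile_frames, csp_frames, delta_frames, region_frames = [], [], [], []
    summary: list[str] = []
    for salt, res in results.items():
        for construct, kinds in res.profiles.items():
            for kind, profile in kinds.items():
                df = profile.to_frame()
                df.insert(0, "salt_mM", salt)
                df.insert(0, "construct", construct)
                profile_frames.append(df)
        for construct, prof in res.csp_profiles.items():
            df = prof.to_frame()
            df.insert(0, "salt_mM", salt)
            df.insert(0, "construct", construct)
            csp_frames.append(df)
        for kind, per_construct in res.deltas.items():
            for construct, dp in per_construct.items():
                df = dp.to_frame()
                df.insert(0, "salt_mM", salt)
                df.insert(0, "construct", construct)
                delta_frames.append(df)
        if res.regions is not None and len(res.regions):
            region_frames.append(res.regions)
        summary.append(f"== {salt} mM KCl ==")
        if "WT" in res.profiles:
            noe = res.profiles["WT"]["hnNOE"]
            mean, sd, n = relaxation.region_average(noe, 3, 36)
            hmean, hsd, hn = relaxation.region_average(noe, 28, 36)
            summary.append(
                f"WT tail hnNOE (T3-K36): {mean:.3f} +/- {sd:.3f} (n={n}); "
                f"hinge S28-K36: {hmean:.3f} +/- {hsd:.3f} (n={hn})"
            )
        for kind, ranking in res.ranking.items():
            order = " > ".join(f"{r.construct} ({r.summed_delta:+.2f})" for r in ranking)
            summary.append(f"summed Delta {kind} ranking: {order}")
        for kind, add in res.additivity.items():
            summary.append(
                f"additivity ({kind}): mean |discrepancy| "
                f"{add.mean_abs_discrepancy:.3g}; {100 * add.fraction_consistent:.0f}% "
                "of residues consistent with additive effects"
            )
    if profile_frames:
        pd.concat(profile_frames, ignore_index=True).to_csv(
            outdir / "profiles.csv", index=False
        )
    if csp_frames:
        pd.concat(csp_frames, ignore_index=True).to_csv(outdir / "csp.csv", index=False)
    if delta_frames:
        pd.concat(delta_frames, ignore_index=True).to_csv(
            outdir / "deltas.csv", index=False
        )
    if region_frames:
        pd.concat(region_frames, ignore_index=True).to_csv(
            outdir / "regions.csv", index=False
        )
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
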