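import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from region_oracle import oracle_regions, qualifying_status
from tailspin import compare, model, relaxation, simulate
from tailspin.compare import (
    AffectedRegion,
    CompareError,
    DeltaEntry,
    DeltaProfile,
    additivity_discrepancy,
    delta_profile,
    detect_affected_regions,
    percent_change,
    rank_mutants,
    render_percent_change,
    summed_delta,
)
from tailspin.relaxation import PeakValue, ResidueProfile


def make_profile(values, errors=None, missing=(), construct="R26Q", kind="hnNOE"):
    """DeltaProfile from {position: delta}; default error 0.1 per side-pair."""
    errors = errors or {}
    vals = {}
    for pos, d in values.items():
        e = errors.get(pos, 0.1)
        vals[pos] = [DeltaEntry("1:1", d, e, e / np.sqrt(2), e / np.sqrt(2))]
    missing_map = {p: "invisible" for p in missing}
    return DeltaProfile(construct, kind, 0, vals, missing_map)


def wt_like_profile(values, kind="hnNOE", construct="WT", salt=0):
    return ResidueProfile(
        construct, salt, kind,
        {p: [PeakValue(1, v, 0.02)] for p, v in values.items()},
    )


# --- delta profiles ---------------------------------------------------------


def test_delta_of_identical_profiles_is_zero():
    wt = wt_like_profile({3: 0.4, 4: 0.35, 5: 0.3})
    dp = delta_profile(wt, wt)
    assert all(e.delta == 0.0 for vals in dp.values.values() for e in vals)
    assert all(e.error == pytest.approx(0.02 * np.sqrt(2)) for vals in dp.values.values() for e in vals)


def test_delta_positive_near_mutation(params):
    wt = model.generate_truth("WT", 0, params, seed=0)
    mut = model.generate_truth("R26Q", 0, params, seed=0)
    wtp = relaxation.noe_profile(simulate.simulate_noe_pair(wt), "WT", 0)
    mutp = relaxation.noe_profile(simulate.simulate_noe_pair(mut), "R26Q", 0)
    dp = delta_profile(wtp, mutp)
    near = [dp.residue_delta(p) for p in range(24, 29) if p in dp.values]
    assert min(near) > 0


def test_delta_doublet_against_singlet_gives_two_values():
    wt = wt_like_profile({5: 0.4})
    mut = ResidueProfile(
        "R17Q", 0, "hnNOE",
        {5: [PeakValue(1, 0.30, 0.02), PeakValue(2, 0.34, 0.02)]},
    )
    dp = delta_profile(wt, mut)
    assert [round(e.delta, 2) for e in dp.values[5]] == [0.10, 0.06]


def test_delta_validation():
    wt = wt_like_profile({3: 0.4})
    r1 = wt_like_profile({3: 1.1}, kind="R1")
    with pytest.raises(CompareError):
        delta_profile(wt, r1)


# --- summed delta and ranking ----------------------------------------------


def test_summed_delta_arithmetic():
    assert summed_delta(make_profile({3: 0.0, 4: 0.0})) == 0.0
    prof = make_profile({3: 0.1, 4: 0.1, 5: 0.1, 6: -0.05})
    assert summed_delta(prof) == pytest.approx(0.25)


def test_summed_delta_linear_and_order_invariant():
    rng = np.random.default_rng(3)
    vals = {p: rng.normal() for p in range(3, 20)}
    prof = make_profile(vals)
    assert summed_delta(prof) == pytest.approx(sum(vals.values()))
    doubled = make_profile({p: 2 * v for p, v in vals.items()})
    assert summed_delta(doubled) == pytest.approx(2 * summed_delta(prof))


def test_rank_mutants_orders_and_flags_ties():
    profs = {
        "R26Q": make_profile({3: 0.3}),
        "R2Q": make_profile({3: 0.1}),
        "R8Q": make_profile({3: 0.1}),
    }
    ranking = rank_mutants(profs)
    assert ranking[0].construct == "R26Q" and not ranking[0].tied_with
    assert {ranking[1].construct, ranking[2].construct} == {"R2Q", "R8Q"}
    assert ranking[1].tied_with and ranking[2].tied_with
    assert rank_mutants({"R2Q": profs["R2Q"]})[0].construct == "R2Q"
    with pytest.raises(CompareError):
        rank_mutants({})


# --- region detection -------------------------------------------------------


def profile_from_pattern(pattern: dict[int, str]) -> DeltaProfile:
    """'Q' -> |delta| over error, 'N' -> under, 'M'/absent -> missing."""
    values, missing = {}, {}
    for pos in range(1, 37):
        s = pattern.get(pos, "M")
        if s == "Q":
            values[pos] = [DeltaEntry("1:1", 0.5, 0.1, 0.07, 0.07)]
        elif s == "N":
            values[pos] = [DeltaEntry("1:1", 0.05, 0.1, 0.07, 0.07)]
        else:
            missing[pos] = "invisible"
    return DeltaProfile("R26Q", "hnNOE", 0, values, missing)


def _spans(regions: list[AffectedRegion]):
    return [(r.start.position, r.end.position) for r in regions]


def test_no_regions_when_nothing_qualifies():
    prof = profile_from_pattern({p: "N" for p in range(3, 36)})
    assert detect_affected_regions(prof) == []


def test_single_region_spanning_invisible_proline():
    # qualifying 22-27 and 29-35, non-qualifying only at 28; P30 missing.
    pattern = {p: "Q" for p in list(range(22, 28)) + list(range(29, 36))}
    pattern[28] = "N"
    pattern.pop(30)
    for p in range(3, 22):
        pattern[p] = "N"
    prof = profile_from_pattern(pattern)
    regions = detect_affected_regions(prof)
    assert _spans(regions) == [(22, 35)]
    assert regions[0].residue_count == 14  # inclusive span counts P30
    assert regions[0].interrupted_positions == (28,)
    assert oracle_regions(qualifying_status(prof)) == [(22, 35)]


def test_two_disjoint_segments():
    # qualifying 15-20 and 24-26 with a two-residue gap (21-23 observed, N)
    pattern = {p: "Q" for p in list(range(15, 21)) + list(range(24, 27))}
    for p in (21, 22, 23):
        pattern[p] = "N"
    prof = profile_from_pattern(pattern)
    regions = detect_affected_regions(prof)
    assert _spans(regions) == [(15, 20), (24, 26)]
    assert [r.residue_count for r in regions] == [6, 3]
    assert oracle_regions(qualifying_status(prof)) == [(15, 20), (24, 26)]


def test_consecutive_nonqualifying_pair_breaks_a_run():
    pattern = {p: "Q" for p in (3, 4, 5, 8, 9, 10)}
    pattern[6] = "N"
    pattern[7] = "N"
    prof = profile_from_pattern(pattern)
    assert _spans(detect_affected_regions(prof)) == [(3, 5), (8, 10)]


def test_endpoints_must_qualify_and_min_three():
    prof = profile_from_pattern({3: "Q", 4: "N", 5: "Q"})
    assert detect_affected_regions(prof) == []  # only two qualifying residues
    prof = profile_from_pattern({3: "N", 4: "Q", 5: "Q", 6: "Q", 7: "N"})
    assert _spans(detect_affected_regions(prof)) == [(4, 6)]


@given(st.data())
@settings(max_examples=120, derandomize=True, deadline=None)
def test_region_detection_matches_exhaustive_oracle(data):
    rng_bits = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(rng_bits)
    pattern = {}
    for pos in range(1, 37):
        r = rng.random()
        if r < 0.2:
            continue  # missing
        pattern[pos] = "Q" if r < 0.55 else "N"
    prof = profile_from_pattern(pattern)
    assert _spans(detect_affected_regions(prof)) == oracle_regions(
        qualifying_status(prof)
    )


def test_region_monotonicity_under_delta_scaling():
    rng = np.random.default_rng(17)
    values = {p: rng.normal(0, 0.15) for p in range(3, 36) if p not in (16, 30)}
    base = make_profile(values)
    grown = make_profile({p: 3 * v for p, v in values.items()})
    cover_base = {
        p for r in detect_affected_regions(base) for p in range(r.start.position, r.end.position + 1)
    }
    cover_grown = {
        p for r in detect_affected_regions(grown) for p in range(r.start.position, r.end.position + 1)
    }
    assert cover_base <= cover_grown


def test_breadth_ordering_reproduced_across_replicates(params):
    """R26Q affects the broadest span and R2Q the narrowest (hnNOE, 0 mM)
    in at least 80% of seeded replicates, under the non-overlapping-error-bar
    reading of the run rule."""
    hits = 0
    n_rep = 50
    for seed in range(1, n_rep + 1):
        profs = {
            c: relaxation.noe_profile(
                simulate.simulate_noe_pair(model.generate_truth(c, 0, params, seed)),
                c,
                0,
            )
            for c in ("WT", "R2Q", "R8Q", "R17Q", "R26Q")
        }
        breadth = {
            c: compare.region_breadth(
                detect_affected_regions(delta_profile(profs["WT"], profs[c]), criterion="sum")
            )
            for c in ("R2Q", "R8Q", "R17Q", "R26Q")
        }
        if breadth["R26Q"] >= max(breadth.values()) and breadth["R2Q"] <= min(
            breadth.values()
        ):
            hits += 1
    assert hits / n_rep >= 0.8


# --- additivity -------------------------------------------------------------


def _noe_deltas(params, salt, seed):
    profs = {
        c: relaxation.noe_profile(
            simulate.simulate_noe_pair(
                model.generate_truth(c, salt, params, seed),
                noise_fraction=0.02,
            ),
            c,
            salt,
        )
        for c in ("WT", "R2Q", "R8Q", "R17Q", "R26Q", "R2/8/17/26Q")
    }
    singles = {c: delta_profile(profs["WT"], profs[c]) for c in ("R2Q", "R8Q", "R17Q", "R26Q")}
    quad = delta_profile(profs["WT"], profs["R2/8/17/26Q"])
    return singles, quad


def test_additivity_exact_on_noiseless_profiles(params):
    profs = {
        c: relaxation.noe_profile(
            simulate.simulate_noe_pair(model.generate_truth(c, 0, params, 0), noise_fraction=0.0),
            c,
            0,
        )
        for c in ("WT", "R2Q", "R8Q", "R17Q", "R26Q", "R2/8/17/26Q")
    }
    singles = {c: delta_profile(profs["WT"], profs[c]) for c in ("R2Q", "R8Q", "R17Q", "R26Q")}
    quad = delta_profile(profs["WT"], profs["R2/8/17/26Q"])
    res = additivity_discrepancy(singles, quad)
    assert res.frame["discrepancy"].abs().max() < 1e-10


def test_additivity_with_noise_mostly_within_error(params):
    fractions = [
        additivity_discrepancy(*_noe_deltas(params, 0, seed)).fraction_consistent
        for seed in range(1, 11)
    ]
    assert float(np.mean(fractions)) >= 0.8


def test_quadruple_replaced_by_wt_gives_sum_of_singles(params):
    singles, _ = _noe_deltas(params, 0, seed=4)
    wt_prof = relaxation.noe_profile(
        simulate.simulate_noe_pair(model.generate_truth("WT", 0, params, 4)), "WT", 0
    )
    null_quad = delta_profile(wt_prof, wt_prof)
    res = additivity_discrepancy(singles, null_quad)
    for row in res.frame.itertuples():
        expected = sum(s.residue_delta(row.residue) for s in singles.values())
        assert row.discrepancy == pytest.approx(expected)


def test_additivity_requires_four_singles(params):
    singles, quad = _noe_deltas(params, 0, seed=4)
    del singles["R2Q"]
    with pytest.raises(CompareError):
        additivity_discrepancy(singles, quad)


# --- percent change ---------------------------------------------------------


@pytest.mark.parametrize(
    "ref, new, pct, rendered",
    [
        (1.07, 1.25, 16.82, "17% increase"),
        (21.0, 8.0, -61.90, "62% decrease"),
        (5.0, 5.0, 0.0, "no change"),
    ],
)
def test_percent_change(ref, new, pct, rendered):
    assert percent_change(ref, new) == pytest.approx(pct, abs=0.005)
    assert render_percent_change(ref, new) == rendered


def test_percent_change_zero_reference():
    with pytest.raises(CompareError):
        percent_change(0.0, 1.0)
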