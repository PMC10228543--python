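"""Rank the four arginine neutralizations and map their affected regions.

Delta = WT - mutant per residue; summing it over the tail ranks the overall
effect (R26Q largest, R2Q smallest), and runs of >=3 residues clearing their
combined error bars give each mutation's breadth of effect.
"""

from tailspin import default_params, generate_truth
from tailspin.compare import delta_profile, detect_affected_regions, rank_mutants
from tailspin.relaxation import noe_profile
from tailspin.simulate import simulate_noe_pair

params = default_params()
profiles = {
    c: noe_profile(simulate_noe_pair(generate_truth(c, 0, params, seed=1)), c, 0)
    for c in ("WT", "R2Q", "R8Q", "R17Q", "R26Q")
}
deltas = {c: delta_profile(profiles["WT"], profiles[c]) for c in profiles if c != "WT"}

print("summed Delta-hnNOE ranking (0 mM KCl):")
for r in rank_mutants(deltas):
    print(f"  {r.construct:5s} {r.summed_delta:+.3f}")

print("\naffected regions (non-overlapping error bars, >=3-residue runs):")
for construct, dp in deltas.items():
    regions = detect_affected_regions(dp, criterion="sum")
    label = ", ".join(f"{r.label} ({r.residue_count} residues)" for r in regions) or "none"
    print(f"  {construct:5s} {label}")
print(
    "\nNeutralizing R26, next to the flexible hinge, mobilizes the widest\n"
    "stretch of the tail; R2 at the free N-terminus the narrowest."
)
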