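"""Do the four single-arginine effects add up to the quadruple mutant?

Compares the sum of the four single-mutant Delta-hnNOE profiles with the
quadruple-mutant profile, residue by residue, with full error propagation
(the shared WT dataset is counted once).
"""

from tailspin import default_params, generate_truth
from tailspin.compare import additivity_discrepancy, delta_profile
from tailspin.relaxation import noe_profile
from tailspin.simulate import simulate_noe_pair

params = default_params()
profiles = {
    c: noe_profile(simulate_noe_pair(generate_truth(c, 0, params, seed=1)), c, 0)
    for c in ("WT", "R2Q", "R8Q", "R17Q", "R26Q", "R2/8/17/26Q")
}
singles = {
    c: delta_profile(profiles["WT"], profiles[c])
    for c in ("R2Q", "R8Q", "R17Q", "R26Q")
}
quad = delta_profile(profiles["WT"], profiles["R2/8/17/26Q"])

res = additivity_discrepancy(singles, quad)
print(res.frame.head(8).to_string(index=False))
print(f"\nmean |discrepancy|: {res.mean_abs_discrepancy:.3f}")
print(f"residues consistent with additivity: {100 * res.fraction_consistent:.0f}%")
print(
    "\nThe summed singles track the quadruple mutant within error bars at\n"
    "most residues: the anchor points act (close to) independently."
)
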