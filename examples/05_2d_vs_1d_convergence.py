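"""Why the alchemical dimension pays off: 2D vs 1D AWH on the gel toy.

The gel toy hinders reorientation everywhere while coupled (a 12 kJ/mol
orientation barrier) and binds opposite orientations in two regions.  A
spatial-only (1D) sampler has to wait out the slow orientation flips; a 2D
sampler decouples, reorients instantly, and re-enters elsewhere.  At an
equal step budget the 2D PMF is systematically closer to the quadrature
reference; a one-sided sign test over paired seeds quantifies it.
"""

from permawh.comparison import two_d_vs_one_d

res = two_d_vs_one_d(n_seeds=21, total_steps=800_000, base_seed=0)
s = res["summary"]

print("seed   RMSD 2D   RMSD 1D   winner")
for i, (a, b) in enumerate(zip(res["final_2d"], res["final_1d"])):
    print(f"{i:4d}   {a:7.3f}   {b:7.3f}   {'2D' if a < b else '1D'}")
print()
print(f"median RMSD: 2D {s['median_rmsd_2d']:.3f} vs 1D {s['median_rmsd_1d']:.3f} kJ/mol")
print(f"2D wins {s['wins_2d']}/{s['n_seeds']} seeds; "
      f"one-sided sign test p = {s['sign_test_pvalue']:.4f}")
print("A p-value below 0.05 confirms the alchemical shortcut accelerates")
print("convergence on this slowly reorienting (gel-like) system.")
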