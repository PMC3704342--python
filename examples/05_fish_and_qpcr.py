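"""Clone designation from FISH nucleus counts and the comparative-CT check.

A single-cell clone is accepted as trisomic or disomic only when at least
95% of 300 scored interphase nuclei show the corresponding signal pattern.
qPCR fold expression uses the comparative CT method, 2**(-ddCT).
"""

import trisomethyl as tm

for n_tri in (285, 284, 150):
    label = tm.classify_clone_by_fish(300, n_tri, 300 - n_tri)
    print(f"{n_tri}/300 trisomic nuclei -> {label}")

counts = tm.simulate_fish_counts(n_nuclei=300, true_trisomy_fraction=0.99,
                                 seed=1, n_clones=3)
for _, row in counts.iterrows():
    label = tm.classify_clone_by_fish(300, row["n_trisomic"], row["n_disomic"])
    print(f"simulated clone with 99% trisomic cells: "
          f"{row['n_trisomic']}/300 -> {label}")

fold = tm.delta_delta_ct(20, 18, 22, 18)
print(f"ddCT example (target/control CTs 20/18 vs calibrator 22/18): "
      f"fold expression {fold:.1f} (ddCT = -2)")
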