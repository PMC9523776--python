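"""Enumerate the in-silico heteroatom-class target list.

Builds the default library of sebum-lipid substrates and their ozonolysis
(A, B/C, AA) and epoxidation (E) products as sodiated / disodiated /
potassium-substituted ions, and looks up the reference ions discussed
throughout the analysis.
"""

import kmdprint as kp

targets = kp.build_target_list()
print(f"target list: {len(targets)} theoretical ions "
      f"({targets[0].mz:.4f} - {targets[-1].mz:.4f} m/z)")

for formula in ("C30H50Na", "C10H19O2Na2", "C40H74O7Na"):
    entry = next(t for t in targets if t.composition.formula() == formula)
    print(
        f"  {formula:>14s}  m/z {entry.mz:9.4f}  DBE {entry.dbe}  "
        f"labels {'/'.join(entry.labels)}"
    )

# The three lines above are, respectively: sodiated squalene (the fast-
# decaying marker of fresh prints), disodiated FA 10:0 (the omega-10
# ozonolysis tail that accumulates with age), and the shared TG(A)/TG(E)
# O7 composition whose bimodal intensity profile separates aldehydes from
# epoxides.
kp.write_target_list(targets, "targets.tsv")
print("wrote targets.tsv")
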