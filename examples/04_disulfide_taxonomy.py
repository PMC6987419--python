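"""Cystine dihedrals, the 20-type taxonomy, and ideality windows.

Builds cystines at chosen (χ1, χ2, χ3, χ2′, χ1′), measures the torsions back
from the coordinates, classifies them and checks the energetic windows.
"""

from peprdc import classify, cystine_dihedrals, ensemble_report, ideality
from peprdc import synthetic as syn
from peprdc.structure_io import Ensemble, Model

for chi in [(-60, -60, -85, -60, -60),   # all negative → left-handed spiral
            (60, 60, 85, 60, 60),        # its mirror image
            (-60, -60, -85, 60, -60),    # one χ2 sign flipped → hook
            (-60, 60, -85, 60, -60)]:    # both flipped → staple
    g = cystine_dihedrals(syn.build_cystine(chi), (1, 2))
    cls = classify(g)
    ide = ideality(g)
    print(f"χ = {chi!s:<28} → {cls.label:<14}"
          f" {'ideal' if ide.all_ideal else 'non-ideal'}")

# conformer census across a heterogeneous ensemble
a = syn.build_cystine((-60, -60, -85, -60, -60))
b = syn.build_cystine((-60, -60, 85, 60, -60))
ens = Ensemble(models=[Model(i + 1, (a if i < 12 else b).atoms) for i in range(20)])
report = ensemble_report(ens, [(1, 2)])
print("\nensemble census:", dict(report[(1, 2)]["census"]),
      "heterogeneous:", report[(1, 2)]["heterogeneous"])
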