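"""Inhibition type and Ki/Kis from published apparent kinetic constants.

Loads the shipped apparent Km/Vmax tables for the porphyrin-amylase
systems, classifies each inhibition mode from the Km/Vmax trends and the
Lineweaver-Burk intersection geometry, and recomputes the secondary-plot
constants Ki (free enzyme) and Kis (enzyme-substrate complex).
"""

import enzybind as eb
from enzybind import datasets

print(f"{'system':>16s} {'type':>16s} {'Ki (ug/mL)':>12s} {'Kis (ug/mL)':>12s}")
for compound in ["TAPP", "THPP", "TCPP", "Fe-TCPP", "Ni-TCPP", "Cu-TCPP"]:
    fits = datasets.kinetic_fits("amy", compound)
    verdict = eb.classify_inhibition(fits)
    ki = eb.estimate_ki(fits).value
    if verdict.inhibition_type == "mixed":
        kis = f"{eb.estimate_kis(fits).value:12.4f}"
    else:
        kis = f"{'-':>12s}"
    print(f"{'aAMY-' + compound:>16s} {verdict.inhibition_type:>16s} "
          f"{ki:12.4f} {kis}")

print()
print("A smaller Ki means tighter binding to the free enzyme, i.e. stronger")
print("inhibition; Ki < Kis for the mixed systems shows the porphyrins")
print("prefer free amylase over the enzyme-substrate complex.  Ni-TCPP's")
print("constant Km with falling Vmax is the non-competitive signature.")
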