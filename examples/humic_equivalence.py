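"""What would the measured humic signal supply in ligands, per substance?

One surface sample: eHS = 75.7 ug/L (SRFA equivalent), in-situ Fe-L =
2.0 nmol/L, DFe = 0.5 nmol/L, log K = 11.3.  For each candidate substance
the chain eHS -> equivalent concentration -> ligand equivalent ->
% contribution is printed, with the Fe saturation that substance would
need to account for the whole in-situ ligand pool, and the
complexing-capacity comparison (substance vs in-situ; a substance can
plausibly control Fe chemistry only when its capacity is >= in-situ).
"""

from felig import equivalence as eq
from felig.substances import load_substance_table

EHS, FEL, DFE, LOGK = 75.7, 2.0, 0.5, 11.3

el, saturated = eq.excess_ligand(FEL, DFE)
cap_insitu = eq.complexing_capacity(el, LOGK)
print(f"sample: eHS={EHS} ug/L, Fe-L={FEL} nM, DFe={DFE} nM, logK={LOGK}")
print(f"excess ligand eL = {el:.2f} nM; in-situ capacity log(eL*K) = {cap_insitu:.3f}\n")

print(f"{'substance':<18}{'L_X (nM)':>10}{'contrib %':>11}"
      f"{'need sat %':>11}{'cap log':>9}")
for prof in load_substance_table().values():
    lx = eq.ligand_equivalent(
        eq.equivalent_substance_concentration(EHS, prof), prof)
    contrib = eq.percent_contribution(lx, FEL)
    need = eq.required_fe_saturation(lx, FEL)
    cap = eq.complexing_capacity(el, prof.logK)
    mark = " *" if cap >= cap_insitu else ""
    print(f"{prof.name:<18}{lx:>10.2f}{contrib:>11.1f}{need:>11.2f}"
          f"{cap:>9.3f}{mark}")

print("\n* capacity >= in-situ: could control Fe biogeochemistry here.")
print("EPS contributions far above 100% mean a few percent Fe saturation")
print("of the EPS pool would already supply the whole in-situ ligand pool.")
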