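"""Is atmospheric dust a relevant source of electroactive humics?

Combines the eHS content of dust (3.7-5.8 mg eHS per g) with Southern
Ocean deposition rates (0.2-12 mg dust m-2 d-1) into an areal eHS flux,
then weighs the upper bound against the standing eHS inventory of a
summer mixed layer.  A daily fraction of ~1e-5 means dust input is
negligible next to in-situ production.
"""

from felig import equivalence as eq

lo, hi = eq.dust_ehs_flux(content_lo_hi=(3.7, 5.8),
                          deposition_lo_hi=(0.2, 12.0))
print(f"dust-borne eHS flux: {lo:.2f} - {hi:.1f} ug eHS m-2 d-1")

for ehs, mld, label in [(50.0, 20.0, "summer, shallow MLD"),
                        (75.7, 100.0, "winter, deep MLD")]:
    frac = eq.mld_inventory_comparison(hi, ehs_conc=ehs, mld=mld)
    print(f"daily input / inventory ({label}: {ehs} ug/L x {mld} m): "
          f"{frac:.2e} per day")
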