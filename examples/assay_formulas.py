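"""The closed-form companion assay metrics.

Receptor internalisation from surface MFI against an on-ice control,
autophagic flux from LC3-II MFI with and without BafA1, and qPCR
relative expression by delta-delta-Ct.
"""

from degradome import autophagic_flux, ddct_fold_change, percent_internalised

pct = percent_internalised(mfi_sample=420.0, mfi_ice90=1200.0)
print(f"internalised receptor after warming: {pct:.1f}%")

flux = autophagic_flux(mfi_bafa1=950.0, mfi_vehicle=610.0)
print(f"autophagic flux (BafA1 - vehicle)/vehicle: {flux:.3f}")

fold = ddct_fold_change(ct_target_test=24.1, ct_ref_test=17.9,
                        ct_target_ctrl=22.6, ct_ref_ctrl=18.0)
print(f"relative mRNA expression 2^(-ddCt): {fold:.3f}")
print("Internalisation compares surface signal to cells held on ice (no")
print("uptake); flux > 0 means cargo accumulates when the lysosome is")
print("blocked; the ddCt fold change is relative to the control condition")
print("after reference-gene normalisation.")
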