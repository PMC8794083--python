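# Example iML1515 reactions with a pronounced flux-range shift between the model
# template BOF (mBOF) and the experimentally determined BOF (eBOF). FVA at 100%
# optimality, default model exchanges with the cobalamin exchange opened.
# Fluxes in mmol/gCDW/h.
reaction	pathway	mbof_min	mbof_max	ebof_min	ebof_max
MCOATA	Membrane Lipid Metabolism	0.0287	0.0289	0.0830	0.0830
UAGDP	Cell Envelope Biosynthesis	0.0628	0.0629	0.1020	0.1020
POR5	Pyruvate Metabolism	0.0938	0.0946	0.0440	0.0441
TMDS	Nucleotide Salvage Pathway	0.0218	0.0218	0.0098	0.0098
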