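# Polymer-incorporated residue masses (monomer minus the water or equivalent
# leaving group lost on polymerization). Masses in g/mmol, average atomic weights.
monomer_id	macro_class	residue_formula	residue_mass
Ala	protein	C3H5NO	0.071079
Arg	protein	C6H12N4O	0.156189
Asn	protein	C4H6N2O2	0.114104
Asp	protein	C4H5NO3	0.115088
Cys	protein	C3H5NOS	0.103139
Gln	protein	C5H8N2O2	0.128131
Glu	protein	C5H7NO3	0.129115
Gly	protein	C2H3NO	0.057052
His	protein	C6H7N3O	0.137142
Ile	protein	C6H11NO	0.113160
Leu	protein	C6H11NO	0.113160
Lys	protein	C6H12N2O	0.128175
Met	protein	C5H9NOS	0.131193
Phe	protein	C9H9NO	0.147177
Pro	protein	C5H7NO	0.097117
Ser	protein	C3H5NO2	0.087078
Thr	protein	C4H7NO2	0.101105
Trp	protein	C11H10N2O	0.186214
Tyr	protein	C9H9NO2	0.163176
Val	protein	C5H9NO	0.099133
mDAP	protein	C7H12N2O3	0.172184
AMP	RNA	C10H12N5O6P	0.329209
GMP	RNA	C10H12N5O7P	0.345208
CMP	RNA	C9H12N3O7P	0.305183
UMP	RNA	C9H11N2O8P	0.306167
dAMP	DNA	C10H12N5O5P	0.313210
dGMP	DNA	C10H12N5O6P	0.329209
dCMP	DNA	C9H12N3O6P	0.289184
dTMP	DNA	C10H13N2O7P	0.304195
glucose	carbohydrate	C6H10O5	0.162141
galactose	carbohydrate	C6H10O5	0.162141
glucosamine	carbohydrate	C6H11NO4	0.161157
N-acetylglucosamine	carbohydrate	C8H13NO5	0.203194
N-acetylmuramate	carbohydrate	C11H17NO7	0.275257
KDO	carbohydrate	C8H12O7	0.220177
heptose	carbohydrate	C7H12O6	0.192167
rhamnose	carbohydrate	C6H10O4	0.146142
ribose	carbohydrate	C5H8O4	0.132115
acyl_3OH_C14	lipid	C14H26O2	0.226360
phosphate	lipid	HO3P	0.079979
lipid	lipid	C37H72NO8P	0.689956
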