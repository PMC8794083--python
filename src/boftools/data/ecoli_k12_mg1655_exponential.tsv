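# Macromolecular biomass composition of E. coli K-12 MG1655, aerobic balanced
# exponential growth on glucose minimal medium (batch fermentor, mu = 0.71 1/h).
# All values in g/gCDW. Class totals ("TOTAL" rows) are measured independently of
# the monomer breakdowns. "A+B" monomer ids are combined pools quantified jointly
# (acid hydrolysis deamidates Gln/Asn to Glu/Asp). status: measured | estimated |
# proxy_derived | not_detected. Ribose is reported but excluded from coverage
# (acid-catalyzed degradation makes it unreliable as an RNA estimate).
class	monomer	mass_fraction	sd	status	note
protein	TOTAL	0.54	0.02	measured
protein	Ala	0.046	0.004	measured
protein	Arg	0.052	0.006	measured
protein	Asp+Asn	0.052	0.009	measured
protein	Cys	0.010		estimated	regression from proteome prevalence
protein	Glu+Gln	0.049	0.007	measured
protein	Gly	0.025	0.003	measured
protein	His	0.012	0.003	measured
protein	Ile	0.026	0.002	measured
protein	Leu	0.050	0.007	measured
protein	Lys	0.036	0.002	measured
protein	Met	0.018		estimated	regression from proteome prevalence
protein	Phe	0.028	0.002	measured
protein	Pro	0.022		estimated	regression from proteome prevalence
protein	Ser	0.021	0.004	measured
protein	Thr	0.028	0.001	measured
protein	Trp	0.012		estimated	regression from proteome prevalence
protein	Tyr	0.016	0.003	measured
protein	Val	0.033	0.003	measured
RNA	TOTAL	0.190	0.004	measured
RNA	AMP	0.050		estimated	distribution from rRNA gene composition
RNA	GMP	0.064		estimated	distribution from rRNA gene composition
RNA	CMP	0.040		estimated	distribution from rRNA gene composition
RNA	UMP	0.037		estimated	distribution from rRNA gene composition
DNA	TOTAL	0.013	0.003	measured
DNA	dAMP	0.003		estimated	distribution from genome sequence
DNA	dGMP	0.004		estimated	distribution from genome sequence
DNA	dCMP	0.003		estimated	distribution from genome sequence
DNA	dTMP	0.003		estimated	distribution from genome sequence
carbohydrate	TOTAL	0.0312	0.0005	measured
carbohydrate	glucose	0.0224	0.0002	measured
carbohydrate	glucosamine	0.0053	0.0002	measured
carbohydrate	galactose	0.0036	0.0004	measured
carbohydrate	rhamnose	0		not_detected
carbohydrate	N-acetylglucosamine	0		not_detected	de-N-acetylated to glucosamine during hydrolysis
carbohydrate	ribose	0.051		measured	excluded: unstable under acid hydrolysis
lipid	TOTAL	0.061	0.002	measured
lipid	lipid	0.061	0.002	measured	gravimetric lumped total
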