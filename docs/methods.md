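# Methods

## The model being built

A biomass objective function is a pseudo-reaction
`sum_i c_i X_i -> biomass` with `c_i < 0` for consumed precursors
(mmol/gCDW). When the biomass pseudo-species has molar mass exactly
1 g/mmol, flux through the reaction equals specific growth rate (1/h), which
is why every built BOF is rescaled so that

    bof_mass = - sum_i c_i * M_i = 1 g/mmol

over the metabolic (non-maintenance) part. The growth-associated maintenance
term (GAM: ATP + H2O -> ADP + Pi + H) is detected in a template by the
magnitude of its hydrolysis products, kept apart, and excluded from
normalization — the set is mass-neutral, so it cannot contribute to the molar
mass, and the energy parameter is outside the scope of composition
measurements.

Mass bookkeeping is *convention independent*: a template may consume free
amino acids and release water per peptide bond, or NTPs with pyrophosphate
release per incorporated NMP. All mass accounting uses the net incorporated
(residue) mass — precursor molar mass minus the byproducts its polymerization
convention releases — so `bof_mass` and the mass-redistribution figures do not
depend on which convention the template happens to use. Residue masses
(monomer minus the water or equivalent leaving group lost on polymerization)
ship as a versioned table (`data/residue_masses.tsv`, average atomic weights)
and are overridable per call.

## Inference steps and their assumptions

* **Amino acid imputation.** Amino acids degraded or invisible in acid
  hydrolysis (Cys, Met, Pro, Trp in the shipped table) are predicted from an
  OLS fit of measured mass fractions against proteome prevalence. Default:
  intercept included, prevalence on a mass basis (both axes in mass-fraction
  units; an additive measurement loss is plausible). A through-origin variant
  is available (`intercept=False`). With exactly proportional truth both
  variants coincide.
* **Deamidation pools.** Glu+Gln and Asp+Asn pools are stored as pairs and
  split downstream, proportional to prevalence; the split conserves the pool
  total exactly. When no sequence data are supplied, the template BOF's own
  molar ratios can serve as the prevalence source
  (`template_pool_prevalence`); with neither, pools are split evenly with a
  warning.
* **Nucleotide distributions.** RNA monomer fractions come from the base
  composition of rRNA genes (gene strand, T read as U; each record weight 1 by
  default, i.e. a 1:1:1 operon stoichiometry, overridable), applied to the
  whole RNA class total — the assumption being that rRNA dominates total RNA
  and the remainder is compositionally similar. DNA fractions come from the
  genome sequence counted on both strands, which enforces dAMP=dTMP and
  dGMP=dCMP exactly. Ambiguous bases (N) are skipped, with an error above 1%.

## Envelope-polymer presets

The K-12 presets (`data/polymer_presets.yaml`) encode:

* **Peptidoglycan** — GlcNAc:MurNAc 1:1 disaccharide with an average
  4.5-residue stem (2.5 Ala, 1 Glu, 1 meso-DAP), i.e. alternating crosslinked
  tetra/pentapeptides, matching the murein precursor conventions of the
  E. coli genome-scale templates. All measured glucosamine is treated as
  de-N-acetylated GlcNAc and rescaled by the residue-mass ratio.
* **LPS (K-12 core type)** — tetraacylated lipid A (2 GlcN, 2 phosphates,
  4x 3-OH-C14, matching the template's KDO2-lipid A precursor), 2 KDO,
  4 heptoses (three inner-core, one side-chain), and an outer core of 3
  glucoses plus the single protruding galactose that marks the K-12 core. The
  galactose fixes the LPS molar amount; outer-core glucose is *not* added as
  implicit mass because hydrolysis releases it into the already measured
  glucose pool.

On the shipped composition these presets take coverage from 83.5% to 91.9% of
cell dry mass and the carbohydrate class to 7.56% — the numbers are sensitive
to the preset stoichiometry at the few-tenths-of-a-percent level (e.g.
dropping the side-chain heptose lowers carbohydrate by ~0.4 points), which is
why the presets are data, not code. Lipid-A glucosamine is classed as
carbohydrate (it is an amino sugar); acyl chains and phosphates as lipid; the
peptide stem as protein.

Measured ribose is parsed but flagged out of coverage by default: released
ribose is unstable under hot acid and unreliable as an RNA estimate. Coverage
figures count only measured and proxy-implied component mass, never
template-only components (ions, cofactors).

## Template merging

Measured components replace template coefficients; byproduct release (PPi,
H2O) is rebalanced by the coefficient difference so each precursor's net
incorporated mass stays equal to its residue mass. Template-only components
are retained unchanged; components measured as not detected are removed. The
lumped gravimetric lipid total is spread over the template's
phosphatidylethanolamine species at their template molar ratios (no
lipid-class resolution is attempted). Whole polymers map onto the template's
envelope precursors (two repeat units per `murein5px4p`, one LPS unit per
`kdo2lipid4`); outer-core sugars beyond the template species are folded into
the measured glucose pool's glycogen assignment. Glucose itself maps to the
template's glycogen precursor.

The bundled template is iJO1366 (shipped with cobrapy and loaded at run time,
never copied). Its biomass reaction re-derives a molar mass of 0.999994
g/mmol under this package's accounting — an independent consistency check of
the residue-mass bookkeeping. The merge policy uses BiGG identifiers and works
unchanged with iML1515 when that file is supplied by the user.

## Flux comparison

FVA runs at an optimality fraction of 1.0 implemented as
`v_obj >= (1 - 1e-9) * mu*` — strict equality is numerically brittle. Reported
fluxes are rounded to 1e-6 before metric computation so xi = 0/1
classifications are reproducible. The overlap metric xi is computed on signed
intervals (reversible reactions are not split). When both intervals are
points (width < 1e-9) the ratio is undefined; the limiting behavior motivates
xi = 1 for coinciding centers, else 0. CP_r is flagged undefined (NaN) when
the reference midpoint is below tolerance. A reaction counts as *high-flux*
when its interval midpoint exceeds 0.001 mmol/gCDW/h in magnitude under
either BOF — the inclusive rule is the symmetric reading of the filter; the
threshold and the 10% center-shift criterion are options. Medium handling
uses the model's default exchange bounds with explicit named overrides only
(the E. coli comparison opens the cobalamin exchange, `EX_cbl1_e` lower bound
-1000, without which neither BOF grows).

LP solving is delegated to cobrapy/GLPK with feasibility tolerance 1e-9. The
correctness reference for FVA is an exhaustive vertex enumeration of the flux
polytope `{v : Sv = 0, l <= v <= u}` (every vertex has at least n - rank(S)
coordinates at a bound; all fixings are enumerated and the square system
solved directly), with the optimality constraint encoded through a bounded
slack variable. The oracle touches no LP code and is exact for the tiny
(<= 8 reaction) networks it is used on.

## Synthetic data: what it emulates, what it does not

`SyntheticScenario` drives three generators from one seed (independent child
streams per generator):

* toy models — substrate uptake, per-precursor synthesis (2-3 precursors,
  randomized capacities/demands), an optional parallel diamond creating
  non-degenerate FVA ranges, finite bounds throughout; ground-truth ranges
  from the vertex oracle;
* sequences — protein-coding, rRNA-gene and genome records built by explicit
  residue counts, so realized frequencies equal their targets exactly;
* measurement tables — truncated multiplicative Gaussian noise per record
  (sd = noise_sd x truth, independent across records), withheld monomers
  (Cys, Met) emulating hydrolysis losses, and merged deamidation pools.

The true composition is constructed to satisfy the inference assumptions
exactly (amino acid mass fractions proportional to prevalence, nucleotide
fractions equal to sequence composition). Passing recovery tests therefore
demonstrates that the pipeline inverts its own model of the measurement
process — unbiased recovery under multiplicative noise and machine-precision
recovery without noise — not that real assays satisfy those assumptions
(real hydrolysis losses are amino-acid specific and correlated; real rRNA is
not the whole of RNA). Default class totals mirror exponentially growing
E. coli (protein 0.54, RNA 0.19, DNA 0.013, carbohydrate 0.031, lipid 0.061
g/gCDW); default noise 5% relative, the scale of the reported per-class
standard deviations.

Problem sizes used by the shipped checks: 100 seeded tiny models for
FVA-vs-oracle agreement, 50 replicates at 5% noise for recovery, 10,000
random interval pairs for the xi invariants; the genome-scale demonstration
runs FVA on the four example envelope/nucleotide reactions of the bundled
template rather than all 2583.

## Known limitations

* The genome-scale reallocation (~9.9% against the bundled iJO1366 template)
  is not numerically identical to the figure obtained against iML1515
  (~14.8%): the templates differ in GAM, lipid species and the presence of a
  glycogen term. The iML1515 comparison runs as a gated integration test when
  the user supplies the model file.
* Lipids are a single gravimetric number spread over template species; no
  lipidomics resolution.
* GAM/NGAM are never re-estimated; they pass through from the template.
* Proxy-based polymer quantification inherits the proxies' assumptions: all
  glucosamine from peptidoglycan GlcNAc, all galactose from LPS. Strains with
  galactose-containing capsular polysaccharides or free glucosamine pools
  would bias both.
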