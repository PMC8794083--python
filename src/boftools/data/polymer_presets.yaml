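# Cell-envelope polymer definitions for E. coli K-12, used to convert measured
# proxy monomers into full polymer mass. Counts are per repeat unit; masses are
# polymer-incorporated residue masses from residue_masses.tsv.
#
# source: proxy         - the measured monomer that reports the polymer level
#         implicit      - not measured directly; added as proxy_derived records
#         measured_pool - released into an already-measured monomer pool during
#                         hydrolysis (mass already counted; annotated only)
peptidoglycan:
  description: >
    Murein repeat unit: GlcNAc-MurNAc disaccharide carrying an average
    4.5-residue peptide stem (alternating crosslinked tetra- and pentapeptides,
    L-Ala-D-Glu-mDAP-D-Ala(-D-Ala)). All detected glucosamine is assumed to
    originate from N-acetylglucosamine de-N-acetylated during hydrolysis.
  constituents:
    - {monomer: N-acetylglucosamine, count: 1, source: proxy}
    - {monomer: N-acetylmuramate, count: 1, source: implicit}
    - {monomer: Ala, count: 2.5, source: implicit}
    - {monomer: Glu, count: 1, source: implicit}
    - {monomer: mDAP, count: 1, source: implicit}
lps:
  description: >
    K-12 core lipopolysaccharide: tetraacylated lipid A (2 GlcN, 2 phosphates,
    4x 3-OH-C14 acyl chains), inner core 2 KDO + 3 heptoses, outer core
    3 glucoses with the single protruding galactose characteristic of the K-12
    core type plus a fourth (side-chain) heptose. Galactose reports the LPS
    level; outer-core glucose is released into the measured glucose pool.
  constituents:
    - {monomer: galactose, count: 1, source: proxy}
    - {monomer: glucose, count: 3, source: measured_pool}
    - {monomer: heptose, count: 4, source: implicit}
    - {monomer: KDO, count: 2, source: implicit}
    - {monomer: glucosamine, count: 2, source: implicit}
    - {monomer: phosphate, count: 2, source: implicit}
    - {monomer: acyl_3OH_C14, count: 4, source: implicit}
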