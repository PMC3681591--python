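# Central carbon metabolism of Pichia pastoris growing on glycerol:
# glycolysis/gluconeogenesis, pentose phosphate pathway, TCA cycle,
# fermentative branch, oxidative phosphorylation and a lumped biomass
# synthesis reaction.
#
# Reaction-text dialect:
#   metabolite <id> "<name>" <compartment> <balanced|unbalanced>
#   <rid>: c1 M1 + c2 M2 -> c3 M3 + ... [rev] [measured] [inactive]
#
# Conventions:
#  - Linear chains are lumped where the intermediates carry no information
#    (GAPDH+PGK, PGM+enolase, G6PDH+6PGDH, aKGDH+succinyl-CoA synthetase).
#  - Succinate dehydrogenase passes its electrons directly to the quinone
#    pool, which is not tracked; as a result the only conserved quantity of
#    the internal network is carbon, and the measured rates carry exactly
#    one redundant (carbon-balance) equation.
#  - The glyoxylate shunt is present but flagged inactive (glycerol-grown
#    cells); inactive reactions are dropped when the model is built.
#  - The biomass reaction r44 uses a placeholder macromolecular composition
#    (precursor coefficients in mmol per gDCW, flux in 1/h); it can be
#    overridden at load time.

metabolite GOLc   "glycerol"                    cytosol       balanced
metabolite G3P    "glycerol-3-phosphate"        cytosol       balanced
metabolite DHAP   "dihydroxyacetone phosphate"  cytosol       balanced
metabolite GAP    "glyceraldehyde-3-phosphate"  cytosol       balanced
metabolite FBP    "fructose-1,6-bisphosphate"   cytosol       balanced
metabolite F6P    "fructose-6-phosphate"        cytosol       balanced
metabolite G6P    "glucose-6-phosphate"         cytosol       balanced
metabolite RU5P   "ribulose-5-phosphate"        cytosol       balanced
metabolite XU5P   "xylulose-5-phosphate"        cytosol       balanced
metabolite R5P    "ribose-5-phosphate"          cytosol       balanced
metabolite S7P    "sedoheptulose-7-phosphate"   cytosol       balanced
metabolite E4P    "erythrose-4-phosphate"       cytosol       balanced
metabolite PG3    "3-phosphoglycerate"          cytosol       balanced
metabolite PEP    "phosphoenolpyruvate"         cytosol       balanced
metabolite PYRc   "pyruvate"                    cytosol       balanced
metabolite ACD    "acetaldehyde"                cytosol       balanced
metabolite ETHc   "ethanol"                     cytosol       balanced
metabolite ACEc   "acetate"                     cytosol       balanced
metabolite ACCOAc "acetyl-CoA"                  cytosol       balanced
metabolite OAc    "oxaloacetate"                cytosol       balanced
metabolite MALc   "malate"                      cytosol       balanced
metabolite PYRm   "pyruvate"                    mitochondria  balanced
metabolite ACCOAm "acetyl-CoA"                  mitochondria  balanced
metabolite OAm    "oxaloacetate"                mitochondria  balanced
metabolite CITm   "citrate"                     mitochondria  balanced
metabolite ICITm  "isocitrate"                  mitochondria  balanced
metabolite AKGm   "alpha-ketoglutarate"         mitochondria  balanced
metabolite SUCm   "succinate"                   mitochondria  balanced
metabolite FUMm   "fumarate"                    mitochondria  balanced
metabolite MALm   "malate"                      mitochondria  balanced
metabolite ATP    "ATP"                         cytosol       balanced
metabolite NADH   "NADH"                        cytosol       balanced
metabolite NADPH  "NADPH"                       cytosol       balanced
metabolite FADH2  "FADH2"                       mitochondria  balanced
metabolite O2d    "dissolved oxygen"            cytosol       balanced
metabolite CO2d   "dissolved carbon dioxide"    cytosol       balanced
metabolite GOLx   "glycerol (medium)"           extracellular unbalanced
metabolite O2x    "oxygen (off-gas)"            extracellular unbalanced
metabolite CO2x   "carbon dioxide (off-gas)"    extracellular unbalanced
metabolite ETHx   "ethanol (medium)"            extracellular unbalanced
metabolite SUCx   "succinate (medium)"          extracellular unbalanced
metabolite ACEx   "acetate (medium)"            extracellular unbalanced
metabolite PYRx   "pyruvate (medium)"           extracellular unbalanced
metabolite CITx   "citrate (medium)"            extracellular unbalanced
metabolite BIOM   "biomass"                     extracellular unbalanced

# glycerol assimilation
r1: GOLc + ATP -> G3P
r2: G3P -> DHAP + FADH2
# gluconeogenesis / upper glycolysis
r3: GAP + DHAP -> FBP rev
r4: FBP -> F6P
r5: DHAP -> GAP rev
r6: GAP -> PG3 + ATP + NADH
r7: F6P -> G6P rev
# lower glycolysis
r8: PG3 -> PEP rev
r9: PEP -> PYRc + ATP
# fermentative branch
r10: PYRc -> ACD + CO2d
r11: ACD + NADH -> ETHc rev
r12: ACD -> ACEc + NADPH
r13: ACEc + 2 ATP -> ACCOAc
# anaplerosis and the malate shuttle
r14: PYRc + ATP + CO2d -> OAc
r15: OAc + NADH -> MALc rev
r16: MALc -> MALm rev
r17: PYRc -> PYRm rev
# TCA cycle
r18: PYRm -> ACCOAm + CO2d + NADH
r19: OAm + ACCOAm -> CITm
r20: CITm -> ICITm rev
r21: ICITm -> AKGm + CO2d + NADH
r22: AKGm -> SUCm + CO2d + NADH + ATP
r23: SUCm -> FUMm rev
r24: FUMm -> MALm rev
r25: MALm -> OAm + NADH rev
# pentose phosphate pathway
r26: G6P -> RU5P + CO2d + 2 NADPH
r27: RU5P -> XU5P rev
r28: RU5P -> R5P rev
r29: XU5P + R5P -> S7P + GAP rev
r30: S7P + GAP -> E4P + F6P rev
r31: XU5P + E4P -> F6P + GAP rev
# energy and redox housekeeping
r32: NADH + 0.5 O2d -> 1.5 ATP
r33: FADH2 + 0.5 O2d -> ATP
r34: ATP ->
r35: NADH + ATP -> NADPH
# exchange with the medium / off-gas (the measured set)
r36: O2x -> O2d measured
r37: CO2d -> CO2x measured
r38: ETHc -> ETHx measured
r39: SUCm -> SUCx measured
r40: GOLx -> GOLc measured
r41: ACEc -> ACEx measured
r42: PYRc -> PYRx measured
r43: CITm -> CITx measured
# biomass synthesis (placeholder macromolecular composition, mmol/gDCW)
r44: 1.2 G6P + 0.5 R5P + 0.4 E4P + 1.3 PG3 + 0.8 PEP + 1.8 PYRc + 2.0 ACCOAc + 1.4 OAc + 1.6 AKGm + 35 ATP + 10 NADPH -> BIOM + 3.2 NADH + 1.6 CO2d measured
# glyoxylate shunt (lumped isocitrate lyase + malate synthase)
r45: ICITm + ACCOAm -> SUCm + MALm inactive
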