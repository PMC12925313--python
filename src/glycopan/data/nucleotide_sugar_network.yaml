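# Reference nucleotide-sugar biosynthesis network.
#
# Directed reaction map from central-carbon entry points
# (fructose-6-phosphate F6P, ribulose-5-phosphate Ru5P,
# sedoheptulose-7-phosphate S7P) to nucleotide-sugar products, each
# reaction gated by KEGG Orthology gene families (outer list = OR over
# isoenzymes, inner list = AND within a complex).
#
# NOTE (data curation): the KO-to-reaction assignments below are a
# best-effort transcription of the standard bacterial nucleotide-sugar
# map; they are editable data, not code, and any re-use against real
# genomes should start by reviewing this file against the current KEGG
# "Biosynthesis of nucleotide sugars" map.

metabolites:
  - F6P
  - Ru5P
  - S7P
  - G6P
  - G1P
  - GlcN6P
  - GlcN1P
  - M6P
  - M1P
  - A5P
  - KDO8P
  - KDO
  - H7P
  - H17PP
  - H1P
  - ADP-DDHep
  - dTDP-4K6DG
  - dTDP-4KRha
  - UDP-4K6D-GlcNAc
  - UDP-4A6D-GlcNAc
  - Pse5Ac7Ac
  - Leg5Ac7Ac
  - UDP-GlcNAc3NAcA
  - GDP-4K6D-Man
  - UDP-Glc
  - UDP-Gal
  - UDP-GlcA
  - UDP-GalA
  - ADP-Glc
  - dTDP-Glc
  - dTDP-Rha
  - dTDP-Fuc4N
  - CDP-Glc
  - UDP-GlcNAc
  - UDP-GalNAc
  - UDP-ManNAc
  - UDP-GlcNAcA
  - UDP-GalNAcA
  - UDP-ManNAc3NAcA
  - UDP-QuiNAc
  - CMP-Pse5Ac7Ac
  - CMP-Leg5Ac7Ac
  - GDP-Man
  - GDP-Fuc
  - GDP-Per
  - GDP-ManA
  - CMP-KDO
  - ADP-LDManHep

sources: [F6P, Ru5P, S7P]

reactions:
  # hexose backbone
  - {id: pgi,   substrate: F6P,  product: G6P,  genes: [[K01810]]}
  - {id: pgm,   substrate: G6P,  product: G1P,  genes: [[K01835]]}
  - {id: galU,  substrate: G1P,  product: UDP-Glc,  genes: [[K00963]]}
  - {id: galE,  substrate: UDP-Glc, product: UDP-Gal, genes: [[K01784]]}
  - {id: ugd,   substrate: UDP-Glc, product: UDP-GlcA, genes: [[K00012]]}
  - {id: glaKL, substrate: UDP-GlcA, product: UDP-GalA, genes: [[K08679]]}
  - {id: glgC,  substrate: G1P,  product: ADP-Glc, genes: [[K00975]]}
  - {id: rffH,  substrate: G1P,  product: dTDP-Glc, genes: [[K00973]]}
  - {id: rfbF,  substrate: G1P,  product: CDP-Glc, genes: [[K00978]]}
  # dTDP deoxyhexoses
  - {id: rmlB,  substrate: dTDP-Glc, product: dTDP-4K6DG, genes: [[K01710]]}
  - {id: rmlC,  substrate: dTDP-4K6DG, product: dTDP-4KRha, genes: [[K01790]]}
  - {id: rmlD,  substrate: dTDP-4KRha, product: dTDP-Rha, genes: [[K00067]]}
  - {id: fdtB,  substrate: dTDP-4K6DG, product: dTDP-Fuc4N, genes: [[K13017]]}
  # hexosamines
  - {id: glmS,  substrate: F6P, product: GlcN6P, genes: [[K00820]]}
  - {id: glmM,  substrate: GlcN6P, product: GlcN1P, genes: [[K03431]]}
  - {id: glmU,  substrate: GlcN1P, product: UDP-GlcNAc, genes: [[K04042]]}
  - {id: gne,   substrate: UDP-GlcNAc, product: UDP-GalNAc, genes: [[K15894]]}
  - {id: wecB,  substrate: UDP-GlcNAc, product: UDP-ManNAc, genes: [[K01791]]}
  # hexosamine uronic acids
  - {id: wbpA,  substrate: UDP-GlcNAc, product: UDP-GlcNAcA, genes: [[K02472]]}
  - {id: gnaAE, substrate: UDP-GlcNAcA, product: UDP-GalNAcA, genes: [[K13019]]}
  - {id: wbpBED, substrate: UDP-GlcNAcA, product: UDP-GlcNAc3NAcA,
     genes: [[K13311, K13312, K13313]]}
  - {id: wbpI,  substrate: UDP-GlcNAc3NAcA, product: UDP-ManNAc3NAcA,
     genes: [[K13014]]}
  # UDP-GlcNAc-derived rare sugars
  - {id: pseB,  substrate: UDP-GlcNAc, product: UDP-4K6D-GlcNAc, genes: [[K15897]]}
  - {id: pseC,  substrate: UDP-4K6D-GlcNAc, product: UDP-4A6D-GlcNAc, genes: [[K15898]]}
  - {id: pseHGI, substrate: UDP-4A6D-GlcNAc, product: Pse5Ac7Ac, genes: [[K15896]]}
  - {id: pseF,  substrate: Pse5Ac7Ac, product: CMP-Pse5Ac7Ac, genes: [[K15912]]}
  - {id: legBCH, substrate: UDP-4K6D-GlcNAc, product: Leg5Ac7Ac, genes: [[K21279]]}
  - {id: legF,  substrate: Leg5Ac7Ac, product: CMP-Leg5Ac7Ac, genes: [[K21280]]}
  - {id: quiB,  substrate: UDP-4K6D-GlcNAc, product: UDP-QuiNAc, genes: [[K24310]]}
  # GDP sugars
  - {id: manA,  substrate: F6P, product: M6P, genes: [[K01809]]}
  - {id: manB,  substrate: M6P, product: M1P, genes: [[K01840]]}
  - {id: manC,  substrate: M1P, product: GDP-Man, genes: [[K00971]]}
  - {id: gmd,   substrate: GDP-Man, product: GDP-4K6D-Man, genes: [[K01711]]}
  - {id: fcl,   substrate: GDP-4K6D-Man, product: GDP-Fuc, genes: [[K02377]]}
  - {id: per,   substrate: GDP-4K6D-Man, product: GDP-Per, genes: [[K13010]]}
  - {id: algD,  substrate: GDP-Man, product: GDP-ManA, genes: [[K00066]]}
  # KDO branch
  - {id: kdsD,  substrate: Ru5P, product: A5P, genes: [[K06041]]}
  - {id: kdsA,  substrate: A5P, product: KDO8P, genes: [[K01627]]}
  - {id: kdsC,  substrate: KDO8P, product: KDO, genes: [[K03270]]}
  - {id: kdsB,  substrate: KDO, product: CMP-KDO, genes: [[K00979]]}
  # heptose branch
  - {id: gmhA,  substrate: S7P, product: H7P, genes: [[K03271]]}
  - {id: hldEk, substrate: H7P, product: H17PP, genes: [[K03272]]}
  - {id: gmhB,  substrate: H17PP, product: H1P, genes: [[K03273]]}
  - {id: hldEa, substrate: H1P, product: ADP-DDHep, genes: [[K03272]]}
  - {id: hldD,  substrate: ADP-DDHep, product: ADP-LDManHep, genes: [[K03274]]}

products:
  UDP-Glc: galU
  UDP-Gal: galE
  UDP-GlcA: ugd
  UDP-GalA: glaKL
  ADP-Glc: glgC
  dTDP-Glc: rffH
  dTDP-Rha: rmlD
  dTDP-Fuc4N: fdtB
  CDP-Glc: rfbF
  UDP-GlcNAc: glmU
  UDP-GalNAc: gne
  UDP-ManNAc: wecB
  UDP-GlcNAcA: wbpA
  UDP-GalNAcA: gnaAE
  UDP-ManNAc3NAcA: wbpI
  UDP-QuiNAc: quiB
  CMP-Pse5Ac7Ac: pseF
  CMP-Leg5Ac7Ac: legF
  GDP-Man: manC
  GDP-Fuc: fcl
  GDP-Per: per
  GDP-ManA: algD
  CMP-KDO: kdsB
  ADP-LDManHep: hldD

route_depth_cap: 15
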