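# Published binarized marker panels: one rule per gene, evaluated on
# technically + biologically normalized counts. An "up" rule scores 1 when
# the count exceeds the cut-off, a "down" rule when it falls below it.
- entity: NSOI
  rules:
    - {gene: ANG, direction: up, cutoff: 60}
    - {gene: AQP1, direction: up, cutoff: 125}
    - {gene: BMPR1A, direction: up, cutoff: 125}
    - {gene: CALD1, direction: up, cutoff: 300}
    - {gene: ERBB2, direction: up, cutoff: 50}
    - {gene: ITGA7, direction: up, cutoff: 50}
    - {gene: NME4, direction: up, cutoff: 50}
    - {gene: NR4A3, direction: up, cutoff: 50}
    - {gene: PDCL3, direction: up, cutoff: 100}
    - {gene: TNXB, direction: up, cutoff: 75}
    - {gene: SDC4, direction: up, cutoff: 100}
    - {gene: RPS27A, direction: down, cutoff: 5500}
- entity: MALT
  rules:
    - {gene: APP, direction: down, cutoff: 400}
    - {gene: AQP1, direction: down, cutoff: 50}
    - {gene: CD59, direction: down, cutoff: 500}
    - {gene: CLIC4, direction: down, cutoff: 200}
    - {gene: HSPB1, direction: down, cutoff: 300}
    - {gene: JAG1, direction: down, cutoff: 50}
    - {gene: LGALS3, direction: down, cutoff: 200}
    - {gene: MEG3, direction: down, cutoff: 75}
    - {gene: NRP1, direction: down, cutoff: 250}
    - {gene: RAC1, direction: down, cutoff: 250}
    - {gene: RTN4, direction: down, cutoff: 250}
    - {gene: TNS1, direction: down, cutoff: 150}
- entity: IgG4-ROD
  rules:
    - {gene: ADAM9, direction: up, cutoff: 250}
    - {gene: ADAM17, direction: up, cutoff: 300}
    - {gene: ANXA2P2, direction: up, cutoff: 3000}
    - {gene: CLEC2B, direction: up, cutoff: 500}
    - {gene: CLIC4, direction: up, cutoff: 500}
    - {gene: FCGR2A, direction: up, cutoff: 500}
    - {gene: GPX1, direction: up, cutoff: 600}
    - {gene: NRP1, direction: up, cutoff: 1200}
    - {gene: PSMD7, direction: up, cutoff: 550}
    - {gene: RBX1, direction: up, cutoff: 500}
    - {gene: RHOA, direction: up, cutoff: 700}
    - {gene: RNH1, direction: up, cutoff: 350}
    - {gene: TCEB1, direction: up, cutoff: 450}
    - {gene: TLR4, direction: up, cutoff: 450}
    - {gene: TNFRSF1A, direction: up, cutoff: 400}
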