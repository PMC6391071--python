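# Native-MS inputs for the helicase-loader system.
#
# Monomer masses are the published average masses of the constructs:
# DnaB after N-terminal Met loss, the lambda-phage loader protein, and the
# origin-derived 43-mer ssDNA with 5'- and 3'-OH termini.  Measured masses
# are the reported assembly masses (magnesium-acetate buffer series plus
# the ssDNA-bound sample).
components:
  - {name: DnaB, monomer_mass: 52259.0, count_min: 0, count_max: 6}
  - {name: lambdaP, monomer_mass: 26518.0, count_min: 0, count_max: 8}
  - {name: ssDNA43, monomer_mass: 13141.0, count_min: 0, count_max: 1}
measured:
  - {label: B6P5, mass: 446500}
  - {label: B6P6, mass: 473100}
  - {label: B6P4, mass: 419950}
  - {label: B6P5_ssDNA, mass: 459480}
ssdna_sequence: TGACGAATAATCTTTTCTTTTTTCTTTTGTAATAGTGTCTTTT
protein_chain_map:
  EcDnaB: [A, B, C, D, E, F]
  lambdaP: [V, W, X, Y, Z]
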