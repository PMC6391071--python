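# Tier definitions for the deposited helicase-loader open-spiral model
# (PDB 6BBM). Domain order is the spiral order, bottom -> top: DnaB chain A
# sits at the bottom of the staircase and chain B at the top, with the
# breached interface between them, so the staircase path is A,F,E,D,C,B.
#
# Two NTD-globe conventions are in circulation for E. coli DnaB
# (residues 31-113 vs a head 32-123 / tail 124-173 split); both are
# provided as separate tiers so neither is silently preferred.
#
# Intervals are author numbering; partially unmodelled intervals are fine
# (the COM is taken over modelled atoms and the modelled fraction logged).
tiers:
  - name: CTD
    domains:
      - {label: CTD_A, chain: A, start: 203, end: 471}
      - {label: CTD_F, chain: F, start: 203, end: 471}
      - {label: CTD_E, chain: E, start: 203, end: 471}
      - {label: CTD_D, chain: D, start: 203, end: 471}
      - {label: CTD_C, chain: C, start: 203, end: 471}
      - {label: CTD_B, chain: B, start: 203, end: 471}
  - name: NTD-globe
    domains:
      - {label: NTD_A, chain: A, start: 31, end: 113}
      - {label: NTD_F, chain: F, start: 31, end: 113}
      - {label: NTD_E, chain: E, start: 31, end: 113}
      - {label: NTD_D, chain: D, start: 31, end: 113}
      - {label: NTD_C, chain: C, start: 31, end: 113}
      - {label: NTD_B, chain: B, start: 31, end: 113}
  - name: NTD-head
    domains:
      - {label: HEAD_A, chain: A, start: 32, end: 123}
      - {label: HEAD_F, chain: F, start: 32, end: 123}
      - {label: HEAD_E, chain: E, start: 32, end: 123}
      - {label: HEAD_D, chain: D, start: 32, end: 123}
      - {label: HEAD_C, chain: C, start: 32, end: 123}
      - {label: HEAD_B, chain: B, start: 32, end: 123}
  - name: NTD-tail
    domains:
      - {label: TAIL_A, chain: A, start: 124, end: 173}
      - {label: TAIL_F, chain: F, start: 124, end: 173}
      - {label: TAIL_E, chain: E, start: 124, end: 173}
      - {label: TAIL_D, chain: D, start: 124, end: 173}
      - {label: TAIL_C, chain: C, start: 124, end: 173}
      - {label: TAIL_B, chain: B, start: 124, end: 173}
  - name: linker
    domains:
      - {label: LNK_A, chain: A, start: 182, end: 202}
      - {label: LNK_F, chain: F, start: 182, end: 202}
      - {label: LNK_E, chain: E, start: 182, end: 202}
      - {label: LNK_D, chain: D, start: 182, end: 202}
      - {label: LNK_C, chain: C, start: 182, end: 202}
      - {label: LNK_B, chain: B, start: 182, end: 202}
  - name: lambdaP
    domains:
      - {label: P1_Z, chain: Z, start: 109, end: 233}
      - {label: P2_Y, chain: Y, start: 109, end: 233}
      - {label: P3_X, chain: X, start: 109, end: 233}
      - {label: P4_W, chain: W, start: 109, end: 233}
      - {label: P5_V, chain: V, start: 109, end: 233}
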