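# Unified nearest-neighbour parameters (SantaLucia 1998, PNAS 95:1460).
# Enthalpies in cal/mol, entropies in cal/(mol*K), 1 M NaCl reference state.
# Stacks are keyed by the 5'->3' dinucleotide on the primer strand; the table
# is strand-symmetric (each stack equals its reverse complement).
name: santalucia1998
description: SantaLucia (1998) unified oligonucleotide parameters
init_dH: 0.0
init_dS: 0.0
# Duplex initiation split per terminal base pair: one term for each duplex
# end, chosen by whether the terminal pair is G.C or A.T.
terminal:
  GC: {dH: 100.0, dS: -2.8}
  AT: {dH: 2300.0, dS: 4.1}
stacks:
  AA: {dH: -7900.0, dS: -22.2}
  AT: {dH: -7200.0, dS: -20.4}
  TA: {dH: -7200.0, dS: -21.3}
  CA: {dH: -8500.0, dS: -22.7}
  GT: {dH: -8400.0, dS: -22.4}
  CT: {dH: -7800.0, dS: -21.0}
  GA: {dH: -8200.0, dS: -22.2}
  CG: {dH: -10600.0, dS: -27.2}
  GC: {dH: -9800.0, dS: -24.4}
  GG: {dH: -8000.0, dS: -19.9}
  TT: {dH: -7900.0, dS: -22.2}
  TG: {dH: -8500.0, dS: -22.7}
  AC: {dH: -8400.0, dS: -22.4}
  AG: {dH: -7800.0, dS: -21.0}
  TC: {dH: -8200.0, dS: -22.2}
  CC: {dH: -8000.0, dS: -19.9}
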