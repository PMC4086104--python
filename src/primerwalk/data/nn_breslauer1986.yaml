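# Nearest-neighbour parameters of Breslauer et al. (1986, PNAS 83:3746).
# Enthalpies in cal/mol, entropies in cal/(mol*K).
# The single initiation entropy (-10.8 cal/(mol*K)) is the convention used by
# the classical oligo/primer calculators built on this table.
name: breslauer1986
description: Breslauer et al. (1986) nearest-neighbour parameters
init_dH: 0.0
init_dS: -10.8
terminal: {}
stacks:
  AA: {dH: -9100.0, dS: -24.0}
  AT: {dH: -8600.0, dS: -23.9}
  TA: {dH: -6000.0, dS: -16.9}
  CA: {dH: -5800.0, dS: -12.9}
  GT: {dH: -6500.0, dS: -17.3}
  CT: {dH: -7800.0, dS: -20.8}
  GA: {dH: -5600.0, dS: -13.5}
  CG: {dH: -11900.0, dS: -27.8}
  GC: {dH: -11100.0, dS: -26.7}
  GG: {dH: -11000.0, dS: -26.6}
  TT: {dH: -9100.0, dS: -24.0}
  TG: {dH: -5800.0, dS: -12.9}
  AC: {dH: -6500.0, dS: -17.3}
  AG: {dH: -7800.0, dS: -20.8}
  TC: {dH: -5600.0, dS: -13.5}
  CC: {dH: -11000.0, dS: -26.6}
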