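# Bundled polymerase-buffer presets.
#
# High-fidelity polymerase buffers are mostly proprietary, so several entries
# are documented approximations derived from published or typical buffer
# compositions folded through the monovalent-equivalent conversion -- read the
# provenance_note of each preset before relying on it quantitatively.  Users
# can override any preset (or add their own) with a YAML file of the same
# shape passed to load_presets().
#
# Concentration units: mM for ions and dNTPs, mol/L for primer and template.
# Presets use the symmetric (4/[Primer]) equilibrium-constant convention of
# the classical online calculators; custom buffers default to the
# excess-primer simplification instead.
presets:
  standard_taq:
    provenance_note: >-
      Standard Taq reaction buffer: 50 mM KCl, 10 mM Tris-HCl, 1.5 mM MgCl2,
      with the usual 0.8 mM total dNTPs (0.2 mM each) and 250 nM primers.
      Composition is published; only the dNTP/primer levels are protocol
      defaults rather than buffer constituents.
    monovalent_mM: 50.0
    tris_mM: 10.0
    divalent_mM: 1.5
    dntp_mM: 0.8
    primer_M: 2.5e-7
    template_M: 5.0e-10
    k_mode: symmetric
  q5:
    provenance_note: >-
      High-fidelity Q5-style reaction buffer. The vendor composition is
      proprietary; these values are approximations assembled from the
      published 2.0 mM Mg2+ content, typical monovalent loads of
      high-fidelity buffers, and the standard protocol of 0.8 mM total dNTPs
      and 500 nM primers. Treat the monovalent equivalent as an estimate.
    monovalent_mM: 100.0
    tris_mM: 25.0
    divalent_mM: 2.0
    dntp_mM: 0.8
    primer_M: 5.0e-7
    template_M: 5.0e-10
    k_mode: symmetric
  phusion_hf:
    provenance_note: >-
      Phusion-style HF buffer approximation: 1.5 mM Mg2+ is published; the
      monovalent load (K+ plus ammonium sulfate) is estimated at 75 mM.
      Standard protocol dNTPs (0.8 mM total) and 500 nM primers.
    monovalent_mM: 75.0
    tris_mM: 0.0
    divalent_mM: 1.5
    dntp_mM: 0.8
    primer_M: 5.0e-7
    template_M: 5.0e-10
    k_mode: symmetric
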