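"""Design primer pairs for a small batch of amplicons.

Generates five synthetic gene-sized templates, designs boundary-anchored
primer pairs targeting 60 +/- 5 degC with BsaI-carrying 5'-extensions, and
prints the resulting primers.  Each forward annealing region is an exact
template prefix and each reverse one the reverse complement of an exact
suffix, so the amplified product is the template to the nucleotide.
"""

from primerwalk import (
    BufferConditions,
    DesignSpec,
    design_batch,
    generate_fixtures,
    load_nn_table,
)

templates, _ = generate_fixtures(
    n=5, length_range=(400, 1200), gc_range=(0.35, 0.55), seed=20
)
spec = DesignSpec(
    tm_optimal=60.0,
    tm_tolerance=5.0,
    force_gc_clamp=True,
    ext_forward="GGTCTCACATG",  # BsaI site + NcoI-compatible overhang
    ext_reverse="GGTCTCTTAAT",
)
params = load_nn_table("santalucia1998")
buffer = BufferConditions()  # 50 mM monovalent, 500 nM primer, excess-primer K

pairs, failures = design_batch(templates, spec, params, buffer)
print(f"designed {len(pairs)} pairs, {len(failures)} failures\n")
for pair in pairs:
    f, r = pair.forward_candidate, pair.reverse_candidate
    print(f"{pair.record_id}")
    print(f"  F {pair.forward_full}  ({f.length} nt anneal, Tm {f.tm:.2f} degC)")
    print(f"  R {pair.reverse_full}  ({r.length} nt anneal, Tm {r.tm:.2f} degC)")
print(
    "\nAnnealing Tms all sit inside the 55-65 degC window, so the whole\n"
    "batch can be amplified in one thermocycler run."
)
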