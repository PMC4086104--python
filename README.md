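# primerwalk

Batch design of PCR primers for single-nucleotide-precision cloning.

When an amplicon's boundaries are fixed exactly — a gene from start codon to
stop codon, a shuffling fragment, an assembly part — the usual primer-design
freedoms (move the primer, tweak the product) are gone. The only degree of
freedom left is how far each primer walks from the boundary into the
template. primerwalk is built around that constraint: it enumerates every
boundary-anchored annealing length, scores each with a buffer-aware
nearest-neighbour melting-temperature engine, keeps candidates inside a Tm
tolerance window, ranks them (optionally preferring a G/C 3′ clamp), and
prepends user-supplied 5′-extensions carrying cloning features (restriction
sites, Gibson/GoldenGate overlaps). It is meant for experimentalists
preparing primer libraries in batches — one FASTA in, one primer FASTA and
one CSV report out — with popular polymerase buffers available as presets.

## The model

Duplex thermodynamics follow the two-state nearest-neighbour model:
ΔH and ΔS are sums of initiation terms plus one term per adjacent
dinucleotide stack (SantaLucia 1998 unified or Breslauer 1986 tables,
shipped as editable YAML). The entropy is salt-corrected,

    ΔS([Mon⁺]) = ΔS(1 M) + 0.368 · (N−1) · ln[Mon⁺],

with the buffer's cations collapsed into one monovalent equivalent
[Mon⁺] = [mono] + [Tris]/2 + 120·√(max(0, [Mg²⁺] − [dNTP])) (mM). The
melting temperature is

    Tm = ΔH / (ΔS − R·ln K),

where the equilibrium constant K depends on the strand-concentration
regime:

| `k_mode`            | K                          | regime                                 |
|---------------------|----------------------------|----------------------------------------|
| `symmetric`         | 4/[Primer]                 | equal strands (classical calculators)  |
| `excess_exact`      | 1/([Primer] − [Template]/2)| primer excess (first PCR cycles)       |
| `excess_simplified` | 1/[Primer]                 | template ≪ primer (genomic extraction) |

The symmetric convention runs about 2 °C cooler than the excess-primer
conventions at typical concentrations — a systematic shift that matters when
a whole library must anneal in one tube. Custom buffers default to
`excess_simplified`; named presets keep `symmetric` for compatibility with
the classical online calculators.

## Worked example

```
$ python examples/melting_temperature.py
primer: AGCGGATAACAATTTCACAC (20 nt)
  symmetric          K = 8.000e+06 /M  Tm = 51.73 degC
  excess_exact       K = 2.001e+06 /M  Tm = 53.62 degC
  excess_simplified  K = 2.000e+06 /M  Tm = 53.63 degC
  q5 preset          monovalent-equivalent = 244.0 mM  Tm = 59.50 degC
```

The ~1.9 °C gap between `symmetric` and the excess modes is the
K-convention shift; dropping the template term (`excess_simplified`)
changes Tm by only 0.01 °C. The q5 preset predicts a hotter Tm because its
higher effective salt stabilizes the duplex.

Batch design from the shell (5 synthetic templates, BsaI tails):

```
$ primerwalk fixtures --out fx --n 5 --seed 20 --min-length 400 --max-length 1200
$ primerwalk design --in fx_templates.fasta --out run \
      --tm 60 --tol 5 --ext-fwd GGTCTCACATG --ext-rev GGTCTCTTAAT
designed 5/5 records (0 failed); outputs at run_primers.fasta / run_report.csv
```

`run_primers.fasta` holds `<id>_F` / `<id>_R` primers; `run_report.csv` has
one row per primer (columns: record_id, status, orientation, full_sequence,
annealing_sequence, extension, annealing_length, tm_celsius, ends_gc,
warnings), e.g.

```
synth_002,ok,forward,GGTCTCACATGCAGTGGGTTCCCCGTAGATAAGAC,CAGTGGGTTCCCCGTAGATAAGAC,GGTCTCACATG,24,60.61,True,
```

meaning: the 24-nt annealing region (an exact template prefix) melts at
60.61 °C, inside the 55–65 °C window, and ends in C (clamped). Records whose
window is unreachable appear as `failed` rows with the nearest achievable Tm
as a diagnostic; `--auto-widen 1.0` relaxes the window stepwise instead.

Validation of an engine configuration against benchmark melting data
(`primerwalk benchmark --in table.csv [--grid] [--plot scatter.png]`)
regresses experimental on predicted Tm and reports slope, intercept, r² and
RMSE — slope 1, intercept 0, r² 1 is a perfectly calibrated engine. See
`examples/benchmark_regression.py`.

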