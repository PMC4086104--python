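# Methods

## Problem and scope

primerwalk designs PCR primer pairs for amplicons whose boundaries are fixed
to the nucleotide. Both primers are anchored at the template ends: the
forward annealing region is a template prefix, the reverse one the reverse
complement of a template suffix. The sole design variable is the annealing
length; the package searches it under a melting-temperature constraint and
assembles the chosen pair with verbatim user 5′-extensions. Out of scope by
design: hairpin/dimer screening, genome-wide specificity checks, automatic
overhang generation for assembly grammars, and mismatch or dangling-end
thermodynamics (perfect-match duplexes are assumed).

## Thermodynamic model

Duplex formation is treated as a two-state transition. For a primer
S = s₁…s_N bound to its perfect complement:

    ΔH = ΔH_init + Σ_ends ΔH_term(s_end) + Σ_{i=1}^{N−1} ΔH_stack(s_i s_{i+1})

and identically for ΔS. Two tables ship as YAML data files (cal/mol,
cal/(mol·K)):

- **santalucia1998** — the unified oligonucleotide parameters, with per-end
  initiation split by terminal base pair (G·C: +0.1 kcal/mol, −2.8 cal/(mol·K);
  A·T: +2.3 kcal/mol, +4.1 cal/(mol·K)). Default.
- **breslauer1986** — the earlier parameter set, with the single initiation
  entropy of −10.8 cal/(mol·K) used by the classical calculators built on it.

Both tables are strand-symmetric (each stack equals its reverse complement),
which makes Tm invariant under which strand is called "primer"; the loader
accepts user tables of the same shape from a path. Units are cal-based with
R = 1.9872 cal/(mol·K).

### Salt correction

The entropic correction ΔS([Mon⁺]) = ΔS(1 M) + c·(N−1)·ln[Mon⁺] is applied
with c = 0.368 cal/(mol·K) by default; N−1 counts the phosphate pairs of an
N-mer duplex, and [Mon⁺] is in mol/L so the correction vanishes at the 1 M
reference state. The coefficient is an explicit argument so alternative
published parameterizations can be substituted without code changes.

### Monovalent equivalent

Buffers rarely contain only Na⁺/K⁺, so all cations are collapsed into one
effective monovalent concentration (mM):

    [Mon⁺] = [monovalent] + [Tris]/2 + 120·√(max(0, [Mg²⁺] − [dNTP]))

Half the Tris is counted (only the protonated form is cationic near PCR pH),
and dNTPs chelate an equimolar amount of Mg²⁺, clamped so free Mg²⁺ is never
negative. Bundled presets (standard_taq, q5, phusion_hf) apply this
conversion to published or typical compositions; where a vendor composition
is proprietary the preset's `provenance_note` says so explicitly and the
values should be read as documented approximations, overridable via a user
preset file.

### Equilibrium constant and Tm

Tm(K) = ΔH / (ΔS_salt − R·ln K), with K selected by `k_mode`:
`symmetric` K = 4/[Primer] (equal strand concentrations, the convention of
the classical calculators and of the melting experiments behind the NN
tables); `excess_exact` 1/K = [Primer] − [Template]/2 (primer in excess, the
regime of early PCR cycles); `excess_simplified` K = 1/[Primer] (template
negligible). The exact and simplified forms agree to <10⁻³ relative once
template is three orders of magnitude below primer, and the symmetric
convention sits ≈2 °C below the excess forms at typical concentrations
(500 nM primer, 0.5 nM template) — the package's acceptance script measures
this gap directly. Custom buffers default to `excess_simplified`; presets
keep `symmetric` for compatibility with existing calculators. A denominator
≥ 0 (possible only for pathological inputs) raises a NumericalError rather
than returning a nonsensical Tm.

An empirical closed form, Tm = 77.1 + 11.7·log₁₀[Mon⁺] + 0.41·%GC − 528/N,
is included for cross-checking; it is less accurate than the NN model and is
never used for design.

### Tm applies to the annealing region only

5′-extensions are excluded from every Tm computation. In the first cycles —
the ones that decide whether a genomic extraction works — only the annealing
region is duplexed; from cycle three onward the full-length primer binds
amplicon and its Tm is strictly higher, so designing on the annealing region
is the conservative choice.

## Design algorithm

For each record and each orientation, lengths L = min_len…min(max_len,
template length) are evaluated (defaults 15–40 nt, bracketing practical PCR
primers; both CLI-exposed). Candidates with |Tm − Tm_opt| ≤ tolerance
(default 60 ± 5 °C, matching the common practice of annealing ~5 °C below
Tm) are kept. Ranking is lexicographic: smallest |Tm − Tm_opt|, then shorter
length (cheaper synthesis), then G/C 3′ end. With the clamp forced, the pool
is first restricted to G/C-ending candidates whenever any exists; if none
does, the global best is returned with an advisory warning rather than a
failure. The procedure is fully deterministic.

A record whose window is unreachable fails loudly with the nearest
achievable Tm and its length as a diagnostic — an explicit alternative to
silently relaxing constraints. The optional `auto_widen` step instead grows
the tolerance iteratively (recorded in the pair's warnings), stopping at a
±25 °C ceiling beyond which the window is no longer meaningful. Batch runs
collect per-record failures and always complete; duplicate ids are rejected
before any work.

## Validation harness

`benchmark()` regresses experimental on predicted Tm by ordinary least
squares (scipy linregress) and reports n, slope, intercept, r², RMSE and
residuals, optionally with an XY scatter plot. `compare_methods()` assays
every NN-table × salt-coefficient × K-mode combination (plus the empirical
formula) on the same records. Real experimental tables load from CSV with
flexible columns; missing condition columns take the buffer defaults.

## Synthetic fixtures

`generate_fixtures(n, length_range, gc_range, seed, noise_sd)` emits random
A/C/G/T templates with controlled composition: each draws a length and a GC
fraction uniformly, then places exactly round(gc·L) G/C bases at random
positions. Benchmark rows set "experimental" Tm to the engine's own
prediction plus N(0, noise_sd) noise. Defaults emulate a batch cloning
experiment — 61 gene-sized templates of 300–2000 nt at 35–55 % GC with
0.5 °C benchmark noise; shorter ranges (16–30 nt, 20–80 % GC) are used where
primer-length oligos are needed. Generation is bitwise reproducible per
seed.

What fixtures can and cannot show: self-generated benchmarks validate the
regression plumbing and statistical recovery (a 200-record, 0.5 °C-noise set
recovers slope ≈ 1, r² > 0.99) but are blind by construction to any bias
shared between generator and engine — only real melting data can test
calibration. Likewise, uniform-random templates are a stand-in for real
genes: real coding sequences have correlated composition, and roughly 0.3 %
of random gene-sized records have a boundary so locally AT- or GC-rich that
no 15–40 nt walk reaches the 55–65 °C window; such records surface as
explicit failures with diagnostics, not as silent omissions.

## Numerical and interface choices

- Strict A/C/G/T alphabet everywhere; ambiguity codes are rejected at the
  I/O boundary with the offending records named, because any assignment for
  them would silently corrupt ΔH/ΔS. Lowercase is uppercased on input;
  internal thermo operations remain strict.
- CSV report: fixed column order (record_id, status, orientation,
  full_sequence, annealing_sequence, extension, annealing_length,
  tm_celsius, ends_gc, warnings), UTF-8, '.' decimal, '\n' newlines, Tm at 2
  decimals. Failed records appear as `failed` rows carrying the diagnostic.
- Outputs are byte-identical across reruns with identical inputs; the run
  log is the only artifact containing timestamps.
- The problem sizes used by the test suite and the acceptance script (100
  oracle templates, 200-record benchmarks, a 61-record batch) are the sizes
  at which the checked properties stabilize while keeping the whole suite
  near-instant.

## Known limitations

- No secondary-structure, self-dimer, cross-dimer or off-target screening.
- Perfect-match duplexes only; no mismatch, dangling-end or terminal-
  mismatch corrections.
- Preset ionic values for proprietary buffers are estimates (see each
  preset's provenance note).
- The empirical Tm formula and the salt-correction coefficient are single
  default parameterizations; both are pluggable but only the defaults are
  exercised by the bundled tests.
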