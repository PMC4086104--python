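"""Nearest-neighbour melting-temperature engine.

The duplex formed by a primer and its perfect complement is scored with the
two-state nearest-neighbour model: total enthalpy and entropy are the sum of
initiation terms plus one term per adjacent dinucleotide "stack".  The
entropy is then adjusted for the ionic strength of the PCR buffer (expressed
as a single monovalent-equivalent cation concentration) and the melting
temperature follows from

    Tm (K) = dH / (dS_salt - R * ln K)

where K is the duplex-formation equilibrium constant at the melting midpoint.
Three conventions for K are supported, reflecting the strand-concentration
regime of the reaction:

``symmetric``
    K = 4/[Primer] — both strands at equal concentration, the regime of the
    classical melting experiments and of most online calculators.
``excess_exact``
    1/K = [Primer] - [Template]/2 — primer in excess over template, the
    regime of the first PCR cycles on genomic template.
``excess_simplified``
    K = 1/[Primer] — the excess-primer expression with the template
    concentration dropped, valid once template is orders of magnitude below
    primer.

Parameter tables (SantaLucia 1998 unified, Breslauer 1986) ship as editable
YAML data files; user tables with the same shape can be loaded from a path.
All enthalpies are cal/mol and entropies cal/(mol*K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

from .errors import (
    AlphabetError,
    KModeError,
    LengthError,
    NumericalError,
    SaltError,
)

#: Gas constant, cal/(mol*K).
R_CAL = 1.9872

#: Default coefficient of the entropic salt correction, cal/(mol*K) per
#: phosphate pair (SantaLucia-form: dS + coeff * (N-1) * ln[Mon+]).
SALT_CORRECTION_COEFF = 0.368

#: Monovalent-equivalent weight of free Mg2+, mM per sqrt(mM).
DIVALENT_EQUIV_COEFF = 120.0

DNA_ALPHABET = frozenset("ACGT")
K_MODES = ("symmetric", "excess_exact", "excess_simplified")

_STACKS = tuple(a + b for a in "ACGT" for b in "ACGT")


def _check_sequence(sequence: str, min_len: int = 2) -> str:
    if not isinstance(sequence, str):
        raise AlphabetError(f"sequence must be a string, got {type(sequence).__name__}")
    bad = sorted(set(sequence) - DNA_ALPHABET)
    if bad:
        raise AlphabetError(
            f"sequence contains characters outside A/C/G/T: {''.join(bad)!r}"
        )
    if len(sequence) < min_len:
        raise LengthError(
            f"sequence of length {len(sequence)} is shorter than the minimum {min_len}"
        )
    return sequence


@dataclass(frozen=True)
class NNParameterSet:
    """A named nearest-neighbour parameter table.

    ``stack_dH``/``stack_dS`` map each of the 16 dinucleotide stacks (keyed
    by the 5'->3' dinucleotide on the primer strand) to cal/mol and
    cal/(mol*K).  ``init_dH``/``init_dS`` are sequence-independent duplex
    initiation terms; ``terminal_dH``/``terminal_dS`` are optional per-end
    corrections keyed by the terminal base, applied once for each duplex end.
    """

    name: str
    stack_dH: dict[str, float]
    stack_dS: dict[str, float]
    init_dH: float = 0.0
    init_dS: float = 0.0
    terminal_dH: dict[str, float] = field(default_factory=dict)
    terminal_dS: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in _STACKS if s not in self.stack_dH or s not in self.stack_dS]
        if missing:
            raise ValueError(f"NN table {self.name!r} missing stacks: {missing}")
        nonneg = [s for s in _STACKS if self.stack_dH[s] >= 0]
        if nonneg:
            raise ValueError(
                f"NN table {self.name!r} has non-negative stack enthalpies "
                f"(duplex formation is exothermic): {nonneg}"
            )

    @property
    def is_strand_symmetric(self) -> bool:
        """True when every stack carries the same values as its reverse
        complement — a prerequisite for Tm being strand-choice invariant."""
        comp = str.maketrans("ACGT", "TGCA")
        for s in _STACKS:
            rc = s.translate(comp)[::-1]
            if not (
                math.isclose(self.stack_dH[s], self.stack_dH[rc])
                and math.isclose(self.stack_dS[s], self.stack_dS[rc])
            ):
                return False
        return True


@dataclass(frozen=True)
class BufferConditions:
    """Ionic content and strand concentrations of a PCR buffer.

    Ion and dNTP concentrations are mM; ``primer_M`` and ``template_M`` are
    mol/L.  ``k_mode`` selects the equilibrium-constant convention (see
    module docstring).
    """

    monovalent_mM: float = 50.0
    tris_mM: float = 0.0
    divalent_mM: float = 0.0
    dntp_mM: float = 0.0
    primer_M: float = 5e-7
    template_M: float = 5e-10
    k_mode: str = "excess_simplified"

    def __post_init__(self) -> None:
        for name in ("monovalent_mM", "tris_mM", "divalent_mM", "dntp_mM", "template_M"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.primer_M <= 0:
            raise ValueError(f"primer_M must be > 0, got {self.primer_M}")
        if self.k_mode not in K_MODES:
            raise KModeError(
                f"unknown k_mode {self.k_mode!r}; expected one of {K_MODES}"
            )
        if self.k_mode == "excess_exact" and self.primer_M - self.template_M / 2 <= 0:
            raise KModeError(
                "excess_exact requires primer_M > template_M/2 "
                f"(primer {self.primer_M}, template {self.template_M})"
            )

    def with_k_mode(self, k_mode: str) -> "BufferConditions":
        return replace(self, k_mode=k_mode)


@dataclass(frozen=True)
class ThermoResult:
    """Full audit trail of one melting-temperature computation."""

    sequence: str
    dH_total: float  # cal/mol
    dS_raw: float  # cal/(mol*K), 1 M reference
    dS_total: float  # cal/(mol*K), salt-corrected
    monovalent_eq_mM: float
    K: float  # 1/M
    tm_celsius: float


def nn_sum(sequence: str, params: NNParameterSet) -> tuple[float, float]:
    """Sum initiation, terminal and stack terms for ``sequence`` duplexed
    with its perfect complement.

    Returns ``(dH_total, dS_total)`` in cal/mol and cal/(mol*K) at the 1 M
    monovalent reference state (no salt correction).
    """
    _check_sequence(sequence)
    dH = params.init_dH
    dS = params.init_dS
    for end in (sequence[0], sequence[-1]):
        dH += params.terminal_dH.get(end, 0.0)
        dS += params.terminal_dS.get(end, 0.0)
    for i in range(len(sequence) - 1):
        stack = sequence[i : i + 2]
        dH += params.stack_dH[stack]
        dS += params.stack_dS[stack]
    return dH, dS


def monovalent_equivalent(buffer: BufferConditions) -> float:
    """Collapse the buffer's cations into one monovalent-equivalent
    concentration (mM).

    Tris contributes half its concentration (only the protonated form is
    cationic at PCR pH); free Mg2+ — total Mg2+ minus dNTP-chelated Mg2+,
    clamped at zero — contributes 120*sqrt(free Mg2+).
    """
    free_mg = max(0.0, buffer.divalent_mM - buffer.dntp_mM)
    return (
        buffer.monovalent_mM
        + buffer.tris_mM / 2.0
        + DIVALENT_EQUIV_COEFF * math.sqrt(free_mg)
    )


def salt_correct(
    dS_raw: float,
    n_bases: int,
    monovalent_eq_mM: float,
    coefficient: float = SALT_CORRECTION_COEFF,
) -> float:
    """Entropic salt correction: ``dS + coefficient * (N-1) * ln[Mon+]``.

    ``[Mon+]`` is the monovalent equivalent in mol/L, so the correction
    vanishes at the 1 M reference state and is negative below it.  The
    coefficient is exposed so alternative published parameterizations can be
    substituted.
    """
    if monovalent_eq_mM <= 0:
        raise SaltError(
            f"monovalent equivalent must be > 0 mM, got {monovalent_eq_mM}"
        )
    return dS_raw + coefficient * (n_bases - 1) * math.log(monovalent_eq_mM / 1000.0)


def equilibrium_constant(buffer: BufferConditions) -> float:
    """Duplex-formation equilibrium constant (1/M) under ``buffer.k_mode``."""
    if buffer.k_mode == "symmetric":
        return 4.0 / buffer.primer_M
    if buffer.k_mode == "excess_exact":
        denom = buffer.primer_M - buffer.template_M / 2.0
        if denom <= 0:
            raise KModeError(
                "excess_exact undefined: primer_M - template_M/2 <= 0"
            )
        return 1.0 / denom
    if buffer.k_mode == "excess_simplified":
        return 1.0 / buffer.primer_M
    raise KModeError(f"unknown k_mode {buffer.k_mode!r}")


def melting_temperature(
    sequence: str,
    params: NNParameterSet,
    buffer: BufferConditions,
    salt_coefficient: float = SALT_CORRECTION_COEFF,
) -> ThermoResult:
    """Predict the melting temperature of ``sequence`` against its perfect
    complement under ``buffer``, returning all intermediates for audit."""
    dH, dS_raw = nn_sum(sequence, params)
    mono = monovalent_equivalent(buffer)
    dS = salt_correct(dS_raw, len(sequence), mono, coefficient=salt_coefficient)
    K = equilibrium_constant(buffer)
    denominator = dS - R_CAL * math.log(K)
    if denominator >= 0:
        raise NumericalError(
            f"non-melting degenerate: dS - R ln K = {denominator:.3f} >= 0 "
            f"for {sequence!r}"
        )
    tm_c = dH / denominator - 273.15
    return ThermoResult(
        sequence=sequence,
        dH_total=dH,
        dS_raw=dS_raw,
        dS_total=dS,
        monovalent_eq_mM=mono,
        K=K,
        tm_celsius=tm_c,
    )


def empirical_tm(sequence: str, buffer: BufferConditions) -> float:
    """Closed-form empirical Tm (deg C) from GC fraction, length and salt.

    Uses the rapid-cycle PCR parameterization

        Tm = 77.1 + 11.7*log10([Mon+]) + 0.41*(%GC) - 528/N

    with [Mon+] the monovalent equivalent in mol/L and N the primer length.
    Cheap and table-free, but less accurate than the nearest-neighbour model;
    kept mainly for cross-checks.
    """
    _check_sequence(sequence)
    mono = monovalent_equivalent(buffer)
    if mono <= 0:
        raise SaltError(f"monovalent equivalent must be > 0 mM, got {mono}")
    n = len(sequence)
    gc_percent = 100.0 * sum(1 for b in sequence if b in "GC") / n
    return 77.1 + 11.7 * math.log10(mono / 1000.0) + 0.41 * gc_percent - 528.0 / n


# ---------------------------------------------------------------------------
# Parameter-table registry


def _table_from_mapping(data: dict) -> NNParameterSet:
    stacks = data["stacks"]
    terminal = data.get("terminal") or {}
    term_dH: dict[str, float] = {}
    term_dS: dict[str, float] = {}
    # terminal sections are keyed by base-pair class (GC / AT); expand to the
    # four terminal bases so lookup is a single dict access.
    for pair_class, bases in (("GC", "GC"), ("AT", "AT")):
        if pair_class in terminal:
            for base in bases:
                term_dH[base] = float(terminal[pair_class]["dH"])
                term_dS[base] = float(terminal[pair_class]["dS"])
    return NNParameterSet(
        name=str(data["name"]),
        stack_dH={k: float(v["dH"]) for k, v in stacks.items()},
        stack_dS={k: float(v["dS"]) for k, v in stacks.items()},
        init_dH=float(data.get("init_dH", 0.0)),
        init_dS=float(data.get("init_dS", 0.0)),
        terminal_dH=term_dH,
        terminal_dS=term_dS,
    )


_BUNDLED_TABLES = {
    "santalucia1998": "nn_santalucia1998.yaml",
    "breslauer1986": "nn_breslauer1986.yaml",
    # short aliases for the CLI
    "santalucia": "nn_santalucia1998.yaml",
    "breslauer": "nn_breslauer1986.yaml",
}


def available_nn_tables() -> tuple[str, ...]:
    return ("santalucia1998", "breslauer1986")


def load_nn_table(name_or_path: str | Path = "santalucia1998") -> NNParameterSet:
    """Load a bundled table by name (``santalucia1998``, ``breslauer1986``)
    or a user-supplied YAML file by path."""
    key = str(name_or_path)
    if key in _BUNDLED_TABLES:
        text = (
            resources.files("primerwalk.data")
            .joinpath(_BUNDLED_TABLES[key])
            .read_text(encoding="utf-8")
        )
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise FileNotFoundError(
                f"no bundled NN table named {key!r} (available: "
                f"{available_nn_tables()}) and no file at that path"
            )
        text = path.read_text(encoding="utf-8")
    return _table_from_mapping(yaml.safe_load(text))
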