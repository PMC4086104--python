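"""Validation harness and synthetic fixture generation.

The melting-temperature engine is validated by regressing experimental Tm
values on predicted ones (ordinary least squares — experimental on the y
axis, predicted on x) and reporting slope, intercept, r-squared and RMSE,
optionally with an XY scatter plot.  A perfectly calibrated engine gives
slope 1, intercept 0, r-squared 1.

A real experimental benchmark table can be supplied as CSV
(``load_benchmark_csv``); for self-contained testing, ``generate_fixtures``
emits reproducible random A/C/G/T templates with controlled GC content and
benchmark rows whose "experimental" Tm is the engine's own prediction plus
Gaussian noise.  Fixtures exercise plumbing and statistical recovery; they
cannot, by construction, detect a systematic bias shared by generator and
engine — only real melting data can.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError, PrimerwalkError
from .io_formats import SequenceRecord, write_fasta
from .thermo import (
    BufferConditions,
    NNParameterSet,
    SALT_CORRECTION_COEFF,
    empirical_tm,
    load_nn_table,
    melting_temperature,
)

BENCHMARK_CSV_COLUMNS = (
    "sequence",
    "monovalent_mM",
    "tris_mM",
    "divalent_mM",
    "dntp_mM",
    "primer_M",
    "template_M",
    "k_mode",
    "tm_experimental",
)


@dataclass(frozen=True)
class BenchmarkRecord:
    """One (sequence, buffer conditions, experimental Tm) benchmark row."""

    sequence: str
    conditions: BufferConditions
    tm_experimental: float


@dataclass(frozen=True)
class RegressionReport:
    """OLS fit of experimental on predicted Tm."""

    n: int
    slope: float
    intercept: float  # deg C
    r_squared: float
    rmse: float  # deg C, around the fitted line
    predicted: np.ndarray
    experimental: np.ndarray
    residuals: np.ndarray


def _predict(
    record: BenchmarkRecord,
    params: NNParameterSet,
    method: str,
    salt_coefficient: float,
) -> float:
    if method == "nn":
        return melting_temperature(
            record.sequence, params, record.conditions, salt_coefficient=salt_coefficient
        ).tm_celsius
    if method == "empirical":
        return empirical_tm(record.sequence, record.conditions)
    raise ValueError(f"unknown Tm method {method!r}; expected 'nn' or 'empirical'")


def benchmark(
    records: Sequence[BenchmarkRecord],
    params: NNParameterSet,
    method: str = "nn",
    salt_coefficient: float = SALT_CORRECTION_COEFF,
    plot_path: str | Path | None = None,
) -> RegressionReport:
    """Regress experimental Tm on predicted Tm over ``records``.

    Records whose prediction fails are excluded with a warning.  Fewer than
    two usable records, or zero variance in the predictions, raise
    InsufficientDataError.  When ``plot_path`` is given, an XY scatter with
    the fitted line and the identity line is written there.
    """
    predicted, experimental = [], []
    for rec in records:
        try:
            predicted.append(_predict(rec, params, method, salt_coefficient))
            experimental.append(rec.tm_experimental)
        except PrimerwalkError as exc:
            _warnings.warn(f"benchmark record excluded ({rec.sequence[:20]}...): {exc}")
    if len(predicted) < 2:
        raise InsufficientDataError(
            f"need >= 2 usable benchmark records, have {len(predicted)}"
        )
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(experimental, dtype=float)
    if np.ptp(x) == 0:
        raise InsufficientDataError("zero variance in predicted Tm; degenerate fit")
    fit = stats.linregress(x, y)
    residuals = y - (fit.slope * x + fit.intercept)
    report = RegressionReport(
        n=len(x),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rmse=float(np.sqrt(np.mean(residuals**2))),
        predicted=x,
        experimental=y,
        residuals=residuals,
    )
    if plot_path is not None:
        _scatter_plot(report, Path(plot_path), params.name, method)
    return report


def _scatter_plot(report: RegressionReport, path: Path, table: str, method: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(report.predicted, report.experimental, s=12, alpha=0.7)
    lo = min(report.predicted.min(), report.experimental.min()) - 1
    hi = max(report.predicted.max(), report.experimental.max()) + 1
    grid = np.linspace(lo, hi, 2)
    ax.plot(grid, grid, "k--", lw=0.8, label="identity")
    ax.plot(
        grid,
        report.slope * grid + report.intercept,
        "r-",
        lw=1.2,
        label=(
            f"fit: y={report.slope:.3f}x+{report.intercept:.2f}, "
            f"r$^2$={report.r_squared:.3f}"
        ),
    )
    ax.set_xlabel("predicted Tm (degC)")
    ax.set_ylabel("experimental Tm (degC)")
    ax.set_title(f"{table} / {method} (n={report.n}, RMSE {report.rmse:.2f} degC)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_methods(
    records: Sequence[BenchmarkRecord],
    nn_tables: Iterable[str | NNParameterSet] = ("santalucia1998", "breslauer1986"),
    k_modes: Iterable[str] = ("symmetric", "excess_exact", "excess_simplified"),
    salt_coefficients: Iterable[float] = (SALT_CORRECTION_COEFF,),
    include_empirical: bool = True,
) -> pd.DataFrame:
    """Systematically assay every (NN table x salt coefficient x K mode)
    combination on one benchmark set; one row of regression statistics per
    combination (plus the empirical formula, which has no table or K mode)."""
    rows = []
    for table in nn_tables:
        params = load_nn_table(table) if isinstance(table, str) else table
        for coeff in salt_coefficients:
            for k_mode in k_modes:
                adjusted = [
                    replace(r, conditions=r.conditions.with_k_mode(k_mode))
                    for r in records
                ]
                rep = benchmark(adjusted, params, "nn", salt_coefficient=coeff)
                rows.append(
                    {
                        "method": "nn",
                        "nn_table": params.name,
                        "salt_coefficient": coeff,
                        "k_mode": k_mode,
                        "n": rep.n,
                        "slope": rep.slope,
                        "intercept": rep.intercept,
                        "r_squared": rep.r_squared,
                        "rmse": rep.rmse,
                    }
                )
    if include_empirical:
        rep = benchmark(records, load_nn_table("santalucia1998"), "empirical")
        rows.append(
            {
                "method": "empirical",
                "nn_table": "",
                "salt_coefficient": np.nan,
                "k_mode": "",
                "n": rep.n,
                "slope": rep.slope,
                "intercept": rep.intercept,
                "r_squared": rep.r_squared,
                "rmse": rep.rmse,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic fixtures


def generate_fixtures(
    n: int = 61,
    length_range: tuple[int, int] = (300, 2000),
    gc_range: tuple[float, float] = (0.35, 0.55),
    seed: int = 0,
    noise_sd: float = 0.5,
    params: NNParameterSet | None = None,
    buffer: BufferConditions | None = None,
    fasta_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> tuple[list[SequenceRecord], list[BenchmarkRecord]]:
    """Reproducible random templates plus a matching benchmark table.

    Each template draws a length uniformly from ``length_range`` and a GC
    fraction uniformly from ``gc_range``; the sequence then contains exactly
    ``round(gc * length)`` G/C bases at random positions.  The defaults
    emulate a batch-cloning experiment: 61 gene-sized templates of
    300-2000 nt at 35-55% GC.  Benchmark rows pair each template with the
    buffer and an "experimental" Tm equal to the engine prediction plus
    N(0, noise_sd) noise.

    Identical arguments (including seed) give bitwise-identical output.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    lo, hi = length_range
    if not (2 <= lo <= hi):
        raise ParameterError(f"invalid length_range {length_range}")
    g_lo, g_hi = gc_range
    if not (0.0 <= g_lo <= g_hi <= 1.0):
        raise ParameterError(f"invalid gc_range {gc_range}")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")

    params = params or load_nn_table("santalucia1998")
    buffer = buffer or BufferConditions()
    rng = np.random.default_rng(seed)

    templates: list[SequenceRecord] = []
    bench: list[BenchmarkRecord] = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        gc_frac = float(rng.uniform(g_lo, g_hi))
        n_gc = int(round(gc_frac * length))
        bases = np.empty(length, dtype="<U1")
        positions = rng.permutation(length)
        bases[positions[:n_gc]] = rng.choice(list("GC"), size=n_gc)
        bases[positions[n_gc:]] = rng.choice(list("AT"), size=length - n_gc)
        seq = "".join(bases)
        templates.append(SequenceRecord(id=f"synth_{i+1:03d}", sequence=seq))
        tm_pred = melting_temperature(seq, params, buffer).tm_celsius
        tm_exp = tm_pred + (float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0)
        bench.append(
            BenchmarkRecord(sequence=seq, conditions=buffer, tm_experimental=tm_exp)
        )

    if fasta_path is not None:
        with open(fasta_path, "w", encoding="utf-8", newline="\n") as fh:
            write_fasta(templates, fh)
    if csv_path is not None:
        write_benchmark_csv(bench, csv_path)
    return templates, bench


def write_benchmark_csv(records: Iterable[BenchmarkRecord], path: str | Path) -> None:
    rows = [
        {
            "sequence": r.sequence,
            "monovalent_mM": r.conditions.monovalent_mM,
            "tris_mM": r.conditions.tris_mM,
            "divalent_mM": r.conditions.divalent_mM,
            "dntp_mM": r.conditions.dntp_mM,
            "primer_M": r.conditions.primer_M,
            "template_M": r.conditions.template_M,
            "k_mode": r.conditions.k_mode,
            "tm_experimental": r.tm_experimental,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(BENCHMARK_CSV_COLUMNS)).to_csv(path, index=False)


def load_benchmark_csv(path: str | Path) -> list[BenchmarkRecord]:
    """Load a benchmark table; missing condition columns take the
    BufferConditions defaults, so a minimal (sequence, monovalent_mM,
    divalent_mM, primer_M, tm_experimental) table from the literature works
    as-is. A ``tm_exp`` column is accepted as an alias."""
    df = pd.read_csv(path)
    if "tm_experimental" not in df.columns and "tm_exp" in df.columns:
        df = df.rename(columns={"tm_exp": "tm_experimental"})
    required = {"sequence", "tm_experimental"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"benchmark CSV missing columns: {sorted(missing)}")
    defaults = BufferConditions()
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for fld in (
            "monovalent_mM",
            "tris_mM",
            "divalent_mM",
            "dntp_mM",
            "primer_M",
            "template_M",
            "k_mode",
        ):
            if hasattr(row, fld) and not pd.isna(getattr(row, fld)):
                kwargs[fld] = getattr(row, fld)
        records.append(
            BenchmarkRecord(
                sequence=str(row.sequence).upper(),
                conditions=replace(defaults, **kwargs),
                tm_experimental=float(row.tm_experimental),
            )
        )
    return records
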