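"""FASTA/CSV input-output and the buffer-preset registry.

Input templates arrive as multi-record FASTA; designed primers leave as
FASTA (``<record_id>_F`` / ``<record_id>_R``) and as a flat CSV report with
a fixed, documented column order.  The alphabet is strictly A/C/G/T:
ambiguity codes would silently corrupt the thermodynamics, so they are
rejected loudly with the offending record named.

Buffer presets live in a human-editable YAML file bundled with the package;
a user file of the same shape can be merged on top, overriding or adding
presets.  Each preset carries a provenance note because several vendor
buffer compositions are proprietary and the bundled ionic values are
documented approximations.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable

import yaml
from Bio import SeqIO

from .design import DesignFailure, PrimerPair
from .errors import AlphabetError, FastaFormatError, PresetNotFoundError
from .thermo import BufferConditions

#: Column order of the CSV report. "status" is "ok" for designed primers and
#: "failed" for records whose window was unreachable; failed rows keep the
#: diagnostic in the "warnings" column.
CSV_COLUMNS = (
    "record_id",
    "status",
    "orientation",
    "full_sequence",
    "annealing_sequence",
    "extension",
    "annealing_length",
    "tm_celsius",
    "ends_gc",
    "warnings",
)


@dataclass(frozen=True)
class SequenceRecord:
    """One normalized FASTA record: uppercased, whitespace-free sequence."""

    id: str
    sequence: str
    description: str = ""


@dataclass(frozen=True)
class BufferPreset:
    name: str
    conditions: BufferConditions
    provenance_note: str = ""


def read_fasta(source: str | Path | IO[str]) -> list[SequenceRecord]:
    """Parse multi-FASTA into normalized records, order preserved.

    Lowercase is uppercased and internal whitespace removed before the
    strict-alphabet check; records containing ambiguity codes (N, R, Y, ...)
    or any other non-ACGT character raise AlphabetError naming every
    offending record and its characters.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    stripped = text.lstrip()
    if not stripped:
        raise FastaFormatError("empty input: no FASTA records")
    if not stripped.startswith(">"):
        raise FastaFormatError("input does not start with a '>' FASTA header")

    records: list[SequenceRecord] = []
    offenders: list[str] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "").replace("\t", "")
        if not rec.id:
            raise FastaFormatError("record with empty identifier")
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence body")
        bad = sorted(set(seq) - set("ACGT"))
        if bad:
            offenders.append(f"{rec.id} ({''.join(bad)})")
        records.append(
            SequenceRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    if offenders:
        raise AlphabetError(
            "records contain characters outside A/C/G/T: " + "; ".join(offenders)
        )
    if not records:
        raise FastaFormatError("no FASTA records parsed")
    return records


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(records: Iterable[SequenceRecord], stream: IO[str]) -> None:
    """Write plain records (used for fixture templates)."""
    for rec in records:
        header = rec.id if not rec.description or rec.description == rec.id else rec.description
        stream.write(f">{header}\n{_wrap(rec.sequence)}\n")


def write_primers_fasta(pairs: Iterable[PrimerPair], stream: IO[str]) -> None:
    """Two FASTA records per pair, ids suffixed ``_F`` and ``_R``."""
    for pair in pairs:
        stream.write(f">{pair.record_id}_F\n{_wrap(pair.forward_full)}\n")
        stream.write(f">{pair.record_id}_R\n{_wrap(pair.reverse_full)}\n")


def write_primers_csv(
    pairs: Iterable[PrimerPair],
    failures: Iterable[DesignFailure],
    stream: IO[str],
) -> None:
    """Flat report: two "ok" rows per pair, one "failed" row per failure.

    Tm is printed with 2 decimals; warnings are joined with '; '.
    UTF-8, '.' decimal separator, '\\n' newlines.
    """
    writer = csv.DictWriter(stream, fieldnames=list(CSV_COLUMNS), lineterminator="\n")
    writer.writeheader()
    for pair in pairs:
        for orientation, full, cand in (
            ("forward", pair.forward_full, pair.forward_candidate),
            ("reverse", pair.reverse_full, pair.reverse_candidate),
        ):
            ext = full[: len(full) - cand.length]
            writer.writerow(
                {
                    "record_id": pair.record_id,
                    "status": "ok",
                    "orientation": orientation,
                    "full_sequence": full,
                    "annealing_sequence": cand.annealing_seq,
                    "extension": ext,
                    "annealing_length": cand.length,
                    "tm_celsius": f"{cand.tm:.2f}",
                    "ends_gc": cand.ends_gc,
                    "warnings": "; ".join(pair.warnings),
                }
            )
    for failure in failures:
        writer.writerow(
            {
                "record_id": failure.record_id,
                "status": "failed",
                "orientation": failure.orientation,
                "full_sequence": "",
                "annealing_sequence": "",
                "extension": "",
                "annealing_length": "",
                "tm_celsius": "",
                "ends_gc": "",
                "warnings": failure.reason,
            }
        )


# ---------------------------------------------------------------------------
# Buffer presets


def _presets_from_mapping(data: dict) -> dict[str, BufferPreset]:
    registry: dict[str, BufferPreset] = {}
    for name, entry in (data.get("presets") or {}).items():
        note = entry.get("provenance_note", "")
        fields = {k: v for k, v in entry.items() if k != "provenance_note"}
        fields.setdefault("k_mode", "symmetric")
        registry[name] = BufferPreset(
            name=name, conditions=BufferConditions(**fields), provenance_note=note
        )
    return registry


def load_presets(user_path: str | Path | None = None) -> dict[str, BufferPreset]:
    """Bundled preset registry, with an optional user YAML merged on top.

    User entries override bundled entries of the same name; new names are
    added.
    """
    text = (
        resources.files("primerwalk.data")
        .joinpath("buffer_presets.yaml")
        .read_text(encoding="utf-8")
    )
    registry = _presets_from_mapping(yaml.safe_load(text))
    if user_path is not None:
        user_data = yaml.safe_load(Path(user_path).read_text(encoding="utf-8"))
        registry.update(_presets_from_mapping(user_data))
    return registry


def resolve_buffer(
    name: str, registry: dict[str, BufferPreset] | None = None
) -> BufferConditions:
    """Look up a preset by name; unknown names raise with the available list."""
    if registry is None:
        registry = load_presets()
    if name not in registry:
        raise PresetNotFoundError(
            f"unknown buffer preset {name!r}; available: {sorted(registry)}"
        )
    return registry[name].conditions
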