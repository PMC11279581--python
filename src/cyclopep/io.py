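"""Readers and writers for peptide records.

Collections are newline-delimited JSON, one record object per line:

    {"id": ..., "sequence": ..., "synthesis": "ribosomal"|"nonribosomal",
     "bonds": [{"kind", "linkage", "pos1", "pos2", "head_to_tail",
                "qualifier": {...}}, ...],
     "source_kingdom": ..., "target_object": ...,
     "mic": [{"strain", "gram", "value", "unit"}, ...]}

Sequences use one-letter codes with bracketed tokens for nonstandard
residues.  FASTA is accepted for sequence-only statistics; bracketed tokens
are forbidden there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
from Bio import SeqIO

from .records import (
    BondKind,
    BondQualifier,
    GramClass,
    IntrachainBond,
    Linkage,
    MICMeasurement,
    PeptideRecord,
    ResidueChain,
    Saturation,
    Synthesis,
    tokenize,
    validate_record,
)


class InputError(ValueError):
    """Unreadable, malformed or schema-violating input."""


def record_to_dict(record: PeptideRecord, include_truth: bool = False) -> dict:
    d: dict = {
        "id": record.chain.id,
        "sequence": record.chain.sequence,
        "synthesis": record.synthesis.value,
        "bonds": [],
    }
    for b in record.bonds:
        bd: dict = {
            "kind": b.kind.value,
            "linkage": b.linkage.value,
            "pos1": b.pos1,
            "pos2": b.pos2,
            "head_to_tail": b.head_to_tail,
        }
        if b.qualifier is not None:
            q = b.qualifier
            qd = {
                k: v
                for k, v in {
                    "ring_members": q.ring_members,
                    "saturation": q.saturation.value if q.saturation else None,
                    "methylated": q.methylated,
                    "alpha_carbon": q.alpha_carbon,
                    "residue1": q.residue1,
                    "residue2": q.residue2,
                }.items()
                if v is not None
            }
            if qd:
                bd["qualifier"] = qd
        d["bonds"].append(bd)
    if record.source_kingdom is not None:
        d["source_kingdom"] = record.source_kingdom
    if record.target_object is not None:
        d["target_object"] = record.target_object
    if record.mic:
        d["mic"] = [
            {
                "strain": m.strain,
                "gram": m.gram.value if m.gram else None,
                "value": m.value,
                "unit": m.unit,
            }
            for m in record.mic
        ]
    if include_truth and record.truth is not None:
        d["truth"] = record.truth
    return d


def record_from_dict(d: dict) -> PeptideRecord:
    try:
        chain = ResidueChain(id=str(d["id"]), tokens=tuple(tokenize(d["sequence"])))
        bonds = []
        for bd in d.get("bonds", []):
            qd = bd.get("qualifier")
            qualifier = None
            if qd:
                qualifier = BondQualifier(
                    ring_members=qd.get("ring_members"),
                    saturation=Saturation(qd["saturation"])
                    if qd.get("saturation")
                    else None,
                    methylated=qd.get("methylated"),
                    alpha_carbon=qd.get("alpha_carbon"),
                    residue1=qd.get("residue1"),
                    residue2=qd.get("residue2"),
                )
            bonds.append(
                IntrachainBond(
                    kind=BondKind(bd["kind"]),
                    linkage=Linkage(bd["linkage"]),
                    pos1=int(bd["pos1"]),
                    pos2=int(bd["pos2"]),
                    head_to_tail=bool(bd.get("head_to_tail", False)),
                    qualifier=qualifier,
                )
            )
        mic = tuple(
            MICMeasurement(
                strain=str(m.get("strain", "")),
                gram=GramClass(m["gram"]) if m.get("gram") else None,
                value=float(m["value"]),
                unit=str(m.get("unit", "ug/mL")),
            )
            for m in d.get("mic", [])
        )
        return PeptideRecord(
            chain=chain,
            synthesis=Synthesis(d.get("synthesis", "ribosomal")),
            bonds=tuple(bonds),
            source_kingdom=d.get("source_kingdom"),
            target_object=d.get("target_object"),
            mic=mic,
            truth=d.get("truth"),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise InputError(f"bad record: {exc}") from exc


@dataclass(frozen=True)
class ReadResult:
    records: list[PeptideRecord]
    diagnostics: list[str]   # one message per rejected line, with line number


def read_records(path: Union[str, Path], strict: bool = False) -> ReadResult:
    """Read newline-delimited JSON records.

    Lenient mode collects a diagnostic per invalid line and keeps going;
    strict mode raises on the first violation.  Schema validity includes the
    record invariants (:func:`validate_record`).
    """
    path = Path(path)
    records: list[PeptideRecord] = []
    diagnostics: list[str] = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            d = json.loads(line)
            rec = record_from_dict(d)
            violations = validate_record(rec)
            if violations:
                raise InputError("; ".join(violations))
        except (json.JSONDecodeError, InputError) as exc:
            msg = f"line {lineno}: {exc}"
            if strict:
                raise InputError(msg) from exc
            diagnostics.append(msg)
            continue
        records.append(rec)
    if not records and not diagnostics:
        diagnostics.append(f"{path}: no records found (empty input)")
    return ReadResult(records=records, diagnostics=diagnostics)


def write_records(
    records: Sequence[PeptideRecord],
    path: Union[str, Path],
    include_truth: bool = False,
) -> None:
    """Write records as newline-delimited JSON (deterministic key order)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_dict(rec, include_truth=include_truth),
                                sort_keys=True))
            fh.write("\n")


def read_fasta(path: Union[str, Path]) -> list[ResidueChain]:
    """Read chains from FASTA (standard alphabet only; wrapped lines fine).

    Ids are the first whitespace-delimited header token; duplicates are an
    error, as is any character outside the standard alphabet.
    """
    path = Path(path)
    chains: list[ResidueChain] = []
    seen: dict[str, int] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    for rec in parsed:
        seq = str(rec.seq).upper()
        if "[" in seq or "]" in seq:
            raise InputError(
                f"{rec.id}: bracketed tokens are not allowed in FASTA mode"
            )
        try:
            tokens = tokenize(seq)
        except ValueError as exc:
            raise InputError(f"{rec.id}: {exc}") from exc
        seen[rec.id] = seen.get(rec.id, 0) + 1
        chains.append(ResidueChain(id=rec.id, tokens=tuple(tokens)))
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise InputError(f"duplicate FASTA ids: {', '.join(dups)}")
    return chains


def records_to_table(records: Sequence[PeptideRecord]) -> pd.DataFrame:
    """Flat TSV-friendly view of a record collection (one row per record)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.chain.id,
                "sequence": rec.chain.sequence,
                "length": rec.chain.length,
                "synthesis": rec.synthesis.value,
                "n_bonds": len(rec.bonds),
                "bond_kinds": ",".join(b.kind.value for b in rec.bonds),
                "source_kingdom": rec.source_kingdom or "",
                "n_mic": len(rec.mic),
            }
        )
    return pd.DataFrame(rows)
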