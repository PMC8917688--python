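"""FASTA and coverage-table I/O, plus the contig fragmentation utility.

Contigs are held as plain uppercase DNA strings over {A,C,G,T,N}; any other
character (IUPAC ambiguity codes and stray symbols) is coerced to N on ingest
so real-world assemblies still load, with the coercion count logged.

The depth table follows the MetaBAT ``jgi_summarize_bam_contig_depths``
dialect: tab-separated with a header naming at least ``contigName``,
``contigLen`` and ``totalAvgDepth``; extra per-sample columns are ignored and
column order is irrelevant.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, InputError, ParameterError

logger = logging.getLogger(__name__)

#: mapping contig_id -> mean read depth (reads per base), all depths >= 0
DepthTable = Dict[str, float]

_INVALID_BASE = re.compile(r"[^ACGTN]")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an {A,C,G,T,N} string (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class ContigRecord:
    """One assembly sequence: identifier, optional description, DNA string."""

    contig_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ParameterError("contig_id must be non-empty")
        if len(self.sequence) < 1:
            raise ParameterError(
                f"contig '{self.contig_id}' has an empty sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> List[ContigRecord]:
    """Read a FASTA assembly into an ordered list of :class:`ContigRecord`.

    Sequences are uppercased; characters outside {A,C,G,T,N} are replaced by
    N (the total replacement count is logged). Duplicate identifiers and
    records with empty sequences are format errors.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"FASTA file not found: {p}")
    records: List[ContigRecord] = []
    seen: set[str] = set()
    n_coerced = 0
    for rec in SeqIO.parse(str(p), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record '{rec.id}' has an empty sequence")
        if rec.id in seen:
            raise FormatError(f"duplicate contig id in FASTA: '{rec.id}'")
        seen.add(rec.id)
        invalid = _INVALID_BASE.findall(seq)
        if invalid:
            n_coerced += len(invalid)
            seq = _INVALID_BASE.sub("N", seq)
        desc = rec.description[len(rec.id):].strip()
        records.append(ContigRecord(rec.id, seq, desc))
    if n_coerced:
        logger.warning(
            "%d non-ACGTN characters coerced to N while reading %s",
            n_coerced, p,
        )
    return records


def write_fasta(records: Iterable[ContigRecord], path, line_width: int = 70) -> None:
    """Write records as FASTA with bodies wrapped at ``line_width`` columns."""
    if line_width < 1:
        raise ParameterError("line_width must be a positive integer")
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.contig_id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=line_width)
        writer.write_file(seqrecords)


def fragment_contigs(
    records: Sequence[ContigRecord],
    length_threshold: int = 1_000_000,
    fragment_size: int = 100_000,
) -> List[ContigRecord]:
    """Split contigs strictly longer than ``length_threshold`` into
    consecutive ``fragment_size`` pieces plus a final remainder.

    Fragment ids are ``<original>_frag<i>`` with a 1-based index; contigs at
    or below the threshold pass through unchanged. Concatenating a contig's
    fragments in order reproduces the original sequence exactly.
    """
    if length_threshold <= 0 or fragment_size <= 0:
        raise ParameterError("length_threshold and fragment_size must be positive")
    if fragment_size > length_threshold:
        raise ParameterError("fragment_size must not exceed length_threshold")
    out: List[ContigRecord] = []
    for rec in records:
        if rec.length <= length_threshold:
            out.append(rec)
            continue
        for i, offset in enumerate(range(0, rec.length, fragment_size), start=1):
            piece = rec.sequence[offset:offset + fragment_size]
            out.append(
                ContigRecord(f"{rec.contig_id}_frag{i}", piece, rec.description)
            )
    return out


_REQUIRED_DEPTH_COLUMNS = ("contigName", "contigLen", "totalAvgDepth")


def read_depth_table(path) -> DepthTable:
    """Parse a MetaBAT-style depth summary into ``{contig: totalAvgDepth}``."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"depth table not found: {p}")
    table = pd.read_csv(p, sep="\t", dtype=str)
    for col in _REQUIRED_DEPTH_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"depth table is missing required column '{col}'")
    depths: DepthTable = {}
    for row_number, (name, depth) in enumerate(
        zip(table["contigName"], table["totalAvgDepth"]), start=2
    ):
        try:
            value = float(depth)
        except (TypeError, ValueError):
            raise FormatError(
                f"non-numeric totalAvgDepth on line {row_number}: {depth!r}"
            ) from None
        if value < 0:
            raise FormatError(
                f"negative depth on line {row_number} for contig '{name}'"
            )
        depths[str(name)] = value
    return depths
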