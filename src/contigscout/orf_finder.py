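"""Six-frame prokaryotic ORF calling and gene-call import.

The built-in caller is a deterministic maximal-span scanner: within each of
the six reading frames an ORF runs from the first permitted start codon after
the previous stop to the next stop codon (inclusive). It deliberately applies
no coding-statistics model, so unlike a trained gene caller it cannot reject
spurious open spans on composition alone; the 300 nt default length floor is
what keeps its false-call rate low (see docs/methods.md). Trailing spans with
a start but no stop before the contig edge are emitted with ``partial=True``.

Users with external gene calls (e.g. from a dedicated prokaryotic gene
predictor) can import them via :func:`import_gene_calls` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import FormatError, InputError, ParameterError
from .sequence_io import ContigRecord, reverse_complement

DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")
DEFAULT_TRANSLATION_TABLE = 11
DEFAULT_MIN_ORF_LENGTH = 300  # nt, including the stop codon


@dataclass
class OrfRecord:
    """A gene call. Coordinates are 1-based inclusive on the forward strand
    with ``start <= end`` on both strands; ``dna`` is the coding strand."""

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    dna: str
    protein: str
    partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_CODON_MAPS: Dict[int, Dict[str, str]] = {}


def _codon_map(table: int) -> Dict[str, str]:
    if table not in _CODON_MAPS:
        try:
            t = CodonTable.unambiguous_dna_by_id[table]
        except KeyError:
            raise ParameterError(f"unknown translation table: {table}") from None
        mapping = dict(t.forward_table)
        for stop in t.stop_codons:
            mapping[stop] = "*"
        _CODON_MAPS[table] = mapping
    return _CODON_MAPS[table]


def translate(dna: str, table: int = DEFAULT_TRANSLATION_TABLE) -> str:
    """Translate a coding-strand DNA string.

    Internal stops render ``*``; codons containing N (or otherwise
    undecodable) render ``X``; a single terminal stop is stripped.
    """
    if len(dna) % 3 != 0:
        raise ParameterError(
            f"DNA length {len(dna)} is not divisible by 3"
        )
    mapping = _codon_map(table)
    aas = [mapping.get(dna[i:i + 3], "X") for i in range(0, len(dna), 3)]
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


# base encoding: A=0 C=1 G=2 T=3 N(and anything else)=4; codons as base-5 codes
_BASE_LUT = np.full(256, 4, dtype=np.int32)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i


def _encode(sequence: str) -> np.ndarray:
    return _BASE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _codon_code(codon: str) -> int:
    a, b, c = (_BASE_LUT[ord(x)] for x in codon)
    return int(a) * 25 + int(b) * 5 + int(c)


_STOP_CODES = np.array([_codon_code(c) for c in ("TAA", "TAG", "TGA")])


def _scan_strand(
    enc: np.ndarray,
    start_codes: np.ndarray,
    min_codons: int,
) -> List[Tuple[int, int, bool]]:
    """Yield (start_nt, end_nt, partial) 0-based inclusive spans on one strand."""
    spans: List[Tuple[int, int, bool]] = []
    n = enc.size
    for frame in range(3):
        n_codons = (n - frame) // 3
        if n_codons < 2:
            continue
        upto = frame + 3 * n_codons
        codes = (
            enc[frame:upto:3] * 25
            + enc[frame + 1:upto:3] * 5
            + enc[frame + 2:upto:3]
        )
        is_stop = np.isin(codes, _STOP_CODES)
        is_start = np.isin(codes, start_codes)
        stops = np.flatnonzero(is_stop)
        starts = np.flatnonzero(is_start)
        if starts.size == 0:
            continue
        prev = np.concatenate(([-1], stops))
        seg_ends = np.concatenate((stops, [n_codons - 1]))
        first = np.searchsorted(starts, prev + 1)
        for k in range(prev.size):
            if first[k] >= starts.size:
                continue
            s = starts[first[k]]
            e = seg_ends[k]
            if s > e:
                continue
            partial = k == prev.size - 1  # ran off the frame without a stop
            if not partial and s == e:
                continue  # a lone stop codon cannot be an ORF
            if e - s + 1 < min_codons:
                continue
            spans.append((frame + 3 * s, frame + 3 * e + 2, partial))
    return spans


def find_orfs(
    contig: ContigRecord,
    min_length: int = DEFAULT_MIN_ORF_LENGTH,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    translation_table: int = DEFAULT_TRANSLATION_TABLE,
) -> List[OrfRecord]:
    """Call ORFs on all six frames of ``contig``.

    ``min_length`` is in nucleotides including the stop codon. Overlapping
    calls on opposite strands are both kept. Output is sorted by forward
    start coordinate (then strand), and ORF ids are
    ``<contig_id>_<1-based serial>`` in that order.
    """
    if min_length < 6:
        raise ParameterError("min_length must be at least 6 nt (codon + stop)")
    start_codes = np.array(sorted(_codon_code(c) for c in start_codons))
    min_codons = (min_length + 2) // 3
    fwd = contig.sequence
    rev = reverse_complement(fwd)
    L = len(fwd)

    raw: List[Tuple[int, int, str, bool]] = []
    for s, e, partial in _scan_strand(_encode(fwd), start_codes, min_codons):
        raw.append((int(s) + 1, int(e) + 1, "+", partial))
    for s, e, partial in _scan_strand(_encode(rev), start_codes, min_codons):
        raw.append((L - int(e), L - int(s), "-", partial))

    raw.sort(key=lambda t: (t[0], t[2], t[1]))
    orfs: List[OrfRecord] = []
    for serial, (start, end, strand, partial) in enumerate(raw, start=1):
        if strand == "+":
            dna = fwd[start - 1:end]
        else:
            dna = rev[L - end:L - start + 1]
        orfs.append(
            OrfRecord(
                orf_id=f"{contig.contig_id}_{serial}",
                contig_id=contig.contig_id,
                start=start,
                end=end,
                strand=strand,
                dna=dna,
                protein=translate(dna, translation_table),
                partial=partial,
            )
        )
    return orfs


def write_gene_calls(orfs: Iterable[OrfRecord], gff_path, protein_path) -> None:
    """Export gene calls as GFF3 CDS features plus a protein FASTA.

    Counterpart of :func:`import_gene_calls`; feature IDs are the ORF ids.
    """
    orfs = list(orfs)
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for orf in orfs:
            gff.write(
                "\t".join(
                    (
                        orf.contig_id,
                        "contigscout",
                        "CDS",
                        str(orf.start),
                        str(orf.end),
                        ".",
                        orf.strand,
                        "0",
                        f"ID={orf.orf_id};partial={'1' if orf.partial else '0'}",
                    )
                )
                + "\n"
            )
    with open(protein_path, "w") as faa:
        for orf in orfs:
            faa.write(f">{orf.orf_id}\n{orf.protein}\n")


def import_gene_calls(
    gff_path,
    protein_fasta_path,
    contigs: Sequence[ContigRecord],
) -> List[OrfRecord]:
    """Build :class:`OrfRecord` objects from external gene calls.

    ``gff_path`` must be GFF3 whose CDS ``seqid`` values match contig ids and
    whose CDS IDs match the protein FASTA identifiers.
    """
    import gffutils

    for path in (gff_path, protein_fasta_path):
        if not Path(path).exists():
            raise InputError(f"gene-call input not found: {path}")
    proteins = {
        rec.id: str(rec.seq).rstrip("*")
        for rec in SeqIO.parse(str(protein_fasta_path), "fasta")
    }
    contig_map = {c.contig_id: c for c in contigs}
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    orfs: List[OrfRecord] = []
    for serial, cds in enumerate(db.features_of_type("CDS"), start=1):
        if cds.seqid not in contig_map:
            raise FormatError(f"CDS references unknown contig '{cds.seqid}'")
        ids = cds.attributes.get("ID", [])
        orf_id = ids[0] if ids else f"{cds.seqid}_{serial}"
        if orf_id not in proteins:
            raise FormatError(f"no protein sequence found for CDS '{orf_id}'")
        contig = contig_map[cds.seqid]
        segment = contig.sequence[cds.start - 1:cds.end]
        strand = cds.strand if cds.strand in "+-" else "+"
        dna = segment if strand == "+" else reverse_complement(segment)
        partial = cds.attributes.get("partial", ["0"])[0] in ("1", "true", "True")
        orfs.append(
            OrfRecord(
                orf_id=orf_id,
                contig_id=cds.seqid,
                start=cds.start,
                end=cds.end,
                strand=strand,
                dna=dna,
                protein=proteins[orf_id],
                partial=partial,
            )
        )
    orfs.sort(key=lambda o: (o.contig_id, o.start, o.strand))
    return orfs
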