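"""Per-contig compositional metrics: GC, coding density, TNF and RSCU.

Tetranucleotide frequencies (TNF) are strand-folded: each 4-mer is mapped to
the lexicographically smaller of itself and its reverse complement, giving
136 canonical classes (16 palindromic + 120 paired), so the signature is
identical for a contig and its reverse complement. Codon usage bias is
quantified as relative synonymous codon usage (RSCU): for codon c in a
synonymous family of size k with family total T, RSCU(c) = k * count(c) / T.
Stop codons and the single-codon families (ATG, TGG) are excluded, leaving a
59-entry vector. RSCU is scale-free across contigs with different gene
counts, which is what makes it usable as a clustering feature.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import ParameterError
from .orf_finder import OrfRecord, _codon_map
from .sequence_io import ContigRecord, reverse_complement

# --- canonical 4-mer classes -------------------------------------------------

_ALL_KMERS = ["".join(p) for p in product("ACGT", repeat=4)]
#: the 136 canonical (strand-folded) tetranucleotide classes, sorted
CANONICAL_KMERS: List[str] = sorted(
    {min(k, reverse_complement(k)) for k in _ALL_KMERS}
)
_CANON_INDEX = {k: i for i, k in enumerate(CANONICAL_KMERS)}
# maps the base-4 code of each of the 256 raw 4-mers to its canonical class
_FOLD = np.array(
    [_CANON_INDEX[min(k, reverse_complement(k))] for k in _ALL_KMERS]
)

_BASE4 = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE4[_b] = _i

# --- RSCU codon bookkeeping (translation table 11) ---------------------------

_STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))
_T11 = _codon_map(11)
_FAMILIES: Dict[str, List[str]] = {}
for _codon, _aa in sorted(_T11.items()):
    if _aa != "*":
        _FAMILIES.setdefault(_aa, []).append(_codon)
#: the 59 codons carrying synonymous-usage information, sorted
RSCU_CODONS: List[str] = sorted(
    c for aa, codons in _FAMILIES.items() if len(codons) > 1 for c in codons
)
_RSCU_INDEX = {c: i for i, c in enumerate(RSCU_CODONS)}


@dataclass
class CompositionProfile:
    """Compositional feature bundle for one contig."""

    contig_id: str
    length: int
    gc_percent: Optional[float]
    coding_density: float
    tnf: np.ndarray
    rscu: np.ndarray
    n_orfs: int
    n_complete_orfs: int


def gc_content(sequence: str) -> Optional[float]:
    """GC percentage of a sequence, with N bases excluded entirely.

    Returns None (missing) for an all-N sequence; raises on an empty one.
    """
    if not sequence:
        raise ParameterError("gc_content of an empty sequence is undefined")
    g = sequence.count("G")
    c = sequence.count("C")
    at = sequence.count("A") + sequence.count("T")
    denom = g + c + at
    if denom == 0:
        return None
    return 100.0 * (g + c) / denom


def coding_density(n_orfs: int, contig_length: int) -> float:
    """Genes per kilobase: 1000 * n_orfs / contig_length."""
    if contig_length < 1:
        raise ParameterError("contig_length must be >= 1")
    return 1000.0 * n_orfs / contig_length


def tnf_vector(sequence: str) -> np.ndarray:
    """Canonical tetranucleotide frequency vector (length 136, sums to 1).

    A 4 bp window slides with step 1; windows containing N are skipped. If no
    valid window exists (sequence shorter than 4 unambiguous bases) the
    all-zero vector is returned.
    """
    if len(sequence) < 4:
        return np.zeros(len(CANONICAL_KMERS))
    enc = _BASE4[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    ok = enc >= 0
    valid = ok[:-3] & ok[1:-2] & ok[2:-1] & ok[3:]
    if not valid.any():
        return np.zeros(len(CANONICAL_KMERS))
    e = np.where(ok, enc, 0)
    codes = e[:-3] * 64 + e[1:-2] * 16 + e[2:-1] * 4 + e[3:]
    counts = np.bincount(codes[valid], minlength=256).astype(float)
    folded = np.zeros(len(CANONICAL_KMERS))
    np.add.at(folded, _FOLD, counts)
    return folded / folded.sum()


def count_codons(orfs: Sequence[OrfRecord]) -> Counter:
    """Pool coding-strand codons of all complete ORFs, excluding each ORF's
    terminal stop codon and any codon containing N."""
    counts: Counter = Counter()
    for orf in orfs:
        if orf.partial:
            continue
        dna = orf.dna
        body = dna[:-3] if dna[-3:] in _STOP_CODONS else dna
        for i in range(0, len(body) - 2, 3):
            codon = body[i:i + 3]
            if "N" not in codon and codon not in _STOP_CODONS:
                counts[codon] += 1
    return counts


def rscu_vector(orfs: Sequence[OrfRecord]) -> np.ndarray:
    """RSCU vector (length 59) over the pooled codons of complete ORFs.

    Families with zero observations contribute zeros; otherwise the family's
    k values average exactly 1.
    """
    counts = count_codons(orfs)
    vec = np.zeros(len(RSCU_CODONS))
    for codons in _FAMILIES.values():
        k = len(codons)
        if k < 2:
            continue
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        for c in codons:
            vec[_RSCU_INDEX[c]] = k * counts.get(c, 0) / total
    return vec


def compute_composition(
    contig: ContigRecord, orfs: Sequence[OrfRecord]
) -> CompositionProfile:
    """Bundle all compositional metrics for one contig and its gene calls."""
    return CompositionProfile(
        contig_id=contig.contig_id,
        length=contig.length,
        gc_percent=gc_content(contig.sequence),
        coding_density=coding_density(len(orfs), contig.length),
        tnf=tnf_vector(contig.sequence),
        rscu=rscu_vector(orfs),
        n_orfs=len(orfs),
        n_complete_orfs=sum(1 for o in orfs if not o.partial),
    )
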