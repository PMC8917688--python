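"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles with plain string/dict
operations — no imports from contigscout internals and no shared lookup
tables — so agreement with the package is a genuine two-route check.
"""

from typing import Dict, List, Set, Tuple

# Standard genetic code (codon -> amino acid; table 11 shares these codes)
GENETIC_CODE: Dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOPS = {"TAA", "TAG", "TGA"}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def translate_oracle(dna: str) -> str:
    aas = []
    for i in range(0, len(dna), 3):
        codon = dna[i:i + 3]
        aas.append(GENETIC_CODE.get(codon, "X"))
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


def _scan_frames(seq: str, min_length: int, starts) -> List[Tuple[int, int, bool]]:
    """0-based inclusive (start, end, partial) spans on the given strand."""
    spans = []
    for frame in range(3):
        seg_start_codon = None  # codon index of first start in open segment
        codon_indices = list(range(frame, len(seq) - 2, 3))
        for ci, pos in enumerate(codon_indices):
            codon = seq[pos:pos + 3]
            if codon in STOPS:
                if seg_start_codon is not None:
                    length = pos + 3 - seg_start_codon
                    if length >= min_length:
                        spans.append((seg_start_codon, pos + 2, False))
                seg_start_codon = None
                open_segment_closed = True
            elif codon in starts and seg_start_codon is None:
                seg_start_codon = pos
        if seg_start_codon is not None and codon_indices:
            last_end = codon_indices[-1] + 2
            length = last_end + 1 - seg_start_codon
            if length >= min_length:
                spans.append((seg_start_codon, last_end, True))
    return spans


def orf_spans_oracle(
    seq: str,
    min_length: int = 90,
    starts=("ATG", "GTG", "TTG"),
) -> Set[Tuple[int, int, str, bool]]:
    """Six-frame maximal ORF spans as 1-based forward-strand coordinates."""
    starts = set(starts)
    out: Set[Tuple[int, int, str, bool]] = set()
    for s, e, partial in _scan_frames(seq, min_length, starts):
        out.add((s + 1, e + 1, "+", partial))
    rc = revcomp(seq)
    L = len(seq)
    for s, e, partial in _scan_frames(rc, min_length, starts):
        out.add((L - e, L - s, "-", partial))
    return out


def gc_oracle(seq: str):
    gc = sum(1 for b in seq if b in "GC")
    acgt = sum(1 for b in seq if b in "ACGT")
    if acgt == 0:
        return None
    return 100.0 * gc / acgt


def tnf_oracle(seq: str) -> Dict[str, float]:
    """Canonical 4-mer frequencies: count all raw 4-mers, then fold each
    onto min(kmer, revcomp(kmer))."""
    counts: Dict[str, int] = {}
    for i in range(len(seq) - 3):
        kmer = seq[i:i + 4]
        if any(b not in "ACGT" for b in kmer):
            continue
        canon = min(kmer, revcomp(kmer))
        counts[canon] = counts.get(canon, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in counts.items()}


def rscu_oracle(coding_seqs: List[str]) -> Dict[str, float]:
    """RSCU per codon from a list of coding sequences (stop included at the
    end of each); single-codon families and stops excluded."""
    families: Dict[str, List[str]] = {}
    for codon, aa in GENETIC_CODE.items():
        if aa != "*":
            families.setdefault(aa, []).append(codon)
    counts: Dict[str, int] = {}
    for dna in coding_seqs:
        body = dna[:-3] if dna[-3:] in STOPS else dna
        for i in range(0, len(body) - 2, 3):
            codon = body[i:i + 3]
            if codon in GENETIC_CODE and codon not in STOPS:
                counts[codon] = counts.get(codon, 0) + 1
    out: Dict[str, float] = {}
    for aa, codons in families.items():
        if len(codons) < 2:
            continue
        total = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = len(codons) * counts.get(c, 0) / total if total else 0.0
    return out
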