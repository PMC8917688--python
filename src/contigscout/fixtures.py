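"""Synthetic assemblies, hit tables, depth tables and marker counts with
planted ground truth.

The generator emulates the things the pipeline measures — per-genome GC,
gene density, codon-usage bias, lineage-labelled homology hits, per-contig
coverage and single-copy-marker counts — while keeping the planted gene
structure exactly recoverable by the built-in maximal-span ORF caller. Two
deliberate idealizations make that possible (see docs/methods.md): planted
genes interleave a fixed 9-codon "shadow-breaker" block that plants stop
codons in all five non-coding frames, and intergenic sequence carries a
periodic all-frame stop cassette, so no spurious open span of 300 nt or
more can occur anywhere. Real genomes are messier in exactly this respect.

Everything is deterministic under fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .binning import UNIVERSAL_MARKERS
from .composition import _FAMILIES
from .errors import ParameterError
from .orf_finder import OrfRecord, translate
from .sequence_io import ContigRecord, fragment_contigs, reverse_complement, write_fasta
from .taxonomy import HitRecord, TaxLineage

# Sense-codon block with a stop in every one of the five shadow frames
# (fwd+1, fwd+2 and all three reverse frames) and none in frame 0.
SHADOW_BREAKER: Tuple[str, ...] = (
    "GTA", "ATT", "GAT", "AAA", "CTA", "ATT", "AGC", "ACT", "CAG",
)
_BREAK_EVERY = 40  # sampled codons between breaker blocks

# 15-mer with TAA at offsets 0,4,8,12 and TTA at 3,7,11: stops in all six
# absolute frames wherever it lands.
STOP_CASSETTE = "TAATTAATTAATTAA"
_CASSETTE_SPACING = 45  # random intergenic bases between cassettes

_AA_WEIGHTS = {
    "A": 9, "C": 1, "D": 5, "E": 6, "F": 4, "G": 7, "H": 2, "I": 6,
    "K": 5, "L": 10, "M": 2, "N": 4, "P": 4, "Q": 4, "R": 5, "S": 6,
    "T": 5, "V": 7, "W": 1, "Y": 3,
}
_AA_LIST = sorted(_AA_WEIGHTS)
_AA_P = np.array([_AA_WEIGHTS[a] for a in _AA_LIST], dtype=float)
_AA_P /= _AA_P.sum()

_STOPS = ("TAA", "TGA", "TAG")
_STOP_P = (0.6, 0.25, 0.15)


@dataclass
class GenomeSpec:
    """Parameters of one synthetic genome."""

    name: str
    lineage: TaxLineage
    genome_length: int = 500_000
    target_gc: float = 50.0
    gene_density: float = 1.0
    coverage: float = 10.0
    codon_bias: Optional[Mapping[str, Sequence[float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 10 < self.target_gc < 90:
            raise ParameterError("target_gc must be in (10, 90)")
        if not 0 < self.gene_density <= 1.2:
            raise ParameterError("gene_density must be in (0, 1.2]")
        if self.genome_length < 1000:
            raise ParameterError("genome_length must be at least 1000 bp")
        if self.coverage < 0:
            raise ParameterError("coverage must be non-negative")


def default_codon_bias(
    rng: np.random.Generator, target_gc: float
) -> Dict[str, List[float]]:
    """A genome-specific codon preference: in each synonymous family one
    codon (picked at random among those whose wobble base matches the GC
    target) gets weight 10, the rest weight 1."""
    prefer_gc = target_gc >= 50.0
    bias: Dict[str, List[float]] = {}
    for aa, codons in _FAMILIES.items():
        weights = [1.0] * len(codons)
        candidates = [
            i for i, c in enumerate(codons)
            if (c[2] in "GC") == prefer_gc
        ] or list(range(len(codons)))
        weights[candidates[int(rng.integers(len(candidates)))]] = 10.0
        bias[aa] = weights
    return bias


def _bias_tables(
    bias: Mapping[str, Sequence[float]]
) -> Dict[str, Tuple[List[str], np.ndarray]]:
    tables = {}
    for aa, codons in _FAMILIES.items():
        weights = np.asarray(bias.get(aa, [1.0] * len(codons)), dtype=float)
        if len(weights) != len(codons):
            raise ParameterError(
                f"codon_bias for '{aa}' must have {len(codons)} weights"
            )
        tables[aa] = (codons, np.cumsum(weights / weights.sum()))
    return tables


def _sample_gene(
    rng: np.random.Generator,
    n_codons: int,
    tables: Mapping[str, Tuple[List[str], np.ndarray]],
) -> str:
    """One coding-strand gene: ATG + biased codons with periodic
    shadow-breaker blocks + a stop codon."""
    codons: List[str] = ["ATG"]
    aas = rng.choice(_AA_LIST, size=n_codons, p=_AA_P)
    draws = rng.random(n_codons)
    i = 0
    since_break = 0
    while len(codons) - 1 < n_codons and i < n_codons:
        if since_break >= _BREAK_EVERY:
            codons.extend(SHADOW_BREAKER)
            since_break = 0
            continue
        choices, cum = tables[aas[i]]
        codons.append(choices[int(np.searchsorted(cum, draws[i]))])
        i += 1
        since_break += 1
    codons.append(_STOPS[int(rng.choice(len(_STOPS), p=_STOP_P))])
    return "".join(codons)


def _intergenic(rng: np.random.Generator, length: int, gc_prob: float) -> str:
    """Intergenic filler: random bases at ``gc_prob`` GC, interleaved with
    the all-frame stop cassette every ~45 random bases."""
    p = min(max(gc_prob, 0.02), 0.98)
    probs = [(1 - p) / 2, p / 2, p / 2, (1 - p) / 2]
    parts: List[str] = []
    remaining = length
    while remaining > 0:
        r = min(_CASSETTE_SPACING, remaining)
        parts.append("".join(rng.choice(("A", "C", "G", "T"), size=r, p=probs)))
        remaining -= r
        if remaining >= len(STOP_CASSETTE):
            parts.append(STOP_CASSETTE)
            remaining -= len(STOP_CASSETTE)
    return "".join(parts)


def synth_genome(spec: GenomeSpec) -> Tuple[ContigRecord, List[OrfRecord]]:
    """Generate one genome contig plus its true gene calls.

    Deterministic for a given spec (the spec's seed drives everything).
    Genes are placed left to right at the planted density with random
    strands; intergenic GC is solved so the whole contig lands on
    ``target_gc`` within about two points.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    n_genes = int(round(spec.gene_density * L / 1000.0))
    bias = spec.codon_bias or default_codon_bias(rng, spec.target_gc)
    tables = _bias_tables(bias)

    sizes = rng.integers(110, 300, size=n_genes)
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    genes = [_sample_gene(rng, int(s), tables) for s in sizes]
    total_gene = sum(len(g) for g in genes)
    intergenic_total = L - total_gene
    if intergenic_total < 60 * (n_genes + 1):
        raise ParameterError(
            f"gene_density {spec.gene_density} is infeasible for "
            f"genome_length {L}"
        )
    gaps = rng.multinomial(
        intergenic_total, [1.0 / (n_genes + 1)] * (n_genes + 1)
    )

    # solve the GC probability of the random intergenic bases so that the
    # realized contig GC matches the target (cassettes contribute zero GC)
    gene_gc = sum(g.count("G") + g.count("C") for g in genes)
    n_random = 0
    for g in map(int, gaps):
        n_cassettes = 0
        remaining = g
        while remaining > 0:
            remaining -= min(_CASSETTE_SPACING, remaining)
            if remaining >= len(STOP_CASSETTE):
                n_cassettes += 1
                remaining -= len(STOP_CASSETTE)
        n_random += g - n_cassettes * len(STOP_CASSETTE)
    target_gc_bases = spec.target_gc / 100.0 * L
    gc_prob = (target_gc_bases - gene_gc) / max(n_random, 1)

    parts: List[str] = []
    orfs: List[OrfRecord] = []
    offset = 0
    for i in range(n_genes):
        gap = _intergenic(rng, int(gaps[i]), gc_prob)
        parts.append(gap)
        offset += len(gap)
        dna = genes[i]
        strand = str(strands[i])
        piece = dna if strand == "+" else reverse_complement(dna)
        parts.append(piece)
        orfs.append(
            OrfRecord(
                orf_id=f"{spec.name}_{i + 1}",
                contig_id=spec.name,
                start=offset + 1,
                end=offset + len(dna),
                strand=strand,
                dna=dna,
                protein=translate(dna),
            )
        )
        offset += len(dna)
    parts.append(_intergenic(rng, int(gaps[n_genes]), gc_prob))
    sequence = "".join(parts)
    assert len(sequence) == L
    return ContigRecord(spec.name, sequence), orfs


DEFAULT_DECOY_LINEAGE = TaxLineage.from_string(
    "Bacteria;Decoyphyla;Decoyia;Decoyales;Decoyaceae;Decoyus;Decoyus fictus"
)


def synth_hit_table(
    orfs: Sequence[OrfRecord],
    lineage_of: Mapping[str, TaxLineage],
    path,
    n_hits: int = 20,
    identity_mean: float = 85.0,
    identity_sd: float = 5.0,
    contamination: float = 0.0,
    decoy_lineage: Optional[TaxLineage] = None,
    overrides: Optional[Mapping[str, Tuple[TaxLineage, float]]] = None,
    seed: int = 0,
) -> None:
    """Write a synthetic ``.blast`` hit table for the given true ORFs.

    Each ORF gets ``n_hits`` rows with strictly decreasing bitscores and
    identities drawn from Normal(identity_mean, identity_sd) clipped to
    [20, 100]. Hits carry the source contig's lineage (``lineage_of``)
    except for a ``contamination`` fraction drawn from ``decoy_lineage``.
    ``overrides`` maps an ORF id to ``(lineage, fraction)``: the top
    ``round(fraction * n_hits)`` hits of that ORF get the given lineage
    (used to plant HGT-like and boundary cases).
    """
    if not 0 <= contamination <= 1:
        raise ParameterError("contamination must be in [0, 1]")
    if n_hits < 1:
        raise ParameterError("n_hits must be >= 1")
    decoy = decoy_lineage or DEFAULT_DECOY_LINEAGE
    overrides = overrides or {}
    rng = np.random.default_rng(seed)
    with open(path, "w") as handle:
        for orf in orfs:
            true_lineage = lineage_of[orf.contig_id]
            override = overrides.get(orf.orf_id)
            n_override = (
                int(round(override[1] * n_hits)) if override is not None else 0
            )
            idents = np.clip(
                rng.normal(identity_mean, identity_sd, size=n_hits), 20.0, 100.0
            )
            decoys = rng.random(n_hits) < contamination
            for rank in range(n_hits):
                if override is not None and rank < n_override:
                    lineage = override[0]
                elif decoys[rank]:
                    lineage = decoy
                else:
                    lineage = true_lineage
                bitscore = 500.0 - 2.0 * rank
                hit = HitRecord(
                    orf_id=orf.orf_id,
                    subject_id=f"REF_{orf.orf_id}_{rank + 1}",
                    percent_identity=round(float(idents[rank]), 1),
                    aln_length=max(len(orf.protein), 1),
                    evalue=10.0 ** (-bitscore / 10.0),
                    bitscore=bitscore,
                    subject_title=f"hypothetical protein [{lineage.species}]",
                    lineage=lineage,
                )
                handle.write(hit.to_line() + "\n")


def write_depth_tsv(contigs: Sequence[ContigRecord],
                    coverage_of: Mapping[str, float], path) -> None:
    """Write a MetaBAT-dialect depth table for the given contigs."""
    with open(path, "w") as handle:
        handle.write("contigName\tcontigLen\ttotalAvgDepth\n")
        for c in contigs:
            handle.write(f"{c.contig_id}\t{c.length}\t{coverage_of[c.contig_id]:g}\n")


def write_marker_tsv(counts: Mapping[str, int], path) -> None:
    """Write a two-column marker-count TSV."""
    with open(path, "w") as handle:
        for marker in counts:
            handle.write(f"{marker}\t{counts[marker]}\n")


@dataclass
class MockCommunity:
    """A synthetic multi-genome assembly plus every sidecar input the
    pipeline consumes, with the planted truth."""

    contigs: List[ContigRecord]
    true_orfs: Dict[str, List[OrfRecord]]  # contig -> gene calls
    truth: Dict[str, str]  # contig -> source genome name
    lineages: Dict[str, TaxLineage]  # genome name -> lineage
    specs: List[GenomeSpec]
    fasta: Path
    depth: Path
    markers: Path
    hits: Path


def mock_community(
    specs: Sequence[GenomeSpec],
    out_dir,
    fragment: bool = True,
    length_threshold: int = 1_000_000,
    fragment_size: int = 100_000,
    n_hits: int = 20,
    identity_mean: float = 85.0,
    identity_sd: float = 5.0,
    contamination: float = 0.0,
    hit_overrides: Optional[Mapping[str, Tuple[TaxLineage, float]]] = None,
    seed: int = 0,
) -> MockCommunity:
    """Concatenate synthetic genomes into one assembly, optionally fragment
    long contigs, and write assembly FASTA, depth TSV, marker TSV and hit
    table.

    The marker table gives each of the 16 universal markers a count equal to
    the number of prokaryotic genomes, so k estimation recovers that number.
    Gene calls spanning a fragment boundary are dropped from the truth (the
    fragment carries a truncated copy, as in real fragmented assemblies).
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ParameterError("duplicate genome names in community specs")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome_contigs: List[ContigRecord] = []
    genome_orfs: Dict[str, List[OrfRecord]] = {}
    for spec in specs:
        contig, orfs = synth_genome(spec)
        genome_contigs.append(contig)
        genome_orfs[contig.contig_id] = orfs

    if fragment:
        contigs = fragment_contigs(genome_contigs, length_threshold, fragment_size)
    else:
        contigs = list(genome_contigs)

    truth: Dict[str, str] = {}
    true_orfs: Dict[str, List[OrfRecord]] = {c.contig_id: [] for c in contigs}
    for contig in contigs:
        if contig.contig_id in genome_orfs:  # not fragmented
            truth[contig.contig_id] = contig.contig_id
            true_orfs[contig.contig_id] = [
                OrfRecord(o.orf_id, o.contig_id, o.start, o.end, o.strand,
                          o.dna, o.protein, o.partial)
                for o in genome_orfs[contig.contig_id]
            ]
        else:
            source, frag = contig.contig_id.rsplit("_frag", 1)
            truth[contig.contig_id] = source
            frag_index = int(frag) - 1
            lo = frag_index * fragment_size  # 0-based offset of the fragment
            hi = lo + contig.length
            serial = 0
            for o in genome_orfs[source]:
                if o.start - 1 >= lo and o.end <= hi:
                    serial += 1
                    true_orfs[contig.contig_id].append(
                        OrfRecord(
                            orf_id=f"{contig.contig_id}_{serial}",
                            contig_id=contig.contig_id,
                            start=o.start - lo,
                            end=o.end - lo,
                            strand=o.strand,
                            dna=o.dna,
                            protein=o.protein,
                        )
                    )

    lineages = {s.name: s.lineage for s in specs}
    coverage_of = {
        c.contig_id: next(s.coverage for s in specs
                          if s.name == truth[c.contig_id])
        for c in contigs
    }
    n_prok = sum(1 for s in specs if s.lineage.domain in ("Bacteria", "Archaea"))
    marker_counts = {m: n_prok for m in UNIVERSAL_MARKERS}

    fasta = out_dir / "assembly.fa"
    depth = out_dir / "depth.tsv"
    markers = out_dir / "markers.tsv"
    hits = out_dir / "hits.blast"
    write_fasta(contigs, fasta)
    write_depth_tsv(contigs, coverage_of, depth)
    write_marker_tsv(marker_counts, markers)
    all_orfs = [o for c in contigs for o in true_orfs[c.contig_id]]
    lineage_of = {c.contig_id: lineages[truth[c.contig_id]] for c in contigs}
    synth_hit_table(
        all_orfs, lineage_of, hits,
        n_hits=n_hits, identity_mean=identity_mean, identity_sd=identity_sd,
        contamination=contamination, overrides=hit_overrides, seed=seed,
    )
    return MockCommunity(
        contigs=contigs, true_orfs=true_orfs, truth=truth, lineages=lineages,
        specs=list(specs), fasta=fasta, depth=depth, markers=markers, hits=hits,
    )
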