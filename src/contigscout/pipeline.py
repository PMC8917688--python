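"""End-to-end run orchestration.

Stage order: read FASTA -> optional min-length filter -> gene calls
(built-in caller or imported) -> hit table -> composition -> per-contig
taxon summaries -> marker-derived k + clustering (when a marker file is
given) -> HGT screen (when requested) -> reports -> FASTA subsets (when
requested). All outputs are deterministic for a fixed config and inputs.

Output files, for prefix P: ``P.csv`` (main report), ``P.tophits.tsv``,
``P.wordfreq.tsv``, ``P.hgt.tsv`` (with --hgt), ``P.matched.fa`` /
``P.unmatched.fa`` (with --fa), ``P.manifest.json``.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set

from . import binning, composition, extraction, hgt, orf_finder, sequence_io, taxonomy
from .errors import InputError, ParameterError
from .extraction import ContigProfile, ExtractionCriteria
from .taxonomy import RANKS

logger = logging.getLogger("contigscout")


@dataclass
class RunConfig:
    """Normalized configuration of one pipeline run (mirrors the CLI)."""

    fasta: str
    blast: str
    out_prefix: str
    depth: Optional[str] = None
    markers: Optional[str] = None
    marker_dialect: str = "tsv"
    gff: Optional[str] = None
    proteins: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None
    domain: Optional[str] = None
    perc: float = 50.0
    lvl: str = "genus"
    hits_n: int = 100
    phage: bool = False
    hgt: bool = False
    fa: bool = False
    gc_min: Optional[float] = None
    gc_max: Optional[float] = None
    density_min: Optional[float] = None
    density_max: Optional[float] = None
    aai_min: Optional[float] = None
    aai_max: Optional[float] = None
    length_min: Optional[int] = None
    coverage_min: Optional[float] = None
    coverage_max: Optional[float] = None
    clusters: Optional[Set[int]] = None
    min_contig_length: Optional[int] = None
    orf_min_length: int = orf_finder.DEFAULT_MIN_ORF_LENGTH
    linkage: str = "ward"
    seed: int = 0

    def __post_init__(self) -> None:
        self.lvl = self.lvl.lower()
        if self.lvl not in RANKS:
            raise ParameterError(
                f"-lvl must be one of {RANKS}, got '{self.lvl}'"
            )
        if not 0 < self.perc <= 100:
            raise ParameterError("-perc must be in (0, 100]")
        if self.hits_n < 1:
            raise ParameterError("-hits must be >= 1")
        taxon_flags = [
            v for v in (self.genus, self.species, self.domain) if v is not None
        ]
        if len(taxon_flags) > 1:
            raise ParameterError(
                "at most one of -genus/-species/-domain may be given"
            )
        if (self.gff is None) != (self.proteins is None):
            raise ParameterError(
                "external gene calls need both -gff and -proteins"
            )

    def taxon_criterion(self):
        if self.genus is not None:
            return self.genus, "genus"
        if self.species is not None:
            return self.species, "species"
        if self.domain is not None:
            return self.domain, "domain"
        return None, None

    def criteria(self) -> Optional[ExtractionCriteria]:
        """The extraction criteria implied by the config, if any are set."""
        taxon, rank = self.taxon_criterion()
        fields = dict(
            taxon=taxon, rank=rank, perc=self.perc, phage=self.phage,
            gc_min=self.gc_min, gc_max=self.gc_max,
            density_min=self.density_min, density_max=self.density_max,
            aai_min=self.aai_min, aai_max=self.aai_max,
            length_min=self.length_min,
            coverage_min=self.coverage_min, coverage_max=self.coverage_max,
            clusters=self.clusters,
        )
        try:
            return ExtractionCriteria(**fields)
        except ParameterError:
            return None  # no criterion active

    def apply_criteria(self, criteria: ExtractionCriteria) -> None:
        """Copy an ExtractionCriteria onto the config's criterion fields."""
        if criteria.taxon is not None:
            setattr(self, criteria.rank, criteria.taxon)
        self.perc = criteria.perc
        self.phage = criteria.phage
        for name in (
            "gc_min", "gc_max", "density_min", "density_max", "aai_min",
            "aai_max", "length_min", "coverage_min", "coverage_max", "clusters",
        ):
            setattr(self, name, getattr(criteria, name))


@dataclass
class RunResult:
    profiles: List[ContigProfile]
    outputs: Dict[str, str]
    matched: List[str] = field(default_factory=list)
    unmatched: List[str] = field(default_factory=list)
    hgt_calls: list = field(default_factory=list)
    k: Optional[int] = None


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; returns profiles and output paths."""
    contigs = sequence_io.read_fasta(config.fasta)
    logger.info("read %d contigs from %s", len(contigs), config.fasta)
    if config.min_contig_length is not None:
        before = len(contigs)
        contigs = [c for c in contigs if c.length >= config.min_contig_length]
        logger.info(
            "min-length filter (%d bp): %d -> %d contigs",
            config.min_contig_length, before, len(contigs),
        )

    # gene calls
    if config.gff is not None:
        all_orfs = orf_finder.import_gene_calls(
            config.gff, config.proteins, contigs
        )
        logger.info("imported %d gene calls", len(all_orfs))
    else:
        all_orfs = []
        for contig in contigs:
            all_orfs.extend(
                orf_finder.find_orfs(contig, min_length=config.orf_min_length)
            )
        logger.info("called %d ORFs (min length %d nt)",
                    len(all_orfs), config.orf_min_length)
    orfs_by_contig: Dict[str, List[orf_finder.OrfRecord]] = defaultdict(list)
    for orf in all_orfs:
        orfs_by_contig[orf.contig_id].append(orf)
    orf_index = {o.orf_id: o for o in all_orfs}

    # homology hits ("reusing hit table": the search itself never runs here)
    logger.info("reusing hit table %s", config.blast)
    hit_groups = taxonomy.parse_hit_table(config.blast)
    contig_ids = {c.contig_id for c in contigs}
    groups_by_contig: Dict[str, List[taxonomy.HitGroup]] = defaultdict(list)
    n_orphan = 0
    for orf_id, group in hit_groups.items():
        cid = taxonomy.contig_of_orf(orf_id)
        if cid in contig_ids:
            groups_by_contig[cid].append(group)
        else:
            n_orphan += 1
    logger.info(
        "parsed hits for %d ORFs (%d not attributable to a contig)",
        len(hit_groups), n_orphan,
    )

    depth = (
        sequence_io.read_depth_table(config.depth)
        if config.depth is not None else None
    )

    comps = {
        c.contig_id: composition.compute_composition(
            c, orfs_by_contig[c.contig_id]
        )
        for c in contigs
    }
    summaries = {
        c.contig_id: taxonomy.summarize_contig(
            c.contig_id,
            groups_by_contig[c.contig_id],
            n_orfs=len(orfs_by_contig[c.contig_id]),
        )
        for c in contigs
    }

    # marker-derived k + clustering
    k: Optional[int] = None
    assignment: Optional[binning.BinAssignment] = None
    if config.markers is not None:
        marker_counts = binning.parse_marker_counts(
            config.markers, dialect=config.marker_dialect
        )
        k = binning.estimate_k(marker_counts)
        matrix, kept = binning.build_feature_matrix(
            [comps[c.contig_id] for c in contigs]
        )
        if matrix is not None:
            k_eff = min(k, matrix.shape[0])
            if k_eff < k:
                logger.warning(
                    "clamping k from %d to %d eligible contigs", k, k_eff
                )
            assignment = binning.hierarchical_cluster(
                matrix, kept, k_eff, method=config.linkage
            )
            logger.info(
                "clustered %d contigs into %d bins", len(kept), assignment.k
            )

    profiles: List[ContigProfile] = []
    for contig in contigs:
        comp = comps[contig.contig_id]
        summary = summaries[contig.contig_id]
        profiles.append(
            ContigProfile(
                contig_id=contig.contig_id,
                length=contig.length,
                gc_percent=comp.gc_percent,
                coding_density=comp.coding_density,
                n_orfs=comp.n_orfs,
                n_orfs_with_hits=summary.n_orfs_with_hits,
                top_hit_taxa=[h.lineage for h in summary.top_hits],
                mean_aai=summary.mean_aai,
                coverage=(
                    depth.get(contig.contig_id) if depth is not None else None
                ),
                cluster=(
                    assignment.labels.get(contig.contig_id)
                    if assignment is not None else None
                ),
                summary=summary,
            )
        )

    # HGT screen
    hgt_calls: list = []
    if config.hgt:
        eukaryotic = [
            p.contig_id
            for p in profiles
            if p.summary is not None
            and hgt.is_eukaryotic_contig(p.summary, perc=config.perc)
        ]
        hgt_calls = hgt.flag_hgt_orfs(
            eukaryotic, hit_groups, n=config.hits_n, perc=config.perc
        )
        logger.info(
            "HGT screen: %d eukaryotic contig(s), %d candidate ORF(s)",
            len(eukaryotic), len(hgt_calls),
        )

    # reports
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}
    main_csv = f"{prefix}.csv"
    extraction.write_main_report(profiles, main_csv, rank=config.lvl)
    outputs["main"] = main_csv
    tophits = f"{prefix}.tophits.tsv"
    extraction.write_tophits_file(hit_groups, tophits, n=config.hits_n)
    outputs["tophits"] = tophits
    wordfreq = f"{prefix}.wordfreq.tsv"
    extraction.write_word_frequencies(
        extraction.word_frequency_table(profiles, depth, rank=config.lvl),
        wordfreq,
    )
    outputs["wordfreq"] = wordfreq
    if config.hgt:
        hgt_tsv = f"{prefix}.hgt.tsv"
        extraction.write_hgt_report(hgt_calls, orf_index, hgt_tsv)
        outputs["hgt"] = hgt_tsv

    # subsets
    matched: List[str] = []
    unmatched: List[str] = []
    criteria = config.criteria()
    if criteria is not None:
        matched, unmatched = extraction.select_contigs(profiles, criteria)
        logger.info(
            "criteria matched %d / %d contigs", len(matched), len(profiles)
        )
    if config.fa:
        if criteria is None:
            raise ParameterError(
                "--fa requires at least one extraction criterion"
            )
        by_id = {c.contig_id: c for c in contigs}
        matched_fa = f"{prefix}.matched.fa"
        unmatched_fa = f"{prefix}.unmatched.fa"
        sequence_io.write_fasta([by_id[c] for c in matched], matched_fa)
        sequence_io.write_fasta([by_id[c] for c in unmatched], unmatched_fa)
        outputs["matched"] = matched_fa
        outputs["unmatched"] = unmatched_fa

    manifest = {
        "config": {
            k: (sorted(v) if isinstance(v, set) else v)
            for k, v in asdict(config).items()
        },
        "n_contigs": len(profiles),
        "n_orfs": len(all_orfs),
        "n_orfs_with_hits": len(hit_groups),
        "k": k,
        "n_hgt_calls": len(hgt_calls),
        "n_matched": len(matched),
        "outputs": outputs,
    }
    manifest_path = f"{prefix}.manifest.json"
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    outputs["manifest"] = manifest_path

    return RunResult(
        profiles=profiles, outputs=outputs, matched=matched,
        unmatched=unmatched, hgt_calls=hgt_calls, k=k,
    )
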