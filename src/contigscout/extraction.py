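"""Criteria-based contig extraction and report writing.

A contig matches an :class:`ExtractionCriteria` iff ALL active criteria
hold: the taxon criterion uses the strict more-than-``perc`` top-hit
majority rule (with phage title matching when requested), and every numeric
range is inclusive of its bounds. Matched and unmatched contigs together
always partition the input. Missing values (no coverage table, no hits, an
all-N contig) fail the criteria that need them.

Reports are deterministic: regenerating any output from the same inputs is
byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .errors import ParameterError
from .hgt import HgtCall
from .orf_finder import OrfRecord
from .sequence_io import DepthTable
from .taxonomy import (
    RANKS,
    ContigTaxonSummary,
    HitGroup,
    TaxLineage,
    classify_contig,
    top_hits,
)

MAIN_REPORT_COLUMNS = (
    "contig", "length", "gc", "coding_density", "mean_aai", "coverage",
    "cluster", "n_orfs", "n_orfs_with_hits", "top_hit_taxa",
)
NA = "NA"


@dataclass
class ContigProfile:
    """The per-contig row of the main report, plus the taxon summary needed
    to evaluate taxon criteria."""

    contig_id: str
    length: int
    gc_percent: Optional[float]
    coding_density: float
    n_orfs: int
    n_orfs_with_hits: int
    top_hit_taxa: List[TaxLineage] = field(default_factory=list)
    mean_aai: Optional[float] = None
    coverage: Optional[float] = None
    cluster: Optional[int] = None
    summary: Optional[ContigTaxonSummary] = None
    matched: Optional[bool] = None


@dataclass
class ExtractionCriteria:
    """The full set of subsetting thresholds mirroring the CLI flags.

    At least one criterion must be active; ``taxon`` and ``rank`` come
    together; range bounds are inclusive.
    """

    taxon: Optional[str] = None
    rank: Optional[str] = None
    perc: float = 50.0
    phage: bool = False
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

    def __post_init__(self) -> None:
        if (self.taxon is None) != (self.rank is None):
            raise ParameterError("taxon and rank must be given together")
        if self.rank is not None and self.rank not in RANKS:
            raise ParameterError(f"unknown rank: '{self.rank}'")
        if not 0 < self.perc <= 100:
            raise ParameterError("perc must be in (0, 100]")
        for lo, hi, name in (
            (self.gc_min, self.gc_max, "gc"),
            (self.density_min, self.density_max, "density"),
            (self.aai_min, self.aai_max, "aai"),
            (self.coverage_min, self.coverage_max, "coverage"),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise ParameterError(f"{name}_min exceeds {name}_max")
        if not self.any_active():
            raise ParameterError("at least one extraction criterion must be set")

    def any_active(self) -> bool:
        return any(
            v is not None
            for v in (
                self.taxon, self.gc_min, self.gc_max, self.density_min,
                self.density_max, self.aai_min, self.aai_max, self.length_min,
                self.coverage_min, self.coverage_max, self.clusters,
            )
        )

    def uses_coverage(self) -> bool:
        return self.coverage_min is not None or self.coverage_max is not None


def _in_range(
    value: Optional[float], lo: Optional[float], hi: Optional[float]
) -> bool:
    if lo is None and hi is None:
        return True
    if value is None:
        return False
    if lo is not None and value < lo:
        return False
    if hi is not None and value > hi:
        return False
    return True


def matches(profile: ContigProfile, criteria: ExtractionCriteria) -> bool:
    """Whether one contig satisfies ALL active criteria."""
    if criteria.taxon is not None:
        if profile.summary is None or not classify_contig(
            profile.summary, criteria.taxon, criteria.rank,
            perc=criteria.perc, phage=criteria.phage,
        ):
            return False
    if not _in_range(profile.gc_percent, criteria.gc_min, criteria.gc_max):
        return False
    if not _in_range(
        profile.coding_density, criteria.density_min, criteria.density_max
    ):
        return False
    if not _in_range(profile.mean_aai, criteria.aai_min, criteria.aai_max):
        return False
    if criteria.length_min is not None and profile.length < criteria.length_min:
        return False
    if not _in_range(
        profile.coverage, criteria.coverage_min, criteria.coverage_max
    ):
        return False
    if criteria.clusters is not None and profile.cluster not in criteria.clusters:
        return False
    return True


def select_contigs(
    profiles: Sequence[ContigProfile],
    criteria: ExtractionCriteria,
) -> Tuple[List[str], List[str]]:
    """Partition contig ids into (matched, unmatched), preserving order."""
    if criteria.uses_coverage() and any(p.coverage is None for p in profiles):
        raise ParameterError(
            "coverage criteria require a depth table covering every contig"
        )
    matched: List[str] = []
    unmatched: List[str] = []
    for profile in profiles:
        ok = matches(profile, criteria)
        profile.matched = ok
        (matched if ok else unmatched).append(profile.contig_id)
    return matched, unmatched


def _fmt(value, digits: int = 3) -> str:
    if value is None:
        return NA
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, int):
        return str(value)
    return f"{value:.{digits}f}"


def write_main_report(
    profiles: Sequence[ContigProfile], path, rank: str = "genus"
) -> None:
    """Write the per-contig CSV report (one row per input contig).

    ``top_hit_taxa`` holds the per-ORF top-hit taxon at the requested rank,
    semicolon-joined in ORF order.
    """
    if rank not in RANKS:
        raise ParameterError(f"unknown rank: '{rank}'")
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(MAIN_REPORT_COLUMNS)
        for p in profiles:
            taxa = ";".join(lin.at(rank) for lin in p.top_hit_taxa)
            writer.writerow(
                (
                    p.contig_id,
                    p.length,
                    _fmt(p.gc_percent, 2),
                    _fmt(p.coding_density, 3),
                    _fmt(p.mean_aai, 2),
                    _fmt(p.coverage, 3),
                    NA if p.cluster is None else p.cluster,
                    p.n_orfs,
                    p.n_orfs_with_hits,
                    taxa if taxa else NA,
                )
            )


def write_tophits_file(
    hit_groups: Mapping[str, HitGroup], path, n: int = 100
) -> None:
    """Write the ranked hits (up to ``n`` per ORF) with original columns."""
    with open(path, "w") as handle:
        for group in hit_groups.values():
            for hit in top_hits(group, n).hits:
                handle.write(hit.to_line() + "\n")


def write_hgt_report(
    calls: Sequence[HgtCall],
    orf_index: Mapping[str, OrfRecord],
    path,
) -> None:
    """Write the putative-HGT TSV, one row per flagged ORF; coordinates come
    from the matching gene call when one exists."""
    header = (
        "orf_id", "contig_id", "start", "end", "strand",
        "fraction_prokaryotic", "n_hits", "top_hit_title", "top_hit_lineage",
    )
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for call in calls:
            orf = orf_index.get(call.orf_id)
            handle.write(
                "\t".join(
                    (
                        call.orf_id,
                        call.contig_id,
                        str(orf.start) if orf else NA,
                        str(orf.end) if orf else NA,
                        orf.strand if orf else NA,
                        f"{call.fraction_prokaryotic:.4f}",
                        str(call.n_hits_considered),
                        call.top_hit_title,
                        str(call.top_hit_lineage),
                    )
                )
                + "\n"
            )


def word_frequency_table(
    profiles: Sequence[ContigProfile],
    depth: Optional[DepthTable] = None,
    rank: str = "genus",
) -> Dict[str, float]:
    """Coverage-weighted taxon term frequencies, normalized to sum 1.

    Each ORF top hit contributes its contig's coverage (or 1 without a depth
    table) to its taxon at ``rank``. This is the deterministic data behind
    the word-cloud view; rendering is left to the user.
    """
    if rank not in RANKS:
        raise ParameterError(f"unknown rank: '{rank}'")
    weights: Dict[str, float] = {}
    for p in profiles:
        if depth is not None:
            w = depth.get(p.contig_id, 0.0)
        else:
            w = 1.0
        for lineage in p.top_hit_taxa:
            term = lineage.at(rank)
            weights[term] = weights.get(term, 0.0) + w
    total = sum(weights.values())
    if total > 0:
        weights = {t: w / total for t, w in weights.items()}
    return weights


def write_word_frequencies(table: Mapping[str, float], path) -> None:
    """Write the term-frequency table, heaviest terms first (ties by term)."""
    with open(path, "w") as handle:
        handle.write("term\tweight\n")
        for term, weight in sorted(table.items(), key=lambda kv: (-kv[1], kv[0])):
            handle.write(f"{term}\t{weight:.6f}\n")


def rerun_from_blast(
    fasta_path,
    blast_path,
    out_prefix,
    criteria: Optional[ExtractionCriteria] = None,
    **run_options,
):
    """Re-run the full pipeline from a saved hit table, skipping the search.

    Produces outputs identical to a run that performed the homology search,
    given the identical hit table. Extra keyword arguments are forwarded to
    :class:`contigscout.pipeline.RunConfig`.
    """
    from .pipeline import RunConfig, run

    config = RunConfig(
        fasta=fasta_path, blast=blast_path, out_prefix=out_prefix, **run_options
    )
    if criteria is not None:
        config.apply_criteria(criteria)
    return run(config)
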