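"""Horizontal-gene-transfer candidate screening on eukaryotic contigs.

A contig is deemed eukaryotic when strictly more than ``perc`` percent of
its hit-bearing ORFs have a Eukaryota top hit (optionally AND a coding
density at or below a ceiling, mirroring the ~0.5 genes/kbp eukaryote
filter). On each such contig, every ORF whose top-n homologs are
predominantly prokaryotic — strictly more than ``perc`` percent of the hits
considered from Bacteria or Archaea pooled — is flagged as a putative HGT.
Viral hits count in the denominator but never in the prokaryotic numerator.

This requires a reference database spanning all domains of life; candidates
are a screen, not evidence — genomic-context validation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence

from .errors import ParameterError
from .taxonomy import (
    ContigTaxonSummary,
    HitGroup,
    TaxLineage,
    contig_of_orf,
    top_hits,
)


@dataclass
class HgtCall:
    """One flagged ORF: its prokaryotic-hit fraction always strictly exceeds
    the threshold used to emit it."""

    orf_id: str
    contig_id: str
    fraction_prokaryotic: float
    n_hits_considered: int
    top_hit_title: str
    top_hit_lineage: TaxLineage


def is_eukaryotic_contig(
    summary: ContigTaxonSummary,
    perc: float = 50.0,
    coding_density: Optional[float] = None,
    density_max: Optional[float] = None,
) -> bool:
    """Majority-domain eukaryote test over per-ORF top hits.

    True iff the Eukaryota fraction (over hit-bearing ORFs) strictly exceeds
    ``perc`` percent; contigs without hits are conservatively non-eukaryotic.
    If both ``coding_density`` and ``density_max`` are given, the density
    must additionally be at or below the ceiling.
    """
    if not 0 < perc <= 100:
        raise ParameterError("perc must be in (0, 100]")
    if not summary.top_hits:
        return False
    if summary.fraction("Eukaryota", "domain") * 100.0 <= perc:
        return False
    if density_max is not None and coding_density is not None:
        return coding_density <= density_max
    return True


def flag_hgt_orfs(
    eukaryotic_contigs: Iterable[str],
    hit_groups: Mapping[str, HitGroup],
    n: int = 100,
    perc: float = 50.0,
) -> List[HgtCall]:
    """Flag ORFs on eukaryotic contigs with predominantly prokaryotic
    homologs among their top-``n`` hits."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not 0 < perc <= 100:
        raise ParameterError("perc must be in (0, 100]")
    eukaryotic = set(eukaryotic_contigs)
    calls: List[HgtCall] = []
    for orf_id, group in hit_groups.items():
        if contig_of_orf(orf_id) not in eukaryotic or not group.hits:
            continue
        considered = top_hits(group, n).hits
        n_prok = sum(1 for h in considered if h.lineage.is_prokaryotic())
        fraction = n_prok / len(considered)
        if fraction * 100.0 > perc:
            best = considered[0]
            calls.append(
                HgtCall(
                    orf_id=orf_id,
                    contig_id=contig_of_orf(orf_id),
                    fraction_prokaryotic=fraction,
                    n_hits_considered=len(considered),
                    top_hit_title=best.subject_title,
                    top_hit_lineage=best.lineage,
                )
            )
    return calls
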