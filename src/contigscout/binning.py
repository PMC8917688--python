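"""Composition-based putative binning.

Contigs are clustered by agglomerative hierarchical clustering (Ward linkage
on Euclidean distance by default) of standardized TNF + RSCU features. The
number of flat clusters k is not chosen by the user: it is estimated as the
average hit count over a set of single-copy marker genes (default: the
16-gene universal ribosomal-protein set), rounded half-up with a floor of 1 —
each genome in the assembly should contribute roughly one hit per marker.

This is deliberately coverage-blind putative binning for spot-checking, not
a replacement for a dedicated binner; completeness/contamination scoring is
out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .composition import CompositionProfile
from .errors import FormatError, InputError, ParameterError

logger = logging.getLogger(__name__)

#: the 16 universal single-copy ribosomal proteins used by default
UNIVERSAL_MARKERS: Tuple[str, ...] = (
    "Ribosomal_L2", "Ribosomal_L3", "Ribosomal_L4", "Ribosomal_L5",
    "Ribosomal_L6", "Ribosomal_L14", "Ribosomal_L15", "Ribosomal_L16",
    "Ribosomal_L18", "Ribosomal_L22", "Ribosomal_L24", "Ribosomal_S3",
    "Ribosomal_S8", "Ribosomal_S10", "Ribosomal_S17", "Ribosomal_S19",
)

MarkerCountTable = Dict[str, int]

DEFAULT_MIN_CLUSTER_CONTIG_LENGTH = 2000
LINKAGE_METHODS = ("ward", "complete", "average")


@dataclass
class BinAssignment:
    """Flat cluster labels (1..k) for the clustered contigs."""

    labels: Dict[str, int]
    k: int


def estimate_k(markers: Mapping[str, int]) -> int:
    """k = max(1, round-half-up(mean marker hit count)).

    Markers with zero hits are included in the mean; an all-zero table gives
    k = 1.
    """
    if not markers:
        raise ParameterError("marker table is empty")
    for marker, count in markers.items():
        if count < 0:
            raise ParameterError(f"negative hit count for marker '{marker}'")
    mean = sum(markers.values()) / len(markers)
    return max(1, int(math.floor(mean + 0.5)))


def parse_marker_counts(
    path,
    dialect: str = "tsv",
    marker_set: Sequence[str] = UNIVERSAL_MARKERS,
) -> MarkerCountTable:
    """Read single-copy-marker hit counts.

    ``dialect='tsv'``: two columns, ``marker_id<TAB>count``.
    ``dialect='hmmsearch_tblout'``: hmmsearch per-target table; the hit count
    of a marker is its number of non-comment target lines (query name is the
    third whitespace-separated field).

    Markers in ``marker_set`` that are absent from the file get count 0;
    markers present in the file but not in the set are kept as well.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"marker file not found: {p}")
    counts: MarkerCountTable = {m: 0 for m in marker_set}
    if dialect == "tsv":
        with open(p) as handle:
            for line_number, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise FormatError(
                        f"line {line_number}: expected 2 columns, "
                        f"found {len(fields)}"
                    )
                try:
                    counts[fields[0]] = counts.get(fields[0], 0) + int(fields[1])
                except ValueError:
                    raise FormatError(
                        f"line {line_number}: non-integer count {fields[1]!r}"
                    ) from None
    elif dialect == "hmmsearch_tblout":
        with open(p) as handle:
            for line in handle:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.split()
                if len(fields) < 3:
                    raise FormatError("malformed hmmsearch tblout line")
                query = fields[2]
                counts[query] = counts.get(query, 0) + 1
    else:
        raise ParameterError(f"unknown marker file dialect: '{dialect}'")
    return counts


def build_feature_matrix(
    profiles: Sequence[CompositionProfile],
    min_length: int = DEFAULT_MIN_CLUSTER_CONTIG_LENGTH,
) -> Tuple[Optional[np.ndarray], List[str]]:
    """Standardized TNF+RSCU matrix over clustering-eligible contigs.

    Eligible contigs are at least ``min_length`` bp with at least one
    complete ORF and a non-degenerate TNF. Columns are standardized to mean
    0, sd 1; constant columns are dropped. With fewer than two eligible
    contigs binning is skipped: returns ``(None, [])`` with a warning.
    """
    eligible = [
        prof
        for prof in profiles
        if prof.length >= min_length
        and prof.n_complete_orfs >= 1
        and prof.tnf.sum() > 0
    ]
    if len(eligible) < 2:
        logger.warning(
            "binning skipped: only %d contig(s) eligible (need >= 2)",
            len(eligible),
        )
        return None, []
    X = np.vstack([np.concatenate((p.tnf, p.rscu)) for p in eligible])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 1e-12
    X = (X[:, keep] - mu[keep]) / sd[keep]
    return X, [p.contig_id for p in eligible]


def hierarchical_cluster(
    matrix: np.ndarray,
    contig_ids: Sequence[str],
    k: int,
    method: str = "ward",
) -> BinAssignment:
    """Cut an agglomerative tree over ``matrix`` into exactly k flat
    clusters; deterministic for a fixed input."""
    if method not in LINKAGE_METHODS:
        raise ParameterError(
            f"linkage method must be one of {LINKAGE_METHODS}, got '{method}'"
        )
    n = matrix.shape[0]
    if len(contig_ids) != n:
        raise ParameterError("contig_ids length must match matrix rows")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of contigs ({n})")
    if k == 1 or n == 1:
        return BinAssignment({c: 1 for c in contig_ids}, 1)
    Z = linkage(matrix, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return BinAssignment(
        {c: int(label) for c, label in zip(contig_ids, labels)},
        int(labels.max()),
    )
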