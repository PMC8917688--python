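"""Optional subprocess/BAM adapters around external tools.

These are conveniences for real-world use and are excluded from the core
test suite: every core computation consumes the parsed tabular dialects
directly. Each adapter raises :class:`InputError` when its tool or input is
unavailable rather than degrading silently.
"""

from __future__ import annotations

import shutil
import subprocess
from pathlib import Path
from typing import Optional, Sequence

from .errors import InputError
from .sequence_io import DepthTable

#: outfmt matching the eight-column hit-table dialect (staxlineage is only
#: available when the DIAMOND database was built with taxonomy files)
DIAMOND_OUTFMT: Sequence[str] = (
    "6", "qseqid", "sseqid", "pident", "length", "evalue", "bitscore",
    "stitle", "sphylums",
)


def diamond_search(
    query_faa,
    database,
    out_blast,
    n_hits: int = 100,
    threads: int = 1,
    extra_args: Optional[Sequence[str]] = None,
) -> None:
    """Run ``diamond blastp`` producing the hit-table dialect."""
    exe = shutil.which("diamond")
    if exe is None:
        raise InputError("diamond executable not found on PATH")
    cmd = [
        exe, "blastp", "--query", str(query_faa), "--db", str(database),
        "--out", str(out_blast), "--max-target-seqs", str(n_hits),
        "--threads", str(threads), "--outfmt", *DIAMOND_OUTFMT,
    ]
    if extra_args:
        cmd.extend(extra_args)
    subprocess.run(cmd, check=True)


def hmmsearch_markers(
    query_faa,
    hmm_file,
    out_tblout,
    threads: int = 1,
) -> None:
    """Run ``hmmsearch --tblout`` for single-copy-marker counting."""
    exe = shutil.which("hmmsearch")
    if exe is None:
        raise InputError("hmmsearch executable not found on PATH")
    subprocess.run(
        [
            exe, "--tblout", str(out_tblout), "--cpu", str(threads),
            str(hmm_file), str(query_faa),
        ],
        check=True,
        stdout=subprocess.DEVNULL,
    )


def depth_from_bam(bam_path) -> DepthTable:
    """Mean per-contig read depth from a position-sorted, indexed BAM.

    Equivalent in spirit to the MetaBAT depth summary's totalAvgDepth:
    summed aligned coverage divided by reference length.
    """
    try:
        import pysam
    except ImportError:  # pragma: no cover - optional extra
        raise InputError(
            "BAM support requires pysam (install the 'bam' extra)"
        ) from None
    if not Path(bam_path).exists():
        raise InputError(f"BAM file not found: {bam_path}")
    depths: DepthTable = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for contig, length in zip(bam.references, bam.lengths):
            covered = sum(
                int(arr.sum()) for arr in bam.count_coverage(contig)
            )
            depths[contig] = covered / length if length else 0.0
    return depths
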