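"""Readers and writers for the standard input/output formats.

Inputs: aligned known sites (FASTA or one-sequence-per-line text), ChIP
peaks (FASTA, or BED intervals plus a genome FASTA), and a background FASTA.
Outputs are plain TSV with '#'-prefixed metadata header lines, plus newick
for dendrograms.  Coordinates are 0-based half-open internally and in BED
interop.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

from Bio import SeqIO

from .motif import AlignedSites

__all__ = [
    "read_aligned_sites",
    "read_peaks",
    "iter_background_records",
    "write_tsv",
]


def _looks_like_fasta(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.lstrip().startswith(">")
    return False


def read_aligned_sites(path) -> AlignedSites:
    """Load aligned binding sites from FASTA or one-per-line text.

    All records must share one length and contain only A/C/G/T (validation
    errors name the offending record).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _looks_like_fasta(path):
        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    else:
        with open(path) as fh:
            seqs = [line.strip() for line in fh if line.strip()]
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    return AlignedSites(seqs)


def read_peaks(path, genome_path=None) -> list[tuple[str, str]]:
    """Load raw ChIP peaks as (id, sequence) pairs.

    ``path`` is either a FASTA of peak sequences or a BED file of intervals,
    in which case ``genome_path`` must name the genome FASTA.  BED intervals
    are 0-based half-open; out-of-bounds intervals raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _looks_like_fasta(path):
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if genome_path is None:
        raise ValueError(
            f"{path} looks like BED intervals; a genome FASTA is required "
            "to extract peak sequences"
        )
    from pyfaidx import Fasta

    genome = Fasta(str(genome_path))
    peaks: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if chrom not in genome:
                raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if start < 0 or end > len(genome[chrom]) or start >= end:
                raise ValueError(
                    f"{path}:{ln}: interval {chrom}:{start}-{end} out of "
                    f"bounds for a {len(genome[chrom])} bp sequence"
                )
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            peaks.append((name, str(genome[chrom][start:end])))
    return peaks


def iter_background_records(path) -> Iterator[str]:
    """Yield background FASTA records one at a time.

    Records are consumed independently downstream so that counting windows
    never spans a record boundary.
    """
    for rec in SeqIO.parse(str(path), "fasta"):
        yield str(rec.seq)


def write_tsv(path, header_meta: dict, columns: list[str], rows) -> None:
    """Write rows as TSV with '#' key<TAB>value metadata lines on top."""
    with open(path, "w") as fh:
        for key, val in header_meta.items():
            fh.write(f"# {key}\t{val}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
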