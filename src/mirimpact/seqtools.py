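"""Small sequence helpers shared across modules.

Genomic sequences are handled as uppercase DNA strings; transcript
sequences (anything that gets folded) are RNA (T -> U). A "genome" is
either a :class:`pyfaidx.Fasta` object or a plain ``dict`` mapping
chromosome name to sequence string — the latter keeps unit tests free of
temporary files.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet on output)."""
    return seq.translate(_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def chrom_length(genome, chrom: str) -> int:
    if isinstance(genome, dict):
        return len(genome[chrom])
    return len(genome[chrom])


def has_chrom(genome, chrom: str) -> bool:
    try:
        genome[chrom]
        return True
    except KeyError:
        return False


def fetch(genome, chrom: str, begin: int, end: int) -> str:
    """Fetch [begin, end) of a chromosome as uppercase DNA.

    Works for pyfaidx.Fasta and for dict fixtures. Coordinates are
    zero-based half-open and must lie within the chromosome.
    """
    if begin < 0 or end < begin:
        raise ValueError(f"invalid interval [{begin},{end})")
    seq = genome[chrom][begin:end]
    if not isinstance(seq, str):  # pyfaidx Sequence
        seq = seq.seq
    seq = seq.upper()
    if len(seq) != end - begin:
        raise ValueError(
            f"interval [{begin},{end}) extends beyond {chrom} "
            f"(got {len(seq)} bases)"
        )
    return seq
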