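"""Shared codon-level machinery built on the standard genetic code.

Used by the NG86 estimator, the paralog-pair forward simulator and the
ORF-based coding-potential rule.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD.forward_table))
AMINO_ACID = dict(_STANDARD.forward_table)  # codon -> one-letter aa, sense only


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def _synonymous_fraction(codon: str) -> tuple[float, float, float]:
    """Fraction of the 3 possible changes at each position that preserve the
    amino acid. Changes producing stop codons count as nonsynonymous."""
    aa = AMINO_ACID[codon]
    out = []
    for pos in range(3):
        syn = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and AMINO_ACID[mutant] == aa:
                syn += 1
        out.append(syn / 3.0)
    return tuple(out)


# codon -> (syn fraction at pos 0, 1, 2); total syn sites = sum of the tuple
SYN_SITE_FRACTION = {c: _synonymous_fraction(c) for c in SENSE_CODONS}
SYN_SITES = {c: sum(f) for c, f in SYN_SITE_FRACTION.items()}

# every synonymous single-nucleotide change available from each sense codon
SYN_CHANGES: dict[str, tuple[tuple[int, str], ...]] = {}
for _codon in SENSE_CODONS:
    _opts = []
    for _pos in range(3):
        for _alt in NUCLEOTIDES:
            if _alt == _codon[_pos]:
                continue
            _mut = _codon[:_pos] + _alt + _codon[_pos + 1 :]
            if _mut not in STOP_CODONS and AMINO_ACID[_mut] == AMINO_ACID[_codon]:
                _opts.append((_pos, _alt))
    SYN_CHANGES[_codon] = tuple(_opts)


def codons_of(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def validate_cds(seq: str) -> None:
    """Reject sequences with internal stop codons or non-ACGT characters."""
    seq = seq.upper()
    for i, codon in enumerate(codons_of(seq)):
        if any(b not in NUCLEOTIDES for b in codon):
            raise ValueError(f"non-ACGT codon {codon!r} at codon {i}")
        if codon in STOP_CODONS and i < len(seq) // 3 - 1:
            raise ValueError(f"internal stop codon {codon} at codon {i}")


def longest_orf_codons(seq: str) -> int:
    """Length in codons (incl. the start) of the longest stop-free reading
    frame starting at ATG, over all three frames of both strands."""
    best = 0
    for strand_seq in (seq.upper(), revcomp(seq.upper())):
        n = len(strand_seq)
        for frame in range(3):
            open_starts: list[int] = []
            for i in range(frame, n - 2, 3):
                codon = strand_seq[i : i + 3]
                if codon in STOP_CODONS:
                    open_starts.clear()
                    continue
                if codon == "ATG" and not open_starts:
                    open_starts.append(i)
                if open_starts:
                    best = max(best, (i - open_starts[0]) // 3 + 1)
    return best
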