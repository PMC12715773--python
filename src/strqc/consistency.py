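"""Read-consistency classification against a called STR genotype.

A spanning read pins a repeat size exactly, so it is consistent only if its
size equals one of the called alleles.  Flanking and in-repeat reads only
lower-bound the size, so they are consistent if their size matches or is
below one of the alleles and non-consistent if they exceed both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import FLANKING, IN_REPEAT, SPANNING, ReadSupport

CONSISTENT = "consistent"
NON_CONSISTENT = "non_consistent"


@dataclass
class ConsistencyCounts:
    """Per-allele tally of consistent and non-consistent read counts."""

    allele_index: int
    consistent: int = 0
    non_consistent: int = 0

    @property
    def total(self) -> int:
        return self.consistent + self.non_consistent


def classify_read(read_size: int, read_type: str, genotype: Sequence[int]) -> str:
    """Classify one read against the genotype's allele sizes."""
    if not genotype:
        raise ValueError("genotype must contain at least one allele size")
    if read_size < 0:
        raise ValueError("read_size must be non-negative")
    if read_type == SPANNING:
        ok = any(read_size == a for a in genotype)
    elif read_type in (FLANKING, IN_REPEAT):
        ok = read_size <= max(genotype)
    else:
        raise ValueError(f"unknown read type {read_type!r}")
    return CONSISTENT if ok else NON_CONSISTENT


def _consistent_with_allele(read_size: int, read_type: str, allele_size: int) -> bool:
    if read_type == SPANNING:
        return read_size == allele_size
    return read_size <= allele_size


def attribute_counts(genotype: Sequence[int], reads: Sequence[ReadSupport]) -> list[ConsistencyCounts]:
    """Attribute read counts to each allele of the genotype.

    A globally consistent read contributes its count to every allele it is
    individually consistent with; a globally non-consistent read counts
    against both alleles.
    """
    counts = [ConsistencyCounts(i) for i in range(len(genotype))]
    for r in reads:
        overall = classify_read(r.repeat_size, r.read_type, genotype)
        if overall == CONSISTENT:
            for i, a in enumerate(genotype):
                if _consistent_with_allele(r.repeat_size, r.read_type, a):
                    counts[i].consistent += r.count
        else:
            for c in counts:
                c.non_consistent += r.count
    return counts
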