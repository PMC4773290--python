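"""Allele-specific double-stranded EMSA probe design.

A probe pair places each allele of a SNV at the centre of the surrounding
genomic context: ``flank_bp`` reference bases on each side (default 15, so
31-mers), plus the reverse complement of each forward strand for annealing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
VALID_BASES = set("ACGT")


class ProbeDesignError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProbeDesign:
    variant_id: str
    flank_bp: int
    forward_ref: str
    forward_alt: str
    reverse_ref: str
    reverse_alt: str

    def to_fasta(self) -> str:
        return "".join(
            f">{self.variant_id}_{name}\n{seq}\n"
            for name, seq in [
                ("forward_ref", self.forward_ref),
                ("forward_alt", self.forward_alt),
                ("reverse_ref", self.reverse_ref),
                ("reverse_alt", self.reverse_alt),
            ]
        )


def design_emsa_probes(
    reference,
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    variant_id: str = "",
    flank_bp: int = 15,
) -> ProbeDesign:
    """Build the four probe strands for one SNV.

    ``reference`` is a pyfaidx.Fasta (or any mapping of chrom -> indexable
    sequence, 0-based slicing).  If the reference base at ``pos`` matches
    neither stated allele a warning is logged and the declared alleles are
    substituted into the genomic context.
    """
    for allele, name in ((ref_allele, "ref"), (alt_allele, "alt")):
        if len(allele) != 1:
            raise ProbeDesignError(f"{variant_id}: {name} allele {allele!r} is not a SNV")
        if allele.upper() not in VALID_BASES:
            raise ProbeDesignError(f"{variant_id}: {name} allele {allele!r} not in ACGT")
    seq = reference[chrom]
    p0 = pos - 1
    if p0 - flank_bp < 0 or p0 + flank_bp + 1 > len(seq):
        raise ProbeDesignError(
            f"{variant_id}: needs {flank_bp} bp flank each side at {chrom}:{pos}"
        )
    left = str(seq[p0 - flank_bp:p0]).upper()
    centre = str(seq[p0:p0 + 1]).upper()
    right = str(seq[p0 + 1:p0 + flank_bp + 1]).upper()
    if not VALID_BASES >= set(left + right):
        raise ProbeDesignError(f"{variant_id}: ambiguous base (N) inside probe context")
    if centre not in (ref_allele.upper(), alt_allele.upper()):
        log.warning(
            "%s: reference base %s at %s:%d matches neither allele %s/%s; using declared alleles",
            variant_id, centre, chrom, pos, ref_allele, alt_allele,
        )
    fwd_ref = left + ref_allele.upper() + right
    fwd_alt = left + alt_allele.upper() + right
    return ProbeDesign(
        variant_id=variant_id,
        flank_bp=flank_bp,
        forward_ref=fwd_ref,
        forward_alt=fwd_alt,
        reverse_ref=reverse_complement(fwd_ref),
        reverse_alt=reverse_complement(fwd_alt),
    )
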