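"""Normalized variant records.

A variant is stored as a single (chrom, pos, ref, alt) allele observation in
VCF coordinates (1-based, inclusive). Alleles are always kept in *minimal*
representation: shared trailing bases are trimmed first, then shared leading
bases, retaining one anchor base whenever either allele would otherwise
become empty (the usual VCF indel anchor). Two records describe the same
variant iff their :class:`VariantKey` compare equal — identity is
allele-aware, not position-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

from .errors import InvalidVariantError

_VALID_BASES = frozenset("ACGTN")


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "INSERTION"
    DELETION = "DELETION"
    MNV = "MNV"


class VariantKey(NamedTuple):
    """Identity of a normalized variant for overlap/membership comparisons."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vclass: VariantClass
    indel_len: int
    sample: str
    filter_pass: bool = True
    info: dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce an allele pair to minimal representation.

    Trims shared trailing bases, then shared leading bases while keeping a
    single anchor base when either allele would become empty; ``pos`` is
    advanced by the number of leading bases removed. Idempotent.

    >>> normalize_variant(100, "CAG", "CG")
    (100, 'CA', 'C')
    """
    if not ref or not alt:
        raise InvalidVariantError("ref and alt must be non-empty")
    if ref == alt:
        raise InvalidVariantError(f"ref == alt ({ref!r}): not a variant")
    # trim shared suffix, keeping at least one base in each allele
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix; stop at one anchor base if either allele would empty
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def classify_variant(ref: str, alt: str) -> tuple[VariantClass, int]:
    """Classify a *normalized* allele pair.

    Returns (class, indel length); indel length is 0 for SNV/MNV and
    ``abs(len(ref) - len(alt))`` otherwise.
    """
    for allele in (ref, alt):
        bad = set(allele) - _VALID_BASES
        if bad:
            raise InvalidVariantError(
                f"invalid allele characters {sorted(bad)} in {allele!r}"
            )
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV, 0
    if len(ref) == len(alt):
        return VariantClass.MNV, 0
    if len(alt) > len(ref):
        return VariantClass.INSERTION, len(alt) - len(ref)
    return VariantClass.DELETION, len(ref) - len(alt)


def make_record(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    sample: str,
    filter_pass: bool = True,
    info: dict[str, str] | None = None,
) -> VariantRecord:
    """Normalize, classify and wrap an allele observation in one step."""
    pos, ref, alt = normalize_variant(pos, ref.upper(), alt.upper())
    vclass, indel_len = classify_variant(ref, alt)
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vclass=vclass,
        indel_len=indel_len,
        sample=sample,
        filter_pass=filter_pass,
        info=dict(info or {}),
    )
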