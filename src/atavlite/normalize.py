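"""Canonical variant representation.

Every sample's VCF may spell the same indel differently (extra shared
bases, right-shifted position inside a repeat).  The store keys all calls by
a single canonical form so that the universal variant list contains each
variant exactly once: alleles are trimmed (shared suffix first, then shared
prefix) and left-aligned against the reference, keeping the VCF anchor-base
convention for indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import IntegrityError, ValidationError, WindowExhaustedError

_ACGT = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class NormalizedVariant:
    """A canonical biallelic variant, 1-based VCF coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str = field(init=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "variant_id", f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}")

    @classmethod
    def from_id(cls, variant_id: str) -> "NormalizedVariant":
        chrom, pos, ref, alt = variant_id.rsplit("-", 3)
        return cls(chrom, int(pos), ref, alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        """Last reference position touched (1-based inclusive)."""
        return self.pos + len(self.ref) - 1


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    window: str,
    window_start: int = 1,
) -> NormalizedVariant:
    """Trim and left-align one ALT allele against a reference window.

    ``window`` is the reference sequence whose first base sits at 1-based
    position ``window_start``.  The algorithm is the standard one: while the
    alleles end in the same base, drop it, fetching the preceding reference
    base whenever an allele would become empty (this is what shifts an indel
    left through a repeat); then drop shared leading bases while both
    alleles are longer than one.  The result is idempotent and identical for
    every equivalent representation of the same haplotype edit.

    Raises IntegrityError when REF does not match the window, and
    WindowExhaustedError when left-alignment needs sequence left of the
    window.
    """
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt:
        raise ValidationError("REF and ALT must be non-empty (VCF convention)")
    if not (_ACGT.issuperset(ref) and _ACGT.issuperset(alt)):
        raise ValidationError(f"alleles must be ACGT strings, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError(f"REF and ALT are identical at {chrom}:{pos}")
    if pos < window_start or pos + len(ref) - 1 > window_start + len(window) - 1:
        raise IntegrityError(
            f"{chrom}:{pos} {ref}>{alt} does not fit the reference window "
            f"[{window_start}, {window_start + len(window) - 1}]"
        )
    observed = window[pos - window_start : pos - window_start + len(ref)].upper()
    if observed != ref:
        raise IntegrityError(
            f"REF mismatch at {chrom}:{pos}: VCF says {ref!r}, reference has {observed!r}"
        )

    # trim shared suffix, extending left when an allele empties
    while ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos - 1 < window_start:
                raise WindowExhaustedError(
                    f"window exhausted left-aligning {chrom}:{pos} (need base at {pos - 1})"
                )
            prev = window[pos - 1 - window_start].upper()
            pos -= 1
            ref, alt = prev + ref, prev + alt
    # trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return NormalizedVariant(chrom, pos, ref, alt)
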