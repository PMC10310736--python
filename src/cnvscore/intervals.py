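"""Genomic interval arithmetic and CNV call types.

Internally every interval is 0-based, half-open (``[start, end)``), the
BED convention.  All on-disk and command-line coordinates are 1-based
inclusive, the convention of clinical CNV reports and of the annotation
exports these tools consume; conversion happens exactly once, at the I/O
boundary (:meth:`GenomicInterval.from_1based` / :meth:`GenomicInterval.to_1based`).

CNVs are unstranded: no strand is stored or consulted anywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional


class CNVType(str, Enum):
    """Direction of the copy-number change."""

    LOSS = "loss"
    GAIN = "gain"


_TYPE_ALIASES = {
    "loss": CNVType.LOSS,
    "del": CNVType.LOSS,
    "deletion": CNVType.LOSS,
    "gain": CNVType.GAIN,
    "dup": CNVType.GAIN,
    "duplication": CNVType.GAIN,
}


def parse_cnv_type(token: str) -> CNVType:
    """Accept the tokens in common use: loss/DEL/deletion, gain/DUP/duplication."""
    try:
        return _TYPE_ALIASES[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unrecognised CNV type token: {token!r}") from None


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to its ``chr``-prefixed form.

    ``"X"`` and ``"chrX"`` are treated identically; annotation exports mix
    both dialects.
    """
    name = str(name).strip()
    if not name:
        raise ValueError("chromosome name must be non-empty")
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)`` (0-based)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval {self.chrom}:[{self.start},{self.end}): end must exceed start"
            )
        if self.start < 0:
            raise ValueError("interval start must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_1based(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (the on-disk convention)."""
        return cls(normalize_chrom(chrom), int(start) - 1, int(end))

    def to_1based(self) -> tuple[str, int, int]:
        """Return ``(chrom, start, end)`` in 1-based inclusive coordinates."""
        return self.chrom, self.start + 1, self.end

    def __str__(self) -> str:
        chrom, s, e = self.to_1based()
        return f"{chrom}:{s}-{e}"


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse ``"chr1:150000-2150000"`` (1-based inclusive, commas allowed)."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region {text!r} (expected chrom:start-end)")
    chrom, s, e = m.groups()
    return GenomicInterval.from_1based(chrom, int(s.replace(",", "")), int(e.replace(",", "")))


@dataclass(frozen=True)
class CNVCall:
    """A located copy-number variant.

    ``copy_number``, when given, must be consistent with the direction:
    below 2 for a loss, above 2 for a gain (2 being the diploid baseline).
    """

    interval: GenomicInterval
    cnv_type: CNVType
    copy_number: Optional[int] = None
    id: Optional[str] = None

    def __post_init__(self) -> None:
        cn = self.copy_number
        if cn is not None:
            if self.cnv_type is CNVType.LOSS and cn >= 2:
                raise ValueError(f"copy number {cn} inconsistent with a loss")
            if self.cnv_type is CNVType.GAIN and cn <= 2:
                raise ValueError(f"copy number {cn} inconsistent with a gain")


def intersect_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across chromosomes or
    when the ranges are disjoint or merely abutting)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def is_contained(inner: GenomicInterval, outer: GenomicInterval) -> bool:
    """True iff ``inner`` lies completely within ``outer`` (identity counts)."""
    return (
        inner.chrom == outer.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def coverage_fraction(target: GenomicInterval, query: GenomicInterval) -> float:
    """Fraction of ``target`` covered by ``query``; 1.0 iff contained."""
    return intersect_length(target, query) / target.length
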