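"""Core domain types for PCR deletion screening of gene knockouts.

The screening workflow amplifies a target region with a nested primer set
(an *amplicon*), detects deletion alleles as short PCR products, and maps
each allele onto a gene model to decide whether it actually disrupts coding
sequence.  This module holds the three record types shared by the rest of
the toolkit — :class:`Amplicon`, :class:`GeneModel` and
:class:`DeletionAllele` — together with the small rules applied to every
reported allele:

* ``classify_silent`` — a deletion that does not extend across at least one
  exon boundary is a *silent* allele and is not counted as a knockout;
* ``check_size_bound`` — deletions recovered by this strategy are bounded
  by the internal primer span and, in practice, are all under 3 kb;
* ``check_band_shift`` — the called deletion must predict a product length
  consistent with the band shift observed on the agarose gel.

Coordinates are 0-based, half-open throughout the library.  Report writers
emit 1-based inclusive positions (the convention used by genome-browser
displays) and say so in their headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Tuple

from .errors import ConfigError, OutOfRangeError

__all__ = [
    "MAX_DELETION_BP",
    "Amplicon",
    "GeneModel",
    "DeletionAllele",
    "classify_silent",
    "check_size_bound",
    "check_band_shift",
    "predicted_product_bp",
]

#: Empirical upper bound on recoverable deletion size.  It derives from the
#: placement of the flanking PCR primers, not from the calling algorithm, so
#: it is applied as a validation check rather than a hard rejection.
MAX_DELETION_BP = 3000

_ALPHABET = frozenset("ACGT")

BreakClass = Literal["clean", "ambiguous", "insertion"]
SilentCall = Literal["silent", "exonic"]


def _check_seq(seq: str, what: str) -> None:
    if not seq:
        raise ConfigError(f"{what}: empty sequence")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ConfigError(f"{what}: non-ACGT characters {sorted(bad)!r}")


@dataclass(frozen=True)
class Amplicon:
    """A wild-type target region with its nested primer anchor positions.

    ``ext_left``/``ext_right`` anchor the external primer pair and
    ``int_left``/``int_right`` the internal (nested) pair.  The scored PCR
    product is the internal span ``[int_left, int_right)``; its length is
    the wild-type band size on the gel.
    """

    id: str
    seq: str
    ext_left: int
    int_left: int
    int_right: int
    ext_right: int

    def __post_init__(self) -> None:
        _check_seq(self.seq, f"amplicon {self.id}")
        ok = (
            0 <= self.ext_left <= self.int_left < self.int_right
            <= self.ext_right <= len(self.seq)
        )
        if not ok:
            raise ConfigError(
                f"amplicon {self.id}: primer anchors must satisfy "
                "0 <= ext_left <= int_left < int_right <= ext_right <= len(seq); "
                f"got ({self.ext_left}, {self.int_left}, {self.int_right}, "
                f"{self.ext_right}) on length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def internal_span(self) -> int:
        """Length of the nested (scored) product on a wild-type template."""
        return self.int_right - self.int_left


@dataclass(frozen=True)
class GeneModel:
    """Minimal exon model of a gene: ordered, disjoint exon intervals.

    Only exon boundaries matter to the silent-allele rule, so no
    transcript/CDS hierarchy is represented.
    """

    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ConfigError(f"gene {self.gene_id}: no exons")
        if self.strand not in ("+", "-"):
            raise ConfigError(f"gene {self.gene_id}: strand must be '+' or '-'")
        prev_end = None
        for start, end in exons:
            if end <= start:
                raise ConfigError(
                    f"gene {self.gene_id}: exon [{start}, {end}) is empty"
                )
            if prev_end is not None and start < prev_end:
                raise ConfigError(
                    f"gene {self.gene_id}: exons must be sorted and non-overlapping"
                )
            prev_end = end

    @property
    def span(self) -> Tuple[int, int]:
        """Chromosomal interval from the first exon start to the last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    def boundaries(self) -> Sequence[int]:
        """All exon starts and ends, in ascending order."""
        out = []
        for start, end in self.exons:
            out.append(start)
            out.append(end)
        return out


@dataclass(frozen=True)
class DeletionAllele:
    """A normalized deletion allele on an amplicon.

    ``[left, right)`` is the deleted interval in amplicon coordinates and
    ``insert`` any novel sequence replacing it.  Breaks come in three basic
    types: *clean* breaks (a unique zero-insert placement), *ambiguous*
    breaks (flanking microhomology allows several equivalent placements;
    ``ambiguity_width`` counts them), and *insertion* breaks (one or more
    bases of inserted material).  The class field is fully determined by
    ``insert`` and ``ambiguity_width`` and is validated on construction.
    """

    allele_id: str
    amplicon_id: str
    left: int
    right: int
    insert: str
    break_class: BreakClass
    ambiguity_width: int = 1

    def __post_init__(self) -> None:
        if self.insert:
            _check_seq(self.insert, f"allele {self.allele_id} insert")
        if not (0 <= self.left < self.right):
            raise ConfigError(
                f"allele {self.allele_id}: need 0 <= left < right, "
                f"got [{self.left}, {self.right})"
            )
        if self.ambiguity_width < 1:
            raise ConfigError(f"allele {self.allele_id}: ambiguity_width < 1")
        expected: BreakClass
        if self.insert:
            expected = "insertion"
        elif self.ambiguity_width >= 2:
            expected = "ambiguous"
        else:
            expected = "clean"
        if self.break_class != expected:
            raise ConfigError(
                f"allele {self.allele_id}: break_class {self.break_class!r} "
                f"inconsistent with insert length {len(self.insert)} and "
                f"ambiguity_width {self.ambiguity_width} (expected {expected!r})"
            )

    @property
    def deletion_size(self) -> int:
        return self.right - self.left

    def validate_against(self, amp: Amplicon) -> None:
        """Check that the deleted interval fits on its amplicon."""
        if self.amplicon_id != amp.id:
            raise ConfigError(
                f"allele {self.allele_id} refers to amplicon "
                f"{self.amplicon_id!r}, not {amp.id!r}"
            )
        if self.right > len(amp):
            raise OutOfRangeError(
                f"allele {self.allele_id}: right={self.right} exceeds "
                f"amplicon length {len(amp)}"
            )


def classify_silent(
    allele: DeletionAllele, gene: GeneModel, amplicon_offset: int
) -> SilentCall:
    """Apply the silent-allele rule to a deletion mapped onto a gene model.

    A deletion is ``"exonic"`` iff the open deleted interval, lifted to
    chromosome coordinates via ``amplicon_offset``, strictly contains at
    least one exon boundary (an exon start or end).  A deletion abutting a
    boundary without crossing it — e.g. one confined to a single intron —
    is ``"silent"`` and is not counted as a gene knockout.

    The predicate uses boundary positions only, so it is invariant under a
    strand flip of the gene model.

    Raises
    ------
    OutOfRangeError
        If the lifted deletion interval lies entirely outside the gene's
        chromosomal span.
    """
    lo = amplicon_offset + allele.left
    hi = amplicon_offset + allele.right
    span_lo, span_hi = gene.span
    if hi <= span_lo or lo >= span_hi:
        raise OutOfRangeError(
            f"allele {allele.allele_id}: deletion [{lo}, {hi}) outside "
            f"gene {gene.gene_id} span [{span_lo}, {span_hi})"
        )
    for b in gene.boundaries():
        if lo < b < hi:
            return "exonic"
    return "silent"


def check_size_bound(allele: DeletionAllele, amp: Amplicon) -> bool:
    """True iff the deletion is smaller than the internal primer span and 3 kb.

    Both bounds follow from primer placement: a product longer than the
    internal span would not have been scored as a deletion band, and in
    practice all recovered deletions are under :data:`MAX_DELETION_BP`.
    """
    allele.validate_against(amp)
    size = allele.deletion_size
    return size < amp.internal_span and size < MAX_DELETION_BP


def predicted_product_bp(allele: DeletionAllele, amp: Amplicon) -> int:
    """Predicted nested-PCR product length for a deletion template.

    The deletion removes ``deletion_size`` bases from the internal span and
    any inserted material adds back ``len(insert)`` bases.
    """
    allele.validate_against(amp)
    return amp.internal_span - allele.deletion_size + len(allele.insert)


def check_band_shift(
    allele: DeletionAllele,
    amp: Amplicon,
    observed_product_bp: int,
    tolerance_frac: float,
) -> bool:
    """True iff the called deletion is consistent with the observed band size.

    Gel sizing is coarse, so the observed product length is accepted when
    ``|predicted - observed| <= tolerance_frac * predicted``.  A tolerance
    of zero demands an exact match; negative tolerances are rejected.
    """
    if observed_product_bp <= 0:
        raise ConfigError("observed product size must be positive")
    if tolerance_frac < 0:
        raise ConfigError("tolerance_frac must be >= 0")
    predicted = predicted_product_bp(allele, amp)
    return abs(predicted - observed_product_bp) <= tolerance_frac * predicted
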