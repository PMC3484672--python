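"""Deletion-breakpoint calling and normalization.

A deletion PCR product is, by construction, the wild-type amplicon with an
internal segment removed and (sometimes) novel bases inserted in its place:

    product = amplicon[0:L] + insert + amplicon[R:]

Sequence identity between the flanks of the breakpoint frequently makes the
placement of ``(L, R)`` non-unique: if the first h deleted bases equal the
first h bases after the deletion (microhomology), the break can be slid
across h+1 equivalent positions.  Because downstream displays require a
single discrete pair of flanking sequences per deletion, every call is
normalized to a canonical placement:

* **ambiguous breaks** (several zero-insert placements): report the left
  breakpoint at the *rightmost* possible position, which shifts the
  microhomology bases onto the left flank;
* **insertion breaks** (no zero-insert placement exists): minimize the
  insert length, which simultaneously maximizes the matched left and right
  portions within the amplicon.  At the minimal insert length the placement
  is unique (both flanks are maximal), so no further tie-break is needed.

``enumerate_decompositions`` is the brute-force enumeration of *every*
valid ``(L, R, insert)`` triple; it exists to serve as the reference for
the direct canonical construction in ``call_breakpoint`` and to expose the
full placement set of ambiguous breaks.  Its output can be quadratic in
the flank-match lengths, so it is intended for amplicon-scale sequences
and test oracles, not genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

from .errors import (
    AssemblyError,
    ConfigError,
    LowQualityError,
    NoDeletionFoundError,
)
from .seqmodel import Amplicon, DeletionAllele

__all__ = [
    "DEFAULT_MIN_ANCHOR",
    "Decomposition",
    "BreakpointReport",
    "enumerate_decompositions",
    "call_breakpoint",
    "call_from_reads",
    "normalize_report",
    "revcomp",
]

#: Minimum exact matching bases required on each flank before a
#: decomposition is considered.  Ten bases make spurious flank matches on
#: random sequence negligible at amplicon scale.
DEFAULT_MIN_ANCHOR = 10

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGT sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def _lcp(a: str, b: str) -> int:
    """Length of the longest common prefix of two strings."""
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    """Length of the longest common suffix of two strings."""
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


@dataclass(frozen=True)
class Decomposition:
    """One way of writing a product as amplicon[:L] + insert + amplicon[R:]."""

    left: int
    right: int
    insert: str
    matched_left: int
    matched_right: int

    def reconstruct(self, amplicon_seq: str) -> str:
        return amplicon_seq[: self.left] + self.insert + amplicon_seq[self.right :]


@dataclass(frozen=True)
class BreakpointReport:
    """A normalized deletion call with its flanks and equivalent placements.

    ``flank_left``/``flank_right`` are the retained amplicon sequence on
    either side of the break, so ``flank_left + insert + flank_right``
    reconstructs the product exactly.  ``all_placements`` lists every
    ``(L, R)`` pair valid for the same product at the reported insert
    length; for ambiguous breaks its size equals the ambiguity width.
    ``merge_conflicts`` counts read-disagreement positions resolved during
    assembly (zero when calling directly from a product sequence).
    """

    allele: DeletionAllele
    amplicon: Amplicon
    flank_left: str
    flank_right: str
    all_placements: Tuple[Tuple[int, int], ...]
    merge_conflicts: int = 0

    def __post_init__(self) -> None:
        seq = self.amplicon.seq
        if self.flank_left != seq[: self.allele.left]:
            raise ConfigError("flank_left does not match the amplicon prefix")
        if self.flank_right != seq[self.allele.right :]:
            raise ConfigError("flank_right does not match the amplicon suffix")
        if (self.allele.left, self.allele.right) not in self.all_placements:
            raise ConfigError("reported placement missing from all_placements")

    @property
    def product(self) -> str:
        """The deletion-product sequence this report explains."""
        return self.flank_left + self.allele.insert + self.flank_right


def _validate_pair(amplicon_seq: str, product_seq: str) -> None:
    for seq, what in ((amplicon_seq, "amplicon"), (product_seq, "product")):
        if not seq:
            raise ConfigError(f"{what} sequence is empty")
        if set(seq) - set("ACGT"):
            raise ConfigError(f"{what} sequence contains non-ACGT characters")
    if len(product_seq) >= len(amplicon_seq):
        raise NoDeletionFoundError(
            "product is not shorter than the amplicon: no deletion to call"
        )


def _anchors(
    amplicon_seq: str, product_seq: str, min_anchor: int
) -> Tuple[int, int]:
    prefix = _lcp(amplicon_seq, product_seq)
    suffix = _lcs(amplicon_seq, product_seq)
    if prefix < min_anchor or suffix < min_anchor:
        raise NoDeletionFoundError(
            f"product shares only {prefix} bp of prefix and {suffix} bp of "
            f"suffix with the amplicon (minimum anchor {min_anchor} bp)"
        )
    return prefix, suffix


def enumerate_decompositions(
    amplicon_seq: str,
    product_seq: str,
    *,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    max_insert: Optional[int] = None,
) -> List[Decomposition]:
    """Enumerate every (L, R, insert) explaining the product, sorted canonically.

    The list is sorted by (insert length, decreasing matched flank total,
    decreasing L), so its first element is the canonical call.  All valid
    placements have ``L`` within the longest common prefix and the right
    flank within the longest common suffix of amplicon and product, which
    bounds the search exactly; each candidate is nevertheless verified by
    full reconstruction.
    """
    _validate_pair(amplicon_seq, product_seq)
    prefix, suffix = _anchors(amplicon_seq, product_seq, min_anchor)
    n, p = len(amplicon_seq), len(product_seq)
    out: List[Decomposition] = []
    for left in range(0, min(prefix, p) + 1):
        max_f = min(suffix, p - left)
        for f in range(0, max_f + 1):
            right = n - f
            if right <= left:
                continue
            insert = product_seq[left : p - f]
            if max_insert is not None and len(insert) > max_insert:
                continue
            d = Decomposition(left, right, insert, left, f)
            if d.reconstruct(amplicon_seq) != product_seq:  # pragma: no cover
                raise AssertionError("decomposition failed reconstruction")
            out.append(d)
    if not out:
        raise NoDeletionFoundError("no decomposition explains the product")
    out.sort(
        key=lambda d: (
            len(d.insert),
            -(d.matched_left + d.matched_right),
            -d.left,
        )
    )
    return out


def call_breakpoint(
    amplicon: Amplicon,
    product_seq: str,
    *,
    allele_id: Optional[str] = None,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> BreakpointReport:
    """Call and normalize the deletion breakpoint of a product sequence.

    Among zero-insert decompositions (if any exist) the one with the
    rightmost left breakpoint is chosen; the break is *clean* if that
    placement is unique and *ambiguous* otherwise, with the ambiguity width
    equal to the number of equivalent placements.  If no zero-insert
    decomposition exists the insert length is minimized, which makes the
    placement unique and both flanks maximal, and the break is an
    *insertion*.

    The construction is direct (linear in the flank-match lengths) and
    agrees exhaustively with the first element of
    :func:`enumerate_decompositions`.
    """
    seq = amplicon.seq
    _validate_pair(seq, product_seq)
    prefix, suffix = _anchors(seq, product_seq, min_anchor)
    n, p = len(seq), len(product_seq)
    if allele_id is None:
        allele_id = f"{amplicon.id}-del"

    lo0 = max(0, p - suffix)
    hi0 = min(prefix, p)
    if lo0 <= hi0:
        # Zero-insert placements exist: deletion size n - p, L in [lo0, hi0].
        shift = n - p
        placements = tuple((left, left + shift) for left in range(lo0, hi0 + 1))
        left = hi0
        right = left + shift
        insert = ""
        width = len(placements)
        break_class = "clean" if width == 1 else "ambiguous"
    else:
        # Minimal insert length makes both flanks maximal and L unique.
        insert_len = p - prefix - suffix
        left = prefix
        right = n - suffix
        insert = product_seq[left : left + insert_len]
        placements = ((left, right),)
        width = 1
        break_class = "insertion"

    allele = DeletionAllele(
        allele_id=allele_id,
        amplicon_id=amplicon.id,
        left=left,
        right=right,
        insert=insert,
        break_class=break_class,
        ambiguity_width=width,
    )
    return BreakpointReport(
        allele=allele,
        amplicon=amplicon,
        flank_left=seq[:left],
        flank_right=seq[right:],
        all_placements=placements,
    )


def normalize_report(
    report: BreakpointReport, *, min_anchor: int = 0
) -> BreakpointReport:
    """Re-normalize a report to the canonical placement (idempotent).

    The product is reconstructed from the report and re-called, so a report
    built from any valid decomposition — e.g. a leftmost ambiguous
    placement, or an insertion whose first base would extend the left
    flank — collapses to the rightmost-L / minimal-insert canonical form.
    The anchor requirement is waived by default because the placement has
    already been established once.
    """
    fresh = call_breakpoint(
        report.amplicon,
        report.product,
        allele_id=report.allele.allele_id,
        min_anchor=min_anchor,
    )
    if report.merge_conflicts:
        fresh = replace(fresh, merge_conflicts=report.merge_conflicts)
    return fresh


def _merge_reads(
    left_read: str,
    right_read: str,
    max_mismatch_rate: float,
    min_overlap: int,
) -> Tuple[str, int]:
    """Merge two inward-facing reads into one product-sequence estimate.

    The largest overlap whose mismatch fraction is within
    ``max_mismatch_rate`` wins.  Conflicting overlap positions are resolved
    in favour of the base with the longer flanking exact stretch in its own
    read; the number of such resolutions is returned so callers can flag
    them.
    """
    max_o = min(len(left_read), len(right_read))
    best_frac = None
    for o in range(max_o, min_overlap - 1, -1):
        a_tail = left_read[len(left_read) - o :]
        b_head = right_read[:o]
        if a_tail == b_head:
            return left_read + right_read[o:], 0
        if max_mismatch_rate > 0:
            mm = sum(x != y for x, y in zip(a_tail, b_head))
            frac = mm / o
            if best_frac is None or frac < best_frac:
                best_frac = frac
            if frac <= max_mismatch_rate:
                consensus = list(a_tail)
                for j in range(o):
                    if a_tail[j] == b_head[j]:
                        continue
                    # Support = distance to the nearest end of the base's
                    # own read: Sanger quality degrades toward read ends.
                    pos_a = len(left_read) - o + j
                    left_support = min(pos_a, len(left_read) - 1 - pos_a)
                    right_support = min(j, len(right_read) - 1 - j)
                    if right_support > left_support:
                        consensus[j] = b_head[j]
                merged = (
                    left_read[: len(left_read) - o]
                    + "".join(consensus)
                    + right_read[o:]
                )
                return merged, mm
    if best_frac is not None and best_frac <= 0.2:
        raise LowQualityError(
            f"best read overlap has mismatch fraction {best_frac:.3f}, above "
            f"the allowed {max_mismatch_rate:.3f}"
        )
    raise AssemblyError(
        f"reads share no overlap of at least {min_overlap} bp"
    )


def call_from_reads(
    amplicon: Amplicon,
    left_read: str,
    right_read: str,
    *,
    max_mismatch_rate: float = 0.0,
    min_overlap: int = 10,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    allele_id: Optional[str] = None,
) -> BreakpointReport:
    """Call a breakpoint from paired Sanger reads off the internal primers.

    The left read runs forward from the left internal primer; the right
    read is sequenced inward from the right internal primer and may be
    supplied either already reverse-complemented to the reference strand or
    as read (orientation is auto-detected by which version anchors on the
    amplicon suffix).  The reads are merged overlap-aware into a single
    product estimate which is then delegated to :func:`call_breakpoint`;
    with error-free reads spanning the break the result is identical to
    calling on the true product.
    """
    if max_mismatch_rate < 0 or max_mismatch_rate >= 1:
        raise ConfigError("max_mismatch_rate must be in [0, 1)")
    oriented_rc = revcomp(right_read)
    # Prefer the orientation whose suffix anchors on the amplicon suffix.
    right_oriented = max(
        (oriented_rc, right_read), key=lambda r: _lcs(amplicon.seq, r)
    )
    merged, conflicts = _merge_reads(
        left_read, right_oriented, max_mismatch_rate, min_overlap
    )
    if _lcp(amplicon.seq, merged) < min_anchor or _lcs(amplicon.seq, merged) < min_anchor:
        raise AssemblyError(
            "merged read sequence does not anchor on the amplicon flanks"
        )
    if merged == amplicon.seq:
        raise NoDeletionFoundError("merged reads reconstruct the wild-type amplicon")
    report = call_breakpoint(
        amplicon, merged, allele_id=allele_id, min_anchor=min_anchor
    )
    if conflicts:
        report = replace(report, merge_conflicts=conflicts)
    return report
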