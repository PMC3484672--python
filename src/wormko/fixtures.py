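"""Synthetic fixtures: amplicons, planted deletions, and Sanger-like reads.

Every planted case carries its ground truth in already-canonical form
(rightmost-L for microhomology, minimal insert for insertion breaks), so a
round trip through read simulation and breakpoint calling must recover the
planted ``(L, R, insert, class, ambiguity_width)`` exactly when reads are
error-free.

Canonical truth is achieved by local sequence surgery rather than
rejection sampling: to realize a microhomology of h bases the h bases
following the right breakpoint are copied from the left breakpoint, and
the bases immediately beyond the engineered homology (and immediately
before the break) are forced to differ so the ambiguity width is exactly
h + 1.  Insertion breaks force the first and last inserted bases to differ
from the flanking deleted bases, which pins the minimal-insert placement.
Because this may edit a few bases, ``plant_deletion`` returns the (possibly
adjusted) amplicon along with the truth allele and product.

Default parameters emulate the published screens: a 2099-bp wild-type
internal product, deletions of 0.2-2 kb (all under 3 kb by primer
placement), about 27% of deletions carrying inserted material
(1097 of 4101 in the published set), and an insert-size mixture in which
roughly 8% of inserts (87 of 1097) are 100 bp to 2 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .errors import ConfigError
from .seqmodel import Amplicon, DeletionAllele

__all__ = [
    "InsertSizeDist",
    "FixtureSpec",
    "PlantedCase",
    "make_amplicon",
    "plant_deletion",
    "make_reads",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class InsertSizeDist:
    """Mixture model for insertion sizes: geometric body plus a heavy tail.

    With probability ``tail_prob`` the insert is uniform on ``tail_range``
    (capped at 2 kb); otherwise its length is geometric with the given
    mean.  The published proportions give the default tail weight.
    """

    geom_mean: float = 3.0
    tail_prob: float = 87 / 1097
    tail_range: Tuple[int, int] = (100, 2000)

    def __post_init__(self) -> None:
        if self.geom_mean < 1:
            raise ConfigError("geom_mean must be >= 1")
        if not 0 <= self.tail_prob <= 1:
            raise ConfigError("tail_prob must be in [0, 1]")
        lo, hi = self.tail_range
        if not 1 <= lo <= hi <= 2000:
            raise ConfigError("tail_range must satisfy 1 <= lo <= hi <= 2000")

    def draw(self, rng: np.random.Generator) -> int:
        if rng.random() < self.tail_prob:
            lo, hi = self.tail_range
            return int(rng.integers(lo, hi + 1))
        return int(rng.geometric(1.0 / self.geom_mean))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the fixture generator (one spec per reproducible run)."""

    seed: int = 0
    amplicon_length: int = 2199
    primer_len: int = 25
    deletion_size_range: Tuple[int, int] = (200, 2000)
    insertion_prob: float = 1097 / 4101
    insertion_size_dist: InsertSizeDist = field(default_factory=InsertSizeDist)
    #: P(microhomology = h) for h = 0..10, applied to zero-insert breaks.
    microhomology_dist: Tuple[float, ...] = (
        0.5, 0.25, 0.125, 0.0625, 0.03125,
        0.015625, 0.0078125, 0.00390625, 0.001953125, 0.0009765625,
        0.0009765625,
    )
    read_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.amplicon_length < 6 * self.primer_len:
            raise ConfigError("amplicon too short for nested primer design")
        lo, hi = self.deletion_size_range
        if not 1 <= lo <= hi:
            raise ConfigError("deletion_size_range must satisfy 1 <= lo <= hi")
        if hi >= 3000:
            raise ConfigError("deletion sizes must stay below 3 kb")
        span = self.amplicon_length - 4 * self.primer_len
        margin = 12 + len(self.microhomology_dist)
        if hi > span - 2 * margin:
            raise ConfigError(
                f"deletion_size_range max {hi} does not fit the internal "
                f"span {span} with breakpoint margins"
            )
        if not 0 <= self.insertion_prob <= 1:
            raise ConfigError("insertion_prob must be in [0, 1]")
        probs = np.asarray(self.microhomology_dist, dtype=float)
        if probs.ndim != 1 or len(probs) > 11 or np.any(probs < 0) or probs.sum() <= 0:
            raise ConfigError("microhomology_dist must be non-negative over 0..10")
        if not 0 <= self.read_error_rate < 1:
            raise ConfigError("read_error_rate must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PlantedCase:
    """One planted deletion: the (possibly edited) amplicon, truth, product."""

    amplicon: Amplicon
    allele: DeletionAllele
    product: str


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _different_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in _BASES if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


def make_amplicon(
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
    amplicon_id: Optional[str] = None,
) -> Amplicon:
    """Random ACGT amplicon with nested primer anchors (external outside).

    Deterministic per spec seed; passing an explicit generator lets callers
    draw many amplicons from one stream.
    """
    if rng is None:
        rng = spec.rng()
    if amplicon_id is None:
        amplicon_id = f"amp-seed{spec.seed}"
    n = spec.amplicon_length
    k = spec.primer_len
    return Amplicon(
        id=amplicon_id,
        seq=_random_seq(rng, n),
        ext_left=k,
        int_left=2 * k,
        int_right=n - 2 * k,
        ext_right=n - k,
    )


def plant_deletion(
    amp: Amplicon,
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
    allele_id: str = "planted-0",
) -> PlantedCase:
    """Plant one deletion inside the internal primer span.

    Draws the break class (insertion with ``insertion_prob``, otherwise a
    zero-insert break with engineered microhomology from
    ``microhomology_dist``), the deletion size, and the position; returns
    the edited amplicon, the canonical ground-truth allele, and the exact
    product sequence.  The truth always reconstructs the product.
    """
    if rng is None:
        rng = spec.rng()
    seq = list(amp.seq)
    lo, hi = spec.deletion_size_range
    size = int(rng.integers(lo, hi + 1))

    # An insertion must stay shorter than the deletion it replaces for the
    # product to remain a deletion product at all.
    is_insertion = size >= 2 and rng.random() < spec.insertion_prob
    probs = np.asarray(spec.microhomology_dist, dtype=float)
    h = 0 if is_insertion else int(rng.choice(len(probs), p=probs / probs.sum()))

    margin = 12 + len(probs)
    left_lo = amp.int_left + margin
    left_hi = amp.int_right - size - margin
    if left_hi < left_lo:
        raise ConfigError(
            f"deletion of {size} bp does not fit the internal span of {amp.id}"
        )
    left = int(rng.integers(left_lo, left_hi + 1))
    right = left + size

    if is_insertion:
        ins_len = min(spec.insertion_size_dist.draw(rng), size - 1)
        ins_len = max(ins_len, 1)
        insert = list(_random_seq(rng, ins_len))
        # Pin the minimal-insert placement: neither insert end may extend a
        # flank into the deleted sequence.
        if ins_len == 1:
            insert[0] = _different_base(rng, seq[left], seq[right - 1])
        else:
            if insert[0] == seq[left]:
                insert[0] = _different_base(rng, seq[left])
            if insert[-1] == seq[right - 1]:
                insert[-1] = _different_base(rng, seq[right - 1])
        insert_str = "".join(insert)
        truth_left, truth_right = left, right
        width = 1
        break_class = "insertion"
    else:
        # Engineer exactly h bases of microhomology at the break: the h
        # bases after the right breakpoint mirror the h bases after the
        # left one, and extension is blocked on both sides.
        for j in range(h):
            seq[right + j] = seq[left + j]
        if seq[right + h] == seq[left + h]:
            seq[right + h] = _different_base(rng, seq[left + h])
        if seq[right - 1] == seq[left - 1]:
            seq[right - 1] = _different_base(rng, seq[left - 1])
        insert_str = ""
        # Canonical (rightmost-L) placement shifts the homology onto the
        # left flank.
        truth_left, truth_right = left + h, right + h
        width = h + 1
        break_class = "ambiguous" if h else "clean"

    new_seq = "".join(seq)
    amp_out = replace(amp, seq=new_seq)
    product = new_seq[:left] + insert_str + new_seq[right:]
    allele = DeletionAllele(
        allele_id=allele_id,
        amplicon_id=amp.id,
        left=truth_left,
        right=truth_right,
        insert=insert_str,
        break_class=break_class,
        ambiguity_width=width,
    )
    reconstructed = new_seq[:truth_left] + insert_str + new_seq[truth_right:]
    if reconstructed != product:  # pragma: no cover - construction invariant
        raise AssertionError("planted truth fails to reconstruct the product")
    return PlantedCase(amplicon=amp_out, allele=allele, product=product)


def make_reads(
    product: str,
    read_len: int,
    error_rate: float,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> Tuple[str, str]:
    """Simulate inward Sanger reads off the internal primers.

    The left read is the product prefix; the right read is the reverse
    complement of the product suffix (as sequenced).  Substitution errors
    are planted independently at ``error_rate``; indel noise is out of
    scope.  The two reads must jointly cover the product.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not 0 <= error_rate < 1:
        raise ConfigError("error_rate must be in [0, 1)")
    if read_len > len(product):
        raise ConfigError("read_len exceeds the product length")
    if 2 * read_len < len(product):
        raise ConfigError(
            f"reads of {read_len} bp cannot jointly cover a "
            f"{len(product)} bp product"
        )

    def noisy(seq: str) -> str:
        if error_rate == 0:
            return seq
        out = list(seq)
        hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
        for i in hits:
            out[i] = _different_base(rng, out[i])
        return "".join(out)

    comp = str.maketrans("ACGT", "TGCA")
    left_read = noisy(product[:read_len])
    right_read = noisy(product[-read_len:].translate(comp)[::-1])
    return left_read, right_read
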