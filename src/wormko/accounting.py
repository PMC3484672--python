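"""Bookkeeping for knockout coverage, essentiality overlap, and gene maps.

Three kinds of arithmetic accompany a large knockout resource:

* **gene-family coverage** — for each multigene family, the percentage of
  members with at least one mutation (round-half-up to integer percent,
  the convention used in published coverage tables);
* **worm-yeast essentiality overlap** — set arithmetic over orthologous
  gene pairs: of the nematode genes that can be mutated to a lethal
  phenotype, which have a yeast ortholog, which of those orthologs are
  essential in yeast too, and how many lethal genes have a nematode
  paralog;
* **chromosome binning** — histograms of all mutated genes and of the
  lethal subset along each chromosome.

The published consortium counts (WormBase WS220 era) are included as
module constants so coverage reports and the overlap arithmetic can be
regenerated from the printed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "FamilyRecord",
    "EssentialitySets",
    "round_half_up_percent",
    "family_coverage",
    "lethal_fraction",
    "essential_overlap",
    "paralog_remainder",
    "chromosome_bins",
    "coverage_table",
    "synthetic_essentiality_sets",
    "PUBLISHED_FAMILY_COUNTS",
    "PUBLISHED_ESSENTIALITY_COUNTS",
]


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """100 * numerator / denominator, rounded half-up to an integer percent.

    Decimal arithmetic avoids binary-float artifacts on exact halves.
    """
    if denominator <= 0:
        raise ConfigError("denominator must be positive")
    frac = Decimal(100 * numerator) / Decimal(denominator)
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FamilyRecord:
    """Knockout coverage counts for one multigene family.

    ``consortium_mutated`` counts family members whose mutation carries a
    consortium allele (tm, ok or gk), a subset of ``mutated_genes``.
    """

    family: str
    total_genes: int
    mutated_genes: int
    consortium_mutated: int = 0

    def __post_init__(self) -> None:
        if not (
            0 <= self.consortium_mutated <= self.mutated_genes <= self.total_genes
        ):
            raise DataError(
                f"family {self.family!r}: need 0 <= consortium_mutated <= "
                f"mutated_genes <= total_genes, got "
                f"({self.consortium_mutated}, {self.mutated_genes}, "
                f"{self.total_genes})"
            )


def family_coverage(rec: FamilyRecord) -> int:
    """Percentage of family members mutated, as a round-half-up integer."""
    if rec.total_genes <= 0:
        raise ConfigError(f"family {rec.family!r}: total_genes must be positive")
    return round_half_up_percent(rec.mutated_genes, rec.total_genes)


def lethal_fraction(n_lethal: int, n_mutated: int) -> int:
    """Integer percent of mutated genes that can be mutated to lethality."""
    if n_mutated <= 0:
        raise ConfigError("n_mutated must be positive")
    if not 0 <= n_lethal <= n_mutated:
        raise DataError("need 0 <= n_lethal <= n_mutated")
    return round_half_up_percent(n_lethal, n_mutated)


@dataclass(frozen=True)
class EssentialitySets:
    """Gene-id sets driving the worm-yeast essentiality overlap.

    ``shared_essential`` defaults to the intersection of the two
    with-ortholog sets; if supplied explicitly it must satisfy the subset
    invariants.
    """

    worm_lethal: FrozenSet[str]
    worm_lethal_with_yeast_ortholog: FrozenSet[str]
    yeast_essential_with_worm_ortholog: FrozenSet[str]
    shared_essential: Optional[FrozenSet[str]] = None

    def __post_init__(self) -> None:
        wl = frozenset(self.worm_lethal)
        wo = frozenset(self.worm_lethal_with_yeast_ortholog)
        yo = frozenset(self.yeast_essential_with_worm_ortholog)
        shared = self.shared_essential
        shared = wo & yo if shared is None else frozenset(shared)
        object.__setattr__(self, "worm_lethal", wl)
        object.__setattr__(self, "worm_lethal_with_yeast_ortholog", wo)
        object.__setattr__(self, "yeast_essential_with_worm_ortholog", yo)
        object.__setattr__(self, "shared_essential", shared)
        if not wo <= wl:
            raise DataError(
                "worm_lethal_with_yeast_ortholog must be a subset of worm_lethal"
            )
        if not (shared <= wo and shared <= yo):
            raise DataError(
                "shared_essential must be a subset of both with-ortholog sets"
            )


def essential_overlap(sets: EssentialitySets) -> Dict[str, int]:
    """Partition the orthologous essential genes into shared/worm-only/yeast-only.

    Conservation holds by construction: ``worm_only + shared`` equals the
    worm-lethal-with-ortholog count, and ``yeast_only + shared`` the
    yeast-essential-with-ortholog count.
    """
    shared = len(sets.shared_essential)
    return {
        "shared": shared,
        "worm_only": len(sets.worm_lethal_with_yeast_ortholog) - shared,
        "yeast_only": len(sets.yeast_essential_with_worm_ortholog) - shared,
    }


def paralog_remainder(total_lethal: int, single_copy: int) -> int:
    """Lethal genes that are not single-copy, i.e. have at least one paralog."""
    if not 0 <= single_copy <= total_lethal:
        raise DataError("need 0 <= single_copy <= total_lethal")
    return total_lethal - single_copy


def chromosome_bins(
    genes: Iterable[Tuple[str, int, bool]],
    bin_width: int,
    chrom_lengths: Mapping[str, int],
) -> Dict[str, Dict[str, np.ndarray]]:
    """Bin mutated genes (and the lethal subset) along each chromosome.

    ``genes`` yields ``(chrom, position, is_lethal)``; every chromosome
    must be declared in ``chrom_lengths`` and every position must fall
    inside it.  Returns, per chromosome, the bin edges plus ``all`` and
    ``lethal`` counts; the lethal histogram is bin-wise bounded by the
    all-genes histogram by construction.
    """
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    by_chrom: Dict[str, List[Tuple[int, bool]]] = {}
    for chrom, pos, is_lethal in genes:
        if chrom not in chrom_lengths:
            raise DataError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < chrom_lengths[chrom]:
            raise DataError(
                f"position {pos} outside declared length of {chrom!r}"
            )
        by_chrom.setdefault(chrom, []).append((pos, bool(is_lethal)))
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for chrom, length in chrom_lengths.items():
        edges = np.arange(0, length + bin_width, bin_width, dtype=np.int64)
        entries = by_chrom.get(chrom, [])
        positions = np.array([p for p, _ in entries], dtype=np.int64)
        lethal_pos = np.array([p for p, l in entries if l], dtype=np.int64)
        all_counts, _ = np.histogram(positions, bins=edges)
        lethal_counts, _ = np.histogram(lethal_pos, bins=edges)
        out[chrom] = {
            "edges": edges,
            "all": all_counts,
            "lethal": lethal_counts,
        }
    return out


def coverage_table(records: Sequence[FamilyRecord]) -> pd.DataFrame:
    """Deterministic coverage report: one row per family plus percent column."""
    rows = [
        {
            "family": r.family,
            "total_genes": r.total_genes,
            "mutated_genes": r.mutated_genes,
            "consortium_mutated": r.consortium_mutated,
            "percent_complete": family_coverage(r),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def synthetic_essentiality_sets(
    n_worm_lethal: int,
    n_worm_with_ortholog: int,
    n_yeast_with_ortholog: int,
    n_shared: int,
) -> EssentialitySets:
    """Build deterministic id sets with the given overlap cardinalities.

    Useful for regenerating the overlap arithmetic when only published
    counts, not gene lists, are available.  Ids are synthetic labels.
    """
    if not n_shared <= min(n_worm_with_ortholog, n_yeast_with_ortholog):
        raise DataError("shared count exceeds a with-ortholog set")
    if not n_worm_with_ortholog <= n_worm_lethal:
        raise DataError("worm with-ortholog count exceeds worm lethal count")
    shared = [f"shared{i}" for i in range(n_shared)]
    worm_only = [f"wormonly{i}" for i in range(n_worm_with_ortholog - n_shared)]
    yeast_only = [f"yeastonly{i}" for i in range(n_yeast_with_ortholog - n_shared)]
    worm_no_orth = [
        f"wormnoorth{i}" for i in range(n_worm_lethal - n_worm_with_ortholog)
    ]
    worm_orth = frozenset(shared + worm_only)
    return EssentialitySets(
        worm_lethal=worm_orth | frozenset(worm_no_orth),
        worm_lethal_with_yeast_ortholog=worm_orth,
        yeast_essential_with_worm_ortholog=frozenset(shared + yeast_only),
        shared_essential=frozenset(shared),
    )


#: Published multigene-family knockout coverage counts
#: (family, total genes, genes with mutations, genes with a consortium
#: tm/ok/gk allele).  The percent column is recomputed, not stored.
PUBLISHED_FAMILY_COUNTS: Tuple[FamilyRecord, ...] = tuple(
    FamilyRecord(*row)
    for row in [
        ("ABC transporters", 58, 57, 53),
        ("Cadherin family", 12, 11, 9),
        ("Calmodulin-like EF hand", 70, 34, 25),
        ("Cytochrome p450", 75, 28, 28),
        ("Degenerin channels", 30, 24, 21),
        ("Epidermal growth factor domain", 191, 119, 98),
        ("Fibronectin type III domain", 47, 37, 35),
        ("GPCR rhodopsin", 139, 74, 73),
        ("GPCR orphan", 1307, 286, 281),
        ("Guanylate cyclase domain", 38, 36, 35),
        ("Helicases", 85, 53, 46),
        ("Heterotrimeric G proteins", 22, 21, 3),
        ("Innexins", 25, 25, 21),
        ("Kinases", 416, 380, 359),
        ("Ligand-gated ion channels", 101, 63, 53),
        ("LIM domain", 30, 25, 24),
        ("LRR domain", 56, 26, 22),
        ("MATH domain", 86, 70, 70),
        ("Metalloproteases", 46, 29, 28),
        ("microRNA (Mir)", 207, 92, 36),
        ("Neuropeptides", 114, 74, 73),
        ("Nuclear hormone receptors", 275, 250, 245),
        ("PAZ (Argonaute/Dicer family)", 26, 25, 23),
        ("PDZ domain", 64, 41, 35),
        ("Phosphatases", 98, 28, 21),
        ("Potassium channels", 72, 40, 31),
        ("RRM (RNA recognition motif)", 110, 67, 56),
        ("Transcription factors", 941, 866, 836),
        ("TRP channels", 21, 21, 19),
        ("Ubiquitin-like", 25, 14, 14),
        ("Ubiquitin conjugating enzyme E2", 31, 15, 13),
        ("Zinc finger proteins", 831, 655, 627),
    ]
)

#: Published headline counts for the essentiality arithmetic.
PUBLISHED_ESSENTIALITY_COUNTS: Dict[str, int] = {
    "genes_mutated": 6013,
    "mutations_total": 6841,
    "lethal_genes": 1436,
    "single_copy_essential": 946,
    "ortholog_pairs": 1905,
    "worm_lethal_with_yeast_ortholog": 413,
    "yeast_essential_genes": 1193,
    "yeast_essential_with_worm_ortholog": 678,
    "shared_essential": 193,
}
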