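"""Stochastic simulator of the pooled PCR deletion-screening workflow.

The simulated protocol mirrors the consortium screen: a mutagenized worm
library is arrayed in 96-well plates, DNA from each plate is pooled into a
grid of rows and columns, pools are screened by nested PCR for the
deletion product, positive row/column intersections are addressed back to
single wells, and animals from a confirmed well go through several rounds
of sib selection — picking single animals, selfing them, and PCR-testing
their progeny — until a homozygous deletion line is obtained or, for
recessive lethals, a persistently heterozygous line is stabilized.

Model choices (all parameters of :class:`ScreenScenario`):

* **PCR sensitivity** — nested PCR is modeled as fully specific
  (mutant-free pools never fire) with per-template detection probability
  ``s``: a reaction whose aliquot holds ``m`` mutant templates is positive
  with probability ``1 - (1 - s)**m``.  The aliquot template count is
  Poisson around ``pool mutant fraction x templates_per_reaction``,
  conditioned on being at least one whenever the pool truly contains a
  carrier (library sampling is sized so that represented genomes are not
  lost at the DNA-prep stage).
* **Duplicate screening** — each pool is run in two independent reactions
  and called positive if at least one fires; the OR rule maximizes
  sensitivity, matching the protocol's intent of not losing hits.
* **Sib selection** — each round picks ``sib_plan[r]`` single founder
  animals from the current positive population (a multivariate
  hypergeometric draw over genotype counts), selfs each founder with
  Mendelian 1:2:1 segregation, removes homozygous-deletion progeny before
  reproduction when the allele is lethal, and recurses into a positive
  sub-population, preferring one founded by a homozygote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError

__all__ = [
    "ScreenScenario",
    "Library",
    "PoolGrid",
    "PoolScreen",
    "AddressingResult",
    "RoundTrace",
    "ScreenResult",
    "detection_probability",
    "build_library",
    "pool_dna",
    "screen_pools",
    "address_positive",
    "mendelian_offspring",
    "run_sib_selection",
    "run_screen",
    "count_reactions",
]

#: Library sizes (mutagenized genomes) typical of the published screens.
PUBLISHED_SCALE_GENOMES = (125_000, 1_400_000)

#: Cap on the simulated census population during sib expansion; only
#: genotype frequencies matter to the draws, so growth beyond this size is
#: rescaled proportionally.
_POPULATION_CAP = 1_000_000


@dataclass(frozen=True)
class ScreenScenario:
    """Configuration of one simulated screen against a single target."""

    n_wells: int
    genomes_per_well: int
    deletion_rate_per_target: float
    plate_rows: int = 8
    plate_cols: int = 12
    duplicate_screening: bool = True
    pcr_sensitivity: float = 1.0
    sib_plan: Tuple[int, ...] = (24, 24, 24)
    lethal: bool = False
    seed: int = 0
    templates_per_reaction: float = 10_000.0
    brood_factor: int = 100
    mutagenized_genomes_total: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sib_plan", tuple(self.sib_plan))
        if self.n_wells <= 0 or self.genomes_per_well <= 0:
            raise ConfigError("n_wells and genomes_per_well must be positive")
        per_plate = self.plate_rows * self.plate_cols
        if per_plate <= 0 or self.n_wells % per_plate:
            raise ConfigError(
                f"n_wells={self.n_wells} is not a whole number of "
                f"{self.plate_rows}x{self.plate_cols} plates"
            )
        if not 0.0 <= self.deletion_rate_per_target <= 1.0:
            raise ConfigError("deletion_rate_per_target must be in [0, 1]")
        if not 0.0 < self.pcr_sensitivity <= 1.0:
            raise ConfigError("pcr_sensitivity must be in (0, 1]")
        if not self.sib_plan or any(k < 1 for k in self.sib_plan):
            raise ConfigError("sib_plan must be a non-empty list of positive picks")
        if self.templates_per_reaction <= 0:
            raise ConfigError("templates_per_reaction must be positive")
        if self.brood_factor < 2:
            raise ConfigError("brood_factor must be at least 2")
        if (
            self.mutagenized_genomes_total is not None
            and self.mutagenized_genomes_total <= 0
        ):
            raise ConfigError("mutagenized_genomes_total must be positive")

    @property
    def n_plates(self) -> int:
        return self.n_wells // (self.plate_rows * self.plate_cols)

    @property
    def genomes_total(self) -> int:
        if self.mutagenized_genomes_total is not None:
            return self.mutagenized_genomes_total
        return self.n_wells * self.genomes_per_well

    @property
    def published_scale(self) -> bool:
        """Whether the library size matches the published screening scale."""
        lo, hi = PUBLISHED_SCALE_GENOMES
        return lo <= self.genomes_total <= hi


@dataclass(frozen=True)
class Library:
    """Arrayed worm library: per-well counts of deletion-carrier genomes."""

    mutants: np.ndarray  # shape (n_plates, plate_rows, plate_cols)
    genomes_per_well: int

    @property
    def total_mutants(self) -> int:
        return int(self.mutants.sum())

    def well_fraction(self) -> np.ndarray:
        return self.mutants / self.genomes_per_well


@dataclass(frozen=True)
class PoolGrid:
    """Row and column pools of well DNA, per plate.

    ``row_fraction[p, r]`` is the mutant-template fraction of the pool of
    row ``r`` on plate ``p`` (the mean of its member-well fractions);
    ``row_mutants`` holds the underlying carrier counts.
    """

    row_mutants: np.ndarray
    col_mutants: np.ndarray
    row_fraction: np.ndarray
    col_fraction: np.ndarray


@dataclass(frozen=True)
class PoolScreen:
    """Outcome of screening every pool of a grid."""

    positive_rows: Tuple[Tuple[int, int], ...]  # (plate, row)
    positive_cols: Tuple[Tuple[int, int], ...]  # (plate, col)
    reactions: int

    @property
    def any_positive(self) -> bool:
        return bool(self.positive_rows or self.positive_cols)


@dataclass(frozen=True)
class AddressingResult:
    confirmed_wells: Tuple[Tuple[int, int, int], ...]  # (plate, row, col)
    lost_at_addressing: bool
    reactions: int


@dataclass(frozen=True)
class RoundTrace:
    """Per-sib-round record: sub-populations tested, positives, allele freq."""

    round_index: int
    wells_tested: int
    positives: int
    allele_frequency: float


@dataclass(frozen=True)
class ScreenResult:
    """End-to-end outcome of one simulated screen."""

    detected: bool
    addressed_well: Optional[str]
    rounds: Tuple[RoundTrace, ...]
    recovered: str  # "homozygous" | "persistent_heterozygous" | "lost"
    reactions_used: int
    pool_reactions: int = 0
    addressing_reactions: int = 0
    sib_reactions: int = 0
    lost_at_addressing: bool = False


def detection_probability(m_templates: int, s: float, duplicate: bool) -> float:
    """Closed-form probability that a reaction (pair) detects m templates.

    One reaction fires with probability ``1 - (1 - s)**m``; under duplicate
    screening a pool is positive if at least one of two independent
    reactions fires.
    """
    if m_templates <= 0:
        return 0.0
    p = 1.0 - (1.0 - s) ** m_templates
    if duplicate:
        p = 1.0 - (1.0 - p) ** 2
    return p


def _zero_truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    """Sample Poisson(lam) conditioned on being >= 1."""
    if lam <= 1e-12:
        return 1
    if lam > 20.0:
        # P(0) < 3e-9: plain Poisson, floored for formal correctness.
        return max(1, int(rng.poisson(lam)))
    p0 = math.exp(-lam)
    target = rng.random() * (1.0 - p0)
    k = 1
    pk = lam * p0
    cum = pk
    while cum < target:
        k += 1
        pk *= lam / k
        cum += pk
    return k


def _reaction_positive(
    rng: np.random.Generator, mutant_fraction: float, sc: ScreenScenario
) -> bool:
    """One nested-PCR reaction on a template with the given carrier fraction.

    Always consumes exactly two RNG draws so that runs with different
    sensitivities remain draw-for-draw comparable.
    """
    m = _zero_truncated_poisson(
        rng, mutant_fraction * sc.templates_per_reaction
    )
    p = 1.0 - (1.0 - sc.pcr_sensitivity) ** m
    return rng.random() < p


def build_library(
    sc: ScreenScenario, rng: Optional[np.random.Generator] = None
) -> Library:
    """Draw the arrayed library: each genome carries the deletion independently."""
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    shape = (sc.n_plates, sc.plate_rows, sc.plate_cols)
    mutants = rng.binomial(
        sc.genomes_per_well, sc.deletion_rate_per_target, size=shape
    )
    return Library(mutants=mutants, genomes_per_well=sc.genomes_per_well)


def pool_dna(lib: Library) -> PoolGrid:
    """Pool well DNA into one row pool and one column pool per plate line.

    Each well contributes to exactly one row pool and one column pool; a
    pool's mutant-template fraction is the mean of its member wells'
    fractions.  Total mutant content (fraction times pool size) is
    conserved between the row view and the column view.
    """
    frac = lib.well_fraction()
    return PoolGrid(
        row_mutants=lib.mutants.sum(axis=2),
        col_mutants=lib.mutants.sum(axis=1),
        row_fraction=frac.mean(axis=2),
        col_fraction=frac.mean(axis=1),
    )


def screen_pools(
    grid: PoolGrid, sc: ScreenScenario, rng: Optional[np.random.Generator] = None
) -> PoolScreen:
    """Screen every row and column pool by nested PCR.

    Mutant-free pools never fire (full specificity); pools holding at least
    one carrier fire per reaction with the per-template detection model,
    OR-ed over duplicates when ``duplicate_screening`` is on.
    """
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    n_reactions = 2 if sc.duplicate_screening else 1
    pos_rows: List[Tuple[int, int]] = []
    pos_cols: List[Tuple[int, int]] = []
    reactions = 0
    for kind, counts, fracs, hits in (
        ("row", grid.row_mutants, grid.row_fraction, pos_rows),
        ("col", grid.col_mutants, grid.col_fraction, pos_cols),
    ):
        n_plates, n_lines = counts.shape
        for p in range(n_plates):
            for i in range(n_lines):
                reactions += n_reactions
                if counts[p, i] == 0:
                    continue
                fired = any(
                    _reaction_positive(rng, fracs[p, i], sc)
                    for _ in range(n_reactions)
                )
                if fired:
                    hits.append((p, i))
    return PoolScreen(
        positive_rows=tuple(pos_rows),
        positive_cols=tuple(pos_cols),
        reactions=reactions,
    )


def address_positive(
    grid: PoolGrid,
    lib: Library,
    screen: PoolScreen,
    sc: ScreenScenario,
    rng: Optional[np.random.Generator] = None,
) -> AddressingResult:
    """Address positive pools back to single wells and retest each candidate.

    Candidate wells are the intersections of positive rows and positive
    columns on each plate; each candidate is retested individually with the
    same PCR model.  A plate whose positives have an empty intersection
    (e.g. a row fired but the matching column was a false negative), or
    whose candidates all fail the retest, raises the lost-at-addressing
    flag.
    """
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    rows_by_plate: dict = {}
    cols_by_plate: dict = {}
    for p, r in screen.positive_rows:
        rows_by_plate.setdefault(p, []).append(r)
    for p, c in screen.positive_cols:
        cols_by_plate.setdefault(p, []).append(c)

    confirmed: List[Tuple[int, int, int]] = []
    reactions = 0
    lost = False
    plates = sorted(set(rows_by_plate) | set(cols_by_plate))
    for p in plates:
        rows = rows_by_plate.get(p, [])
        cols = cols_by_plate.get(p, [])
        if not rows or not cols:
            lost = True
            continue
        plate_confirmed = False
        for r in rows:
            for c in cols:
                reactions += 1
                m = int(lib.mutants[p, r, c])
                if m == 0:
                    continue
                frac = m / lib.genomes_per_well
                if _reaction_positive(rng, frac, sc):
                    confirmed.append((p, r, c))
                    plate_confirmed = True
        if not plate_confirmed:
            lost = True
    return AddressingResult(
        confirmed_wells=tuple(confirmed),
        lost_at_addressing=lost,
        reactions=reactions,
    )


def mendelian_offspring(
    rng: np.random.Generator,
    wt: int,
    het: int,
    hom: int,
    n_offspring: int,
    lethal: bool,
) -> Tuple[int, int, int]:
    """Draw surviving-adult genotype counts for one selfing generation.

    Parents self-fertilize: wild-type parents yield wild-type, homozygous
    parents yield homozygous, and heterozygous parents segregate 1:2:1
    WT:het:hom.  When the deletion is lethal, homozygous progeny arrest and
    are removed before the next reproduction (so a selfed heterozygote
    leaves surviving adults in a 2:1 het:WT ratio).
    """
    total = wt + het + hom
    if total == 0 or n_offspring == 0:
        return 0, 0, 0
    p_wt = (wt + het / 4.0) / total
    p_het = (het / 2.0) / total
    p_hom = (hom + het / 4.0) / total
    o_wt, o_het, o_hom = rng.multinomial(n_offspring, (p_wt, p_het, p_hom))
    if lethal:
        o_hom = 0
    return int(o_wt), int(o_het), int(o_hom)


def _expand(
    rng: np.random.Generator,
    wt: int,
    het: int,
    hom: int,
    brood_factor: int,
    lethal: bool,
) -> Tuple[int, int, int]:
    total = wt + het + hom
    n_off = min(total * brood_factor, _POPULATION_CAP)
    return mendelian_offspring(rng, wt, het, hom, n_off, lethal)


def _allele_frequency(wt: int, het: int, hom: int) -> float:
    total = wt + het + hom
    if total == 0:
        return 0.0
    return (0.5 * het + hom) / total


def run_sib_selection(
    carriers: int,
    sc: ScreenScenario,
    rng: Optional[np.random.Generator] = None,
    total_animals: Optional[int] = None,
) -> ScreenResult:
    """Run the sib-selection rounds on a confirmed well.

    ``carriers`` heterozygous animals (out of ``total_animals``, default
    the scenario's genomes per well) seed the starting population.  Each
    round expands the population by selfing, picks ``sib_plan[r]`` single
    founders (hypergeometric over genotype counts), PCR-tests each
    founder's selfed progeny, and recurses into a positive sub-population.
    Termination:

    * ``homozygous`` — a positive sub-population founded by a homozygote
      (a single-parent population segregating 100% deletion);
    * ``persistent_heterozygous`` — rounds exhaust with only heterozygous
      positives (the expected outcome for lethal alleles);
    * ``lost`` — a round yields no positive sub-population.

    Only the deletion band is scored, so a sub-population is detectable iff
    its founder carries the allele, with the usual sensitivity model.
    """
    if carriers < 1:
        raise ConfigError("sib selection needs at least one carrier animal")
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    if total_animals is None:
        total_animals = max(sc.genomes_per_well, carriers)

    wt, het, hom = total_animals - carriers, carriers, 0
    trace: List[RoundTrace] = []
    reactions = 0
    recovered = "lost"
    for round_index, n_picks in enumerate(sc.sib_plan):
        wt, het, hom = _expand(rng, wt, het, hom, sc.brood_factor, sc.lethal)
        total = wt + het + hom
        freq = _allele_frequency(wt, het, hom)
        if total == 0:
            trace.append(RoundTrace(round_index, 0, 0, 0.0))
            recovered = "lost"
            break
        n_picks = min(n_picks, total)
        founders = rng.multivariate_hypergeometric((wt, het, hom), n_picks)
        f_wt, f_het, f_hom = (int(x) for x in founders)
        reactions += n_picks
        # Progeny carrier fraction under selfing: hom founders breed true;
        # het founders leave 3/4 carriers (2/3 among survivors if lethal).
        het_carrier_frac = 2.0 / 3.0 if sc.lethal else 0.75
        hom_positive = sum(
            _reaction_positive(rng, 1.0, sc) for _ in range(f_hom)
        )
        het_positive = sum(
            _reaction_positive(rng, het_carrier_frac, sc) for _ in range(f_het)
        )
        positives = hom_positive + het_positive
        trace.append(RoundTrace(round_index, n_picks, positives, freq))
        if hom_positive:
            recovered = "homozygous"
            break
        if het_positive == 0:
            recovered = "lost"
            break
        # Continue from one positive heterozygous founder's line.
        wt, het, hom = 0, 1, 0
        recovered = "persistent_heterozygous"
    return ScreenResult(
        detected=True,
        addressed_well=None,
        rounds=tuple(trace),
        recovered=recovered,
        reactions_used=reactions,
        sib_reactions=reactions,
    )


def run_screen(
    sc: ScreenScenario, rng: Optional[np.random.Generator] = None
) -> ScreenResult:
    """Simulate one full screen: library, pooling, screening, addressing, sibs."""
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    lib = build_library(sc, rng)
    grid = pool_dna(lib)
    screen = screen_pools(grid, sc, rng)
    if not screen.any_positive:
        return ScreenResult(
            detected=False,
            addressed_well=None,
            rounds=(),
            recovered="lost",
            reactions_used=screen.reactions,
            pool_reactions=screen.reactions,
        )
    addressing = address_positive(grid, lib, screen, sc, rng)
    if not addressing.confirmed_wells:
        return ScreenResult(
            detected=True,
            addressed_well=None,
            rounds=(),
            recovered="lost",
            reactions_used=screen.reactions + addressing.reactions,
            pool_reactions=screen.reactions,
            addressing_reactions=addressing.reactions,
            lost_at_addressing=True,
        )
    p, r, c = addressing.confirmed_wells[0]
    well_id = f"P{p + 1}-{chr(ord('A') + r)}{c + 1}"
    sib = run_sib_selection(int(lib.mutants[p, r, c]), sc, rng)
    total = screen.reactions + addressing.reactions + sib.sib_reactions
    return ScreenResult(
        detected=True,
        addressed_well=well_id,
        rounds=sib.rounds,
        recovered=sib.recovered,
        reactions_used=total,
        pool_reactions=screen.reactions,
        addressing_reactions=addressing.reactions,
        sib_reactions=sib.sib_reactions,
        lost_at_addressing=addressing.lost_at_addressing,
    )


def count_reactions(result: ScreenResult, sc: ScreenScenario) -> dict:
    """Break down PCR reactions used and compare with the no-pooling baseline.

    Without pooling every well would need its own (duplicated) screening
    reaction; grid pooling needs only rows + columns per plate, which is
    the protocol's reason for pooling in the first place.
    """
    baseline = sc.n_wells
    total = (
        result.pool_reactions
        + result.addressing_reactions
        + result.sib_reactions
    )
    if total != result.reactions_used:
        raise ConfigError("reaction trace does not sum to reactions_used")
    return {
        "pool_reactions": result.pool_reactions,
        "addressing_reactions": result.addressing_reactions,
        "sib_reactions": result.sib_reactions,
        "total": total,
        "baseline_no_pooling": baseline,
        "saved_vs_baseline": baseline - total,
    }
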