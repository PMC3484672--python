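"""Deletion validation by array-CGH copy-loss calling and diagnostic PCR.

Array comparative genome hybridization compares a mutant genome against the
wild-type reference: probes over a heterozygous deletion drop to a log2
ratio around -1 (one copy lost of two) and probes over a homozygous
deletion fall to the signal floor (modeled here at -4; only the ordering
hom << het < 0 matters to the caller).  Both single-copy and two-copy
losses are therefore readily detectable, which makes CGH a convenient
validation assay: the deletion found by PCR must reappear as a copy loss,
and any *additional* losses elsewhere in the genome are reported so the
strain can be outcrossed before use.

Loss calling here is a run/threshold method rather than full segmentation:
maximal runs of at least ``min_probes`` consecutive probes below the
heterozygous cut become calls, classified homozygous when the run mean is
below the homozygous cut.  Defaults (-0.5 / -2.0 / 3 probes) are standard
aCGH heuristics.

``diagnostic_pcr`` models the older validation assay: a primer pair with
one primer internal to the deletion and one external yields a product of
predicted size from a wild-type template but not from the deletion
template, so a product from the mutant strain means an intact copy of the
target survives somewhere in its genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .seqmodel import Amplicon, DeletionAllele

__all__ = [
    "HOM_LOSS_LOG2",
    "HET_LOSS_LOG2",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_MIN_PROBES",
    "ProbeTrack",
    "LossCall",
    "ValidationResult",
    "simulate_track",
    "call_losses",
    "validate_deletion",
    "diagnostic_pcr",
]

#: Expected log2 ratios by copy state (two copies = 0).  The homozygous
#: value is a finite proxy for the signal floor.
HET_LOSS_LOG2 = -1.0
HOM_LOSS_LOG2 = -4.0

DEFAULT_THRESHOLDS = (-0.5, -2.0)  # (het_cut, hom_cut)
DEFAULT_MIN_PROBES = 3


@dataclass(frozen=True)
class ProbeTrack:
    """Ordered probe intervals with log2 ratios (BED-like table).

    ``probes`` has columns chrom, start, end, log2; rows are sorted by
    (chrom, start) with non-overlapping intervals within a chromosome.
    """

    probes: pd.DataFrame
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        df = self.probes
        required = ["chrom", "start", "end", "log2"]
        if list(df.columns) != required:
            raise ConfigError(f"probe table must have columns {required}")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(ends <= starts):
                raise ConfigError(f"{chrom}: empty probe interval")
            if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
                raise ConfigError(
                    f"{chrom}: probes must be sorted and non-overlapping"
                )

    def __len__(self) -> int:
        return len(self.probes)


@dataclass(frozen=True)
class LossCall:
    """A called copy-loss segment spanning a run of low probes."""

    chrom: str
    start: int
    end: int
    copy_state: str  # "one_copy_loss" | "two_copy_loss"
    n_probes: int
    mean_log2: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigError("loss call has empty span")
        if self.copy_state not in ("one_copy_loss", "two_copy_loss"):
            raise ConfigError(f"unknown copy state {self.copy_state!r}")


@dataclass(frozen=True)
class ValidationResult:
    status: str  # "confirmed" | "failed"
    extra: Tuple[LossCall, ...]

    @property
    def confirmed(self) -> bool:
        return self.status == "confirmed"


def simulate_track(
    genome_len: int,
    probe_spacing: int,
    deletions: Sequence[Tuple[Tuple[int, int], str]],
    noise_sd: float,
    seed: int,
    chrom: str = "chrI",
) -> ProbeTrack:
    """Tile a chromosome with probes and plant copy-loss signals.

    Probes tile ``[0, genome_len)`` at ``probe_spacing``; a probe reports
    the copy state of the deletion containing its midpoint, plus Normal
    noise with the given standard deviation.  ``deletions`` is a list of
    ``((start, end), copy_state)`` with copy_state ``"one_copy_loss"``
    (heterozygous) or ``"two_copy_loss"`` (homozygous); planted deletions
    must not overlap.
    """
    if probe_spacing <= 0:
        raise ConfigError("probe_spacing must be positive")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    sorted_dels = sorted(deletions, key=lambda d: d[0][0])
    for (a, b), _state in sorted_dels:
        if b <= a:
            raise ConfigError(f"planted deletion [{a}, {b}) is empty")
    for ((_a1, b1), _s1), ((a2, _b2), _s2) in zip(sorted_dels, sorted_dels[1:]):
        if a2 < b1:
            raise ConfigError("planted deletions overlap")
    mu_by_state = {"one_copy_loss": HET_LOSS_LOG2, "two_copy_loss": HOM_LOSS_LOG2}
    for _iv, state in sorted_dels:
        if state not in mu_by_state:
            raise ConfigError(f"unknown copy state {state!r}")

    starts = np.arange(0, genome_len, probe_spacing, dtype=np.int64)
    ends = np.minimum(starts + probe_spacing, genome_len)
    mids = (starts + ends) / 2.0
    mu = np.zeros(len(starts))
    for (a, b), state in sorted_dels:
        mu[(mids >= a) & (mids < b)] = mu_by_state[state]
    rng = np.random.default_rng(seed)
    log2 = mu if noise_sd == 0 else mu + rng.normal(0.0, noise_sd, len(mu))
    df = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "log2": log2}
    )
    return ProbeTrack(probes=df, noise_sd=noise_sd)


def call_losses(
    track: ProbeTrack,
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> List[LossCall]:
    """Call copy losses as runs of consecutive low probes.

    Maximal runs of at least ``min_probes`` probes with log2 below the
    heterozygous cut become calls spanning the first to last probe of the
    run; a run whose mean is below the homozygous cut is a two-copy loss.
    """
    het_cut, hom_cut = thresholds
    if not hom_cut < het_cut < 0:
        raise ConfigError("thresholds must satisfy hom_cut < het_cut < 0")
    if min_probes < 1:
        raise ConfigError("min_probes must be >= 1")
    calls: List[LossCall] = []
    if len(track) == 0:
        return calls
    for chrom, sub in track.probes.groupby("chrom", sort=False):
        low = (sub["log2"] < het_cut).to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        log2 = sub["log2"].to_numpy()
        i = 0
        n = len(low)
        while i < n:
            if not low[i]:
                i += 1
                continue
            j = i
            while j < n and low[j]:
                j += 1
            if j - i >= min_probes:
                mean = float(log2[i:j].mean())
                state = "two_copy_loss" if mean < hom_cut else "one_copy_loss"
                calls.append(
                    LossCall(
                        chrom=str(chrom),
                        start=int(starts[i]),
                        end=int(ends[j - 1]),
                        copy_state=state,
                        n_probes=j - i,
                        mean_log2=mean,
                    )
                )
            i = j
    return calls


def validate_deletion(
    calls: Sequence[LossCall],
    target: Tuple[str, int, int],
    min_overlap_frac: float = 0.5,
) -> ValidationResult:
    """Check that the PCR-detected deletion is confirmed by the CGH calls.

    The target is confirmed iff some call overlaps at least
    ``min_overlap_frac`` of its interval.  Calls not overlapping the target
    at all are returned as *extra* deletions — additional losses in the
    same strain that the user should outcross away.  Confirmation is
    unaffected by extras elsewhere in the genome.
    """
    chrom, t_start, t_end = target
    if t_end <= t_start:
        raise ConfigError("target interval is empty")
    t_len = t_end - t_start
    confirmed = False
    extra: List[LossCall] = []
    for call in calls:
        if call.chrom != chrom:
            extra.append(call)
            continue
        overlap = min(call.end, t_end) - max(call.start, t_start)
        if overlap <= 0:
            extra.append(call)
        elif overlap >= min_overlap_frac * t_len:
            confirmed = True
    return ValidationResult(
        status="confirmed" if confirmed else "failed", extra=tuple(extra)
    )


def diagnostic_pcr(
    amplicon: Amplicon,
    allele: DeletionAllele,
    internal_primer_pos: Tuple[int, int],
    external_primer_pos: Tuple[int, int],
    strain_retains_wild_type: bool = False,
) -> str:
    """Predict the outcome of the diagnostic-PCR validation assay.

    Returns ``"invalid_design"`` unless the internal primer lies wholly
    inside the deleted interval and the external primer wholly outside
    (a primer overlapping the breakpoint is invalid).  With a valid design
    the deletion chromosome cannot template the product, so the assay
    reports ``"wild_type_present"`` iff the strain retains an intact copy
    of the target — the rare (<1%) failure mode that gets a strain
    discarded — and ``"wild_type_absent"`` otherwise.
    """
    allele.validate_against(amplicon)
    for name, (a, b) in (
        ("internal", internal_primer_pos),
        ("external", external_primer_pos),
    ):
        if not (0 <= a < b <= len(amplicon)):
            raise ConfigError(f"{name} primer [{a}, {b}) outside the amplicon")
    i_a, i_b = internal_primer_pos
    e_a, e_b = external_primer_pos
    internal_inside = allele.left <= i_a and i_b <= allele.right
    external_outside = e_b <= allele.left or e_a >= allele.right
    if not (internal_inside and external_outside):
        return "invalid_design"
    return "wild_type_present" if strain_retains_wild_type else "wild_type_absent"
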