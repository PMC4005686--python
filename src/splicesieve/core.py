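"""Core domain types shared across the pipeline.

A splice junction is identified in genome space by the intron it skips:
a half-open, 0-based interval ``[intron_start, intron_end)`` on a reference
sequence, optionally stranded. Reads that align across a junction carry an
N operation in their CIGAR string; the shorter of the two aligned arms is
the read's *overhang*, the minimal anchoring evidence on one side of the
splice site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

STRAND_UNKNOWN = "."
VALID_STRANDS = ("+", "-", STRAND_UNKNOWN)


@dataclass(frozen=True, order=True)
class JunctionKey:
    """Identity of a splice junction: the skipped intron as a half-open interval.

    ``intron_start`` is the 0-based first intronic base; ``intron_end`` is
    exclusive. Junctions with identical coordinates but different strands are
    distinct.
    """

    reference: str
    intron_start: int
    intron_end: int
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if self.intron_end <= self.intron_start:
            raise ValueError(
                f"intron_end ({self.intron_end}) must exceed intron_start "
                f"({self.intron_start})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class OverhangObservation:
    """One (read, junction) incidence: arm lengths and near-splice mismatches.

    ``mismatch_positions`` are 1-based distances from the splice site within
    the overhang (shorter) arm; position 1 is the base adjacent to the splice
    site. ``indel_near_junction`` marks observations where an insertion or
    deletion falls close to the splice site (excluded from evidence by
    default, since arm lengths are then ambiguous).
    """

    key: JunctionKey
    left_arm: int
    right_arm: int
    mismatch_positions: tuple[int, ...]
    indel_near_junction: bool = False
    mismatches_unknown: bool = False

    @property
    def overhang(self) -> int:
        return min(self.left_arm, self.right_arm)


@dataclass
class SplicedAlignmentRecord:
    """A parsed N-gapped alignment with its spanned junctions.

    ``arms`` holds per-junction (left_arm_len, right_arm_len) pairs of
    read-consuming lengths flanking each N gap; ``mismatch_read_offsets`` are
    0-based query offsets of reference mismatches (``None`` when the MD tag
    is absent but NM > 0, i.e. mismatch positions unknown).
    """

    read_id: str
    reference: str
    strand: str
    junctions: tuple[JunctionKey, ...]
    arms: tuple[tuple[int, int], ...]
    mismatch_read_offsets: Optional[tuple[int, ...]]
    n_hits: int
    read_length: int
    is_secondary: bool = False
    mapq: int = 0
    observations: tuple[OverhangObservation, ...] = ()


@dataclass
class JunctionEvidence:
    """Aggregate evidence for one junction from uniquely mapping reads.

    ``raw_overhangs`` is the multiset O_j of per-read overhangs o_i;
    ``trimmed_overhangs`` truncates each at its first mismatching position
    counted from the splice site. Reads with multiple reported alignment
    locations never contribute overhangs, only their ids (rescue candidates).
    """

    key: JunctionKey
    raw_overhangs: list[int] = field(default_factory=list)
    trimmed_overhangs: list[int] = field(default_factory=list)
    mismatch_positions: list[int] = field(default_factory=list)
    multiread_ids: set[str] = field(default_factory=set)
    max_read_length: int = 0

    @property
    def n_unique(self) -> int:
        return len(self.raw_overhangs)


class FPReason(str, enum.Enum):
    SINGLE_MISMATCH_RULE = "single-mismatch-rule"
    NO_MATCHING_OVERHANG = "no-matching-overhang"
    DEFAULT = "default"


@dataclass(frozen=True)
class FPLabel:
    """Semi-supervised class label: POTENTIAL_FP junctions patently violate
    the uniform-overhang expectation; everything else is PRESUMED_OK."""

    is_potential_fp: bool
    reason: FPReason = FPReason.DEFAULT

    def __post_init__(self) -> None:
        fp_reasons = (FPReason.SINGLE_MISMATCH_RULE, FPReason.NO_MATCHING_OVERHANG)
        if self.is_potential_fp != (self.reason in fp_reasons):
            raise ValueError(
                "reason must be single-mismatch-rule or no-matching-overhang "
                "iff the label is POTENTIAL_FP"
            )


POTENTIAL_FP_SINGLE_MISMATCH = FPLabel(True, FPReason.SINGLE_MISMATCH_RULE)
POTENTIAL_FP_NO_OVERHANG = FPLabel(True, FPReason.NO_MATCHING_OVERHANG)
PRESUMED_OK = FPLabel(False, FPReason.DEFAULT)


class Status(str, enum.Enum):
    ACCEPTED = "ACCEPTED"
    DISCARDED = "DISCARDED"
    AUTO_DISCARDED = "AUTO_DISCARDED"


@dataclass
class JunctionDecision:
    key: JunctionKey
    posterior_fp: float
    status: Status
    label: FPLabel

    @property
    def accepted(self) -> bool:
        return self.status == Status.ACCEPTED


@dataclass
class JunctionCall:
    """Final reported junction with read counts.

    ``unique_count`` counts uniquely mapping spanning reads;
    ``rescued_count`` counts multireads allocated to this junction after
    filtering left them a single surviving location.
    """

    key: JunctionKey
    unique_count: int
    rescued_count: int
    posterior_fp: float
    status: Status

    @property
    def total_count(self) -> int:
        return self.unique_count + self.rescued_count

    def __post_init__(self) -> None:
        if self.status != Status.ACCEPTED and self.rescued_count != 0:
            raise ValueError("rescued_count must be 0 for non-accepted junctions")


class ContractViolation(ValueError):
    """An operation was called outside its stated preconditions."""


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration."""
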