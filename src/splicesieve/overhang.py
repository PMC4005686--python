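"""The discrete-uniform overhang model and per-junction features.

Under random cDNA fragmentation, the overhang of a read across a true
junction — the shorter of its two aligned arms — is equally likely to take
any admissible length, i.e. discrete uniform on {o_min, ..., o_max} with
o_max = floor(read_length / 2) for equal-length reads. Junctions produced
by artefactual alignments violate this expectation: their reads pile up at
short overhangs, often sharing a recurrent mismatch position next to the
splice site.

Two devices exploit this. First, a labelling rule flags *potential false
positives*: junctions where every read stops at a single shared mismatch
position p* although, at the observed read count, at least one longer
overhang would be expected with high probability under uniformity — or
junctions with no matching overhang at all. Second, every junction gets a
feature vector of log2 deviations between observed and expected exceedance
counts (reads overhanging each position p), computed after trimming each
overhang at its first mismatching base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    ConfigurationError,
    ContractViolation,
    FPLabel,
    JunctionEvidence,
    POTENTIAL_FP_NO_OVERHANG,
    POTENTIAL_FP_SINGLE_MISMATCH,
    PRESUMED_OK,
)

DEFAULT_ALPHA = 0.99
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class OverhangSupport:
    """Support {o_min, ..., o_max} of the uniform overhang distribution."""

    o_max: int
    o_min: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.o_min <= self.o_max:
            raise ConfigurationError(
                f"require 1 <= o_min <= o_max, got o_min={self.o_min}, "
                f"o_max={self.o_max}"
            )

    @property
    def size(self) -> int:
        return self.o_max - self.o_min + 1

    def cdf(self, p: int) -> float:
        """P(O <= p) for O uniform on the support (0 below, 1 above)."""
        if p < self.o_min:
            return 0.0
        if p >= self.o_max:
            return 1.0
        return (p - self.o_min + 1) / self.size

    @classmethod
    def from_read_length(cls, read_length: int, o_min: int = 1) -> "OverhangSupport":
        return cls(o_max=max(read_length // 2, o_min), o_min=o_min)


@dataclass(frozen=True)
class FeatureVector:
    """Per-junction log2 deviations of observed from expected exceedance
    counts, indexed by position p = o_min ... o_max - 1."""

    x: np.ndarray
    n_reads: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.x)):
            raise ContractViolation("feature vector contains non-finite values")


def trim_overhang(raw_overhang: int, mismatch_positions: Sequence[int]) -> int:
    """Truncate an overhang at the first mismatching base from the splice site.

    ``mismatch_positions`` are 1-based distances within the overhang arm;
    a mismatch at position 1 leaves no matching overhang (0).
    """
    if raw_overhang < 1:
        raise ContractViolation(f"raw_overhang must be >= 1, got {raw_overhang}")
    if not mismatch_positions:
        return raw_overhang
    first = min(mismatch_positions)
    if not 1 <= first <= raw_overhang:
        raise ContractViolation(
            f"mismatch position {first} outside overhang arm [1, {raw_overhang}]"
        )
    return first - 1


def prob_exceed(p_star: int, n: int, support: OverhangSupport) -> float:
    """Probability that at least one of n uniform overhangs exceeds p_star.

    Under O_i iid uniform on {o_min..o_max}: 1 - F(p_star)^n, with F the
    uniform CDF. Monotone increasing in n, decreasing in p_star. This is the
    quantity compared against the labelling threshold: when it is high yet
    no overhang beyond p_star is observed, uniformity is patently violated.
    """
    if not support.o_min <= p_star <= support.o_max:
        raise ContractViolation(
            f"p_star={p_star} outside support [{support.o_min}, {support.o_max}]"
        )
    if n < 1:
        raise ContractViolation(f"n must be >= 1, got {n}")
    return 1.0 - support.cdf(p_star) ** n


def label_junction(
    evidence: JunctionEvidence,
    support: OverhangSupport,
    alpha: float = DEFAULT_ALPHA,
) -> FPLabel:
    """Label a junction POTENTIAL_FP or PRESUMED_OK.

    POTENTIAL_FP (single-mismatch-rule) requires: (i) mismatches occur at
    exactly one distinct position p* within the overhang arm across the
    junction's reads, (ii) no raw overhang exceeds p*, and (iii) the
    probability of seeing a longer overhang among n_unique uniform draws
    exceeds ``alpha``. POTENTIAL_FP (no-matching-overhang) requires every
    trimmed overhang to be 0. Everything else is PRESUMED_OK — assumed to be
    in vast majority proper mappings, label noise tolerated.
    """
    if evidence.n_unique < 1:
        raise ContractViolation(f"junction {evidence.key} has no unique reads")
    if evidence.trimmed_overhangs and all(t == 0 for t in evidence.trimmed_overhangs):
        return POTENTIAL_FP_NO_OVERHANG
    distinct = set(evidence.mismatch_positions)
    if len(distinct) == 1:
        (p_star,) = distinct
        p_star = min(p_star, support.o_max)
        if max(evidence.raw_overhangs) <= p_star:
            if prob_exceed(p_star, evidence.n_unique, support) > alpha:
                return POTENTIAL_FP_SINGLE_MISMATCH
    return PRESUMED_OK


def exceedance_counts(
    trimmed_overhangs: Iterable[int], support: OverhangSupport
) -> np.ndarray:
    """Observed C_p = #{reads with trimmed overhang > p}, p = o_min..o_max-1.

    Non-increasing in p by construction.
    """
    positions = np.arange(support.o_min, support.o_max)
    overhangs = np.asarray(list(trimmed_overhangs), dtype=int)
    if overhangs.size == 0:
        return np.zeros(positions.size, dtype=int)
    if overhangs.max() > support.o_max or overhangs.min() < 0:
        raise ContractViolation("trimmed overhang outside [0, o_max]")
    return (overhangs[None, :] > positions[:, None]).sum(axis=1)


def expected_exceedance(n: int, p: int, support: OverhangSupport) -> float:
    """Expected E_p = n * (o_max - p) / |support| under the uniform model."""
    if not support.o_min <= p <= support.o_max - 1:
        raise ContractViolation(
            f"p={p} outside feature range [{support.o_min}, {support.o_max - 1}]"
        )
    return n * (support.o_max - p) / support.size


def expected_exceedance_vector(n: int, support: OverhangSupport) -> np.ndarray:
    positions = np.arange(support.o_min, support.o_max)
    return n * (support.o_max - positions) / support.size


def build_feature_vector(
    evidence: JunctionEvidence,
    support: OverhangSupport,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FeatureVector:
    """x_p = log2((C_p + pseudocount) / (E_p + pseudocount)).

    The pseudocount keeps every entry finite (C_p = 0 is common beyond the
    observed overhang range) and leaves x_p = 0 wherever observation matches
    expectation. The index p = o_max is excluded: E_p vanishes there.
    """
    if pseudocount <= 0:
        raise ConfigurationError(f"pseudocount must be > 0, got {pseudocount}")
    if evidence.n_unique < 1:
        raise ContractViolation(f"junction {evidence.key} has no unique reads")
    c = exceedance_counts(evidence.trimmed_overhangs, support)
    e = expected_exceedance_vector(evidence.n_unique, support)
    x = np.log2((c + pseudocount) / (e + pseudocount))
    return FeatureVector(x=x, n_reads=evidence.n_unique)
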