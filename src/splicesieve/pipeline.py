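"""End-to-end junction filtering: evidence -> labels -> model -> rescue.

Single pass over the numbered procedure: aggregate overhang evidence from
unique gapped alignments, label the patently anomalous junctions, fit the
L1-logistic filter on labels vs. feature vectors, score and discard, then
rescue multireads left with a unique surviving location. Rescued counts do
not feed back into the fit.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .alignment_io import (
    DEFAULT_INDEL_EXCLUSION_BP,
    DEFAULT_MIN_MAPQ,
    MultireadLocations,
    ParseStats,
    collect_evidence,
)
from .classify import (
    DEFAULT_L1_C,
    DEFAULT_THRESHOLD,
    FilterModel,
    NoLabeledClassError,
    apply_filter,
    fit_filter_model,
)
from .core import (
    JunctionCall,
    JunctionDecision,
    JunctionEvidence,
    JunctionKey,
    PRESUMED_OK,
    Status,
)
from .overhang import (
    DEFAULT_ALPHA,
    DEFAULT_PSEUDOCOUNT,
    OverhangSupport,
    build_feature_vector,
    label_junction,
)
from .rescue import build_calls, rescue_multireads

logger = logging.getLogger(__name__)


class DataQualityError(RuntimeError):
    """The alignment data cannot support the semi-supervised scheme."""


@dataclass
class PipelineResult:
    calls: list[JunctionCall]
    decisions: dict[JunctionKey, JunctionDecision]
    evidence: dict[JunctionKey, JunctionEvidence]
    model: Optional[FilterModel]
    support: OverhangSupport
    rescued: dict[JunctionKey, int] = field(default_factory=dict)
    stats: Optional[ParseStats] = None

    @property
    def accepted_keys(self) -> set[JunctionKey]:
        return {c.key for c in self.calls if c.status == Status.ACCEPTED}

    def counts(self, accepted_only: bool = True) -> dict[JunctionKey, int]:
        return {
            c.key: c.total_count for c in self.calls
            if c.status == Status.ACCEPTED or not accepted_only
        }


def _modal_read_length(evidence: dict[JunctionKey, JunctionEvidence]) -> int:
    lengths = Counter(ev.max_read_length for ev in evidence.values()
                      if ev.max_read_length > 0)
    if not lengths:
        raise DataQualityError("no unique gapped alignments found")
    return lengths.most_common(1)[0][0]


def filter_junctions(
    evidence: dict[JunctionKey, JunctionEvidence],
    support: OverhangSupport,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    l1_strength: float = DEFAULT_L1_C,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 17,
    hard_labels: bool = False,
) -> tuple[dict[JunctionKey, JunctionDecision], Optional[FilterModel]]:
    """Label, fit and score all junctions with unique-read evidence.

    Junctions supported only by multireads cannot be evaluated and are
    auto-discarded. If no junction earns the POTENTIAL_FP label, no model is
    fitted and everything is accepted with posterior 0; if none is
    PRESUMED_OK the data are unusable and a DataQualityError is raised.
    """
    scored: dict[JunctionKey, tuple] = {}
    decisions: dict[JunctionKey, JunctionDecision] = {}
    for key in sorted(evidence):
        ev = evidence[key]
        if ev.n_unique == 0:
            decisions[key] = JunctionDecision(
                key=key, posterior_fp=1.0, status=Status.AUTO_DISCARDED,
                label=PRESUMED_OK)
            continue
        label = label_junction(ev, support, alpha=alpha)
        fv = build_feature_vector(ev, support, pseudocount=pseudocount)
        scored[key] = (fv, label)

    labels = [lab for (_fv, lab) in scored.values()]
    n_fp = sum(lab.is_potential_fp for lab in labels)
    n_ok = len(labels) - n_fp
    logger.info("labelled %d/%d junctions as potential false positives",
                n_fp, len(labels))
    if n_ok == 0 and n_fp > 0:
        raise DataQualityError(
            "every junction is labelled as a potential false positive; "
            "the alignment data look unusable"
        )
    model: Optional[FilterModel] = None
    if n_fp == 0:
        logger.warning(
            "no junction labelled as potential false positive: "
            "no filter model fitted, all %d junctions accepted", len(scored))
        for key, (_fv, label) in scored.items():
            decisions[key] = JunctionDecision(
                key=key, posterior_fp=0.0, status=Status.ACCEPTED, label=label)
        return decisions, model
    try:
        model = fit_filter_model(
            [fv for (fv, _lab) in scored.values()], labels,
            l1_strength=l1_strength, seed=seed)
    except NoLabeledClassError as exc:  # pragma: no cover - guarded above
        raise DataQualityError(str(exc)) from exc
    decisions.update(
        apply_filter(scored, model, threshold=threshold, hard_labels=hard_labels)
    )
    return decisions, model


def run_pipeline(
    alignment_path: str,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    o_min: int = 1,
    o_max: Optional[int] = None,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    l1_strength: float = DEFAULT_L1_C,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 17,
    hard_labels: bool = False,
    collapse_pairs: bool = False,
    indel_exclusion_bp: int = DEFAULT_INDEL_EXCLUSION_BP,
) -> PipelineResult:
    """Run the full filter on a SAM/BAM file of spliced alignments."""
    stats = ParseStats()
    evidence, multireads = collect_evidence(
        alignment_path, min_mapq=min_mapq,
        indel_exclusion_bp=indel_exclusion_bp,
        collapse_pairs=collapse_pairs, stats=stats)
    if o_max is None:
        support = OverhangSupport.from_read_length(
            _modal_read_length(evidence), o_min=o_min)
    else:
        support = OverhangSupport(o_max=o_max, o_min=o_min)
    decisions, model = filter_junctions(
        evidence, support, alpha=alpha, pseudocount=pseudocount,
        l1_strength=l1_strength, threshold=threshold, seed=seed,
        hard_labels=hard_labels)
    rescued = rescue_multireads(multireads, decisions)
    unique_counts = {key: ev.n_unique for key, ev in evidence.items()}
    calls = build_calls(decisions, unique_counts, rescued)
    # drop accepted junctions with no reads at all (cannot happen for unique
    # evidence, but keeps the reported-call invariant total_count >= 1)
    calls = [c for c in calls if c.status != Status.ACCEPTED or c.total_count >= 1]
    return PipelineResult(
        calls=calls, decisions=decisions, evidence=evidence, model=model,
        support=support, rescued=rescued, stats=stats)
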