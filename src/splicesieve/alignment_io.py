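"""Parsing of spliced (N-gapped) SAM/BAM alignments into junction evidence.

Reads are consumed through pysam. Only alignments whose CIGAR contains an N
(skipped reference) operation describe splice junctions; each N gap yields
one junction, flanked by a left and a right arm whose lengths are the
read-consuming lengths of the adjacent aligned segments. Mismatch offsets
are recovered from the MD tag via pysam's reconstructed reference sequence,
so no genome FASTA is needed.

Uniqueness follows the NH tag (NH=1); when NH is absent, a MAPQ threshold
stands in (TopHat2 reports unique hits at MAPQ 50). Reads reported at
multiple locations contribute no overhang evidence but are indexed as
rescue candidates together with all their alignment locations, including
ungapped ones — a multiread whose alternative location is a contiguous
genomic hit can never be rescued to a junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

import pysam

from .core import (
    ContractViolation,
    JunctionEvidence,
    JunctionKey,
    OverhangObservation,
    SplicedAlignmentRecord,
    STRAND_UNKNOWN,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 50
DEFAULT_INDEL_EXCLUSION_BP = 3

_READ_CONSUMING = {0, 1, 4, 7, 8}  # M, I, S, =, X
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X


class MalformedRecordError(ValueError):
    """Per-record parse failure (bad CIGAR/MD); the record is skipped."""


@dataclass
class MultireadLocations:
    """All observed alignment locations of one multiply-mapping read.

    ``gapped`` holds the junction set of each N-gapped alignment;
    ``n_ungapped`` counts contiguous (junction-free) alignments, which block
    rescue because they remain valid candidate locations after junction
    filtering. ``n_hits`` is the NH value reported by the aligner.
    """

    gapped: list[frozenset[JunctionKey]] = field(default_factory=list)
    n_ungapped: int = 0
    n_hits: int = 0

    @property
    def n_observed(self) -> int:
        return len(self.gapped) + self.n_ungapped


@dataclass
class ParseStats:
    n_records: int = 0
    n_gapped: int = 0
    n_skipped_malformed: int = 0
    n_mismatch_unknown: int = 0


def _segment_structure(aln: pysam.AlignedSegment):
    """Split an aligned read at N gaps.

    Returns a list of segments, one per exonic block, as dicts with the
    read-consuming length, query span [qstart, qend), reference end points,
    and query positions of I/D ops (for indel-proximity checks).
    """
    segments = []
    cur = {"arm": 0, "qstart": None, "qend": None, "ref_start": None,
           "ref_end": None, "indels": []}
    qpos = 0
    rpos = aln.reference_start
    for op, length in aln.cigartuples:
        if op == 3:  # N: close current segment
            if cur["arm"] == 0:
                raise MalformedRecordError("N gap with empty flanking segment")
            segments.append(cur)
            rpos += length
            cur = {"arm": 0, "qstart": None, "qend": None, "ref_start": None,
                   "ref_end": None, "indels": []}
            continue
        if op in (0, 7, 8):  # M, =, X
            if cur["qstart"] is None:
                cur["qstart"] = qpos
                cur["ref_start"] = rpos
            cur["arm"] += length
            qpos += length
            rpos += length
            cur["qend"] = qpos
            cur["ref_end"] = rpos
        elif op == 1:  # I: read-consuming, counts toward arm length
            if cur["qstart"] is not None:
                cur["arm"] += length
                cur["indels"].append(qpos)
            qpos += length
            cur["qend"] = qpos if cur["qstart"] is not None else cur["qend"]
        elif op == 2:  # D: reference-consuming only
            if cur["qstart"] is None:
                raise MalformedRecordError("deletion before first aligned base")
            cur["indels"].append(qpos)
            rpos += length
            cur["ref_end"] = rpos
        elif op == 4:  # S
            qpos += length
        elif op == 5 or op == 6:  # H, P
            continue
        else:
            raise MalformedRecordError(f"unsupported CIGAR op {op}")
    if cur["arm"] == 0:
        raise MalformedRecordError("trailing N gap with empty segment")
    segments.append(cur)
    return segments


def _mismatch_offsets(aln: pysam.AlignedSegment) -> tuple[Optional[tuple[int, ...]], bool]:
    """Recover 0-based query offsets of substitutions from the MD tag.

    Returns (offsets, unknown). MD absent with NM=0 means no mismatches;
    MD absent with NM>0 means the positions cannot be recovered.
    """
    if aln.has_tag("MD"):
        try:
            pairs = aln.get_aligned_pairs(with_seq=True)
        except (ValueError, TypeError) as exc:
            raise MalformedRecordError(f"cannot resolve MD tag: {exc}") from exc
        offsets = tuple(
            q for q, _r, s in pairs
            if q is not None and s is not None and s.islower()
        )
        return offsets, False
    nm = aln.get_tag("NM") if aln.has_tag("NM") else None
    if nm == 0:
        return (), False
    return None, True


def _strand(aln: pysam.AlignedSegment) -> str:
    if aln.has_tag("XS"):
        xs = aln.get_tag("XS")
        if xs in ("+", "-"):
            return xs
    return STRAND_UNKNOWN


def _n_hits(aln: pysam.AlignedSegment, min_mapq: int) -> int:
    if aln.has_tag("NH"):
        return int(aln.get_tag("NH"))
    # NH absent: fall back on MAPQ to decide uniqueness
    return 1 if aln.mapping_quality >= min_mapq else 2


def parse_record(
    aln: pysam.AlignedSegment,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    indel_exclusion_bp: int = DEFAULT_INDEL_EXCLUSION_BP,
) -> Optional[SplicedAlignmentRecord]:
    """Parse one pysam record into a SplicedAlignmentRecord, or None if it
    spans no junction (unmapped, supplementary, or ungapped)."""
    if aln.is_unmapped or aln.is_supplementary or aln.cigartuples is None:
        return None
    if not any(op == 3 for op, _ in aln.cigartuples):
        return None

    segments = _segment_structure(aln)
    strand = _strand(aln)
    reference = aln.reference_name
    offsets, unknown = _mismatch_offsets(aln)

    junctions = []
    arms = []
    observations = []
    for left, right in zip(segments, segments[1:]):
        key = JunctionKey(reference, left["ref_end"], right["ref_start"], strand)
        l_arm, r_arm = left["arm"], right["arm"]
        junctions.append(key)
        arms.append((l_arm, r_arm))

        # indel within `indel_exclusion_bp` of the splice site, in read coords
        near_indel = any(
            left["qend"] - q <= indel_exclusion_bp for q in left["indels"]
        ) or any(
            q - right["qstart"] < indel_exclusion_bp for q in right["indels"]
        )

        # mismatch positions within the overhang (shorter) arm, 1-based from
        # the splice site; ties resolve to the left arm
        positions: tuple[int, ...] = ()
        if offsets:
            if l_arm <= r_arm:
                qs, qe = left["qstart"], left["qend"]
                positions = tuple(sorted(qe - q for q in offsets if qs <= q < qe))
            else:
                qs, qe = right["qstart"], right["qend"]
                positions = tuple(sorted(q - qs + 1 for q in offsets if qs <= q < qe))
        observations.append(
            OverhangObservation(
                key=key,
                left_arm=l_arm,
                right_arm=r_arm,
                mismatch_positions=positions,
                indel_near_junction=near_indel,
                mismatches_unknown=unknown,
            )
        )

    return SplicedAlignmentRecord(
        read_id=read_key(aln),
        reference=reference,
        strand=strand,
        junctions=tuple(junctions),
        arms=tuple(arms),
        mismatch_read_offsets=offsets,
        n_hits=_n_hits(aln, min_mapq),
        read_length=aln.infer_read_length() or aln.query_length,
        is_secondary=aln.is_secondary,
        mapq=aln.mapping_quality,
        observations=tuple(observations),
    )


def read_key(aln: pysam.AlignedSegment) -> str:
    """Identity of one sequenced read; paired-end mates are distinct
    observations, so the mate flag is folded into the key."""
    if aln.is_read1:
        return aln.query_name + "/1"
    if aln.is_read2:
        return aln.query_name + "/2"
    return aln.query_name


def parse_spliced_alignments(
    alignments: Iterable[pysam.AlignedSegment],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    indel_exclusion_bp: int = DEFAULT_INDEL_EXCLUSION_BP,
    stats: Optional[ParseStats] = None,
) -> Iterator[SplicedAlignmentRecord]:
    """Stream SplicedAlignmentRecords from an iterable of pysam records.

    Records without an N operation are skipped; malformed records are
    counted, logged with their read id and skipped.
    """
    for aln in alignments:
        if stats is not None:
            stats.n_records += 1
        try:
            rec = parse_record(aln, min_mapq=min_mapq,
                               indel_exclusion_bp=indel_exclusion_bp)
        except MalformedRecordError as exc:
            logger.warning("skipping malformed record %s: %s", aln.query_name, exc)
            if stats is not None:
                stats.n_skipped_malformed += 1
            continue
        if rec is None:
            continue
        if stats is not None:
            stats.n_gapped += 1
            if rec.mismatch_read_offsets is None:
                stats.n_mismatch_unknown += 1
        yield rec


def aggregate_evidence(
    records: Iterable[SplicedAlignmentRecord],
    collapse_pairs: bool = False,
) -> dict[JunctionKey, JunctionEvidence]:
    """Aggregate parsed records into per-junction evidence.

    Only uniquely mapping reads (n_hits == 1, primary) contribute overhangs;
    multireads contribute their ids to every junction they span. A read
    spanning k junctions contributes one independent overhang to each.
    """
    from .overhang import trim_overhang

    evidence: dict[JunctionKey, JunctionEvidence] = {}
    seen_pairs: set[tuple[str, JunctionKey]] = set()
    for rec in records:
        for obs in rec.observations:
            if obs.indel_near_junction:
                continue
            ev = evidence.setdefault(obs.key, JunctionEvidence(key=obs.key))
            if rec.n_hits > 1 or rec.is_secondary:
                ev.multiread_ids.add(rec.read_id)
                continue
            if collapse_pairs:
                base_id = rec.read_id.rsplit("/", 1)[0]
                pair_key = (base_id, obs.key)
                if pair_key in seen_pairs:
                    continue
                seen_pairs.add(pair_key)
            raw = obs.overhang
            if raw < 1:
                raise ContractViolation(
                    f"read {rec.read_id}: zero-length arm at {obs.key}"
                )
            ev.raw_overhangs.append(raw)
            ev.trimmed_overhangs.append(trim_overhang(raw, obs.mismatch_positions))
            ev.mismatch_positions.extend(obs.mismatch_positions)
            ev.max_read_length = max(ev.max_read_length, rec.read_length)
    return evidence


def collect_evidence(
    path: Union[str, "pysam.AlignmentFile"],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    indel_exclusion_bp: int = DEFAULT_INDEL_EXCLUSION_BP,
    collapse_pairs: bool = False,
    stats: Optional[ParseStats] = None,
) -> tuple[dict[JunctionKey, JunctionEvidence], dict[str, MultireadLocations]]:
    """Single pass over a SAM/BAM file: junction evidence plus the multiread
    location index needed for rescue.

    Unlike :func:`parse_spliced_alignments`, this also observes *ungapped*
    alignments of multireads, which make a read ineligible for rescue.
    """
    own_handle = isinstance(path, str)
    af = pysam.AlignmentFile(path, check_sq=False) if own_handle else path
    evidence: dict[JunctionKey, JunctionEvidence] = {}
    multireads: dict[str, MultireadLocations] = {}

    def _records():
        for aln in af:
            if aln.is_unmapped or aln.is_supplementary:
                continue
            nh = _n_hits(aln, min_mapq)
            gapped = aln.cigartuples is not None and any(
                op == 3 for op, _ in aln.cigartuples
            )
            if nh > 1 and not gapped:
                loc = multireads.setdefault(read_key(aln), MultireadLocations())
                loc.n_ungapped += 1
                loc.n_hits = max(loc.n_hits, nh)
                continue
            yield aln

    records = list(parse_spliced_alignments(
        _records(), min_mapq=min_mapq,
        indel_exclusion_bp=indel_exclusion_bp, stats=stats))
    evidence = aggregate_evidence(records, collapse_pairs=collapse_pairs)
    for rec in records:
        if rec.n_hits > 1 or rec.is_secondary:
            loc = multireads.setdefault(rec.read_id, MultireadLocations())
            loc.gapped.append(frozenset(rec.junctions))
            loc.n_hits = max(loc.n_hits, rec.n_hits)
    if own_handle:
        af.close()
    return evidence, multireads
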