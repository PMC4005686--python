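"""Multiread rescue and final junction call output.

After filtering, a multiply-mapping read may be left with a single
surviving alignment location: every junction of exactly one of its gapped
alignments is accepted, all its other gapped alignments contain a discarded
junction, and it has no contiguous (ungapped) alignment that would keep its
location ambiguous. Such reads are allocated to the surviving location,
incrementing each junction that alignment spans; every other multiread
contributes nothing. A read is rescued at most once, so total counts remain
conservative: unique incidences plus rescued reads, nothing double-counted.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Union

from .alignment_io import MultireadLocations
from .core import (
    ContractViolation,
    JunctionCall,
    JunctionDecision,
    JunctionKey,
    Status,
)

LocationsLike = Union[MultireadLocations, Iterable[JunctionKey]]


def _normalize(locations: LocationsLike) -> MultireadLocations:
    if isinstance(locations, MultireadLocations):
        return locations
    # a bare collection of junction keys: one single-junction alignment each
    gapped = [frozenset([k]) for k in locations]
    return MultireadLocations(gapped=gapped, n_ungapped=0, n_hits=len(gapped))


def rescue_multireads(
    multiread_index: Mapping[str, LocationsLike],
    decisions: Mapping[JunctionKey, JunctionDecision],
) -> dict[JunctionKey, int]:
    """Count increments per junction from rescued multireads.

    A read is rescued iff exactly one of its gapped alignments has all its
    junctions accepted, no other candidate location survives (including
    ungapped alignments, which always survive junction filtering), and all
    of its reported hits were observed (n_hits matches the locations seen).
    """
    increments: dict[JunctionKey, int] = {}
    for read_id, raw in multiread_index.items():
        loc = _normalize(raw)
        for aln in loc.gapped:
            for key in aln:
                if key not in decisions:
                    raise ContractViolation(
                        f"multiread {read_id} references junction {key} "
                        "with no decision"
                    )
        if loc.n_ungapped > 0:
            continue
        if loc.n_hits > loc.n_observed:
            # some reported alignment was not seen; location stays ambiguous
            continue
        surviving = [
            aln for aln in loc.gapped
            if all(decisions[k].status == Status.ACCEPTED for k in aln)
        ]
        if len(surviving) != 1:
            continue
        for key in surviving[0]:
            increments[key] = increments.get(key, 0) + 1
    return increments


def build_calls(
    decisions: Mapping[JunctionKey, JunctionDecision],
    unique_counts: Mapping[JunctionKey, int],
    rescued: Mapping[JunctionKey, int],
) -> list[JunctionCall]:
    """Assemble final calls, sorted by (reference, intron_start, intron_end)."""
    calls = []
    for key in sorted(decisions):
        dec = decisions[key]
        accepted = dec.status == Status.ACCEPTED
        calls.append(
            JunctionCall(
                key=key,
                unique_count=unique_counts.get(key, 0),
                rescued_count=rescued.get(key, 0) if accepted else 0,
                posterior_fp=dec.posterior_fp,
                status=dec.status if accepted else Status.DISCARDED,
            )
        )
    return calls


TSV_COLUMNS = (
    "reference\tintron_start\tintron_end\tstrand\tunique_count\t"
    "rescued_count\ttotal_count\tposterior_fp\tstatus"
)


def write_junction_calls(
    calls: Iterable[JunctionCall],
    path: str,
    format: str = "tsv",
    report_discarded: bool = False,
) -> None:
    """Write junction calls as TSV (full dialect) or BED6.

    Coordinates are the 0-based half-open intron interval. By default only
    accepted junctions are reported; ``report_discarded`` adds the rest with
    their status. BED scores are read counts capped at 1000.
    """
    ordered = sorted(
        (c for c in calls if report_discarded or c.status == Status.ACCEPTED),
        key=lambda c: (c.key.reference, c.key.intron_start, c.key.intron_end),
    )
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(TSV_COLUMNS + "\n")
            for c in ordered:
                k = c.key
                fh.write(
                    f"{k.reference}\t{k.intron_start}\t{k.intron_end}\t"
                    f"{k.strand}\t{c.unique_count}\t{c.rescued_count}\t"
                    f"{c.total_count}\t{c.posterior_fp:.6g}\t{c.status.value}\n"
                )
    elif format == "bed":
        with open(path, "w") as fh:
            for i, c in enumerate(ordered):
                k = c.key
                score = min(c.total_count, 1000)
                fh.write(
                    f"{k.reference}\t{k.intron_start}\t{k.intron_end}\t"
                    f"JUNC{i:08d}\t{score}\t{k.strand}\n"
                )
    else:
        raise ValueError(f"unknown output format {format!r}")


def read_junction_calls(path: str) -> list[JunctionCall]:
    """Read back a TSV produced by :func:`write_junction_calls`."""
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != TSV_COLUMNS:
            raise ValueError(f"unexpected header in {path}")
        for line in fh:
            ref, s, e, strand, u, r, _t, post, status = line.rstrip("\n").split("\t")
            calls.append(
                JunctionCall(
                    key=JunctionKey(ref, int(s), int(e), strand),
                    unique_count=int(u),
                    rescued_count=int(r),
                    posterior_fp=float(post),
                    status=Status(status),
                )
            )
    return calls
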