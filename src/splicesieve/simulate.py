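"""Synthetic spliced-alignment generator with ground truth.

Emulates the statistical structure the filter assumes, over fictitious
references (no genome sequence is needed — MD tags are synthesized
directly):

* *expressed* junctions receive reads whose overhangs are discrete-uniform
  over all admissible lengths {1..floor(L/2)}, with independent per-base
  background mismatches;
* *artefactual* junctions receive reads with systematically short overhangs
  and a recurrent mismatch position p adjacent to the splice site:
  overhangs are uniform on {1..p}, every read reaching position p mismatches
  there, and one such read is guaranteed per junction;
* a configurable fraction of expressed-junction reads is additionally given
  a second alignment across an artefactual junction (NH=2, secondary),
  providing rescue material.

Per-junction read counts are 1 + Poisson(mean - 1), so every simulated
junction is detectable. Output is coordinate-sorted SAM plus a truth table;
both are byte-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pysam

from .core import ConfigurationError, JunctionKey

BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic alignment world.

    Defaults describe a 50 bp single-end experiment with a 10:1 ratio of
    expressed to artefactual junctions, artefact overhangs capped at 4 bp,
    and 10% multireads — the regime in which the filter is meant to operate.
    """

    n_true_junctions: int = 2000
    n_fp_junctions: int = 200
    read_length: int = 50
    mean_reads_per_junction: float = 20.0
    background_mismatch_rate: float = 0.002
    fp_max_overhang: int = 4
    fp_mismatch_position: Union[int, str] = "random-per-junction"
    fraction_multireads: float = 0.1
    seed: int = 17
    n_references: int = 5
    reference_length: int = 1_000_000
    min_intron: int = 100
    max_intron: int = 10_000

    def __post_init__(self) -> None:
        if self.fp_max_overhang >= self.read_length // 2:
            raise ConfigurationError(
                "fp_max_overhang must be smaller than floor(read_length/2)"
            )
        for name in ("background_mismatch_rate", "fraction_multireads"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if isinstance(self.fp_mismatch_position, int):
            if self.fp_mismatch_position > self.fp_max_overhang + 1:
                raise ConfigurationError(
                    "fp_mismatch_position cannot exceed fp_max_overhang + 1"
                )
            if self.fp_mismatch_position < 1:
                raise ConfigurationError("fp_mismatch_position must be >= 1")
        elif self.fp_mismatch_position != "random-per-junction":
            raise ConfigurationError(
                "fp_mismatch_position must be an int or 'random-per-junction'"
            )
        if self.mean_reads_per_junction < 1:
            raise ConfigurationError("mean_reads_per_junction must be >= 1")


@dataclass
class TruthTable:
    """Ground truth: expressed junctions with true counts, plus the
    artefactual junction set. The two sets are disjoint."""

    expressed: dict[JunctionKey, int] = field(default_factory=dict)
    artefactual: set[JunctionKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.expressed) & self.artefactual
        if overlap:
            raise ValueError(f"junctions both expressed and artefactual: {overlap}")


def write_truth_table(truth: TruthTable, path: str,
                      artefact_counts: Optional[dict[JunctionKey, int]] = None) -> None:
    with open(path, "w") as fh:
        fh.write("reference\tintron_start\tintron_end\tstrand\tclass\ttrue_count\n")
        rows = [(k, "expressed", c) for k, c in truth.expressed.items()]
        rows += [(k, "artefactual", (artefact_counts or {}).get(k, 0))
                 for k in truth.artefactual]
        for k, cls, count in sorted(rows, key=lambda r: (r[0].reference,
                                                         r[0].intron_start,
                                                         r[0].intron_end)):
            fh.write(f"{k.reference}\t{k.intron_start}\t{k.intron_end}\t"
                     f"{k.strand}\t{cls}\t{count}\n")


def read_truth_table(path: str) -> TruthTable:
    truth = TruthTable()
    with open(path) as fh:
        fh.readline()
        for line in fh:
            ref, s, e, strand, cls, count = line.rstrip("\n").split("\t")
            key = JunctionKey(ref, int(s), int(e), strand)
            if cls == "expressed":
                truth.expressed[key] = int(count)
            else:
                truth.artefactual.add(key)
    return truth


def _draw_junctions(rng: np.random.Generator, n: int, config: SimulationConfig,
                    taken: set[JunctionKey]) -> list[JunctionKey]:
    keys = []
    margin = config.read_length + 1
    while len(keys) < n:
        ref = f"contig{int(rng.integers(config.n_references)) + 1}"
        intron_len = int(rng.integers(config.min_intron, config.max_intron + 1))
        start = int(rng.integers(margin,
                                 config.reference_length - intron_len - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        key = JunctionKey(ref, start, start + intron_len, strand)
        if key in taken:
            continue
        taken.add(key)
        keys.append(key)
    return keys


def _md_and_nm(aligned_len: int, mismatch_offsets: list[int],
               seq: str, rng: np.random.Generator) -> tuple[str, int]:
    """Synthesize an MD tag for a gapless-in-read alignment (M/N only):
    the MD walk concatenates matched lengths across N gaps."""
    parts = []
    prev = 0
    for off in sorted(mismatch_offsets):
        parts.append(str(off - prev))
        read_base = seq[off]
        choices = [b for b in BASES if b != read_base]
        parts.append(choices[int(rng.integers(3))])
        prev = off + 1
    parts.append(str(aligned_len - prev))
    return "".join(parts), len(mismatch_offsets)


def _make_segment(header: pysam.AlignmentHeader, name: str, key: JunctionKey,
                  left_arm: int, right_arm: int, mismatch_offsets: list[int],
                  nh: int, secondary: bool, rng: np.random.Generator,
                  ) -> pysam.AlignedSegment:
    read_len = left_arm + right_arm
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = header.get_tid(key.reference)
    a.reference_start = key.intron_start - left_arm
    intron_len = key.intron_end - key.intron_start
    a.cigarstring = f"{left_arm}M{intron_len}N{right_arm}M"
    a.flag = 0x100 if secondary else 0
    a.mapping_quality = 0 if nh > 1 else 50
    seq = "".join(BASES[i] for i in rng.integers(0, 4, size=read_len))
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
    md, nm = _md_and_nm(read_len, mismatch_offsets, seq, rng)
    a.set_tags([("NH", nh), ("NM", nm), ("MD", md), ("XS", key.strand)])
    return a


def _arm_split(overhang: int, read_len: int, rng: np.random.Generator
               ) -> tuple[int, int]:
    """Place the short arm left or right with equal probability."""
    if rng.random() < 0.5:
        return overhang, read_len - overhang
    return read_len - overhang, overhang


def _offsets_in_overhang_arm(left_arm: int, right_arm: int, position: int) -> int:
    """Query offset of the base at 1-based distance `position` from the
    splice site within the shorter arm (ties resolve left)."""
    if left_arm <= right_arm:
        return left_arm - position
    return left_arm + position - 1


def simulate_dataset(config: SimulationConfig, sam_path: str,
                     truth_path: Optional[str] = None) -> TruthTable:
    """Generate a coordinate-sorted SAM file and its truth table.

    Returns the TruthTable; writes it as TSV when ``truth_path`` is given.
    """
    rng = np.random.default_rng(config.seed)
    L = config.read_length
    o_max = L // 2
    taken: set[JunctionKey] = set()
    true_keys = _draw_junctions(rng, config.n_true_junctions, config, taken)
    fp_keys = _draw_junctions(rng, config.n_fp_junctions, config, taken)

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": f"contig{i + 1}", "LN": config.reference_length}
               for i in range(config.n_references)],
    })

    records: list[pysam.AlignedSegment] = []
    truth = TruthTable()
    artefact_counts: dict[JunctionKey, int] = {}

    # anomaly position per artefactual junction
    fp_positions: dict[JunctionKey, int] = {}
    for key in fp_keys:
        if config.fp_mismatch_position == "random-per-junction":
            fp_positions[key] = int(rng.integers(1, config.fp_max_overhang + 1))
        else:
            fp_positions[key] = int(config.fp_mismatch_position)

    def fp_read(key: JunctionKey, force_anomaly: bool) -> tuple[int, int, list[int]]:
        """Overhang arm split and mismatch offsets for an artefactual read."""
        p = fp_positions[key]
        cap = min(config.fp_max_overhang, p)
        o = cap if force_anomaly else int(rng.integers(1, cap + 1))
        la, ra = _arm_split(o, L, rng)
        offsets = []
        if p <= o:
            offsets.append(_offsets_in_overhang_arm(la, ra, p))
        # background mismatches confined to the long arm keep the anomaly's
        # single-position signature intact
        long_lo, long_hi = (la, L) if la <= ra else (0, la)
        for q in range(long_lo, long_hi):
            if rng.random() < config.background_mismatch_rate:
                offsets.append(q)
        return la, ra, sorted(set(offsets))

    n_multi = 0
    for j, key in enumerate(true_keys):
        n_reads = 1 + int(rng.poisson(config.mean_reads_per_junction - 1))
        truth.expressed[key] = n_reads
        for i in range(n_reads):
            name = f"t{j:05d}r{i:04d}"
            o = int(rng.integers(1, o_max + 1))
            la, ra = _arm_split(o, L, rng)
            offsets = sorted(
                q for q in range(L)
                if rng.random() < config.background_mismatch_rate
            )
            multi = (config.fraction_multireads > 0 and fp_keys
                     and rng.random() < config.fraction_multireads)
            nh = 2 if multi else 1
            records.append(_make_segment(header, name, key, la, ra, offsets,
                                         nh, False, rng))
            if multi:
                n_multi += 1
                alt = fp_keys[int(rng.integers(len(fp_keys)))]
                a_la, a_ra, a_off = fp_read(alt, force_anomaly=False)
                records.append(_make_segment(header, name, alt, a_la, a_ra,
                                             a_off, nh, True, rng))

    for j, key in enumerate(fp_keys):
        n_reads = 1 + int(rng.poisson(config.mean_reads_per_junction - 1))
        truth.artefactual.add(key)
        artefact_counts[key] = n_reads
        for i in range(n_reads):
            name = f"f{j:05d}r{i:04d}"
            la, ra, offsets = fp_read(key, force_anomaly=(i == 0))
            records.append(_make_segment(header, name, key, la, ra, offsets,
                                         1, False, rng))

    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name,
                                bool(r.flag & 0x100)))
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for rec in records:
            out.write(rec)

    if truth_path is not None:
        write_truth_table(truth, truth_path, artefact_counts)
    return truth
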