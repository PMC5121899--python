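"""Per-arm read counting, RPM normalisation and the knockdown filters.

Reads are assigned to a precursor arm when their 5' end lies within a small
tolerance of the arm's annotated 5' end (isomiR wobble) and the read is
fully contained in the precursor extended by the same tolerance.  Counts
are library-size normalised to reads per million mapped reads (RPM), and
the control vs Dicer-depleted contrast is summarised as
``log2((mean depleted RPM + pc) / (mean control RPM + pc))`` with a small
pseudocount so a fully silenced arm stays finite.  Negative-control regions
(short, well-covered, miRNA-free stretches of genome) provide the baseline
showing that the depletion signal is not a normalisation artefact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import (
    CONTROL,
    DICER_DEPLETED,
    ConfigurationError,
    ContractError,
    GenomeSequence,
    Library,
    Locus,
    MiRNACandidate,
    ReadRecord,
    extract_locus_sequence,
    reverse_complement,
)

_INDEX_K = 16  # collapsed reads are >=16 nt, so a 16-mer prefix always exists


@dataclass(frozen=True)
class ArmExpression:
    """Per-library read counts and RPM for one arm of one candidate."""

    candidate_id: str
    arm: str
    counts: Mapping[str, int]
    rpm: Mapping[str, float]

    def total(self, library_ids: Iterable[str] | None = None) -> int:
        ids = self.counts.keys() if library_ids is None else library_ids
        return sum(self.counts[i] for i in ids)


@dataclass(frozen=True)
class FoldChange:
    """Control vs Dicer-depleted log2 fold change for one feature/arm."""

    candidate_id: str
    arm: str
    log2fc: float
    mean_control_rpm: float
    mean_depleted_rpm: float


def make_arm_expression(
    candidate_id: str,
    arm: str,
    counts: Mapping[str, int],
    libraries: Sequence[Library],
) -> ArmExpression:
    totals = {lib.id: lib.total_mapped_reads for lib in libraries}
    rpm = {
        lid: (c * 1e6 / totals[lid] if totals[lid] > 0 else 0.0)
        for lid, c in counts.items()
    }
    return ArmExpression(candidate_id, arm, dict(counts), rpm)


def _offset_order(tolerance: int) -> list[int]:
    """Offsets by increasing distance from the annotated 5' end (0, 1, -1...)."""
    return sorted(range(-tolerance, tolerance + 1), key=lambda o: (abs(o), -o))


def _extended_precursor(
    candidate: MiRNACandidate,
    tolerance: int,
    genome: Mapping[str, GenomeSequence] | None,
) -> tuple[str, int]:
    """Precursor sequence padded by ``tolerance`` nt (transcript space).

    Returns (sequence, offset of the precursor start within it).  Without a
    genome the bare precursor is used (no padding available).
    """
    if genome is None or tolerance == 0:
        return candidate.precursor_seq, 0
    p = candidate.precursor_locus
    contig = genome[p.seq_id]
    start = max(0, p.start - tolerance)
    end = min(len(contig), p.end + tolerance)
    ext = extract_locus_sequence(genome, Locus(p.seq_id, start, end, p.strand))
    lead = p.start - start if p.strand == "+" else end - p.end
    return ext, lead


def _match_reads_to_arm(
    seq_counts: Mapping[str, int],
    ext_seq: str,
    arm_start_ext: int,
    tolerance: int,
) -> tuple[int, dict[int, int]]:
    """Total count and per-5'-offset histogram of reads matching one arm."""
    total = 0
    by_offset: dict[int, int] = {}
    assigned: set[str] = set()
    for off in _offset_order(tolerance):
        start = arm_start_ext + off
        if start < 0:
            continue
        for read_len in range(16, 31):
            end = start + read_len
            if end > len(ext_seq):
                break
            sub = ext_seq[start:end]
            if sub in assigned:
                continue
            c = seq_counts.get(sub)
            if c:
                total += c
                by_offset[off] = by_offset.get(off, 0) + c
                assigned.add(sub)
    return total, by_offset


def _library_seq_counts(reads: Iterable[ReadRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in reads:
        counts[r.sequence] = counts.get(r.sequence, 0) + r.count
    return counts


def count_arm_reads(
    reads_by_library: Mapping[str, Sequence[ReadRecord]],
    libraries: Sequence[Library],
    candidate: MiRNACandidate,
    tolerance: int = 2,
    genome: Mapping[str, GenomeSequence] | None = None,
) -> tuple[ArmExpression, ArmExpression]:
    """Count collapsed reads on the 5p and 3p arms of a candidate.

    Returns the (5p, 3p) :class:`ArmExpression` pair with counts and RPM for
    every library in ``reads_by_library``.
    """
    ext_seq, lead = _extended_precursor(candidate, tolerance, genome)
    out = []
    for arm in ("5p", "3p"):
        arm_start, _ = candidate.arm_interval(arm)
        counts: dict[str, int] = {}
        for lib in libraries:
            seq_counts = _library_seq_counts(reads_by_library.get(lib.id, ()))
            total, _hist = _match_reads_to_arm(
                seq_counts, ext_seq, arm_start + lead, tolerance
            )
            counts[lib.id] = total
        out.append(make_arm_expression(candidate.id, arm, counts, libraries))
    return out[0], out[1]


def arm_offset_histogram(
    reads_by_library: Mapping[str, Sequence[ReadRecord]],
    candidate: MiRNACandidate,
    arm: str,
    tolerance: int = 2,
    genome: Mapping[str, GenomeSequence] | None = None,
    library_ids: Iterable[str] | None = None,
) -> dict[int, int]:
    """Histogram of read 5'-end offsets (relative to the arm 5' end)."""
    ext_seq, lead = _extended_precursor(candidate, tolerance, genome)
    arm_start, _ = candidate.arm_interval(arm)
    hist: dict[int, int] = {}
    ids = reads_by_library.keys() if library_ids is None else library_ids
    for lid in ids:
        seq_counts = _library_seq_counts(reads_by_library.get(lid, ()))
        _, by_offset = _match_reads_to_arm(
            seq_counts, ext_seq, arm_start + lead, tolerance
        )
        for off, c in by_offset.items():
            hist[off] = hist.get(off, 0) + c
    return hist


def compute_log2fc(
    expr: ArmExpression,
    libraries: Sequence[Library],
    pseudocount: float = 0.25,
) -> FoldChange:
    """log2 fold change of depleted over control mean RPM (plus pseudocount).

    Negative values mean the arm's expression dropped under Dicer depletion.
    """
    control = [l for l in libraries if l.condition == CONTROL]
    depleted = [l for l in libraries if l.condition == DICER_DEPLETED]
    if not control or not depleted:
        raise ConfigurationError(
            "log2FC needs at least one control and one depleted library"
        )
    mc = float(np.mean([expr.rpm[l.id] for l in control]))
    md = float(np.mean([expr.rpm[l.id] for l in depleted]))
    if pseudocount <= 0 and (mc == 0 or md == 0):
        raise ConfigurationError(
            "zero mean RPM with no pseudocount gives an infinite log2FC"
        )
    fc = math.log2((md + pseudocount) / (mc + pseudocount))
    return FoldChange(expr.candidate_id, expr.arm, fc, mc, md)


def support_filter(
    expr5p: ArmExpression,
    expr3p: ArmExpression,
    control_libs: Sequence[Library],
) -> bool:
    """True iff every control library has >=1 read on BOTH arms."""
    if not control_libs:
        raise ConfigurationError("support filter needs control libraries")
    return all(
        expr5p.counts.get(l.id, 0) >= 1 and expr3p.counts.get(l.id, 0) >= 1
        for l in control_libs
    )


# ---------------------------------------------------------------------------
# Genome-wide exact read mapping and negative-control regions
# ---------------------------------------------------------------------------


def _genome_index(
    genome: Mapping[str, GenomeSequence]
) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for sid, contig in genome.items():
        seq = contig.sequence
        for pos in range(len(seq) - _INDEX_K + 1):
            index.setdefault(seq[pos : pos + _INDEX_K], []).append((sid, pos))
    return index


def map_reads_exact(
    genome: Mapping[str, GenomeSequence],
    reads: Iterable[ReadRecord],
    index: dict[str, list[tuple[str, int]]] | None = None,
) -> list[tuple[ReadRecord, str, int, int, str]]:
    """Exact (mismatch-free) alignments of reads to the genome, both strands.

    Returns (read, seq_id, start, end, strand) tuples, one per occurrence.
    """
    if index is None:
        index = _genome_index(genome)
    hits: list[tuple[ReadRecord, str, int, int, str]] = []
    for read in reads:
        for query, strand in ((read.sequence, "+"), (reverse_complement(read.sequence), "-")):
            for sid, pos in index.get(query[:_INDEX_K], ()):
                seq = genome[sid].sequence
                if seq[pos : pos + len(query)] == query:
                    hits.append((read, sid, pos, pos + len(query), strand))
    return hits


def coverage_arrays(
    genome: Mapping[str, GenomeSequence],
    reads: Iterable[ReadRecord],
    index: dict[str, list[tuple[str, int]]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-contig depth-of-coverage from exact read mapping (both strands)."""
    cov = {sid: np.zeros(len(c), dtype=np.int64) for sid, c in genome.items()}
    for read, sid, start, end, _strand in map_reads_exact(genome, reads, index):
        cov[sid][start:end] += read.count
    return cov


def select_negative_controls(
    genome: Mapping[str, GenomeSequence],
    reads_by_library: Mapping[str, Sequence[ReadRecord]],
    libraries: Sequence[Library],
    excluded: Iterable[Locus],
    max_len: int = 500,
    min_cov: int = 10,
) -> list[Locus]:
    """Select short, well-covered, miRNA-free regions as knockdown baselines.

    A region qualifies when it is a maximal run of bases covered at depth
    >= ``min_cov`` in *every* control library, is shorter than ``max_len``,
    and does not touch any ``excluded`` locus (known miRNA/coding regions).
    """
    control = [l for l in libraries if l.condition == CONTROL]
    if not control:
        raise ConfigurationError("negative controls need control libraries")
    index = _genome_index(genome)
    masks: dict[str, np.ndarray] = {
        sid: np.ones(len(c), dtype=bool) for sid, c in genome.items()
    }
    for lib in control:
        cov = coverage_arrays(genome, reads_by_library.get(lib.id, ()), index)
        for sid in masks:
            masks[sid] &= cov[sid] >= min_cov
    excluded = list(excluded)
    regions: list[Locus] = []
    for sid, mask in masks.items():
        padded = np.concatenate(([False], mask, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            locus = Locus(sid, int(s), int(e), "+")
            if len(locus) >= max_len:
                continue
            if any(locus.overlaps(x) for x in excluded):
                continue
            regions.append(locus)
    return sorted(regions)


def region_fold_changes(
    regions: Sequence[Locus],
    genome: Mapping[str, GenomeSequence],
    reads_by_library: Mapping[str, Sequence[ReadRecord]],
    libraries: Sequence[Library],
    pseudocount: float = 0.25,
) -> list[FoldChange]:
    """log2FC of read counts overlapping each region (negative-control check)."""
    import bisect

    index = _genome_index(genome)
    # accumulate per-region counts in one pass over hits (regions disjoint)
    region_order = sorted(
        range(len(regions)), key=lambda i: (regions[i].seq_id, regions[i].start)
    )
    by_contig: dict[str, tuple[list[int], list[int], list[int]]] = {}
    for idx in region_order:
        r = regions[idx]
        starts, ends, ids = by_contig.setdefault(r.seq_id, ([], [], []))
        starts.append(r.start)
        ends.append(r.end)
        ids.append(idx)
    counts: list[dict[str, int]] = [
        {lib.id: 0 for lib in libraries} for _ in regions
    ]
    for lib in libraries:
        for read, sid, start, end, _ in map_reads_exact(
            genome, reads_by_library.get(lib.id, ()), index
        ):
            if sid not in by_contig:
                continue
            starts, ends, ids = by_contig[sid]
            k = bisect.bisect_right(starts, end - 1) - 1
            # a short read overlaps at most a few consecutive regions
            while k >= 0 and ends[k] > start:
                if starts[k] < end:
                    counts[ids[k]][lib.id] += read.count
                k -= 1
    out: list[FoldChange] = []
    for i in range(len(regions)):
        expr = make_arm_expression(f"negctrl_{i}", "region", counts[i], libraries)
        out.append(compute_log2fc(expr, libraries, pseudocount))
    return out


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Requires each group to hold >=2 values with nonzero variance
    (Welch-Satterthwaite degrees of freedom are undefined otherwise).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, g in (("A", a), ("B", b)):
        if g.size < 2:
            raise ContractError(f"group {name} has fewer than 2 values")
        if np.var(g) == 0:
            raise ContractError(f"group {name} has zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
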