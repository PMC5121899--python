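"""Per-miRNA graphical/text reports: precursor, structure, stacked reads.

A report shows the precursor extended by flanking sequence, its dot-bracket
structure, the annotated 5p/3p arm intervals, and every 18-26 nt read
aligned under the precursor with its per-library counts, so that control
vs Dicer-depleted support is visible read by read.  Alignments are
ungapped, tolerate at most one mismatch, and must be mismatch-free inside
the seed region.  Rendering is pure and deterministic: identical inputs
produce identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import expression as expr_mod
from . import structure
from .config import PipelineConfig
from .core_io import (
    GenomeSequence,
    Library,
    Locus,
    MiRNACandidate,
    ReadRecord,
    extract_locus_sequence,
)


@dataclass(frozen=True)
class AlignedRead:
    sequence: str
    offset: int  # start within the extended precursor
    counts: Mapping[str, int]  # library_id -> collapsed count
    mismatches: int
    multi_hit: bool


@dataclass(frozen=True)
class MiRNAReport:
    candidate_id: str
    extended_precursor: str
    dot_bracket: str
    arm_annotations: Mapping[str, tuple[int, int]]  # arm -> extended coords
    aligned_reads: tuple[AlignedRead, ...]
    homologue_alignments: tuple[tuple[str, str], ...] = field(default=())


def align_reads_for_report(
    reads: Sequence[ReadRecord],
    extended_precursor: str,
    seed_region: tuple[int, int],
    read_len_range: tuple[int, int] = (18, 26),
    max_mismatch: int = 1,
) -> list[AlignedRead]:
    """Ungapped alignments of reads against an extended precursor.

    Reads outside ``read_len_range`` are dropped.  An alignment needs at
    most ``max_mismatch`` mismatches overall and none inside
    ``seed_region``; reads hitting several positions are reported at all
    of them with the multi-hit flag set.
    """
    lo, hi = read_len_range
    ss, se = seed_region
    by_seq: dict[str, dict[str, int]] = {}
    for r in reads:
        if lo <= len(r.sequence) <= hi:
            d = by_seq.setdefault(r.sequence, {})
            d[r.library_id] = d.get(r.library_id, 0) + r.count
    out: list[AlignedRead] = []
    for seq in sorted(by_seq):
        hits: list[tuple[int, int]] = []
        for pos in range(len(extended_precursor) - len(seq) + 1):
            mm = 0
            seed_ok = True
            for k, base in enumerate(seq):
                if extended_precursor[pos + k] != base:
                    if ss <= pos + k < se:
                        seed_ok = False
                        break
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                if seed_ok:
                    hits.append((pos, mm))
                continue
            # inner break: alignment disqualified at this position
        multi = len(hits) > 1
        for pos, mm in hits:
            out.append(AlignedRead(seq, pos, by_seq[seq], mm, multi))
    out.sort(key=lambda a: (a.offset, a.sequence))
    return out


def build_report(
    candidate: MiRNACandidate,
    genome: Mapping[str, GenomeSequence],
    reads_by_library: Mapping[str, Sequence[ReadRecord]],
    libraries: Sequence[Library],
    mature_arm: str = "5p",
    cfg: PipelineConfig | None = None,
    homologue_alignments: Sequence[tuple[str, str]] = (),
) -> MiRNAReport:
    """Assemble a report for one candidate from genome and read data."""
    cfg = cfg or PipelineConfig()
    flank = cfg.report_flank
    p = candidate.precursor_locus
    contig_len = len(genome[p.seq_id])
    start = max(0, p.start - flank)
    end = min(contig_len, p.end + flank)
    ext_locus = Locus(p.seq_id, start, end, p.strand)
    ext_seq = extract_locus_sequence(genome, ext_locus)
    lead = (p.start - start) if p.strand == "+" else (end - p.end)
    fold = structure.fold_hairpin(candidate.precursor_seq, backend=cfg.fold_backend)
    dot = "." * lead + fold.dot_bracket
    dot += "." * (len(ext_seq) - len(dot))
    arms = {
        arm: tuple(x + lead for x in candidate.arm_interval(arm))
        for arm in ("5p", "3p")
    }
    ms, me = candidate.arm_interval(mature_arm)
    seed_region = (lead + ms + cfg.seed_start - 1, lead + ms + cfg.seed_end)
    all_reads = [r for lib in libraries for r in reads_by_library.get(lib.id, ())]
    aligned = align_reads_for_report(
        all_reads,
        ext_seq,
        seed_region,
        (cfg.report_read_min, cfg.report_read_max),
    )
    return MiRNAReport(
        candidate_id=candidate.id,
        extended_precursor=ext_seq,
        dot_bracket=dot,
        arm_annotations=arms,
        aligned_reads=tuple(aligned),
        homologue_alignments=tuple(homologue_alignments),
    )


def _arm_ruler(report: MiRNAReport) -> str:
    ruler = [" "] * len(report.extended_precursor)
    for arm, (s, e) in sorted(report.arm_annotations.items()):
        mark = "5" if arm == "5p" else "3"
        for k in range(s, e):
            ruler[k] = mark
    return "".join(ruler)


def render_report(
    report: MiRNAReport,
    format: str = "text",
    libraries: Sequence[Library] | None = None,
) -> str:
    """Render a report deterministically as plain text or minimal SVG."""
    lib_ids = (
        [l.id for l in libraries]
        if libraries is not None
        else sorted({lid for a in report.aligned_reads for lid in a.counts})
    )
    lines = [
        f"miRNA report: {report.candidate_id}",
        f"extended precursor ({len(report.extended_precursor)} nt):",
        report.extended_precursor,
        report.dot_bracket,
        _arm_ruler(report),
        "",
        f"aligned reads ({len(report.aligned_reads)}):",
    ]
    header = "offset  sequence" + " " * 24 + "\t" + "\t".join(lib_ids) + "\tflags"
    lines.append(header)
    for a in report.aligned_reads:
        flags = []
        if a.mismatches:
            flags.append(f"{a.mismatches}mm")
        if a.multi_hit:
            flags.append("multi")
        counts = "\t".join(str(a.counts.get(l, 0)) for l in lib_ids)
        pad = " " * a.offset
        lines.append(f"{a.offset:>6}  {pad}{a.sequence}\t{counts}\t{','.join(flags)}")
    if report.homologue_alignments:
        lines.append("")
        lines.append("homologue alignments:")
        for name, aln in report.homologue_alignments:
            lines.append(f"  {name}\t{aln}")
    text = "\n".join(lines) + "\n"
    if format == "text":
        return text
    if format == "svg":
        rows = text.rstrip("\n").split("\n")
        width = 8 * max(len(r.expandtabs()) for r in rows) + 20
        height = 16 * len(rows) + 20
        body = "\n".join(
            f'<text x="10" y="{16 * (i + 1)}" xml:space="preserve" '
            f'font-family="monospace" font-size="12">{_escape(r.expandtabs())}</text>'
            for i, r in enumerate(rows)
        )
        return (
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
            f'height="{height}">\n{body}\n</svg>\n'
        )
    raise ValueError(f"unknown report format {format!r}")


def _escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
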