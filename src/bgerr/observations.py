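"""Streaming of per-base observations from aligned reads over a target panel.

The profiling pipeline consumes a flat stream of :class:`BaseObservation`
records: one per aligned, non-clipped read base that falls inside the target
panel.  Each observation carries the reference base at its position, the UMI
of its read, the outer coordinates of the sequenced DNA fragment (from the
proper pair), and the base's 1-based distance from its read's 5' end -- the
quantity the fragment-end damage analysis bins in 5-bp windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pysam
from pyfaidx import Fasta

from .datamodel import BASES, BaseObservation


@dataclass(frozen=True)
class TargetPanel:
    """Sorted, merged set of target intervals (0-based half-open)."""

    intervals: tuple[tuple[str, int, int], ...]

    @property
    def total_bp(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(chrom for chrom, _, _ in self.intervals))

    def __contains__(self, site: tuple[str, int]) -> bool:
        chrom, pos = site
        return any(c == chrom and s <= pos < e for c, s, e in self.intervals)

    def positions(self) -> Iterator[tuple[str, int]]:
        for chrom, start, end in self.intervals:
            for pos in range(start, end):
                yield chrom, pos


def merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> tuple[tuple[str, int, int], ...]:
    """Sort intervals and merge overlapping/adjacent ones per chromosome."""
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged.pop()
            merged.append((chrom, prev[1], max(prev[2], end)))
        else:
            merged.append((chrom, start, end))
    return tuple(merged)


def load_panel(path: str | Path) -> TargetPanel:
    """Load a 3+ column BED file into a merged, sorted :class:`TargetPanel`.

    Raises ``ValueError`` with the offending line number on malformed input
    and on an empty panel.
    """
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\s+", line)
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            intervals.append((fields[0], start, end))
    if not intervals:
        raise ValueError(f"{path}: empty panel")
    return TargetPanel(merge_intervals(intervals))


def fragment_bin(dist: int) -> int | None:
    """5-bp bin index (1..10) for a breakpoint distance, or None beyond 50 bp.

    Distances 1-5 fall in bin 1, 6-10 in bin 2, ..., 46-50 in bin 10.
    """
    if dist < 1:
        raise ValueError(f"dist_from_breakpoint must be >= 1, got {dist}")
    if dist > 50:
        return None
    return (dist + 4) // 5


# ---------------------------------------------------------------------------
# BAM streaming
# ---------------------------------------------------------------------------

_EXCLUDE_FLAGS = (
    pysam.FUNMAP | pysam.FSECONDARY | pysam.FQCFAIL | pysam.FDUP | pysam.FSUPPLEMENTARY
)


def _umi_from_read(read: pysam.AlignedSegment, umi_source: str, on_missing: str) -> str | None:
    if umi_source.startswith("tag:"):
        tag = umi_source.split(":", 1)[1]
        if read.has_tag(tag):
            return str(read.get_tag(tag))
    else:  # read-name suffix, delimiter given after "name:"
        delim = umi_source.split(":", 1)[1] if ":" in umi_source else "_"
        name = read.query_name or ""
        if delim in name:
            return name.rsplit(delim, 1)[1]
    if on_missing == "skip":
        return None
    raise ValueError(f"read {read.query_name!r} carries no UMI under rule {umi_source!r}")


def _fragment_coords(read: pysam.AlignedSegment) -> tuple[int, int] | None:
    """Outer fragment coordinates from the proper pair's template span."""
    if read.is_paired and read.is_proper_pair and read.template_length != 0:
        tlen = read.template_length
        if tlen > 0:
            return read.reference_start, read.reference_start + tlen
        return read.next_reference_start, read.next_reference_start - tlen
    if not read.is_paired:
        return read.reference_start, read.reference_end
    return None


def stream_observations(
    bam_path: str | Path,
    panel: TargetPanel,
    reference_path: str | Path,
    umi_source: str = "tag:RX",
    min_mapq: int = 1,
    on_missing_umi: str = "fail",
    improper_pairs: str = "skip",
) -> Iterator[BaseObservation]:
    """Yield one observation per aligned, non-clipped, in-panel read base.

    Secondary, supplementary, duplicate-flagged, unmapped and low-MAPQ reads
    are skipped.  ``umi_source`` is ``"tag:RX"``-style for a BAM tag or
    ``"name:<delim>"`` for a read-name suffix.  Reads without resolvable
    fragment coordinates (improper pairs) are skipped or treated as
    single-read fragments per ``improper_pairs`` ("skip" | "own_span").
    Both mates of an overlapping pair are emitted (simple pileup semantics);
    downstream UMI consensus collapses true duplicates.
    """
    bam_path = Path(bam_path)
    if not (bam_path.with_suffix(bam_path.suffix + ".bai").exists()
            or Path(str(bam_path) + ".csi").exists()
            or bam_path.with_suffix(".bai").exists()):
        raise FileNotFoundError(f"no index found for {bam_path}")
    ref = Fasta(str(reference_path), as_raw=True, sequence_always_upper=True)

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for chrom, start, end in panel.intervals:
            if chrom not in ref:
                raise KeyError(f"contig {chrom!r} missing from reference {reference_path}")
            refseq = str(ref[chrom][:])
            for read in bam.fetch(chrom, start, end):
                if read.flag & _EXCLUDE_FLAGS or read.mapping_quality < min_mapq:
                    continue
                umi = _umi_from_read(read, umi_source, on_missing_umi)
                if umi is None:
                    continue
                frag = _fragment_coords(read)
                if frag is None:
                    if improper_pairs == "skip":
                        continue
                    frag = (read.reference_start, read.reference_end)
                frag_start, frag_end = frag
                # Strand of R1 keys the UMI family (single-strand UMI scheme).
                if read.is_paired:
                    r1_reverse = read.is_reverse if read.is_read1 else read.mate_is_reverse
                else:
                    r1_reverse = read.is_reverse
                fragment_strand = "-" if r1_reverse else "+"
                seq = read.query_sequence
                quals = read.query_qualities
                qlen = read.query_length
                read_id = f"{read.query_name}/{2 if read.is_read2 else 1}"
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if not (start <= rpos < end):
                        continue
                    obs_base = seq[qpos]
                    ref_base = refseq[rpos]
                    if obs_base not in BASES or ref_base not in BASES:
                        continue  # N bases leave both numerator and denominator
                    dist = qlen - qpos if read.is_reverse else qpos + 1
                    yield BaseObservation(
                        chrom=chrom,
                        pos=rpos,
                        ref_base=ref_base,
                        obs_base=obs_base,
                        base_quality=int(quals[qpos]),
                        read_id=read_id,
                        umi=umi,
                        fragment_start=frag_start,
                        fragment_end=frag_end,
                        dist_from_breakpoint=dist,
                        fragment_strand=fragment_strand,
                    )


__all__ = [
    "TargetPanel",
    "merge_intervals",
    "load_panel",
    "fragment_bin",
    "stream_observations",
]
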