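"""Mate-pair misassembly screening, contig splitting and organelle filtering.

A position inside a correctly assembled contig should be *spanned* by
concordant large-insert read pairs: one read entirely to its left, the mate
entirely to its right.  A run of interior positions with zero spanning
coverage is the signature of a chimeric junction; such contigs are split at
the run and fragments below a minimum length are discarded.  Contigs matching
an organelle reference (chloroplast by identity/coverage, mitochondrion by
E-value) are removed before scaffolding.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ORGANELLE_SUBJECTS = ("chloroplast", "mitochondrion")


@dataclass(frozen=True)
class PairAlignment:
    """A concordant large-insert read-pair placement on one contig."""

    contig_id: str
    start1: int
    end1: int
    start2: int
    end2: int
    proper: bool = True

    def __post_init__(self) -> None:
        if self.end1 <= self.start1 or self.end2 <= self.start2:
            raise ValueError("read intervals must be non-empty")

    @property
    def outer_span(self) -> tuple[int, int]:
        return (min(self.start1, self.start2), max(self.end1, self.end2))

    @property
    def inner_gap(self) -> tuple[int, int]:
        """Interval of positions this pair spans (left read end, right read start)."""
        if self.start1 <= self.start2:
            return (self.end1, self.start2)
        return (self.end2, self.start1)


@dataclass(frozen=True)
class Breakpoint:
    """An inferred misassembly split position inside a contig."""

    contig_id: str
    position: int
    window: tuple[int, int]  # zero-spanning run, 0-based half-open
    support: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (lo <= self.position <= hi):
            raise ValueError("breakpoint position outside its window")


@dataclass(frozen=True)
class ScreenHit:
    """An aggregated organelle-screen alignment for one contig."""

    contig_id: str
    subject: str  # "chloroplast" | "mitochondrion"
    identity: float  # percent
    query_coverage: float  # percent of the contig covered
    evalue: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be a percentage")
        if not (0.0 <= self.query_coverage <= 100.0):
            raise ValueError("coverage must be a percentage")
        if self.evalue < 0:
            raise ValueError("negative E-value")


# ---------------------------------------------------------------------------
# Spanning coverage and breakpoint calling
# ---------------------------------------------------------------------------


def spanning_coverage(pairs: Iterable[PairAlignment], contig_length: int) -> np.ndarray:
    """Per-position count of proper pairs whose reads straddle the position.

    ``profile[p]`` counts pairs with the left read ending at or before ``p``
    and the right read starting after ``p`` (p >= left end, p < right start).
    Computed with a difference array in O(pairs + length).
    """
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    for pair in pairs:
        if not pair.proper:
            continue
        lo, hi = pair.outer_span
        if lo < 0 or hi > contig_length:
            raise ValueError(
                f"pair {lo}..{hi} outside contig of length {contig_length}"
            )
        a, b = pair.inner_gap
        if b > a:
            diff[a] += 1
            diff[b] -= 1
    return np.cumsum(diff[:-1])


def call_breakpoints(
    profile: np.ndarray,
    min_span: int = 1,
    edge_exclusion: int = 0,
    contig_id: str = "",
) -> list[Breakpoint]:
    """Call breakpoints from maximal low-spanning runs in a coverage profile.

    Runs of positions with coverage below ``min_span`` are clipped to the
    interior ``[edge_exclusion, L - edge_exclusion)`` — contig ends cannot be
    spanned, so ``edge_exclusion`` should be at least the largest configured
    insert size.  Runs lying entirely in the edge zones produce no call.  Each
    surviving run is reported once, at its midpoint.
    """
    profile = np.asarray(profile)
    length = profile.size
    lo_bound, hi_bound = edge_exclusion, length - edge_exclusion
    if hi_bound <= lo_bound:
        return []
    low = profile < min_span
    # run boundaries of the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
    out: list[Breakpoint] = []
    for s, e in zip(edges[::2], edges[1::2]):
        cs, ce = max(int(s), lo_bound), min(int(e), hi_bound)
        if ce <= cs:
            continue
        mid = (cs + ce) // 2
        out.append(
            Breakpoint(
                contig_id=contig_id,
                position=mid,
                window=(cs, ce),
                support=int(profile[mid]),
            )
        )
    return out


def detect_misassemblies(
    pairs: Iterable[PairAlignment],
    contig_lengths: Mapping[str, int],
    min_span: int = 1,
    edge_exclusion: int = 0,
) -> dict[str, list[Breakpoint]]:
    """Group pairs per contig, profile spanning coverage and call breakpoints.

    Contigs shorter than twice the edge exclusion have no assessable interior
    and yield no calls.
    """
    by_contig: dict[str, list[PairAlignment]] = {cid: [] for cid in contig_lengths}
    for pair in pairs:
        if pair.contig_id in by_contig:
            by_contig[pair.contig_id].append(pair)
    calls: dict[str, list[Breakpoint]] = {}
    for cid, length in contig_lengths.items():
        profile = spanning_coverage(by_contig[cid], length)
        bps = call_breakpoints(profile, min_span, edge_exclusion, contig_id=cid)
        if bps:
            calls[cid] = bps
    return calls


def split_at_breakpoints(
    sequences: Mapping[str, str],
    breakpoints: Iterable[Breakpoint],
    min_length: int = 1000,
) -> dict[str, str]:
    """Cut contigs at breakpoint positions and drop short fragments.

    Fragments of a split contig are renamed ``<id>_1``, ``<id>_2``, ... in
    left-to-right order; fragments shorter than ``min_length`` are discarded.
    Contigs without breakpoints keep their name and sequence.
    """
    cuts: dict[str, list[int]] = {}
    for bp in breakpoints:
        if bp.contig_id not in sequences:
            raise KeyError(f"breakpoint on unknown contig {bp.contig_id}")
        length = len(sequences[bp.contig_id])
        if not (0 < bp.position < length):
            raise ValueError(
                f"breakpoint {bp.position} not interior to {bp.contig_id} ({length} bp)"
            )
        cuts.setdefault(bp.contig_id, []).append(bp.position)

    out: dict[str, str] = {}
    for cid, seq in sequences.items():
        if cid not in cuts:
            if len(seq) >= min_length:
                out[cid] = seq
            continue
        positions = sorted(set(cuts[cid]))
        bounds = [0] + positions + [len(seq)]
        n = 0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            n += 1
            frag = seq[lo:hi]
            if len(frag) >= min_length:
                out[f"{cid}_{n}"] = frag
    return out


# ---------------------------------------------------------------------------
# Organelle screening
# ---------------------------------------------------------------------------


def organelle_filter(
    hits: Iterable[ScreenHit],
    contigs: Mapping[str, str],
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Remove contigs matching an organelle reference.

    Chloroplast rule: identity >= 98% and query coverage >= 80%.
    Mitochondrion rule: E-value < 1e-40.
    A contig is removed as soon as any of its hits satisfies its subject's
    rule.  Returns (kept contigs, list of (contig_id, reason)).
    """
    removed: dict[str, str] = {}
    for hit in hits:
        if hit.subject not in ORGANELLE_SUBJECTS:
            raise ValueError(f"unknown organelle subject {hit.subject!r}")
        if hit.contig_id in removed:
            continue
        if hit.subject == "chloroplast":
            if hit.identity >= 98.0 and hit.query_coverage >= 80.0:
                removed[hit.contig_id] = (
                    f"chloroplast: identity {hit.identity:.1f}%, "
                    f"coverage {hit.query_coverage:.1f}%"
                )
        else:
            if hit.evalue < 1e-40:
                removed[hit.contig_id] = f"mitochondrion: evalue {hit.evalue:.2g}"
    kept = {cid: seq for cid, seq in contigs.items() if cid not in removed}
    return kept, sorted(removed.items())


BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _merged_interval_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_lo = cur_hi = None
    for lo, hi in sorted(intervals):
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total


def read_blast_hits(
    path: str,
    subject_labels: Mapping[str, str],
    contig_lengths: Mapping[str, int],
) -> list[ScreenHit]:
    """Aggregate a BLAST outfmt-6 table into per-(contig, subject) screen hits.

    Query coverage is the merged, non-overlapping HSP footprint over the
    contig length; identity is the alignment-length-weighted mean percent
    identity; the E-value is the best (minimum) over HSPs.  ``subject_labels``
    maps BLAST subject ids to "chloroplast"/"mitochondrion".
    """
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    hits: list[ScreenHit] = []
    df["subject"] = df["sseqid"].map(dict(subject_labels))
    if df["subject"].isna().any():
        unknown = sorted(df.loc[df["subject"].isna(), "sseqid"].unique())
        raise ValueError(f"BLAST subjects without organelle label: {unknown}")
    for (qid, subject), grp in df.groupby(["qseqid", "subject"], sort=True):
        # outfmt 6 is 1-based inclusive; qstart/qend may be reversed
        intervals = [
            (min(a, b) - 1, max(a, b)) for a, b in zip(grp["qstart"], grp["qend"])
        ]
        cov_bp = _merged_interval_length(intervals)
        qlen = contig_lengths[qid]
        weights = grp["length"].to_numpy(dtype=float)
        identity = float(np.average(grp["pident"].to_numpy(dtype=float), weights=weights))
        hits.append(
            ScreenHit(
                contig_id=str(qid),
                subject=str(subject),
                identity=identity,
                query_coverage=min(100.0, 100.0 * cov_bp / qlen),
                evalue=float(grp["evalue"].min()),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Pair-table and SAM I/O
# ---------------------------------------------------------------------------

PAIR_TABLE_COLUMNS = ["contig_id", "start1", "end1", "start2", "end2", "orientation"]


def write_pair_table(pairs: Iterable[PairAlignment], path: str) -> None:
    """Write pairs as the simple TSV dialect (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_TABLE_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.contig_id}\t{p.start1}\t{p.end1}\t{p.start2}\t{p.end2}\t+-\n"
            )


def read_pair_table(path: str) -> list[PairAlignment]:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    return [
        PairAlignment(
            contig_id=str(r.contig_id),
            start1=int(r.start1),
            end1=int(r.end1),
            start2=int(r.start2),
            end2=int(r.end2),
        )
        for r in df.itertuples(index=False)
    ]


def write_sam(
    pairs: Sequence[PairAlignment],
    contig_lengths: Mapping[str, int],
    path: str,
) -> None:
    """Write pairs as a coordinate-unsorted SAM file (sequence-less records)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": cid, "LN": int(ln)} for cid, ln in contig_lengths.items()],
    }
    ref_ids = {cid: i for i, cid in enumerate(contig_lengths)}
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for i, p in enumerate(pairs):
            for which, (start, end, mate_start, flag_extra) in enumerate(
                [
                    (p.start1, p.end1, p.start2, 0x40 | 0x20),  # read1, mate reversed
                    (p.start2, p.end2, p.start1, 0x80 | 0x10),  # read2, reversed
                ]
            ):
                a = pysam.AlignedSegment()
                a.query_name = f"pair{i}"
                a.flag = 0x1 | 0x2 | flag_extra
                a.reference_id = ref_ids[p.contig_id]
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = f"{end - start}M"
                a.next_reference_id = ref_ids[p.contig_id]
                a.next_reference_start = mate_start
                a.template_length = 0
                fh.write(a)


def read_sam_pairs(path: str) -> list[PairAlignment]:
    """Reconstruct pair placements from a SAM/BAM of paired alignments.

    Mates are matched by query name on the same reference; the ``proper``
    flag follows the 0x2 SAM flag.
    """
    import pysam

    firsts: dict[str, tuple[str, int, int, bool]] = {}
    pairs: list[PairAlignment] = []
    with pysam.AlignmentFile(path, "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            key = rec.query_name
            entry = (rec.reference_name, rec.reference_start, rec.reference_end,
                     rec.is_proper_pair)
            if key not in firsts:
                firsts[key] = entry
                continue
            ref1, s1, e1, proper = firsts.pop(key)
            ref2, s2, e2, _ = entry
            if ref1 != ref2:
                continue  # cross-contig pair carries no spanning information here
            pairs.append(
                PairAlignment(
                    contig_id=ref1, start1=s1, end1=e1, start2=s2, end2=e2,
                    proper=proper,
                )
            )
    return pairs


def write_breakpoints_bed(breakpoints: Iterable[Breakpoint], path: str) -> None:
    """Write breakpoint windows as BED (0-based half-open), midpoint in column 5."""
    with open(path, "w") as fh:
        for bp in breakpoints:
            fh.write(
                f"{bp.contig_id}\t{bp.window[0]}\t{bp.window[1]}\t"
                f"breakpoint\t{bp.position}\n"
            )
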