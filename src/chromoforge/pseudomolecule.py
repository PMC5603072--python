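"""Pseudomolecule construction (AGP v2.0 + FASTA) and assembly statistics.

A :class:`~chromoforge.anchoring.ScaffoldLayout` fixes, per chromosome, an
ordered list of oriented scaffolds.  Chromosome objects are built by
concatenating the scaffolds (reverse-complemented where oriented ``-``) with
fixed-size N gaps between them, described losslessly by AGP v2.0 records.
Coordinates are 0-based half-open internally and 1-based inclusive in files,
per the AGP convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving N and case."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class AgpRecord:
    """One AGP v2.0 line; either a W (component) or N (gap) record."""

    object: str
    object_beg: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # "W" | "N"
    # W fields
    component_id: str | None = None
    component_beg: int | None = None  # 1-based inclusive
    component_end: int | None = None
    orientation: str | None = None
    # N fields
    gap_length: int | None = None
    gap_type: str | None = None
    linkage: str | None = None
    evidence: str | None = None

    def to_line(self) -> str:
        if self.component_type == "W":
            tail = [self.component_id, self.component_beg, self.component_end,
                    self.orientation]
        else:
            tail = [self.gap_length, self.gap_type, self.linkage, self.evidence]
        return "\t".join(
            str(x)
            for x in [self.object, self.object_beg, self.object_end,
                      self.part_number, self.component_type, *tail]
        )


@dataclass
class AgpAssembly:
    records: list[AgpRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev: dict[str, AgpRecord] = {}
        for rec in self.records:
            if rec.component_type not in ("W", "N"):
                raise ValueError(f"bad component type {rec.component_type!r}")
            if rec.object in prev:
                p = prev[rec.object]
                if rec.object_beg != p.object_end + 1:
                    raise ValueError(
                        f"{rec.object}: object coordinates not contiguous at part "
                        f"{rec.part_number}"
                    )
            elif rec.object_beg != 1:
                raise ValueError(f"{rec.object}: first record must start at 1")
            if rec.component_type == "W":
                span = rec.component_end - rec.component_beg + 1
                if span != rec.object_end - rec.object_beg + 1:
                    raise ValueError(
                        f"{rec.object} part {rec.part_number}: W span mismatch"
                    )
            prev[rec.object] = rec

    def objects(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.object, None)
        return list(seen)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##agp-version\t2.0\n")
            for rec in self.records:
                fh.write(rec.to_line() + "\n")

    @classmethod
    def read(cls, path: str) -> "AgpAssembly":
        records: list[AgpRecord] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if f[4] == "W":
                    records.append(
                        AgpRecord(f[0], int(f[1]), int(f[2]), int(f[3]), "W",
                                  component_id=f[5], component_beg=int(f[6]),
                                  component_end=int(f[7]), orientation=f[8])
                    )
                else:
                    records.append(
                        AgpRecord(f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                                  gap_length=int(f[5]), gap_type=f[6],
                                  linkage=f[7], evidence=f[8])
                    )
        return cls(records)


def chromosome_names_by_length(
    groups: Mapping, scaffold_lengths: Mapping[str, int]
) -> dict:
    """Map layout group keys to ``chr1..chrN`` by decreasing anchored length."""
    anchored = {
        g: sum(scaffold_lengths[sid] for sid, _ in order)
        for g, order in groups.items()
    }
    ranked = sorted(groups, key=lambda g: (-anchored[g], str(g)))
    return {g: f"chr{i + 1}" for i, g in enumerate(ranked)}


def build_agp(
    layout,
    scaffold_lengths: Mapping[str, int],
    gap_size: int = 100,
    chrom_names: Mapping | None = None,
) -> AgpAssembly:
    """Build AGP records from a scaffold layout.

    ``layout`` is a :class:`~chromoforge.anchoring.ScaffoldLayout` or a plain
    mapping of group -> ordered ``(scaffold_id, orientation)`` lists.  Gaps
    between anchored scaffolds are N records of ``gap_size`` with gap type
    "scaffold", linkage "yes" and evidence "map".  Scaffolds absent from the
    layout are emitted as their own single-record objects.
    """
    groups = layout.groups if hasattr(layout, "groups") else dict(layout)
    if chrom_names is None:
        chrom_names = chromosome_names_by_length(groups, scaffold_lengths)

    seen: set[str] = set()
    records: list[AgpRecord] = []
    for g in sorted(groups, key=lambda g: chrom_names[g]):
        obj = chrom_names[g]
        pos = 0  # 0-based running offset
        part = 0
        for k, (sid, orient) in enumerate(groups[g]):
            if sid in seen:
                raise ValueError(f"scaffold {sid} appears more than once in layout")
            seen.add(sid)
            if k > 0 and gap_size > 0:
                part += 1
                records.append(
                    AgpRecord(obj, pos + 1, pos + gap_size, part, "N",
                              gap_length=gap_size, gap_type="scaffold",
                              linkage="yes", evidence="map")
                )
                pos += gap_size
            length = scaffold_lengths[sid]
            part += 1
            records.append(
                AgpRecord(obj, pos + 1, pos + length, part, "W",
                          component_id=sid, component_beg=1,
                          component_end=length, orientation=orient)
            )
            pos += length
    for sid in scaffold_lengths:
        if sid not in seen:
            length = scaffold_lengths[sid]
            records.append(
                AgpRecord(sid, 1, length, 1, "W", component_id=sid,
                          component_beg=1, component_end=length, orientation="+")
            )
    return AgpAssembly(records)


def build_fasta(agp: AgpAssembly, scaffold_seqs: Mapping[str, str]) -> dict[str, str]:
    """Materialize object sequences from AGP records and component sequences."""
    chunks: dict[str, list[str]] = {}
    for rec in agp.records:
        parts = chunks.setdefault(rec.object, [])
        if rec.component_type == "N":
            parts.append("N" * rec.gap_length)
            continue
        src = scaffold_seqs[rec.component_id]
        if rec.component_end > len(src):
            raise ValueError(
                f"component {rec.component_id} span {rec.component_end} exceeds "
                f"sequence length {len(src)}"
            )
        piece = src[rec.component_beg - 1:rec.component_end]
        if rec.orientation == "-":
            piece = reverse_complement(piece)
        parts.append(piece)
    return {obj: "".join(parts) for obj, parts in chunks.items()}


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass
class AssemblyStats:
    n_sequences: int
    total_length: int
    n50: int
    unknown_sites: int
    unknown_pct: float
    anchored_length: int
    anchored_pct: float
    per_chromosome: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "total_length": self.total_length,
            "n50": self.n50,
            "unknown_sites": self.unknown_sites,
            "unknown_pct": self.unknown_pct,
            "anchored_length": self.anchored_length,
            "anchored_pct": self.anchored_pct,
            "per_chromosome": self.per_chromosome,
        }


def n50(lengths: Iterable[int]) -> int:
    """Length at which cumulative sorted-descending length first reaches half
    the total."""
    arr = sorted((int(x) for x in lengths), reverse=True)
    total = sum(arr)
    if total == 0:
        return 0
    acc = 0
    for x in arr:
        acc += x
        if 2 * acc >= total:
            return x
    return 0


def assembly_stats(sequences: Mapping[str, str], layout=None) -> AssemblyStats:
    """Assembly summary over a set of sequences (typically scaffolds).

    When a layout is given, anchored length is the summed length of scaffolds
    placed on a chromosome, and per-chromosome lengths (including inter-
    scaffold gaps of the layout's AGP, excluded here) and scaffold counts are
    reported.
    """
    lengths = {k: len(s) for k, s in sequences.items()}
    total = sum(lengths.values())
    unknown = sum(s.count("N") + s.count("n") for s in sequences.values())
    per_chrom: dict[str, dict] = {}
    anchored = 0
    if layout is not None:
        groups = layout.groups if hasattr(layout, "groups") else dict(layout)
        names = chromosome_names_by_length(groups, lengths)
        for g, order in groups.items():
            ln = sum(lengths[sid] for sid, _ in order)
            anchored += ln
            per_chrom[names[g]] = {"length": ln, "n_scaffolds": len(order)}
        per_chrom = dict(sorted(per_chrom.items(),
                                key=lambda kv: int(kv[0].removeprefix("chr"))))
    return AssemblyStats(
        n_sequences=len(sequences),
        total_length=total,
        n50=n50(lengths.values()),
        unknown_sites=unknown,
        unknown_pct=100.0 * unknown / total if total else 0.0,
        anchored_length=anchored,
        anchored_pct=100.0 * anchored / total if total else 0.0,
        per_chromosome=per_chrom,
    )


def density_tracks(
    features: Iterable[tuple[str, int]],
    chrom_lengths: Mapping[str, int],
    window: int = 400_000,
) -> pd.DataFrame:
    """Per-window feature counts along chromosomes (Fig.-3-style track).

    Windows tile each chromosome from 0 in non-overlapping blocks of
    ``window`` bp; the last, possibly partial window is included.  A feature
    is counted in the window containing its start position.
    """
    counts: dict[str, np.ndarray] = {}
    n_windows = {
        c: max(1, -(-length // window)) for c, length in chrom_lengths.items()
    }
    for c, n in n_windows.items():
        counts[c] = np.zeros(n, dtype=np.int64)
    for chrom, pos in features:
        if chrom not in counts:
            continue
        counts[chrom][pos // window] += 1
    rows = []
    for c in chrom_lengths:
        length = chrom_lengths[c]
        for w in range(n_windows[c]):
            rows.append(
                {
                    "chromosome": c,
                    "start": w * window,
                    "end": min((w + 1) * window, length),
                    "count": int(counts[c][w]),
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "count"])
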