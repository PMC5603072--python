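"""Exact-match annotation transfer between assembly versions.

Each exon of a gene model, extended by a fixed flank (20 bp by default) on
both sides, is searched for as an exact, full-length substring of the target
assembly on both strands.  A gene transfers when every exon probe hits, a
single consistent placement exists (one target sequence, one strand, exons
colinear, non-overlapping, with positive inter-exon spacing and bounded
intron inflation), and that placement is unique.  Anything else is a typed
failure, never a guess.

Coordinates are 0-based half-open internally and 1-based inclusive in GFF3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .pseudomolecule import reverse_complement

FAILURE_REASONS = ("exon-missing", "multi-hit-ambiguous", "inconsistent-placement")


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered list of exon intervals on a source sequence."""

    gene_id: str
    seq_id: str
    strand: str  # "+" | "-"
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, 0-based half-open

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene without exons")
        prev_end = -1
        for s, e in self.exons:
            if e <= s or s < prev_end:
                raise ValueError(f"exons of {self.gene_id} not sorted/non-overlapping")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class Probe:
    """An exon sequence extended by flanks (clipped at sequence bounds)."""

    seq: str
    left_flank: int  # flank actually available on the left
    right_flank: int


@dataclass
class TransferResult:
    gene_id: str
    status: str  # "transferred" | "failed"
    reason: str | None = None
    seq_id: str | None = None
    strand: str | None = None
    exons: tuple[tuple[int, int], ...] | None = None


def extract_probes(
    gene: GeneModel, source_seq: str, flank: int = 20
) -> list[Probe]:
    """One probe per exon, in gene order; flanks clipped at sequence bounds."""
    probes = []
    for s, e in gene.exons:
        lo = max(0, s - flank)
        hi = min(len(source_seq), e + flank)
        probes.append(Probe(source_seq[lo:hi], left_flank=s - lo, right_flank=hi - e))
    return probes


def place_probe(
    probe: str, target: Mapping[str, str]
) -> list[tuple[str, int, str]]:
    """All exact full-length occurrences of ``probe`` in the target, both strands.

    Returns ``(sequence id, start, strand)`` tuples; a ``-`` hit means the
    reverse complement of the probe occurs at that position.
    """
    hits: list[tuple[str, int, str]] = []
    rc = reverse_complement(probe)
    for sid in target:
        seq = target[sid]
        for query, strand in ((probe, "+"), (rc, "-")):
            if strand == "-" and rc == probe:
                continue  # palindromic probe: forward scan already found it
            start = seq.find(query)
            while start != -1:
                hits.append((sid, start, strand))
                start = seq.find(query, start + 1)
    hits.sort()
    return hits


def _placement_from_hits(
    gene: GeneModel,
    probes: Sequence[Probe],
    combo: Sequence[tuple[str, int, str]],
    max_intron_inflation: float,
) -> tuple[str, str, tuple[tuple[int, int], ...]] | None:
    """Check one hit-per-exon combination for consistency; return placement."""
    seqs = {h[0] for h in combo}
    strands = {h[2] for h in combo}
    if len(seqs) != 1 or len(strands) != 1:
        return None
    sid, hit_strand = combo[0][0], combo[0][2]
    exons_t: list[tuple[int, int]] = []
    for probe, (_, start, _) in zip(probes, combo):
        if hit_strand == "+":
            lo = start + probe.left_flank
            hi = start + len(probe.seq) - probe.right_flank
        else:
            lo = start + probe.right_flank
            hi = start + len(probe.seq) - probe.left_flank
        exons_t.append((lo, hi))
    if hit_strand == "-":
        exons_t = exons_t[::-1]  # gene order maps right-to-left on the target
        source_introns = [
            gene.exons[k + 1][0] - gene.exons[k][1]
            for k in range(len(gene.exons) - 1)
        ][::-1]
    else:
        source_introns = [
            gene.exons[k + 1][0] - gene.exons[k][1]
            for k in range(len(gene.exons) - 1)
        ]
    for k in range(len(exons_t) - 1):
        intron = exons_t[k + 1][0] - exons_t[k][1]
        if intron < 1:
            return None
        if intron > max(1, source_introns[k]) * max_intron_inflation:
            return None
    strand = gene.strand if hit_strand == "+" else ("-" if gene.strand == "+" else "+")
    return sid, strand, tuple(sorted(exons_t))


def transfer_gene(
    gene: GeneModel,
    source: Mapping[str, str],
    target: Mapping[str, str],
    flank: int = 20,
    max_intron_inflation: float = 10.0,
    max_combinations: int = 10_000,
) -> TransferResult:
    """Attempt to relocate one gene onto the target assembly.

    Transfer succeeds only when every exon probe hits and exactly one
    consistent combination of hits exists.  Combinatorial blow-ups (more than
    ``max_combinations`` hit combinations) are declared ambiguous.
    """
    probes = extract_probes(gene, source[gene.seq_id], flank)
    per_exon_hits = [place_probe(p.seq, target) for p in probes]
    if any(not h for h in per_exon_hits):
        return TransferResult(gene.gene_id, "failed", reason="exon-missing")

    n_combos = 1
    for h in per_exon_hits:
        n_combos *= len(h)
    if n_combos > max_combinations:
        return TransferResult(gene.gene_id, "failed", reason="multi-hit-ambiguous")

    placements = []
    for combo in itertools.product(*per_exon_hits):
        placement = _placement_from_hits(gene, probes, combo, max_intron_inflation)
        if placement is not None and placement not in placements:
            placements.append(placement)
            if len(placements) > 1:
                return TransferResult(
                    gene.gene_id, "failed", reason="multi-hit-ambiguous"
                )
    if not placements:
        return TransferResult(gene.gene_id, "failed", reason="inconsistent-placement")
    sid, strand, exons = placements[0]
    return TransferResult(
        gene.gene_id, "transferred", seq_id=sid, strand=strand, exons=exons
    )


def transfer_genes(
    genes: Iterable[GeneModel],
    source: Mapping[str, str],
    target: Mapping[str, str],
    flank: int = 20,
    max_intron_inflation: float = 10.0,
) -> list[TransferResult]:
    return [
        transfer_gene(g, source, target, flank, max_intron_inflation) for g in genes
    ]


def transfer_report(
    results: Iterable[TransferResult],
    source_class: Mapping[str, str] | None = None,
    target_class: Mapping[str, str] | None = None,
) -> dict:
    """Summarize transfer outcomes.

    With ``source_class`` (gene id -> class, e.g. anchored/unanchored) and
    ``target_class`` (target sequence id -> class), a relocation table of
    transferred-gene counts by (source class, target class) is included.
    """
    results = list(results)
    n = len(results)
    n_ok = sum(r.status == "transferred" for r in results)
    by_reason: dict[str, int] = {}
    for r in results:
        if r.status == "failed":
            by_reason[r.reason] = by_reason.get(r.reason, 0) + 1
    report = {
        "n_genes": n,
        "n_transferred": n_ok,
        "n_failed": n - n_ok,
        "transfer_rate_pct": 100.0 * n_ok / n if n else 0.0,
        "failures_by_reason": by_reason,
    }
    if source_class is not None and target_class is not None:
        table: dict[tuple[str, str], int] = {}
        for r in results:
            if r.status != "transferred":
                continue
            key = (source_class.get(r.gene_id, "unknown"),
                   target_class.get(r.seq_id, "unknown"))
            table[key] = table.get(key, 0) + 1
        report["relocation"] = {f"{a}->{b}": c for (a, b), c in sorted(table.items())}
    return report


# ---------------------------------------------------------------------------
# GFF3 I/O (two-level gene/exon records)
# ---------------------------------------------------------------------------


def write_gff3(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span
            fh.write(
                f"{g.seq_id}\tchromoforge\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.seq_id}\tchromoforge\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )


def read_gff3(path: str) -> list[GeneModel]:
    meta: dict[str, tuple[str, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            if f[2] == "gene":
                gid = attrs["ID"]
                meta[gid] = (f[0], f[6])
                exons.setdefault(gid, [])
                order.append(gid)
            elif f[2] == "exon":
                gid = attrs["Parent"]
                exons.setdefault(gid, []).append((int(f[3]) - 1, int(f[4])))
    genes = []
    for gid in order:
        seq_id, strand = meta[gid]
        genes.append(
            GeneModel(gid, seq_id, strand, tuple(sorted(exons[gid])))
        )
    return genes
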