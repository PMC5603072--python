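"""Synthetic genomes, crosses and sequencing artifacts with known ground truth.

The simulator produces every input the pipeline consumes: a multi-chromosome
genome fragmented into scaffolds of known order and orientation, a biparental
outcross (CP population) genotyped at SNP markers, GBS-style degradation
(read depth, genotype error, missingness), chimeric contigs with recorded
junctions, concordant mate pairs that never span a chimeric junction, and
multi-exon gene models for liftover testing.

Meiosis follows the Haldane model (no crossover interference): the
recombination fraction between loci d cM apart is ``(1 - exp(-2d/100)) / 2``.
Every operation is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .liftover import GeneModel
from .pseudomolecule import reverse_complement
from .qc import MISSING, N_CATEGORIES, SEG_TYPES, GenotypeMatrix, MarkerMeta
from .screen import Breakpoint, PairAlignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def haldane(d_cm) -> float:
    """Recombination fraction for a genetic distance in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def haldane_inverse(rf) -> float:
    """Genetic distance in cM implied by a recombination fraction."""
    rf = np.asarray(rf, dtype=float)
    return -50.0 * np.log(1.0 - 2.0 * rf)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome and cross.

    Physical scale is desk-size (a few Mb per chromosome) while the genetic
    length per chromosome stays realistic (~100 cM at the defaults), which is
    what two-point anchoring actually senses.  ``seed`` fully determines all
    outputs.
    """

    n_chromosomes: int = 3
    chromosome_length: int = 2_000_000
    n_scaffolds_per_chromosome: int = 10
    n_markers: int = 900
    n_progeny: int = 200
    cm_per_mb: float = 50.0
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    mean_depth: float = 30.0
    seg_type_proportions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    true_gap: int = 100  # bp of real sequence between scaffolds on a chromosome
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chromosome_length",
                     "n_scaffolds_per_chromosome", "n_markers", "n_progeny"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("missing_rate", "genotype_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cm_per_mb <= 0 or self.mean_depth < 0 or self.true_gap < 0:
            raise ValueError("invalid rate parameter")
        if abs(sum(self.seg_type_proportions) - 1.0) > 1e-9:
            raise ValueError("segregation type proportions must sum to 1")


@dataclass(frozen=True)
class MarkerTruth:
    marker_id: str
    chromosome: str
    position: int  # bp on the true chromosome
    cm: float  # genetic position


@dataclass
class TrueGenome:
    """Ground-truth genome: chromosome sequences, scaffold tiling, markers."""

    chromosomes: dict[str, str]
    #: chromosome -> ordered (scaffold_id, start, end, orientation)
    scaffold_map: dict[str, list[tuple[str, int, int, str]]]
    marker_truth: list[MarkerTruth]
    cm_per_mb: float = 50.0

    def scaffold_sequences(self) -> dict[str, str]:
        """Scaffold sequences as assembled (oriented as they would be sequenced)."""
        out: dict[str, str] = {}
        for chrom, intervals in self.scaffold_map.items():
            seq = self.chromosomes[chrom]
            for sid, start, end, orient in intervals:
                piece = seq[start:end]
                out[sid] = reverse_complement(piece) if orient == "-" else piece
        return out

    def true_layout(self) -> dict[str, list[tuple[str, str]]]:
        """Per-chromosome ordered, signed scaffold list (the anchoring truth)."""
        return {
            chrom: [(sid, orient) for sid, _, _, orient in intervals]
            for chrom, intervals in self.scaffold_map.items()
        }

    def marker_locations(self) -> dict[str, tuple[str, int]]:
        """Marker id -> (scaffold id, 0-based position on the scaffold)."""
        out: dict[str, tuple[str, int]] = {}
        by_chrom: dict[str, list[tuple[str, int, int, str]]] = self.scaffold_map
        for mt in self.marker_truth:
            for sid, start, end, orient in by_chrom[mt.chromosome]:
                if start <= mt.position < end:
                    if orient == "+":
                        out[mt.marker_id] = (sid, mt.position - start)
                    else:
                        out[mt.marker_id] = (sid, end - 1 - mt.position)
                    break
            else:
                raise ValueError(f"marker {mt.marker_id} outside every scaffold")
        return out

    def marker_chromosome(self) -> dict[str, str]:
        return {mt.marker_id: mt.chromosome for mt in self.marker_truth}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def simulate_genome(config: SimConfig) -> TrueGenome:
    """Draw a genome with a known scaffold tiling and marker placement.

    Scaffold lengths follow a log-normal spread normalized to the chromosome
    length (minus fixed inter-scaffold gaps); marker positions are uniform
    over scaffold-covered sequence, distinct, and sorted.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    chromosomes: dict[str, str] = {}
    scaffold_map: dict[str, list[tuple[str, int, int, str]]] = {}
    marker_truth: list[MarkerTruth] = []

    n_scaf = config.n_scaffolds_per_chromosome
    per_chrom = [config.n_markers // config.n_chromosomes] * config.n_chromosomes
    for k in range(config.n_markers % config.n_chromosomes):
        per_chrom[k] += 1

    scaffold_counter = 0
    marker_counter = 0
    for c in range(config.n_chromosomes):
        chrom = f"chrom_{c + 1}"
        length = config.chromosome_length
        chromosomes[chrom] = _random_sequence(rng, length)

        avail = length - (n_scaf - 1) * config.true_gap
        if avail < n_scaf:
            raise ValueError("chromosome too short for requested scaffolds/gaps")
        weights = rng.lognormal(0.0, 0.4, n_scaf)
        lens = np.maximum((weights / weights.sum() * avail).astype(int), 1)
        lens[-1] += avail - lens.sum()
        intervals = []
        pos = 0
        for ln in lens:
            scaffold_counter += 1
            sid = f"scaffold_{scaffold_counter:04d}"
            # a scaffold tiling a whole chromosome has no meaningful sign
            orient = "+" if n_scaf == 1 or rng.random() < 0.5 else "-"
            intervals.append((sid, pos, pos + int(ln), orient))
            pos += int(ln) + config.true_gap
        scaffold_map[chrom] = intervals

        covered = np.concatenate(
            [np.arange(s, e) for _, s, e, _ in intervals]
        )
        n_mark = per_chrom[c]
        if n_mark > covered.size:
            raise ValueError("more markers requested than placeable positions")
        positions = np.sort(rng.choice(covered, size=n_mark, replace=False))
        for p in positions:
            marker_counter += 1
            marker_truth.append(
                MarkerTruth(
                    marker_id=f"M{marker_counter:05d}",
                    chromosome=chrom,
                    position=int(p),
                    cm=float(p) * config.cm_per_mb / 1e6,
                )
            )
    return TrueGenome(chromosomes, scaffold_map, marker_truth, config.cm_per_mb)


def simulate_cross(genome: TrueGenome, config: SimConfig) -> GenotypeMatrix:
    """Genotype a simulated biparental outcross at the genome's markers.

    Both parents undergo independent Haldane meioses per progeny; each marker
    is assigned a CP segregation class (lmxll / nnxnp / hkxhk in the
    configured proportions) with a random linkage phase per informative
    parent.  The clean matrix carries a constant read depth of
    ``round(mean_depth)``; :func:`degrade_genotypes` adds realism.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    markers = genome.marker_truth
    n_mark, n_prog = len(markers), config.n_progeny
    seg_idx = rng.choice(3, size=n_mark, p=list(config.seg_type_proportions))
    phase1 = rng.integers(0, 2, n_mark).astype(np.int8)
    phase2 = rng.integers(0, 2, n_mark).astype(np.int8)

    calls = np.zeros((n_mark, n_prog), dtype=np.int8)
    # per chromosome, per parent: inheritance indicator matrices
    start = 0
    while start < n_mark:
        chrom = markers[start].chromosome
        stop = start
        while stop < n_mark and markers[stop].chromosome == chrom:
            stop += 1
        cms = np.array([markers[k].cm for k in range(start, stop)])
        r = haldane(np.diff(cms))
        m = stop - start
        alleles = np.zeros((2, n_prog, m), dtype=np.int8)
        for parent in range(2):
            first = rng.integers(0, 2, (n_prog, 1)).astype(np.int8)
            if m > 1:
                switch = (rng.random((n_prog, m - 1)) < r[None, :]).astype(np.int8)
                h = np.bitwise_xor.accumulate(
                    np.concatenate([first, switch], axis=1), axis=1
                )
            else:
                h = first
            alleles[parent] = h
        seg = seg_idx[start:stop]
        ph1 = phase1[start:stop]
        ph2 = phase2[start:stop]
        a1 = np.where(seg[None, :] != 1, alleles[0] ^ ph1[None, :], 0)
        a2 = np.where(seg[None, :] != 0, alleles[1] ^ ph2[None, :], 0)
        calls[start:stop] = (a1 + a2).T
        start = stop

    locations = genome.marker_locations()
    metas = []
    ref_idx = rng.integers(0, 4, n_mark)
    alt_shift = rng.integers(1, 4, n_mark)
    bases = "ACGT"
    for k, mt in enumerate(markers):
        sid, pos = locations[mt.marker_id]
        metas.append(
            MarkerMeta(
                marker_id=mt.marker_id,
                scaffold_id=sid,
                position=pos,
                segregation_type=SEG_TYPES[seg_idx[k]],
                ref=bases[ref_idx[k]],
                alt=(bases[(ref_idx[k] + alt_shift[k]) % 4],),
            )
        )
    samples = [f"progeny_{j + 1:03d}" for j in range(n_prog)]
    depths = np.full((n_mark, n_prog), int(round(config.mean_depth)), dtype=np.int32)
    return GenotypeMatrix(metas, samples, calls, depths)


def degrade_genotypes(gm: GenotypeMatrix, config: SimConfig) -> GenotypeMatrix:
    """Apply GBS-style imperfection: Poisson depth, category flips, missingness.

    Calls are flipped to a different legal category with probability
    ``genotype_error_rate`` and erased with probability ``missing_rate``;
    per-call depths are redrawn from Poisson(``mean_depth``).  The input is
    left untouched (the clean truth stays available for recovery checks).
    """
    rng = np.random.default_rng([int(config.seed), 2])
    out = gm.copy()
    shape = out.calls.shape
    out.depths = rng.poisson(config.mean_depth, shape).astype(np.int32)
    ncat = np.array(
        [N_CATEGORIES[m.segregation_type] for m in out.markers], dtype=np.int8
    )[:, None]
    if config.genotype_error_rate > 0:
        err = rng.random(shape) < config.genotype_error_rate
        shift = 1 + np.floor(rng.random(shape) * (ncat - 1)).astype(np.int8)
        flippable = err & (out.calls != MISSING)
        out.calls = np.where(
            flippable, (out.calls + shift) % ncat, out.calls
        ).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(shape) < config.missing_rate
        out.calls[miss] = MISSING
    return out


# ---------------------------------------------------------------------------
# Misassembled contigs and mate pairs
# ---------------------------------------------------------------------------


@dataclass
class ContigSet:
    """Contig sequences plus the contiguous true-genome segments inside each.

    A non-chimeric contig has a single segment covering its whole length; a
    chimeric contig has one segment per source fragment, so mate-pair
    simulation never samples a pair across the junction.
    """

    sequences: dict[str, str]
    segments: dict[str, list[tuple[int, int]]]
    sources: dict[str, tuple[str, str]] = field(default_factory=dict)

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "ContigSet":
        seqs = dict(sequences)
        return cls(seqs, {cid: [(0, len(s))] for cid, s in seqs.items()})


def inject_misassemblies(
    genome: TrueGenome, n_chimeras: int, seed: int
) -> tuple[ContigSet, list[Breakpoint]]:
    """Replace ``2*n_chimeras`` scaffolds by chimeric concatenations.

    Each chimera joins two whole scaffolds from (usually) different loci; the
    junction coordinate is recorded as ground truth.  With ``n_chimeras=0``
    the contig set equals the scaffold set.
    """
    scaffolds = genome.scaffold_sequences()
    ids = sorted(scaffolds)
    if 2 * n_chimeras > len(ids):
        raise ValueError(
            f"{n_chimeras} chimeras need {2 * n_chimeras} scaffolds, "
            f"only {len(ids)} available"
        )
    rng = np.random.default_rng([int(seed), 5])
    chosen = list(rng.choice(ids, size=2 * n_chimeras, replace=False))
    sequences: dict[str, str] = {}
    segments: dict[str, list[tuple[int, int]]] = {}
    sources: dict[str, tuple[str, str]] = {}
    breakpoints: list[Breakpoint] = []
    for k in range(n_chimeras):
        a, b = chosen[2 * k], chosen[2 * k + 1]
        cid = f"chimera_{k + 1:03d}"
        sa, sb = scaffolds[a], scaffolds[b]
        sequences[cid] = sa + sb
        segments[cid] = [(0, len(sa)), (len(sa), len(sa) + len(sb))]
        sources[cid] = (a, b)
        breakpoints.append(
            Breakpoint(contig_id=cid, position=len(sa), window=(len(sa), len(sa)))
        )
    used = set(chosen)
    for sid in ids:
        if sid not in used:
            sequences[sid] = scaffolds[sid]
            segments[sid] = [(0, len(scaffolds[sid]))]
    return ContigSet(sequences, segments, sources), breakpoints


def simulate_mate_pairs(
    contigs: ContigSet | Mapping[str, str],
    insert_mean: float = 5000.0,
    insert_sd: float = 500.0,
    coverage: float = 20.0,
    seed: int = 0,
    read_length: int = 100,
) -> list[PairAlignment]:
    """Sample concordant large-insert pairs from contiguous true sequence only.

    Pair count per segment targets ``coverage`` fold in read bases; inserts
    are Normal(mean, sd) truncated to fit the segment.  Chimeric junctions
    therefore receive zero spanning pairs by construction, and contigs (or
    segments) shorter than an insert simply yield none.
    """
    if not isinstance(contigs, ContigSet):
        contigs = ContigSet.from_sequences(contigs)
    rng = np.random.default_rng([int(seed), 6])
    pairs: list[PairAlignment] = []
    for cid in sorted(contigs.sequences):
        for seg_start, seg_end in contigs.segments[cid]:
            length = seg_end - seg_start
            min_insert = 2 * read_length + 1
            if length < min_insert or coverage <= 0:
                continue
            n_pairs = int(round(coverage * length / (2 * read_length)))
            if n_pairs == 0:
                continue
            inserts = np.clip(
                np.rint(rng.normal(insert_mean, insert_sd, n_pairs)),
                min_insert,
                length,
            ).astype(np.int64)
            starts = seg_start + np.floor(
                rng.random(n_pairs) * (length - inserts + 1)
            ).astype(np.int64)
            for s, ins in zip(starts, inserts):
                pairs.append(
                    PairAlignment(
                        contig_id=cid,
                        start1=int(s),
                        end1=int(s + read_length),
                        start2=int(s + ins - read_length),
                        end2=int(s + ins),
                    )
                )
    return pairs


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def simulate_gene_models(
    genome: TrueGenome,
    n_genes: int,
    seed: int,
    n_exons_range: tuple[int, int] = (1, 4),
    exon_length_range: tuple[int, int] = (80, 300),
    intron_length_range: tuple[int, int] = (60, 250),
    margin: int = 20,
) -> list[GeneModel]:
    """Place non-overlapping multi-exon genes inside scaffolds.

    Exon intervals are sorted and non-overlapping, strands random, and each
    gene leaves ``margin`` bp to the scaffold ends so flank-extended probes
    remain un-clipped.  Deterministic per seed.
    """
    rng = np.random.default_rng([int(seed), 7])
    scaffolds = genome.scaffold_sequences()
    sids = sorted(scaffolds)
    lengths = np.array([len(scaffolds[s]) for s in sids], dtype=float)
    weights = lengths / lengths.sum()
    used: dict[str, list[tuple[int, int]]] = {s: [] for s in sids}
    genes: list[GeneModel] = []
    attempts = 0
    while len(genes) < n_genes and attempts < 100 * n_genes:
        attempts += 1
        sid = sids[int(rng.choice(len(sids), p=weights))]
        length = len(scaffolds[sid])
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        exon_lens = rng.integers(*exon_length_range, size=n_exons)
        intron_lens = rng.integers(*intron_length_range, size=max(0, n_exons - 1))
        span = int(exon_lens.sum() + intron_lens.sum())
        if length < span + 2 * margin + 2:
            continue
        start = int(rng.integers(margin, length - span - margin))
        lo, hi = start, start + span
        if any(not (hi <= a or lo >= b) for a, b in used[sid]):
            continue
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        used[sid].append((lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"gene_{len(genes) + 1:04d}", sid, strand, tuple(exons))
        )
    if len(genes) < n_genes:
        raise ValueError("could not place all requested genes without overlap")
    return genes


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    """Write sequences wrapped at 60 columns."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_truth_json(
    genome: TrueGenome,
    path: str,
    breakpoints: Sequence[Breakpoint] = (),
) -> None:
    """Dump the ground truth (layout, markers, injected junctions) as JSON."""
    payload = {
        "scaffold_map": {
            chrom: [
                {"scaffold": sid, "start": s, "end": e, "orientation": o}
                for sid, s, e, o in intervals
            ]
            for chrom, intervals in genome.scaffold_map.items()
        },
        "markers": [
            dataclasses.asdict(mt) for mt in genome.marker_truth
        ],
        "breakpoints": [
            {"contig": bp.contig_id, "position": bp.position}
            for bp in breakpoints
        ],
        "cm_per_mb": genome.cm_per_mb,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
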