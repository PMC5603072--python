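"""GBS genotype matrices and the marker quality-control cascade.

Genotypes from an outcrossing biparental population (a CP cross) are held as a
markers x progeny matrix of small integer codes.  Each marker belongs to one of
three segregation classes, following the usual cross-pollinator notation:

``lmxll``
    first parent heterozygous (l/m), second homozygous; progeny are ``ll`` (0)
    or ``lm`` (1) and segregate 1:1.
``nnxnp``
    second parent heterozygous; progeny ``nn`` (0) or ``np`` (1), 1:1.
``hkxhk``
    both parents heterozygous for the same alleles; progeny ``hh`` (0),
    ``hk`` (1) or ``kk`` (2), segregating 1:2:1.

The QC cascade applies, in fixed order: biallelic-SNP selection, per-call read
depth masking (calls backed by fewer than ``min_depth`` reads become missing),
per-marker missingness filtering, minor-allele-frequency filtering, and a
chi-square test against the Mendelian segregation ratio.  Inequalities are
strict where the defaults say so: depth < 10 masks, missing fraction > 0.5
drops, MAF must exceed 0.01, and the segregation P-value must exceed 1e-6.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

MISSING = -1

SEG_TYPES = ("lmxll", "nnxnp", "hkxhk")

#: number of legal genotype categories per segregation class
N_CATEGORIES = {"lmxll": 2, "nnxnp": 2, "hkxhk": 3}

#: human-readable genotype labels, indexed by integer code
CATEGORY_LABELS = {
    "lmxll": ("ll", "lm"),
    "nnxnp": ("nn", "np"),
    "hkxhk": ("hh", "hk", "kk"),
}

#: expected Mendelian proportions per category
SEG_RATIOS = {
    "lmxll": (0.5, 0.5),
    "nnxnp": (0.5, 0.5),
    "hkxhk": (0.25, 0.5, 0.25),
}


@dataclass
class MarkerMeta:
    """Per-marker metadata: location on a scaffold and segregation class."""

    marker_id: str
    scaffold_id: str
    position: int  # 0-based bp on the scaffold
    segregation_type: str
    is_snp: bool = True
    n_alleles: int = 2
    ref: str = "A"
    alt: tuple[str, ...] = ("C",)

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position for {self.marker_id}")
        if self.n_alleles < 2:
            raise ValueError(f"n_alleles < 2 for {self.marker_id}")
        if self.segregation_type not in SEG_TYPES:
            raise ValueError(f"unknown segregation type {self.segregation_type!r}")


@dataclass
class GenotypeMatrix:
    """Markers x samples categorical genotype calls with per-call read depth.

    ``calls`` uses the integer coding of :data:`CATEGORY_LABELS` with
    :data:`MISSING` (= -1) as the missing sentinel.  ``depths`` may be ``None``
    when the source carried no per-call depth; depth-dependent operations then
    refuse to run rather than silently passing everything.
    """

    markers: list[MarkerMeta]
    samples: list[str]
    calls: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError("calls shape does not match markers x samples")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=np.int32)
            if self.depths.shape != self.calls.shape:
                raise ValueError("depths shape does not match calls")
        for i, m in enumerate(self.markers):
            ncat = N_CATEGORIES[m.segregation_type]
            row = self.calls[i]
            bad = (row != MISSING) & ((row < 0) | (row >= ncat))
            if bad.any():
                raise ValueError(f"illegal genotype code for marker {m.marker_id}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [dataclasses.replace(m) for m in self.markers],
            list(self.samples),
            self.calls.copy(),
            None if self.depths is None else self.depths.copy(),
        )

    def subset(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = list(rows)
        return GenotypeMatrix(
            [dataclasses.replace(self.markers[i]) for i in rows],
            list(self.samples),
            self.calls[rows].copy(),
            None if self.depths is None else self.depths[rows].copy(),
        )

    def marker_index(self) -> dict[str, int]:
        return {m.marker_id: i for i, m in enumerate(self.markers)}

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=1)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_GT_BY_CODE = {
    # segregation type -> code -> VCF GT string (parent-1 allele coded as REF)
    "lmxll": {0: "0/0", 1: "0/1"},
    "nnxnp": {0: "0/0", 1: "0/1"},
    "hkxhk": {0: "0/0", 1: "0/1", 2: "1/1"},
}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a plain-text VCF v4.2 with GT (and DP when present) per sample.

    CHROM is the scaffold id, POS the 1-based marker position and the
    segregation class travels in ``INFO/SEG`` so that loading is lossless.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen: dict[str, None] = {}
        for m in gm.markers:
            seen.setdefault(m.scaffold_id, None)
        for sid in seen:
            fh.write(f"##contig=<ID={sid}>\n")
        fh.write('##INFO=<ID=SEG,Number=1,Type=String,Description="CP segregation type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        fmt = "GT:DP" if gm.depths is not None else "GT"
        for i, m in enumerate(gm.markers):
            gt_map = _GT_BY_CODE[m.segregation_type]
            cols = [
                m.scaffold_id,
                str(m.position + 1),
                m.marker_id,
                m.ref,
                ",".join(m.alt),
                ".",
                "PASS",
                f"SEG={m.segregation_type}",
                fmt,
            ]
            for j in range(gm.n_samples):
                code = int(gm.calls[i, j])
                gt = "./." if code == MISSING else gt_map[code]
                if gm.depths is not None:
                    gt = f"{gt}:{int(gm.depths[i, j])}"
                cols.append(gt)
            fh.write("\t".join(cols) + "\n")


def _infer_segregation(gt_types: np.ndarray, parent_idx: tuple[int, int] | None) -> str:
    """Infer the CP segregation class of one VCF record.

    With parent columns the parents' het/hom pattern decides; otherwise the
    progeny genotype classes are used (hom-alt present implies both parents
    were heterozygous).
    """
    if parent_idx is not None:
        p1, p2 = (gt_types[k] for k in parent_idx)
        p1_het, p2_het = p1 == 1, p2 == 1
        if p1_het and p2_het:
            return "hkxhk"
        if p1_het:
            return "lmxll"
        if p2_het:
            return "nnxnp"
        return "lmxll"  # uninformative marker; class is moot
    if (gt_types == 3).any():
        return "hkxhk"
    return "lmxll"


def load_vcf(path: str, parents: tuple[str, str] | None = None) -> GenotypeMatrix:
    """Load genotypes from a VCF with per-sample GT (and optionally DP).

    Records are classified as SNP/indel/multi-allelic from REF/ALT.  The
    segregation class is taken from ``INFO/SEG`` when present; otherwise it is
    inferred from the parental columns named in ``parents`` (which are removed
    from the sample set) or, failing that, from the progeny genotype classes.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    parent_idx = None
    keep = list(range(len(samples)))
    if parents is not None:
        parent_idx = (samples.index(parents[0]), samples.index(parents[1]))
        keep = [k for k in keep if k not in parent_idx]

    markers: list[MarkerMeta] = []
    call_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    any_depth = False
    for var in vcf:
        alts = tuple(var.ALT)
        n_alleles = 1 + len(alts)
        is_snp = len(var.REF) == 1 and all(len(a) == 1 and a in "ACGT" for a in alts)
        seg = var.INFO.get("SEG")
        gt_types = np.asarray(var.gt_types)
        if seg is None:
            seg = _infer_segregation(gt_types, parent_idx)
        ncat = N_CATEGORIES[seg]
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        codes[gt_types == 0] = 0
        codes[gt_types == 1] = 1
        codes[gt_types == 3] = 2 if ncat == 3 else MISSING
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_depth = True
            dp = dp.reshape(-1).astype(np.int64)
            dp = np.where(dp < 0, 0, dp)
        else:
            dp = np.zeros(len(samples), dtype=np.int64)
        markers.append(
            MarkerMeta(
                marker_id=var.ID or f"{var.CHROM}_{var.POS}",
                scaffold_id=var.CHROM,
                position=var.POS - 1,
                segregation_type=seg,
                is_snp=is_snp,
                n_alleles=n_alleles,
                ref=var.REF,
                alt=alts,
            )
        )
        call_rows.append(codes[keep])
        depth_rows.append(dp[keep])

    n = len(markers)
    calls = np.vstack(call_rows) if n else np.zeros((0, len(keep)), dtype=np.int8)
    depths = np.vstack(depth_rows) if (n and any_depth) else None
    return GenotypeMatrix(markers, [samples[k] for k in keep], calls, depths)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_biallelic_snps(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only biallelic SNP markers (indels and multi-allelic sites go)."""
    rows = [i for i, m in enumerate(gm.markers) if m.is_snp and m.n_alleles == 2]
    return gm.subset(rows)


def mask_low_depth(gm: GenotypeMatrix, min_depth: int = 10) -> GenotypeMatrix:
    """Set calls backed by fewer than ``min_depth`` reads to missing.

    Depths themselves are left untouched.  Raises when the matrix carries no
    depth information (a silent no-op would defeat the filter).
    """
    if min_depth <= 0:
        return gm.copy()
    if gm.depths is None:
        raise ValueError("genotype matrix has no per-call depths; cannot depth-mask")
    out = gm.copy()
    out.calls[out.depths < min_depth] = MISSING
    return out


def filter_missing(gm: GenotypeMatrix, max_missing: float = 0.5) -> GenotypeMatrix:
    """Drop markers whose missing-call fraction exceeds ``max_missing`` (strict)."""
    frac = gm.missing_fraction()
    rows = [i for i in range(gm.n_markers) if frac[i] <= max_missing]
    return gm.subset(rows)


def minor_allele_frequency(row: np.ndarray, seg_type: str) -> float:
    """MAF of one marker row from expanded allele counts over non-missing calls.

    For testcross markers the counts are those of the segregating parent's two
    alleles as seen in the progeny (e.g. ``lm`` contributes one ``m``); for
    ``hkxhk`` the h/k allele tally.  Returns NaN when no call is observed.
    """
    obs = row[row != MISSING]
    if obs.size == 0:
        return float("nan")
    if seg_type == "hkxhk":
        minor_count = int(2 * (obs == 2).sum() + (obs == 1).sum())
    else:
        minor_count = int((obs == 1).sum())
    total = 2 * obs.size
    f = minor_count / total
    return min(f, 1.0 - f)


def filter_maf(
    gm: GenotypeMatrix, min_maf: float = 0.01
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Keep markers with minor allele frequency strictly above ``min_maf``.

    Returns the filtered matrix and a list of (marker_id, reason) drops;
    markers with zero non-missing calls are dropped with reason ``no data``.
    """
    rows: list[int] = []
    dropped: list[tuple[str, str]] = []
    for i, m in enumerate(gm.markers):
        maf = minor_allele_frequency(gm.calls[i], m.segregation_type)
        if np.isnan(maf):
            dropped.append((m.marker_id, "no data"))
        elif maf > min_maf:
            rows.append(i)
        else:
            dropped.append((m.marker_id, f"maf {maf:.4g} <= {min_maf}"))
    return gm.subset(rows), dropped


def segregation_chisq(row: np.ndarray, seg_type: str) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of one marker row against its Mendelian ratio.

    1:1 for testcross classes, 1:2:1 for ``hkxhk``; no continuity correction.
    Returns ``(chi2, df, p)``; raises on a row with no observed calls.
    """
    obs_calls = row[row != MISSING]
    n = obs_calls.size
    if n == 0:
        raise ValueError("no observed calls; segregation test undefined")
    ratios = SEG_RATIOS[seg_type]
    observed = np.array([(obs_calls == c).sum() for c in range(len(ratios))], dtype=float)
    expected = np.asarray(ratios) * n
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = len(ratios) - 1
    p = float(_chi2_dist.sf(stat, df))
    return stat, df, p


def filter_segregation(
    gm: GenotypeMatrix, min_p: float = 1e-6
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Keep markers whose segregation-test P-value is strictly above ``min_p``."""
    rows: list[int] = []
    dropped: list[tuple[str, str]] = []
    for i, m in enumerate(gm.markers):
        try:
            _, _, p = segregation_chisq(gm.calls[i], m.segregation_type)
        except ValueError:
            dropped.append((m.marker_id, "no data"))
            continue
        if p > min_p:
            rows.append(i)
        else:
            dropped.append((m.marker_id, f"seg p {p:.3g} <= {min_p}"))
    return gm.subset(rows), dropped


@dataclass
class QCParams:
    min_depth: int = 10
    max_missing: float = 0.5
    min_maf: float = 0.01
    seg_p: float = 1e-6


@dataclass
class QCReport:
    """Marker counts surviving each stage of the cascade, plus drop reasons."""

    stages: list[tuple[str, int]] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [{"stage": s, "markers": n} for s, n in self.stages]


def run_qc_cascade(
    gm: GenotypeMatrix, params: QCParams | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full marker filter cascade in its fixed order.

    biallelic SNPs -> depth masking -> missingness -> MAF -> segregation test.
    The order is part of the contract: depth masking changes missingness, so
    the filters do not commute.
    """
    params = params or QCParams()
    report = QCReport()
    report.stages.append(("input", gm.n_markers))

    gm = filter_biallelic_snps(gm)
    report.stages.append(("biallelic_snp", gm.n_markers))

    gm = mask_low_depth(gm, params.min_depth)
    report.stages.append(("depth_mask", gm.n_markers))

    gm = filter_missing(gm, params.max_missing)
    report.stages.append(("missingness", gm.n_markers))

    gm, dropped = filter_maf(gm, params.min_maf)
    report.dropped.extend(dropped)
    report.stages.append(("maf", gm.n_markers))

    gm, dropped = filter_segregation(gm, params.seg_p)
    report.dropped.extend(dropped)
    report.stages.append(("segregation", gm.n_markers))
    return gm, report
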