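"""Two-point recombination analysis and linkage-group assignment.

For an outcrossing (CP) population the information content of a marker pair
depends on which parents are heterozygous:

* same-parent testcross pairs (lmxll-lmxll, nnxnp-nnxnp): the recombination
  fraction is a direct recombinant count under the better of the two linkage
  phases;
* pairs involving hkxhk markers: some progeny classes are phase-ambiguous, so
  the ML recombination fraction is found by EM over the two-point likelihood,
  maximized over the parental phase combinations;
* testcross pairs segregating from *different* parents (lmxll-nnxnp) carry no
  two-point information and are flagged unusable (``n_inf = 0``).

LOD is ``log10 L(rf_hat) / L(0.5)``; markers are grouped by single-linkage
closure of edges with ``rf <= rf_max`` and ``lod >= lod_min``.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .qc import MISSING, N_CATEGORIES, GenotypeMatrix

_LN10 = math.log(10.0)

#: per segregation type: (parent1 homolog alleles, parent2 homolog alleles),
#: 1 marking the minor allele (m/p/k); progeny code = sum of inherited alleles
PARENT_HOMOLOGS = {
    "lmxll": ((0, 1), (0, 0)),
    "nnxnp": ((0, 0), (0, 1)),
    "hkxhk": ((0, 1), (0, 1)),
}


@functools.lru_cache(maxsize=None)
def _pair_models(type_i: str, type_j: str) -> tuple[int, tuple[np.ndarray, ...]]:
    """Class-probability coefficient matrices for a marker-type pair.

    For each parental phase combination, returns a matrix ``K`` of shape
    (C_i*C_j, G+1) such that the probability of joint progeny class c is
    ``sum_k K[c, k] * r^k * (1-r)^(G-k)``, where G is the number of
    doubly-heterozygous (informative) parents and k counts recombinant
    gametes.  Returns ``(G, (K_phase0, K_phase1, ...))``.
    """
    ci, cj = N_CATEGORIES[type_i], N_CATEGORIES[type_j]
    homs_i = PARENT_HOMOLOGS[type_i]
    homs_j = PARENT_HOMOLOGS[type_j]
    informative = [
        homs_i[p][0] != homs_i[p][1] and homs_j[p][0] != homs_j[p][1]
        for p in (0, 1)
    ]
    g = sum(informative)
    flip_axes = [(0, 1) if informative[p] else (0,) for p in (0, 1)]
    matrices = []
    for flips in itertools.product(*flip_axes):
        parent_opts = []
        for p in (0, 1):
            hi, hj = homs_i[p], homs_j[p]
            if flips[p]:
                hj = hj[::-1]
            het_i, het_j = hi[0] != hi[1], hj[0] != hj[1]
            if het_i and het_j:
                opts = [
                    (hi[0], hj[0], 0, 0.5), (hi[1], hj[1], 0, 0.5),
                    (hi[0], hj[1], 1, 0.5), (hi[1], hj[0], 1, 0.5),
                ]
            elif het_i:
                opts = [(hi[0], hj[0], 0, 0.5), (hi[1], hj[0], 0, 0.5)]
            elif het_j:
                opts = [(hi[0], hj[0], 0, 0.5), (hi[0], hj[1], 0, 0.5)]
            else:
                opts = [(hi[0], hj[0], 0, 1.0)]
            parent_opts.append(opts)
        k_mat = np.zeros((ci * cj, g + 1))
        for o1, o2 in itertools.product(*parent_opts):
            cls = (o1[0] + o2[0]) * cj + (o1[1] + o2[1])
            k_mat[cls, o1[2] + o2[2]] += o1[3] * o2[3]
        matrices.append(k_mat)
    return g, tuple(matrices)


def _powers(r: np.ndarray, g: int) -> np.ndarray:
    if g == 1:
        return np.stack([1.0 - r, r], axis=-1)
    return np.stack([(1.0 - r) ** 2, r * (1.0 - r), r ** 2], axis=-1)


def _loglik(counts: np.ndarray, k_mat: np.ndarray, r: np.ndarray, g: int) -> np.ndarray:
    probs = _powers(r, g) @ k_mat.T
    safe = np.log(np.maximum(probs, 1e-300))
    return np.where(counts > 0, counts * safe, 0.0).sum(axis=-1)


def _em_rf(
    counts: np.ndarray, k_mat: np.ndarray, g: int,
    max_iter: int = 100, tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EM for the recombination fraction, one row per marker pair.

    ``counts`` has one row per pair and one column per joint progeny class.
    Returns the converged r and the log-likelihood at r.
    """
    karr = np.arange(g + 1, dtype=float)
    k_weighted = k_mat * karr
    n = counts.sum(axis=1)
    n_safe = np.where(n > 0, n, 1.0)
    r = np.full(counts.shape[0], 0.25)
    for _ in range(max_iter):
        pk = _powers(r, g)
        probs = pk @ k_mat.T
        numer = pk @ k_weighted.T
        expected = np.divide(
            numer, probs, out=np.zeros_like(numer), where=probs > 0
        )
        r_new = (counts * expected).sum(axis=1) / (g * n_safe)
        r_new = np.clip(r_new, 1e-9, 1.0 - 1e-9)
        if np.all(np.abs(r_new - r) < tol):
            r = r_new
            break
        r = r_new
    return r, _loglik(counts, k_mat, r, g)


def _rf_em_pairs(
    counts: np.ndarray, type_i: str, type_j: str
) -> tuple[np.ndarray, np.ndarray]:
    """ML rf and LOD for many pairs at once, maximized over parental phases."""
    g, models = _pair_models(type_i, type_j)
    if g == 0:
        raise ValueError("uninformative type pair")
    results = [_em_rf(counts, k_mat, g) for k_mat in models]
    all_r = np.stack([r for r, _ in results])
    all_ll = np.stack([ll for _, ll in results])
    # phases with (relatively) tied likelihood resolve to the smaller rf
    ll_max = all_ll.max(axis=0)
    tol = 1e-7 * (np.abs(ll_max) + 1.0)
    tied = all_ll >= ll_max - tol
    masked_r = np.where(tied, all_r, np.inf)
    best_r = masked_r.min(axis=0)
    best_ll = np.take_along_axis(
        all_ll, np.argmin(masked_r, axis=0)[None, :], axis=0
    )[0]
    # at r = 0.5 the phase does not matter: gametes are independent
    ll_half = _loglik(counts, models[0], np.full(counts.shape[0], 0.5), g)
    lod = np.maximum((best_ll - ll_half) / _LN10, 0.0)
    rf = np.minimum(best_r, 0.5)
    return rf, lod


def _testcross_rf_lod(
    mismatch: np.ndarray, n: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form rf/LOD for same-parent testcross pairs (best phase)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        rec = np.minimum(mismatch, n - mismatch)
        rf = rec / n
        term_r = np.where(rec > 0, rec * np.log10(np.maximum(2.0 * rf, 1e-300)), 0.0)
        term_p = np.where(
            n - rec > 0,
            (n - rec) * np.log10(np.maximum(2.0 * (1.0 - rf), 1e-300)),
            0.0,
        )
        lod = np.maximum(term_r + term_p, 0.0)
    rf = np.where(n > 0, rf, np.nan)
    lod = np.where(n > 0, lod, 0.0)
    return rf, lod


def estimate_rf(
    calls_i: np.ndarray,
    calls_j: np.ndarray,
    type_i: str,
    type_j: str,
) -> tuple[float, float, int]:
    """Two-point recombination fraction, LOD and informative count for one pair.

    Returns ``(rf, lod, n_inf)``; an unusable pair (no informative parent, or
    no jointly observed progeny) yields ``(nan, 0.0, 0)`` rather than raising.
    """
    calls_i = np.asarray(calls_i, dtype=np.int8)
    calls_j = np.asarray(calls_j, dtype=np.int8)
    valid = (calls_i != MISSING) & (calls_j != MISSING)
    n_inf = int(valid.sum())
    g, _ = _pair_models(type_i, type_j)
    if g == 0 or n_inf == 0:
        return float("nan"), 0.0, 0
    xi, xj = calls_i[valid], calls_j[valid]
    testcross = {type_i, type_j} <= {"lmxll"} or {type_i, type_j} <= {"nnxnp"}
    if testcross:
        mismatch = np.array([float((xi != xj).sum())])
        rf, lod = _testcross_rf_lod(mismatch, np.array([float(n_inf)]))
        return float(rf[0]), float(lod[0]), n_inf
    cj = N_CATEGORIES[type_j]
    counts = np.bincount(
        (xi.astype(np.int64) * cj + xj), minlength=N_CATEGORIES[type_i] * cj
    ).astype(float)[None, :]
    rf, lod = _rf_em_pairs(counts, type_i, type_j)
    return float(rf[0]), float(lod[0]), n_inf


# ---------------------------------------------------------------------------
# Pairwise matrix
# ---------------------------------------------------------------------------


@dataclass
class RecombinationMatrix:
    """Symmetric pairwise recombination fractions with LOD and n_inf."""

    marker_ids: list[str]
    rf: np.ndarray
    lod: np.ndarray
    n_inf: np.ndarray

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def index(self) -> dict[str, int]:
        return {mid: k for k, mid in enumerate(self.marker_ids)}

    def usable(self) -> np.ndarray:
        return (self.n_inf > 0) & ~np.isnan(self.rf)

    def write_tsv(self, rf_path: str, lod_path: str | None = None) -> None:
        pd.DataFrame(self.rf, index=self.marker_ids, columns=self.marker_ids).to_csv(
            rf_path, sep="\t", float_format="%.6g"
        )
        if lod_path:
            pd.DataFrame(
                self.lod, index=self.marker_ids, columns=self.marker_ids
            ).to_csv(lod_path, sep="\t", float_format="%.6g")


def build_rf_matrix(gm: GenotypeMatrix) -> RecombinationMatrix:
    """All-pairs two-point estimates, computed per segregation-type block.

    Same-parent testcross blocks use the vectorized closed form; blocks
    involving hkxhk markers run the vectorized EM.  Cross-parent testcross
    pairs stay unusable.
    """
    m = gm.n_markers
    rf = np.full((m, m), np.nan)
    lod = np.zeros((m, m))
    n_inf = np.zeros((m, m), dtype=np.int64)
    valid = gm.calls != MISSING
    types = np.array([mk.segregation_type for mk in gm.markers])
    idx_of = {t: np.flatnonzero(types == t) for t in ("lmxll", "nnxnp", "hkxhk")}

    for t in ("lmxll", "nnxnp"):
        idx = idx_of[t]
        if idx.size == 0:
            continue
        x = gm.calls[idx]
        v = valid[idx].astype(np.float64)
        p1 = ((x == 1) & valid[idx]).astype(np.float64)
        p0 = ((x == 0) & valid[idx]).astype(np.float64)
        n = v @ v.T
        mismatch = p1 @ p0.T + p0 @ p1.T
        block_rf, block_lod = _testcross_rf_lod(mismatch, n)
        rf[np.ix_(idx, idx)] = block_rf
        lod[np.ix_(idx, idx)] = block_lod
        n_inf[np.ix_(idx, idx)] = n.astype(np.int64)

    em_blocks = [("lmxll", "hkxhk"), ("nnxnp", "hkxhk"), ("hkxhk", "hkxhk")]
    for ta, tb in em_blocks:
        ia, ib = idx_of[ta], idx_of[tb]
        if ia.size == 0 or ib.size == 0:
            continue
        ca, cb = N_CATEGORIES[ta], N_CATEGORIES[tb]
        ind_a = [((gm.calls[ia] == a) & valid[ia]).astype(np.float64)
                 for a in range(ca)]
        ind_b = [((gm.calls[ib] == b) & valid[ib]).astype(np.float64)
                 for b in range(cb)]
        counts = np.empty((ia.size, ib.size, ca * cb))
        for a in range(ca):
            for b in range(cb):
                counts[:, :, a * cb + b] = ind_a[a] @ ind_b[b].T
        flat = counts.reshape(-1, ca * cb)
        block_rf, block_lod = _rf_em_pairs(flat, ta, tb)
        block_rf = block_rf.reshape(ia.size, ib.size)
        block_lod = block_lod.reshape(ia.size, ib.size)
        block_n = (valid[ia].astype(np.float64) @ valid[ib].astype(np.float64).T)
        no_data = block_n == 0
        block_rf[no_data] = np.nan
        block_lod[no_data] = 0.0
        rf[np.ix_(ia, ib)] = block_rf
        lod[np.ix_(ia, ib)] = block_lod
        n_inf[np.ix_(ia, ib)] = block_n.astype(np.int64)
        if ta != tb:
            rf[np.ix_(ib, ia)] = block_rf.T
            lod[np.ix_(ib, ia)] = block_lod.T
            n_inf[np.ix_(ib, ia)] = block_n.T.astype(np.int64)

    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(n_inf, valid.sum(axis=1))
    return RecombinationMatrix([mk.marker_id for mk in gm.markers], rf, lod, n_inf)


# ---------------------------------------------------------------------------
# Grouping and consistency
# ---------------------------------------------------------------------------


@dataclass
class LinkageGroupAssignment:
    """Partition of markers into linkage groups (singletons allowed).

    Groups are labeled 1..k by decreasing size (ties broken by the smallest
    member marker id), so labels are invariant to marker input order.
    """

    groups: dict[str, int]
    sizes: dict[int, int]

    def members(self, min_size: int = 1) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for mid, g in self.groups.items():
            if self.sizes[g] >= min_size:
                out.setdefault(g, []).append(mid)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(mid, g, self.sizes[g]) for mid, g in self.groups.items()],
            columns=["marker_id", "group", "group_size"],
        )


def assign_linkage_groups(
    rm: RecombinationMatrix, rf_max: float = 0.35, lod_min: float = 5.0
) -> LinkageGroupAssignment:
    """Single-linkage transitive closure of the rf/LOD threshold graph."""
    adj = rm.usable() & (rm.rf <= rf_max) & (rm.lod >= lod_min)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, connection="weak"
    )
    comp_members: dict[int, list[str]] = {}
    for mid, lab in zip(rm.marker_ids, labels):
        comp_members.setdefault(int(lab), []).append(mid)
    ranked = sorted(
        comp_members.items(), key=lambda kv: (-len(kv[1]), min(kv[1]))
    )
    groups: dict[str, int] = {}
    sizes: dict[int, int] = {}
    for gid, (_, members) in enumerate(ranked, start=1):
        sizes[gid] = len(members)
        for mid in members:
            groups[mid] = gid
    return LinkageGroupAssignment(groups, sizes)


@dataclass(frozen=True)
class ScaffoldConflict:
    scaffold_id: str
    groups: tuple[tuple[int, int], ...]  # (group, marker count) pairs


def check_scaffold_consistency(
    lga: LinkageGroupAssignment,
    marker_to_scaffold: Mapping[str, str],
    min_group_size: int = 2,
) -> list[ScaffoldConflict]:
    """Scaffolds whose grouped markers span two or more linkage groups.

    Only markers in groups of at least ``min_group_size`` count — a singleton
    "group" is an ungrouped marker, not evidence of a chimeric scaffold.  An
    empty list is the expected outcome on a correctly scaffolded assembly.
    """
    per_scaffold: dict[str, dict[int, int]] = {}
    for mid, g in lga.groups.items():
        if lga.sizes[g] < min_group_size or mid not in marker_to_scaffold:
            continue
        sid = marker_to_scaffold[mid]
        per_scaffold.setdefault(sid, {})
        per_scaffold[sid][g] = per_scaffold[sid].get(g, 0) + 1
    conflicts = []
    for sid in sorted(per_scaffold):
        counts = per_scaffold[sid]
        if len(counts) >= 2:
            conflicts.append(
                ScaffoldConflict(sid, tuple(sorted(counts.items())))
            )
    return conflicts
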