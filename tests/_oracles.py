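"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: per-position stabbing
counts instead of difference arrays, regex scans instead of str.find loops,
python loops instead of vectorized filters, exhaustive layout enumeration
instead of agglomerative ordering.
"""

import itertools
import re

import numpy as np
from scipy.stats import chi2 as chi2_dist

from chromoforge.anchoring import junction_cost
from chromoforge.qc import MISSING, SEG_RATIOS


def brute_spanning(pairs, length):
    """O(pairs * length) per-position spanning count."""
    profile = np.zeros(length, dtype=int)
    for pair in pairs:
        if not pair.proper:
            continue
        if pair.start1 <= pair.start2:
            left_end, right_start = pair.end1, pair.start2
        else:
            left_end, right_start = pair.end2, pair.start1
        for p in range(length):
            if left_end <= p < right_start:
                profile[p] += 1
    return profile


def regex_find_all(probe, target):
    """All exact occurrences on both strands via regex lookahead."""
    from chromoforge.pseudomolecule import reverse_complement

    hits = []
    rc = reverse_complement(probe)
    for sid, seq in target.items():
        for query, strand in ((probe, "+"), (rc, "-")):
            if strand == "-" and rc == probe:
                continue
            for m in re.finditer(f"(?={re.escape(query)})", seq):
                hits.append((sid, m.start(), strand))
    return sorted(hits)


def n50_loop(lengths):
    arr = sorted(lengths, reverse=True)
    total = sum(arr)
    if total == 0:
        return 0
    acc = 0
    for x in arr:
        acc += x
        if acc * 2 >= total:
            return x
    return 0


def exhaustive_best_layout(scaffold_ids, rm, marker_map, k_terminal=3):
    """Minimum junction cost over every signed order (n! * 2^n layouts)."""
    best = None
    for perm in itertools.permutations(scaffold_ids):
        for signs in itertools.product("+-", repeat=len(perm)):
            order = list(zip(perm, signs))
            cost = junction_cost(order, rm, marker_map, k_terminal)
            if best is None or cost < best[0]:
                best = (cost, order)
    return best


# -- genotype-QC filters, re-done with explicit loops ------------------------


def qc_biallelic_rows(gm):
    return [i for i, m in enumerate(gm.markers)
            if m.is_snp and m.n_alleles == 2]


def qc_depth_masked_calls(gm, min_depth):
    out = gm.calls.copy()
    for i in range(gm.n_markers):
        for j in range(gm.n_samples):
            if gm.depths[i, j] < min_depth:
                out[i, j] = MISSING
    return out


def qc_missing_rows(calls, max_missing):
    keep = []
    for i in range(calls.shape[0]):
        n_missing = sum(1 for c in calls[i] if c == MISSING)
        if n_missing / calls.shape[1] <= max_missing:
            keep.append(i)
    return keep


def qc_maf(calls_row, seg_type):
    obs = [c for c in calls_row if c != MISSING]
    if not obs:
        return None
    if seg_type == "hkxhk":
        minor = sum(2 for c in obs if c == 2) + sum(1 for c in obs if c == 1)
    else:
        minor = sum(1 for c in obs if c == 1)
    f = minor / (2 * len(obs))
    return min(f, 1 - f)


def qc_seg_p(calls_row, seg_type):
    obs = [c for c in calls_row if c != MISSING]
    if not obs:
        return None
    ratios = SEG_RATIOS[seg_type]
    stat = 0.0
    for c, frac in enumerate(ratios):
        o = sum(1 for x in obs if x == c)
        e = frac * len(obs)
        stat += (o - e) ** 2 / e
    return float(chi2_dist.sf(stat, len(ratios) - 1))


def qc_cascade_rows(gm, params):
    """Surviving original-row indices of the full cascade, done by loops."""
    rows = qc_biallelic_rows(gm)
    calls = qc_depth_masked_calls(gm, params.min_depth)
    rows = [i for i in rows
            if i in set(qc_missing_rows(calls, params.max_missing))]
    out = []
    for i in rows:
        seg = gm.markers[i].segregation_type
        maf = qc_maf(calls[i], seg)
        if maf is None or maf <= params.min_maf:
            continue
        p = qc_seg_p(calls[i], seg)
        if p is None or p <= params.seg_p:
            continue
        out.append(i)
    return out


def rf_count_testcross(calls_i, calls_j):
    """Exhaustive recombinant tally under both phases for a testcross pair."""
    n = mis = 0
    for a, b in zip(calls_i, calls_j):
        if a == MISSING or b == MISSING:
            continue
        n += 1
        if a != b:
            mis += 1
    if n == 0:
        return None, 0
    return min(mis, n - mis) / n, n
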