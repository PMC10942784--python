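"""Independent, deliberately naive oracles used by the test suite.

These are straight-from-definition loop implementations kept free of any
code path from the package under test.
"""
from __future__ import annotations

import itertools
import math


# ---------------------------------------------------------------------------
# TMM, written as a literal transcription of the definition
# ---------------------------------------------------------------------------

def _percentile_linear(sorted_values, q):
    n = len(sorted_values)
    if n == 1:
        return sorted_values[0]
    h = (n - 1) * q
    lo = int(math.floor(h))
    frac = h - lo
    if lo + 1 >= n:
        return sorted_values[-1]
    return sorted_values[lo] + frac * (sorted_values[lo + 1] - sorted_values[lo])


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_oracle(counts, trim_m=0.30, trim_a=0.05):
    """TMM scaling factors computed row by row from the definition."""
    rows = [[float(c) for c in row] for row in counts]
    n_samples = len(rows[0])
    lib = [sum(row[k] for row in rows) for k in range(n_samples)]

    f75 = []
    for k in range(n_samples):
        nonzero = sorted(row[k] / lib[k] * 1e6 for row in rows if row[k] > 0)
        f75.append(_percentile_linear(nonzero, 0.75))
    mean_f75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda k: (abs(f75[k] - mean_f75), k))

    factors = [1.0] * n_samples
    for k in range(n_samples):
        if k == ref:
            continue
        m_vals, a_vals, w_vals = [], [], []
        for row in rows:
            yk, yr = row[k], row[ref]
            if yk > 0 and yr > 0:
                pk, pr = yk / lib[k], yr / lib[ref]
                m_vals.append(math.log2(pk / pr))
                a_vals.append(0.5 * math.log2(pk * pr))
                w_vals.append(
                    1.0
                    / ((lib[k] - yk) / (lib[k] * yk) + (lib[ref] - yr) / (lib[ref] * yr))
                )
        if not m_vals:
            continue
        n = len(m_vals)
        rm = _average_ranks(m_vals)
        ra = _average_ranks(a_vals)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        keep = [
            i
            for i in range(n)
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a
        ]
        if len(keep) < 10:
            keep = list(range(n))
        num = sum(w_vals[i] * m_vals[i] for i in keep)
        den = sum(w_vals[i] for i in keep)
        factors[k] = 2.0 ** (num / den)

    log_gm = sum(math.log(f) for f in factors) / n_samples
    return [f / math.exp(log_gm) for f in factors]


# ---------------------------------------------------------------------------
# Exhaustive splice-event enumeration over junction pairs/triples
# ---------------------------------------------------------------------------

def enumerate_events_oracle(junctions, model):
    """All SE/A5SS/A3SS/MXE events by exhaustive enumeration.

    Returns a set of (event_type, inclusion tuple, exclusion tuple)."""
    js = sorted(set(junctions))
    exons = set()
    for ex in model.transcripts.values():
        exons.update(ex)
    tx_sets = [set(ex) for ex in model.transcripts.values()]

    events = set()

    # inclusion paths j1 -> annotated exon -> j2
    paths = []
    for j1 in js:
        for j2 in js:
            if j2.start > j1.end + 1 and (j1.end + 1, j2.start - 1) in exons:
                paths.append((j1, j2, (j1.end + 1, j2.start - 1)))

    # SE: path plus a skipping junction spanning the same outer coordinates
    for j1, j2, _exon in paths:
        for j3 in js:
            if j3.start == j1.start and j3.end == j2.end:
                events.add(("SE", (j1, j2), (j3,)))

    # A5SS / A3SS: pairs sharing one end
    for ja, jb in itertools.combinations(js, 2):
        if ja.end == jb.end and ja.start != jb.start:
            incl, excl = (ja, jb) if ja.intron_length < jb.intron_length else (jb, ja)
            events.add(("A5SS", (incl,), (excl,)))
        if ja.start == jb.start and ja.end != jb.end:
            incl, excl = (ja, jb) if ja.intron_length < jb.intron_length else (jb, ja)
            events.add(("A3SS", (incl,), (excl,)))

    # MXE: two paths with same outer coordinates through exclusive exons
    for pa, pb in itertools.combinations(paths, 2):
        if (
            pa[0].start == pb[0].start
            and pa[1].end == pb[1].end
            and pa[2] != pb[2]
            and not any(pa[2] in t and pb[2] in t for t in tx_sets)
        ):
            first, second = (pa, pb) if pa[2] <= pb[2] else (pb, pa)
            events.add(("MXE", (first[0], first[1]), (second[0], second[1])))

    return events
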