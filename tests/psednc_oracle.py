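"""Brute-force reference encoder, kept deliberately independent of the
production code: plain Python loops and ``math`` only, its own
standardization, its own dinucleotide bookkeeping. Used to cross-check the
vectorized encoder component by component."""

import math

BASES = "ACGU"
DINUCS = [a + b for a in BASES for b in BASES]


def standardize_columns(raw_rows):
    """Z-score each column of a 16-row table with population SD."""
    ncols = len(raw_rows[0])
    out = [[0.0] * ncols for _ in range(16)]
    for c in range(ncols):
        col = [raw_rows[r][c] for r in range(16)]
        mean = sum(col) / 16.0
        var = sum((x - mean) ** 2 for x in col) / 16.0
        sd = math.sqrt(var)
        for r in range(16):
            out[r][c] = (raw_rows[r][c] - mean) / sd
    return out


def oracle_encode(seq, w, lam, raw_rows, mode="overlapping"):
    """Direct nested-loop PseDNC: frequencies, tier correlations, then the
    normalized 16 + lam vector."""
    z = standardize_columns(raw_rows)
    nprops = len(raw_rows[0])
    L = len(seq)

    def prop(dinuc, u):
        return z[DINUCS.index(dinuc)][u]

    def theta_fn(d1, d2):
        total = 0.0
        for u in range(nprops):
            total += (prop(d1, u) - prop(d2, u)) ** 2
        return total / nprops

    freqs = [0.0] * 16
    if mode == "overlapping":
        positions = range(L - 1)
        step = 1
    else:
        positions = range(0, L - 1, 2)
        step = 2
    count = 0
    for i in positions:
        freqs[DINUCS.index(seq[i : i + 2])] += 1
        count += 1
    freqs = [f / count for f in freqs]

    thetas = []
    for j in range(1, lam + 1):
        total = 0.0
        npairs = 0
        for i in range(L - 1 - j):
            total += theta_fn(seq[i : i + 2], seq[i + j : i + j + 2])
            npairs += 1
        thetas.append(total / npairs)

    denom = sum(freqs) + w * sum(thetas)
    vec = [f / denom for f in freqs]
    vec.extend(w * t / denom for t in thetas)
    return vec
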