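"""Independent brute-force transcriptions of every encoder formula.

Deliberately written with plain Python loops and dictionaries, no shared
code with the package's vectorized implementations, so that agreement is
evidence of correctness rather than of shared bugs.
"""

import statistics
from itertools import product

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def standardize(raw: dict) -> dict:
    vals = [raw[a] for a in ALPHABET]
    mu = statistics.fmean(vals)
    sd = statistics.pstdev(vals)
    return {a: (raw[a] - mu) / sd for a in ALPHABET}


# --- composition ---------------------------------------------------------

def naive_kmer(seq: str, k: int, normalize: bool) -> list:
    words = ["".join(w) for w in product(ALPHABET, repeat=k)]
    counts = {w: 0 for w in words}
    for i in range(len(seq) - k + 1):
        counts[seq[i:i + k]] += 1
    out = [counts[w] for w in words]
    if normalize:
        total = len(seq) - k + 1
        out = [c / total for c in out]
    return out


def naive_dr(seq: str, dmax: int, normalize: bool, mapping=None, m=20) -> list:
    if mapping is None:
        mapping = {a: i for i, a in enumerate(ALPHABET)}
    codes = [mapping[a] for a in seq]
    blocks = []
    mono = [0] * m
    for c in codes:
        mono[c] += 1
    blocks.append(mono)
    for d in range(1, dmax + 1):
        block = [0] * (m * m)
        for i in range(len(codes) - d):
            block[codes[i] * m + codes[i + d]] += 1
        blocks.append(block)
    out = []
    for block in blocks:
        total = sum(block)
        if normalize and total > 0:
            out.extend(v / total for v in block)
        else:
            out.extend(float(v) for v in block)
    return out


# --- autocorrelation ------------------------------------------------------

def naive_ac(seq: str, index_values: dict, dmax: int) -> list:
    L = len(seq)
    vals = [index_values[a] for a in seq]
    mean = sum(vals) / L
    out = []
    for d in range(1, dmax + 1):
        s = 0.0
        for i in range(L - d):
            s += (vals[i] - mean) * (vals[i + d] - mean)
        out.append(s / (L - d))
    return out


def naive_cc(seq: str, index_u: dict, index_v: dict, dmax: int) -> list:
    L = len(seq)
    u = [index_u[a] for a in seq]
    v = [index_v[a] for a in seq]
    mu, mv = sum(u) / L, sum(v) / L
    out = []
    for d in range(1, dmax + 1):
        s = 0.0
        for i in range(L - d):
            s += (u[i] - mu) * (v[i + d] - mv)
        out.append(s / (L - d))
    return out


def naive_pdt(seq: str, index_values: dict, dmax: int) -> list:
    L = len(seq)
    vals = [index_values[a] for a in seq]
    out = []
    for d in range(1, dmax + 1):
        s = 0.0
        for i in range(L - d):
            s += (vals[i] - vals[i + d]) ** 2
        out.append(s / (L - d))
    return out


# --- pseudo amino acid composition ---------------------------------------

def naive_parallel_theta(seq: str, prop_tables: list, lam: int) -> list:
    L = len(seq)
    theta = []
    for j in range(1, lam + 1):
        s = 0.0
        for i in range(L - j):
            corr = 0.0
            for table in prop_tables:
                corr += (table[seq[i]] - table[seq[i + j]]) ** 2
            s += corr / len(prop_tables)
        theta.append(s / (L - j))
    return theta


def naive_series_theta(seq: str, prop_tables: list, lam: int) -> list:
    L = len(seq)
    theta = []
    for j in range(1, lam + 1):
        for table in prop_tables:
            s = 0.0
            for i in range(L - j):
                s += table[seq[i]] * table[seq[i + j]]
            theta.append(s / (L - j))
    return theta


def naive_pseaac(seq: str, theta: list, w: float) -> list:
    freqs = [seq.count(a) / len(seq) for a in ALPHABET]
    denom = sum(freqs) + w * sum(theta)
    return [f / denom for f in freqs] + [w * t / denom for t in theta]


# --- profile encoders -----------------------------------------------------

def naive_top_n_grams(freq_rows, n: int) -> list:
    grams = []
    for row in freq_rows:
        ranked = sorted(zip(row, ALPHABET), key=lambda t: (-t[0], t[1]))
        grams.append(tuple(a for _, a in ranked[:n]))
    return grams


def naive_top_n_gram_counts(freq_rows, n: int, normalize: bool) -> list:
    words = list(product(ALPHABET, repeat=n))
    counts = {w: 0 for w in words}
    for g in naive_top_n_grams(freq_rows, n):
        counts[g] += 1
    out = [float(counts[w]) for w in words]
    if normalize:
        out = [c / len(freq_rows) for c in out]
    return out


def naive_dt(freq_rows, n: int, dmax: int, normalize: bool) -> list:
    grams = naive_top_n_grams(freq_rows, n)
    words = list(product(ALPHABET, repeat=n))
    idx = {w: i for i, w in enumerate(words)}
    m = len(words)
    out = []
    for d in range(1, dmax + 1):
        block = [0.0] * (m * m)
        for i in range(len(grams) - d):
            block[idx[grams[i]] * m + idx[grams[i + d]]] += 1
        total = sum(block)
        if normalize and total > 0:
            block = [v / total for v in block]
        out.extend(block)
    return out


def naive_pdt_profile(freq_rows, dmax: int) -> list:
    L = len(freq_rows)
    out = []
    for d in range(1, dmax + 1):
        s = 0.0
        for i in range(L - d):
            for j in range(20):
                s += (freq_rows[i][j] - freq_rows[i + d][j]) ** 2
        out.append(s / (20 * (L - d)))
    return out


def naive_pssm_ac(freq_rows, dmax: int) -> list:
    L = len(freq_rows)
    out = []
    for j in range(20):
        col = [row[j] for row in freq_rows]
        mean = sum(col) / L
        for d in range(1, dmax + 1):
            s = 0.0
            for i in range(L - d):
                s += (col[i] - mean) * (col[i + d] - mean)
            out.append(s / (L - d))
    return out


def naive_pssm_cc(freq_rows, dmax: int) -> list:
    L = len(freq_rows)
    cols = [[row[j] for row in freq_rows] for j in range(20)]
    means = [sum(c) / L for c in cols]
    out = []
    for j in range(20):
        for jp in range(20):
            if j == jp:
                continue
            for d in range(1, dmax + 1):
                s = 0.0
                for i in range(L - d):
                    s += (cols[j][i] - means[j]) * (cols[jp][i + d] - means[jp])
                out.append(s / (L - d))
    return out


def naive_pssm_dt(freq_rows, dmax: int) -> list:
    L = len(freq_rows)
    out = []
    for d in range(1, dmax + 1):
        for a in range(20):
            for b in range(20):
                s = 0.0
                for i in range(L - d):
                    s += freq_rows[i][a] * freq_rows[i + d][b]
                out.append(s / (L - d))
    return out


def naive_pssm_rt(score_rows, dmax: int, threshold: float) -> list:
    L = len(score_rows)
    binary = [[1.0 if v > threshold else 0.0 for v in row] for row in score_rows]
    out = []
    for d in range(1, dmax + 1):
        for a in range(20):
            for b in range(20):
                s = 0.0
                for i in range(L - d):
                    s += binary[i][a] * binary[i + d][b]
                out.append(s / (L - d))
    return out


# --- metrics --------------------------------------------------------------

def naive_auc_paircount(scores, labels) -> float:
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
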