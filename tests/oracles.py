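"""Naive, dictionary-based reference implementations used as test oracles.

Everything here is written with plain Python loops and string k-mers,
independently of the package's vectorized code paths, so the two can be
compared on random instances.
"""

from __future__ import annotations

import itertools
import math

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def all_kmers(k: int):
    for tup in itertools.product("ACGT", repeat=k):
        yield "".join(tup)


def naive_counts(seq: str, k: int, double_strand: bool = True):
    """Sliding-window dict counts; windows containing N are skipped.

    Returns (dict kmer -> count, number of windows counted).
    """
    counts: dict[str, int] = {}
    total = 0
    strands = [seq, revcomp(seq)] if double_strand else [seq]
    for s in strands:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" in w:
                continue
            counts[w] = counts.get(w, 0) + 1
            total += 1
    return counts, total


def naive_pooled_counts(seqs, k: int, double_strand: bool = True):
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        c, t = naive_counts(seq, k, double_strand)
        for w, n in c.items():
            counts[w] = counts.get(w, 0) + n
        total += t
    return counts, total


def naive_expected_markov(seqs, k: int, order: int, double_strand: bool = True):
    """Order-r product-form expectations E(X_w) for every k-mer.

    Transitions are (r+1)-mer counts normalized by their context row sum,
    with a +1/+4 pseudocount row when the context was never observed (or its
    row sum is zero); the leading factor is the r-mer relative frequency
    (1 for order 0). Scaled by the number of k-mer windows counted.
    """
    counts_k, n_windows = naive_pooled_counts(seqs, k, double_strand)
    counts_rp1, _ = naive_pooled_counts(seqs, order + 1, double_strand)
    counts_r, total_r = (
        naive_pooled_counts(seqs, order, double_strand) if order >= 1 else ({}, 0)
    )

    def trans(ctx: str, base: str) -> float:
        row = [counts_rp1.get(ctx + b, 0) for b in "ACGT"]
        row_sum = sum(row)
        ctx_count = counts_r.get(ctx, 0) if order >= 1 else row_sum
        if ctx_count > 0 and row_sum > 0:
            return counts_rp1.get(ctx + base, 0) / row_sum
        return (counts_rp1.get(ctx + base, 0) + 1.0) / (row_sum + 4.0)

    expected = {}
    for w in all_kmers(k):
        if order == 0:
            lead = 1.0
        else:
            lead = counts_r.get(w[:order], 0) / total_r if total_r else 0.0
        prod = 1.0
        for n in range(k - order):
            prod *= trans(w[n : n + order], w[n + order])
        expected[w] = n_windows * lead * prod
    observed = {w: counts_k.get(w, 0) for w in all_kmers(k)}
    return observed, expected, n_windows


def naive_expected_k2(seqs, k: int, double_strand: bool = True):
    """(k-2)-order count-ratio expectations and Teeling variances."""
    counts_k, _ = naive_pooled_counts(seqs, k, double_strand)
    counts_km1, _ = naive_pooled_counts(seqs, k - 1, double_strand)
    counts_km2, _ = naive_pooled_counts(seqs, k - 2, double_strand)
    observed, expected, variance, ratio = {}, {}, {}, {}
    for w in all_kmers(k):
        x = counts_k.get(w, 0)
        pre = counts_km1.get(w[:-1], 0)
        suf = counts_km1.get(w[1:], 0)
        inner = counts_km2.get(w[1:-1], 0)
        observed[w] = x
        if inner > 0:
            e = pre * suf / inner
            expected[w] = e
            variance[w] = e * (inner - pre) * (inner - suf) / inner**2
            ratio[w] = x / e if e > 0 else 0.0
        else:
            expected[w] = 0.0
            variance[w] = 0.0
            ratio[w] = 0.0
    return observed, expected, variance, ratio


# ---------------------------------------------------------------------------
# naive measures (dict/loop arithmetic straight from the definitions)
# ---------------------------------------------------------------------------

def naive_frequency_distance(name, fx: dict, fy: dict, k: int):
    diffs = [fx.get(w, 0.0) - fy.get(w, 0.0) for w in all_kmers(k)]
    if name == "euclidean":
        return sum(d * d for d in diffs)
    if name == "manhattan":
        return sum(abs(d) for d in diffs)
    if name == "chebyshev":
        return max(abs(d) for d in diffs)
    raise ValueError(name)


def naive_d2(cx: dict, cy: dict, k: int):
    num = sum(cx.get(w, 0) * cy.get(w, 0) for w in all_kmers(k))
    nx = math.sqrt(sum(c * c for c in cx.values()))
    ny = math.sqrt(sum(c * c for c in cy.values()))
    return 0.5 * (1.0 - num / (nx * ny))


def naive_d2star(obs_x, exp_x, obs_y, exp_y, k: int):
    num = dxx = dyy = 0.0
    for w in all_kmers(k):
        ex, ey = exp_x[w], exp_y[w]
        cx = obs_x[w] - ex
        cy = obs_y[w] - ey
        if ex > 0 and ey > 0:
            num += cx * cy / math.sqrt(ex * ey)
        if ex > 0:
            dxx += cx * cx / ex
        if ey > 0:
            dyy += cy * cy / ey
    return 0.5 * (1.0 - num / (math.sqrt(dxx) * math.sqrt(dyy)))


def naive_d2s(obs_x, exp_x, obs_y, exp_y, k: int):
    num = dxx = dyy = 0.0
    for w in all_kmers(k):
        cx = obs_x[w] - exp_x[w]
        cy = obs_y[w] - exp_y[w]
        denom = math.sqrt(cx * cx + cy * cy)
        if denom > 0:
            num += cx * cy / denom
            dxx += cx * cx / denom
            dyy += cy * cy / denom
    return 0.5 * (1.0 - num / (math.sqrt(dxx) * math.sqrt(dyy)))


def naive_cvtree(ratio_x: dict, ratio_y: dict, k: int):
    num = sum(ratio_x[w] * ratio_y[w] for w in all_kmers(k))
    nx = math.sqrt(sum(v * v for v in ratio_x.values()))
    ny = math.sqrt(sum(v * v for v in ratio_y.values()))
    return 0.5 * (1.0 - num / (nx * ny))


def naive_teeling(obs_x, exp_x, var_x, obs_y, exp_y, var_y, k: int):
    total = 0.0
    for w in all_kmers(k):
        if var_x[w] > 0 and var_y[w] > 0:
            zx = (obs_x[w] - exp_x[w]) / math.sqrt(var_x[w])
            zy = (obs_y[w] - exp_y[w]) / math.sqrt(var_y[w])
            total += zx * zy
    return total


def naive_euf(ratio_x: dict, ratio_y: dict, k: int):
    return sum(abs(ratio_x[w] - ratio_y[w]) for w in all_kmers(k)) / 4**k


def naive_auroc(scores, labels, positive_is_low=True, positive_label="temperate"):
    """Brute-force pairwise win fraction (0.5 credit for ties)."""
    pos = [s for s, l in zip(scores, labels) if l == positive_label]
    neg = [s for s, l in zip(scores, labels) if l != positive_label]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p == n:
                wins += 0.5
            elif (p < n) == positive_is_low:
                wins += 1.0
    return wins / (len(pos) * len(neg))


def random_dna(rng, length: int, n_rate: float = 0.0) -> str:
    bases = "ACGT"
    out = []
    for _ in range(length):
        if n_rate and rng.random() < n_rate:
            out.append("N")
        else:
            out.append(bases[rng.randrange(4)])
    return "".join(out)
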