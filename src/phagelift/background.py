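"""Markov null models for oligonucleotide frequencies.

Two flavours of expected k-mer count are used by the dissimilarity measures:

* the order-r product form
  ``E(X_w) = N * f(w_1..w_r) * prod_n P(w_{n+r} | w_n..w_{n+r-1})``,
  where N is the effective number of k-mer windows (the multi-sequence,
  two-strand generalization of L - k + 1), the transition probabilities are
  count ratios ``P(b | c) = X(cb) / X(c)``, and for order 0 the leading
  context factor is 1;
* the (k-2)-order count-ratio form
  ``E(X_w) = X(w_1..w_{k-1}) * X(w_2..w_k) / X(w_2..w_{k-1})``
  with its companion variance, used by CVTree, Teeling and EuF.

Zero-count contexts in the product form fall back to an additive
pseudocount (1 on the extended word, 4 on the context, i.e. a uniform row);
contexts with observed counts use raw ratios so the printed formulas are
preserved exactly. In the count-ratio form a zero inner count simply zeroes
the word's expectation, variance and ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmer import KmerCountVector, count_kmers_pooled


@dataclass(frozen=True)
class MarkovBackground:
    """An order-r Markov model estimated from k-mer counts.

    ``transition`` has shape (4**order, 4) and rows summing to 1;
    ``context_freqs`` is the relative frequency of each length-r context
    (for order 0 it is the scalar array [1.0], the empty context).
    """

    order: int
    transition: np.ndarray
    context_freqs: np.ndarray

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("Markov order must be >= 0")


@dataclass(frozen=True)
class NormalizedCounts:
    """Observed, expected and centered counts of all 4^k k-mers.

    ``centered`` is X~_w = X_w - E(X_w); ``ratio`` is X_w / E(X_w) (zero
    where E is zero), exposed for the ratio-normalized measures;
    ``length_basis`` is the (L - k + 1)-analogue used for scaling.
    """

    k: int
    observed: np.ndarray
    expected: np.ndarray
    centered: np.ndarray
    ratio: np.ndarray
    length_basis: int


def fit_markov(
    counts_rp1: KmerCountVector, counts_r: KmerCountVector | None, order: int
) -> MarkovBackground:
    """Estimate an order-r model from (r+1)-mer and r-mer counts.

    For order 0, ``counts_rp1`` holds mononucleotide counts and ``counts_r``
    is ignored (may be None). Transition rows for contexts never observed
    fall back to the pseudocounted uniform row.
    """
    if order < 0:
        raise ValueError("Markov order must be >= 0")
    if counts_rp1.k != order + 1:
        raise ValueError(
            f"counts_rp1 must be at word length {order + 1}, got {counts_rp1.k}"
        )
    ext = counts_rp1.counts.astype(float).reshape(4**order, 4)
    if order == 0:
        total = ext.sum()
        if total == 0:
            row = np.full((1, 4), 0.25)
        else:
            row = ext / total
        return MarkovBackground(order=0, transition=row, context_freqs=np.array([1.0]))
    if counts_r is None or counts_r.k != order:
        raise ValueError(f"counts_r must be at word length {order}")
    ctx = counts_r.counts.astype(float)
    trans = np.empty_like(ext)
    observed = ctx > 0
    # raw count ratios where the context was observed
    # note: rows are normalized by the extended-word row sum, not the raw
    # context count, so rows sum to 1 exactly even at sequence edges where
    # X(c) exceeds sum_b X(cb)
    row_sums = ext.sum(axis=1)
    ok = observed & (row_sums > 0)
    trans[ok] = ext[ok] / row_sums[ok, None]
    trans[~ok] = (ext[~ok] + 1.0) / (row_sums[~ok, None] + 4.0)
    total_ctx = ctx.sum()
    freqs = ctx / total_ctx if total_ctx > 0 else np.full(ctx.size, 1.0 / ctx.size)
    return MarkovBackground(order=order, transition=trans, context_freqs=freqs)


def fit_markov_from_records(records, order: int, double_strand: bool = True) -> MarkovBackground:
    """Convenience: count (r+1)-mers and r-mers from records, then fit."""
    rp1 = count_kmers_pooled(records, order + 1, double_strand)
    r = count_kmers_pooled(records, order, double_strand) if order >= 1 else None
    return fit_markov(rp1, r, order)


def _expected_product_form(k: int, bg: MarkovBackground, length_basis: float) -> np.ndarray:
    """E(X_w) for all 4^k words under the order-r product formula."""
    r = bg.order
    if r > k - 1:
        raise ValueError(f"Markov order {r} must be <= k - 1 = {k - 1}")
    # grow the product word by word: appending base b to prefix-index i gives
    # index 4*i + b, and the transition context is the last r characters,
    # i.e. i mod 4**r
    if r == 0:
        vals = np.array([1.0])
        for _ in range(k):
            vals = (vals[:, None] * bg.transition[0][None, :]).ravel()
    else:
        vals = bg.context_freqs.copy()
        mask = 4**r
        for m in range(r, k):
            ctx = np.arange(4**m, dtype=np.int64) % mask
            vals = (vals[:, None] * bg.transition[ctx]).ravel()
    return length_basis * vals


def expected_counts(obs: KmerCountVector, bg: MarkovBackground) -> NormalizedCounts:
    """Expected/centered counts under an order-r product-form model.

    ``length_basis`` is ``obs.effective_positions``, the number of k-mer
    windows actually counted across both strands and all sequences.
    """
    expected = _expected_product_form(obs.k, bg, float(obs.effective_positions))
    observed = obs.counts.astype(float)
    ratio = np.where(expected > 0, observed / np.where(expected > 0, expected, 1.0), 0.0)
    return NormalizedCounts(
        k=obs.k,
        observed=observed,
        expected=expected,
        centered=observed - expected,
        ratio=ratio,
        length_basis=obs.effective_positions,
    )


def _flank_indices(k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prefix (w_1..w_{k-1}), suffix (w_2..w_k), inner (w_2..w_{k-1}) indices."""
    idx = np.arange(4**k, dtype=np.int64)
    prefix = idx // 4
    suffix = idx % 4 ** (k - 1)
    inner = suffix // 4
    return prefix, suffix, inner


def expected_counts_k2(
    obs: KmerCountVector, obs_km1: KmerCountVector, obs_km2: KmerCountVector
) -> NormalizedCounts:
    """(k-2)-order expectation by the count-ratio formula.

    ``E(X_w) = X(w_1..w_{k-1}) X(w_2..w_k) / X(w_2..w_{k-1})``; words whose
    inner (k-2)-mer was never observed get expectation 0 and ratio 0.
    """
    k = obs.k
    if k < 3:
        raise ValueError(f"count-ratio expectation requires k >= 3, got {k}")
    if obs_km1.k != k - 1 or obs_km2.k != k - 2:
        raise ValueError("companion vectors must be at word lengths k-1 and k-2")
    prefix, suffix, inner = _flank_indices(k)
    km1 = obs_km1.counts.astype(float)
    km2 = obs_km2.counts.astype(float)
    inner_counts = km2[inner]
    safe = np.where(inner_counts > 0, inner_counts, 1.0)
    expected = np.where(inner_counts > 0, km1[prefix] * km1[suffix] / safe, 0.0)
    observed = obs.counts.astype(float)
    ratio = np.where(expected > 0, observed / np.where(expected > 0, expected, 1.0), 0.0)
    return NormalizedCounts(
        k=k,
        observed=observed,
        expected=expected,
        centered=observed - expected,
        ratio=ratio,
        length_basis=obs.effective_positions,
    )


def variance_teeling(
    obs: KmerCountVector, obs_km1: KmerCountVector, obs_km2: KmerCountVector
) -> np.ndarray:
    """Per-word variance under the (k-2)-order model.

    ``var(X_w) = E(X_w) (X(inner) - X(prefix)) (X(inner) - X(suffix)) / X(inner)^2``
    with prefix/suffix/inner as in :func:`expected_counts_k2`; zero wherever
    the inner count (hence E) is zero.
    """
    k = obs.k
    norm = expected_counts_k2(obs, obs_km1, obs_km2)
    prefix, suffix, inner = _flank_indices(k)
    km1 = obs_km1.counts.astype(float)
    km2 = obs_km2.counts.astype(float)
    inner_counts = km2[inner]
    safe = np.where(inner_counts > 0, inner_counts, 1.0)
    var = norm.expected * (inner_counts - km1[prefix]) * (inner_counts - km1[suffix]) / safe**2
    return np.where(inner_counts > 0, var, 0.0)
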