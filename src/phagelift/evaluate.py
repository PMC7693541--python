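"""Evaluation protocol: ROC/AUROC grids, TPR tables, mutation sensitivity.

The protocol mirrors a benchmark of contig lifestyle classifiers: test
genomes are split into non-overlapping fragments of fixed length, classes
are balanced by random subsampling, every fragment is scored by the
temperate/lytic distance ratio, and the ranking quality is summarized by
the AUROC (Mann-Whitney rank statistic, mid-ranks for ties). Hard calls at
the ratio-1 threshold give per-class true positive rates (TPR1 temperate,
TPR2 lytic) and overall accuracy. The mutation experiment re-scores
subsampled fragments after injecting random substitutions and compares the
per-rate AUROC samples with the no-mutation baseline by Welch's t-test.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .classify import ClassificationResult, MeasureSpec, TrainedModel, predict_batch, train
from .measures import MARKOV_MEASURES, canonical_name
from .sequence_io import SequenceRecord, balanced_subsample, fragment_genomes, inject_mutations

DEFAULT_FRAGMENT_LENGTHS = (500, 1000, 3000, 5000, 10_000)
DEFAULT_MUTATION_RATES = (0.001, 0.005, 0.01)


def derive_seed(*parts) -> int:
    """Stable 31-bit seed derived from arbitrary cell coordinates."""
    return zlib.crc32("|".join(map(str, parts)).encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class EvaluationReport:
    """AUROC and threshold-1 call rates for one grid cell."""

    measure: str
    k: int
    markov_order: int
    fragment_length: int
    auroc: float
    tpr_temperate: float
    tpr_lytic: float
    accuracy: float
    n_pos: int
    n_neg: int
    seed: int


@dataclass(frozen=True)
class TprSummary:
    tpr_temperate: float
    tpr_lytic: float
    accuracy: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class MutationReport:
    """Per-rate AUROC samples vs the no-mutation baseline."""

    measure: str
    rates: tuple
    baseline_aurocs: tuple
    aurocs_by_rate: dict
    mean_baseline: float
    means_by_rate: dict
    p_values: dict  # rate -> Welch t-test p vs baseline


def auroc(
    scores: Sequence[float], labels: Sequence[str], positive_is_low: bool = True,
    positive_label: str = "temperate",
) -> float:
    """AUROC via the Mann-Whitney rank statistic with mid-ranks for ties.

    ``positive_is_low`` means lower scores indicate the positive class
    (the temperate side of the distance ratio).
    """
    y = np.asarray([lab == positive_label for lab in labels], dtype=bool)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs at least one positive and one negative")
    s = np.asarray(scores, dtype=float)
    if positive_is_low:
        s = -s
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def tpr_report(
    results: Sequence[ClassificationResult], truth: Mapping[str, str]
) -> TprSummary:
    """Per-class TPRs and accuracy at the ratio-1 threshold.

    TPR1 = fraction of true temperate called temperate; TPR2 likewise for
    lytic; accuracy is the overall fraction correct.
    """
    n_pos = n_neg = hit_pos = hit_neg = 0
    for res in results:
        if res.contig_id not in truth:
            raise KeyError(f"no truth label for contig {res.contig_id!r}")
        true_label = truth[res.contig_id]
        if true_label == "temperate":
            n_pos += 1
            hit_pos += res.label == "temperate"
        elif true_label == "lytic":
            n_neg += 1
            hit_neg += res.label == "lytic"
        else:
            raise ValueError(f"truth label for {res.contig_id!r} must be temperate/lytic")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must appear in the truth labels")
    tpr1 = hit_pos / n_pos
    tpr2 = hit_neg / n_neg
    acc = (hit_pos + hit_neg) / (n_pos + n_neg)
    return TprSummary(tpr1, tpr2, acc, n_pos, n_neg)


def _score_balanced(
    model: TrainedModel,
    measure: MeasureSpec,
    frags_t: Sequence[SequenceRecord],
    frags_l: Sequence[SequenceRecord],
) -> tuple[list[float], list[str], TprSummary]:
    contigs = list(frags_t) + list(frags_l)
    truth = {r.id: r.label for r in contigs}
    results, skipped = predict_batch(contigs, model, measure)
    if skipped:
        kept_ids = {r.contig_id for r in results}
        truth = {i: lab for i, lab in truth.items() if i in kept_ids}
    scores = [r.score for r in results]
    labels = [truth[r.contig_id] for r in results]
    summary = tpr_report(results, truth)
    return scores, labels, summary


def evaluate_cell(
    model: TrainedModel,
    measure: MeasureSpec,
    test_temperate: Sequence[SequenceRecord],
    test_lytic: Sequence[SequenceRecord],
    fragment_length: int,
    seed: int,
    n_max_per_class: int | None = None,
) -> EvaluationReport:
    """Fragment, balance, score and summarize one grid cell."""
    frags_t = fragment_genomes(test_temperate, fragment_length)
    frags_l = fragment_genomes(test_lytic, fragment_length)
    if not frags_t or not frags_l:
        raise ValueError(
            f"a test class is empty after fragmentation at L={fragment_length}"
        )
    cell_seed = derive_seed(seed, measure.name, measure.k, measure.markov_order, fragment_length)
    frags_t, frags_l = balanced_subsample(frags_t, frags_l, cell_seed)
    if n_max_per_class is not None and len(frags_t) > n_max_per_class:
        frags_t = frags_t[:n_max_per_class]
        frags_l = frags_l[:n_max_per_class]
    scores, labels, summary = _score_balanced(model, measure, frags_t, frags_l)
    return EvaluationReport(
        measure=measure.name,
        k=measure.k,
        markov_order=measure.markov_order,
        fragment_length=fragment_length,
        auroc=auroc(scores, labels),
        tpr_temperate=summary.tpr_temperate,
        tpr_lytic=summary.tpr_lytic,
        accuracy=summary.accuracy,
        n_pos=summary.n_pos,
        n_neg=summary.n_neg,
        seed=cell_seed,
    )


def grid_evaluate(
    train_temperate: Sequence[SequenceRecord],
    train_lytic: Sequence[SequenceRecord],
    test_temperate: Sequence[SequenceRecord],
    test_lytic: Sequence[SequenceRecord],
    measure_names: Sequence[str],
    ks: Sequence[int],
    orders: Sequence[int],
    fragment_lengths: Sequence[int],
    seed: int,
    n_max_per_class: int | None = None,
    warn=None,
) -> list[EvaluationReport]:
    """Evaluate every measure x k x order x fragment-length cell.

    Measures that carry no explicit Markov order (everything except d2*/d2S)
    are run once per (measure, k) at order 0. Training genomes must be
    disjoint from test genomes by id. Cells whose test class is empty after
    fragmentation are skipped with a warning callback.
    """
    train_ids = {r.id for r in train_temperate} | {r.id for r in train_lytic}
    test_ids = {r.id for r in test_temperate} | {r.id for r in test_lytic}
    overlap = train_ids & test_ids
    if overlap:
        raise ValueError(f"train/test genome ids overlap: {sorted(overlap)[:5]}")
    names = [canonical_name(n) for n in measure_names]
    reports: list[EvaluationReport] = []
    for k in ks:
        for order in orders:
            specs = []
            for name in names:
                if name in MARKOV_MEASURES:
                    specs.append(MeasureSpec(name, k, order))
                elif order == orders[0]:  # order-free measures: one run per k
                    specs.append(MeasureSpec(name, k, 0))
            if not specs:
                continue
            model = train(train_temperate, train_lytic, k, order)
            for spec in specs:
                for length in fragment_lengths:
                    try:
                        reports.append(
                            evaluate_cell(
                                model, spec, test_temperate, test_lytic,
                                length, seed, n_max_per_class,
                            )
                        )
                    except ValueError as exc:
                        if warn is not None:
                            warn(f"cell ({spec.name}, k={k}, r={order}, L={length}) skipped: {exc}")
    return reports


def mutation_experiment(
    model: TrainedModel,
    measure: MeasureSpec,
    test_temperate: Sequence[SequenceRecord],
    test_lytic: Sequence[SequenceRecord],
    rates: Sequence[float] = DEFAULT_MUTATION_RATES,
    replicates: int = 30,
    seed: int = 0,
    fragment_length: int = 1000,
    n_per_class: int = 150,
) -> MutationReport:
    """AUROC under injected point mutations, vs a no-mutation baseline.

    Each replicate subsamples ``n_per_class`` fragments per class (the same
    subsample across rates, so rate effects are paired by construction),
    injects substitutions at the given per-bp rate, scores, and computes
    AUROC. Each rate's sample is compared with the rate-0 baseline by
    Welch's two-sample t-test.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates for a t-test")
    frags_t = fragment_genomes(test_temperate, fragment_length)
    frags_l = fragment_genomes(test_lytic, fragment_length)
    all_rates = [0.0] + [r for r in rates if r != 0.0]
    aurocs: dict[float, list[float]] = {r: [] for r in all_rates}
    for rep in range(replicates):
        sub_seed = derive_seed(seed, "subsample", rep)
        sel_t, sel_l = balanced_subsample(frags_t, frags_l, sub_seed)
        sel_t, sel_l = sel_t[:n_per_class], sel_l[:n_per_class]
        for rate in all_rates:
            if rate == 0.0:
                mut_t, mut_l = sel_t, sel_l
            else:
                mut_t = [
                    inject_mutations(f, rate, derive_seed(seed, "mut", rate, rep, f.id))
                    for f in sel_t
                ]
                mut_l = [
                    inject_mutations(f, rate, derive_seed(seed, "mut", rate, rep, f.id))
                    for f in sel_l
                ]
            scores, labels, _ = _score_balanced(model, measure, mut_t, mut_l)
            aurocs[rate].append(auroc(scores, labels))
    baseline = aurocs[0.0]
    p_values: dict[float, float] = {}
    for rate in all_rates[1:]:
        sample = aurocs[rate]
        if sample == baseline:
            p_values[rate] = 1.0
        else:
            p_values[rate] = float(
                stats.ttest_ind(sample, baseline, equal_var=False).pvalue
            )
    return MutationReport(
        measure=measure.name,
        rates=tuple(all_rates[1:]),
        baseline_aurocs=tuple(baseline),
        aurocs_by_rate={r: tuple(aurocs[r]) for r in all_rates[1:]},
        mean_baseline=float(np.mean(baseline)),
        means_by_rate={r: float(np.mean(aurocs[r])) for r in all_rates[1:]},
        p_values=p_values,
    )
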