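"""Sequence input/output and simulation utilities.

Handles FASTA reading/writing, fragmentation of genomes into contig-like
pieces, point-mutation injection (a stand-in for sequencing error), and
generation of synthetic two-class genome corpora from parameterized Markov
sources. Sequences are normalized to the {A, C, G, T, N} alphabet on ingest;
any IUPAC ambiguity code becomes N.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_NORMALIZE = str.maketrans(
    {c: ("N" if c not in "ACGT" else c) for c in map(chr, range(65, 91))}
)

#: lifestyle labels recognized throughout the package
LABELS = ("temperate", "lytic", "unknown")


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single sequence with an optional lifestyle label.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within one file.
    sequence : str
        Uppercase string over {A, C, G, T, N}.
    label : str
        One of ``temperate``, ``lytic`` or ``unknown``.
    """

    id: str
    sequence: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.label not in LABELS:
            raise ValueError(f"unknown lifestyle label {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str) -> str:
    """Uppercase and map every non-ACGT character to N."""
    s = raw.upper()
    if set(s) <= VALID_BASES:
        return s
    return "".join(c if c in "ACGT" else "N" for c in s)


def read_fasta(path: str | Path, label: str = "unknown") -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into normalized records.

    Lowercase bases are uppercased; ambiguity codes map to N. An empty file
    yields an empty list. A file whose first non-blank line is not a header
    raises :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    kept: list[str] = []
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(";"):  # classic FASTA comment (provenance headers)
            continue
        if stripped.startswith(">"):
            header_seen = True
        elif not header_seen:
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before any '>' header"
            )
        kept.append(line)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(StringIO("".join(kept)), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, normalize_sequence(str(rec.seq)), label))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to a FASTA file (60-column wrapped)."""
    bio = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, lifestyle) TSV into a dict."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            rec_id, label = parts
            if label not in LABELS:
                raise ValueError(f"{path}: line {lineno}: bad label {label!r}")
            labels[rec_id] = label
    return labels


def fragment_genome(rec: SequenceRecord, length: int) -> list[SequenceRecord]:
    """Split a genome into consecutive non-overlapping fragments.

    Windows are ``[0, L), [L, 2L), ...``; a trailing remainder shorter than
    ``length`` is discarded, so a genome shorter than ``length`` yields an
    empty list. Fragment ids are ``<parent_id>_<index>`` and labels are
    inherited.
    """
    if length < 1:
        raise ValueError(f"fragment length must be >= 1, got {length}")
    n = len(rec.sequence) // length
    return [
        SequenceRecord(f"{rec.id}_{i}", rec.sequence[i * length : (i + 1) * length], rec.label)
        for i in range(n)
    ]


def fragment_genomes(
    records: Iterable[SequenceRecord], length: int
) -> list[SequenceRecord]:
    """Fragment every genome in a collection (see :func:`fragment_genome`)."""
    out: list[SequenceRecord] = []
    for rec in records:
        out.extend(fragment_genome(rec, length))
    return out


_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = np.array(list("ACGT"))


def inject_mutations(rec: SequenceRecord, rate: float, seed: int) -> SequenceRecord:
    """Substitute each position independently with probability ``rate``.

    A substituted base is replaced by one of the three other bases, chosen
    uniformly. N positions are never mutated; substitutions only, so the
    output has the same length. Deterministic under ``seed``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate must be in [0, 1], got {rate}")
    if rate == 0.0 or not rec.sequence:
        return rec
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(seq.size) < rate
    hit &= seq != ord("N")
    idx = np.flatnonzero(hit)
    if idx.size:
        codes = np.zeros(seq.size, dtype=np.int8)
        for b, c in _BASE_TO_CODE.items():
            codes[seq == ord(b)] = c
        # shift by 1..3 mod 4 guarantees a different base
        shift = rng.integers(1, 4, size=idx.size)
        new_codes = (codes[idx] + shift) % 4
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        seq[idx] = lut[new_codes]
    return replace(rec, sequence=seq.tobytes().decode("ascii"))


@dataclass(frozen=True)
class SyntheticSourceSpec:
    """Parameters of one Markov genome source.

    ``transition_matrix`` has shape ``(4**order, 4)``: row ``c`` is the
    distribution of the next base given the length-``order`` context with
    lexicographic index ``c`` (A<C<G<T). Order 0 uses a single row.
    """

    order: int
    transition_matrix: np.ndarray
    genome_length: int
    n_genomes: int
    seed: int

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        tm = np.asarray(self.transition_matrix, dtype=float)
        expected_shape = (4**self.order, 4)
        if tm.shape != expected_shape:
            raise ValueError(
                f"transition matrix shape {tm.shape} != {expected_shape} for order {self.order}"
            )
        if (tm < 0).any():
            raise ValueError("transition probabilities must be >= 0")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every conditional distribution must sum to 1 (1e-9)")
        object.__setattr__(self, "transition_matrix", tm)
        if self.genome_length < 1 or self.n_genomes < 1:
            raise ValueError("genome_length and n_genomes must be >= 1")


def _context_transition_operator(tm: np.ndarray, order: int) -> np.ndarray:
    """Dense transition matrix of the context chain over 4**order states."""
    m = 4**order
    op = np.zeros((m, m))
    for c in range(m):
        for b in range(4):
            nxt = (c * 4 + b) % m if order > 0 else 0
            op[c, nxt] += tm[c if order > 0 else 0, b]
    return op


def stationary_distribution(
    tm: np.ndarray, order: int, tol: float = 1e-10, max_iter: int = 10_000
) -> np.ndarray:
    """Stationary distribution of the context chain by power iteration.

    Raises if the iteration has not converged (L1 change below ``tol``)
    within ``max_iter`` sweeps, which covers non-ergodic matrices.
    """
    if order == 0:
        return np.asarray(tm, dtype=float)[0]
    op = _context_transition_operator(np.asarray(tm, dtype=float), order)
    m = op.shape[0]
    pi = np.full(m, 1.0 / m)
    for _ in range(max_iter):
        nxt = pi @ op
        if np.abs(nxt - pi).sum() < tol:
            return nxt
        pi = nxt
    raise RuntimeError(
        f"stationary distribution did not converge in {max_iter} iterations "
        "(non-ergodic transition matrix?)"
    )


def _sample_markov_sequence(
    tm: np.ndarray, order: int, length: int, pi: np.ndarray, rng: np.random.Generator
) -> str:
    """Sample one sequence; initial context drawn from the stationary law."""
    cum = np.cumsum(tm, axis=1)
    # guard against float round-off leaving the last cumsum below a uniform
    cum[:, -1] = 1.0
    out = np.empty(length, dtype=np.int8)
    if order == 0:
        u = rng.random(length)
        out = np.searchsorted(cum[0], u).astype(np.int8)
        return "".join(_CODE_TO_BASE[out])
    ctx = int(rng.choice(pi.size, p=pi / pi.sum()))
    mask = 4**order
    u = rng.random(length)
    cum_rows = cum.tolist()
    codes = []
    for i in range(length):
        row = cum_rows[ctx]
        ui = u[i]
        b = 0
        while row[b] < ui:
            b += 1
        codes.append(b)
        ctx = (ctx * 4 + b) % mask
    return "".join(_CODE_TO_BASE[np.array(codes, dtype=np.int8)])


def generate_genomes(spec: SyntheticSourceSpec, label: str, id_prefix: str) -> list[SequenceRecord]:
    """Sample ``spec.n_genomes`` genomes from one Markov source."""
    pi = stationary_distribution(spec.transition_matrix, spec.order)
    rng = np.random.default_rng(spec.seed)
    return [
        SequenceRecord(
            f"{id_prefix}{i}",
            _sample_markov_sequence(spec.transition_matrix, spec.order, spec.genome_length, pi, rng),
            label,
        )
        for i in range(spec.n_genomes)
    ]


def generate_synthetic_classes(
    spec_a: SyntheticSourceSpec, spec_b: SyntheticSourceSpec, id_prefix: str = ""
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Generate a labeled two-class corpus: (temperate list, lytic list).

    ``id_prefix`` is prepended to every genome id, letting several corpora
    (e.g. a training and a testing set) coexist with disjoint ids.
    """
    temperate = generate_genomes(spec_a, "temperate", f"{id_prefix}temperate_")
    lytic = generate_genomes(spec_b, "lytic", f"{id_prefix}lytic_")
    return temperate, lytic


def balanced_subsample(
    pos: Sequence[SequenceRecord], neg: Sequence[SequenceRecord], seed: int
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Sample min(|pos|, |neg|) records from each class without replacement."""
    if not pos or not neg:
        raise ValueError("both classes must be non-empty for balanced subsampling")
    n = min(len(pos), len(neg))
    rng = np.random.default_rng(seed)
    pos_idx = rng.choice(len(pos), size=n, replace=False)
    neg_idx = rng.choice(len(neg), size=n, replace=False)
    return [pos[i] for i in pos_idx], [neg[i] for i in neg_idx]


# ---------------------------------------------------------------------------
# Default synthetic study conditions
# ---------------------------------------------------------------------------

#: Order-1 base transition matrix used by the synthetic presets. Rows are the
#: next-base distribution given context A, C, G, T. Mildly AT-rich with weak
#: first-order autocorrelation, in the range typical of phage genomes.
BASE_TRANSITIONS = np.array(
    [
        [0.32, 0.20, 0.22, 0.26],  # after A
        [0.28, 0.24, 0.20, 0.28],  # after C
        [0.26, 0.22, 0.24, 0.28],  # after G
        [0.28, 0.20, 0.22, 0.30],  # after T
    ]
)


def perturbed_transitions(base: np.ndarray, epsilon: float = 0.1) -> np.ndarray:
    """Shift ``epsilon`` of probability mass from A/T to C/G in the G and C
    context rows, producing a source divergent from ``base``.
    """
    tm = np.asarray(base, dtype=float).copy()
    for row in (1, 2):  # C and G contexts
        take = epsilon / 2.0
        tm[row, 0] -= take
        tm[row, 3] -= take
        tm[row, 1] += take
        tm[row, 2] += take
    if (tm < 0).any():
        raise ValueError("epsilon too large for the base matrix")
    return tm


def divergent_source_pair(
    genome_length: int = 50_000,
    n_genomes: int = 30,
    seed: int = 0,
    epsilon: float = 0.1,
) -> tuple[SyntheticSourceSpec, SyntheticSourceSpec]:
    """Two order-1 sources whose transition rows differ by ``epsilon``."""
    spec_a = SyntheticSourceSpec(1, BASE_TRANSITIONS, genome_length, n_genomes, seed)
    spec_b = SyntheticSourceSpec(
        1, perturbed_transitions(BASE_TRANSITIONS, epsilon), genome_length, n_genomes, seed + 1
    )
    return spec_a, spec_b


def null_source_pair(
    genome_length: int = 50_000, n_genomes: int = 30, seed: int = 0
) -> tuple[SyntheticSourceSpec, SyntheticSourceSpec]:
    """Two sources with identical transition laws, differing only in seed."""
    spec_a = SyntheticSourceSpec(1, BASE_TRANSITIONS, genome_length, n_genomes, seed)
    spec_b = SyntheticSourceSpec(1, BASE_TRANSITIONS, genome_length, n_genomes, seed + 1)
    return spec_a, spec_b
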