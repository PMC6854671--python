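"""Canonical k-mer indexes and presence/absence region (PAR) detection.

A PAR is a run of at least ``min_len`` (default 35) positions inside a target
sequence that no k-mer of any comparison line covers, after subtracting
annotated repeats.  Coverage is per-position: a position is covered iff at
least one k-mer window overlapping it is a member of a comparison index.
K-mers are strand-collapsed (canonical = lexicographic min of the k-mer and
its reverse complement), so PAR calls are strand symmetric.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Union

import numpy as np

from .breakpoints import revcomp

DEFAULT_K = 17
DEFAULT_MIN_PAR_LEN = 35


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    kmer = kmer.upper()
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    """Membership/multiplicity structure over canonical k-mers.

    ``counts`` maps canonical k-mer -> total occurrences (scanning one strand
    of the source sequences; canonicalisation makes lookups strand-blind).
    K-mers containing N are never members.
    """

    k: int = DEFAULT_K
    source: str = "assembly"  # {"assembly", "reads"}
    min_occurrence: int = 1
    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError(f"k={self.k} < 11")

    def __contains__(self, kmer: str) -> bool:
        return self.counts.get(canonical(kmer), 0) >= self.min_occurrence

    def count(self, kmer: str) -> int:
        """Occurrence count of a k-mer (0 if below min_occurrence)."""
        c = self.counts.get(canonical(kmer), 0)
        return c if c >= self.min_occurrence else 0

    def __len__(self) -> int:
        return sum(1 for c in self.counts.values() if c >= self.min_occurrence)


def build_kmer_index(
    sequences: Union[Mapping[str, str], Iterable[str]],
    k: int = DEFAULT_K,
    min_occurrence: int = 1,
    source: str = "assembly",
) -> KmerIndex:
    """Count canonical k-mers over a set of sequences.

    ``sequences`` is a mapping name->sequence or an iterable of sequences.
    Sequences shorter than k contribute nothing (a warning is emitted).
    """
    if isinstance(sequences, Mapping):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    counter: Counter = Counter()
    for seq in seqs:
        seq = seq.upper()
        if len(seq) < k:
            warnings.warn(f"sequence of length {len(seq)} < k={k} ignored", stacklevel=2)
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counter[canonical(kmer)] += 1
    return KmerIndex(k=k, source=source, min_occurrence=min_occurrence, counts=dict(counter))


@dataclass(frozen=True)
class PARInterval:
    seq_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def coverage_mask(
    target: str,
    others: Sequence[Union[KmerIndex, Sequence[KmerIndex]]],
    k: int = DEFAULT_K,
    within_line: str = "or",
) -> np.ndarray:
    """Boolean per-position coverage of ``target`` by the other lines' k-mers.

    ``others`` is a flat list of indexes, or a list of per-line index groups.
    Evidence within one line's group is combined by ``within_line`` ("or":
    membership in either index covers; "and": both required); coverage across
    lines is always OR (any line's k-mer covers the position).
    """
    if within_line not in ("or", "and"):
        raise ValueError("within_line must be 'or' or 'and'")
    groups: List[List[KmerIndex]] = [
        list(g) if isinstance(g, (list, tuple)) else [g] for g in others
    ]
    n = len(target)
    covered = np.zeros(n, dtype=bool)
    n_win = n - k + 1
    if n_win <= 0:
        return covered
    target = target.upper()
    member = np.zeros(n_win, dtype=bool)
    for i in range(n_win):
        kmer = target[i : i + k]
        if "N" in kmer:
            continue
        for group in groups:
            hits = [kmer in idx for idx in group]
            ok = any(hits) if within_line == "or" else all(hits)
            if ok:
                member[i] = True
                break
    # a position is covered iff any member window overlaps it
    for i in np.flatnonzero(member):
        covered[i : i + k] = True
    return covered


def annotate_uncovered_regions(
    target: str,
    others: Sequence[Union[KmerIndex, Sequence[KmerIndex]]],
    k: int = DEFAULT_K,
    min_len: int = DEFAULT_MIN_PAR_LEN,
    seq_id: str = "seq",
    within_line: str = "or",
) -> List[PARInterval]:
    """Maximal uncovered runs of length >= min_len, sorted and disjoint."""
    if len(target) < k:
        raise ValueError(f"target length {len(target)} < k={k}")
    covered = coverage_mask(target, others, k=k, within_line=within_line)
    out: List[PARInterval] = []
    start = None
    for pos, cov in enumerate(covered):
        if not cov and start is None:
            start = pos
        elif cov and start is not None:
            if pos - start >= min_len:
                out.append(PARInterval(seq_id, start, pos))
            start = None
    if start is not None and len(covered) - start >= min_len:
        out.append(PARInterval(seq_id, start, len(covered)))
    return out


def subtract_repeats(
    pars: Sequence[PARInterval],
    repeats: Sequence[tuple],
    min_len: int = DEFAULT_MIN_PAR_LEN,
) -> List[PARInterval]:
    """Set-difference PARs minus repeat intervals; short fragments dropped.

    ``repeats`` is a sequence of (start, end) or (seq_id, start, end) tuples
    on the same coordinate system as the PARs.
    """
    norm = []
    for r in repeats:
        if len(r) == 2:
            sid, s, e = None, *r
        else:
            sid, s, e = r[0], int(r[1]), int(r[2])
        if e <= s:
            raise ValueError(f"malformed interval: ({s}, {e})")
        norm.append((sid, s, e))
    out: List[PARInterval] = []
    for par in pars:
        pieces = [(par.start, par.end)]
        for sid, s, e in norm:
            if sid is not None and sid != par.seq_id:
                continue
            nxt = []
            for ps, pe in pieces:
                if e <= ps or s >= pe:  # no overlap
                    nxt.append((ps, pe))
                    continue
                if ps < s:
                    nxt.append((ps, s))
                if e < pe:
                    nxt.append((e, pe))
            pieces = nxt
        out.extend(
            PARInterval(par.seq_id, ps, pe) for ps, pe in pieces if pe - ps >= min_len
        )
    return sorted(out, key=lambda p: (p.seq_id, p.start))
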