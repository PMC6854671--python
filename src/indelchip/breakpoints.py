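"""InDel breakpoint representation, classification and BP probe construction.

An InDel is a sequence present at a locus in one line and absent at the same
locus in the other.  The junction of the absence allele may carry a short
microhomology (the first/last bases of the missing sequence duplicated at the
junction) and/or a short non-homologous inserted fragment.  Four breakpoint
types follow:

=====  =============  ===========
type   microhomology  inserted
=====  =============  ===========
I      m == 0         i == 0
II     m  > 0         i == 0
III    m == 0         i  > 0
IV     m  > 0         i  > 0
=====  =============  ===========

Breakpoints with microhomology longer than 5 bp are excluded from probe
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

PROBE_LEN = 35
#: bases of context on each side of the interrogated base in a 35 bp probe
_LEFT_CTX = (PROBE_LEN - 1) // 2   # 17
_RIGHT_CTX = PROBE_LEN - 1 - _LEFT_CTX  # 17

MAX_DESIGN_MICROHOMOLOGY = 5

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (ACGTN alphabet, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FlankTooShortError(ValueError):
    """Raised when a flank is too short to bound the microhomology scan."""


@dataclass
class InDelVariant:
    """One insertion/deletion event with breakpoint-resolved coordinates.

    ``deleted_seq`` is the sequence present in one line and absent in the
    other; ``inserted_fragment`` is the (possibly empty) short non-homologous
    sequence found in its place on the absence allele.  Coordinates are
    0-based half-open on the carrier sequence.
    """

    id: str
    kind: str  # {"deletion_vs_ref", "insertion_vs_ref"}
    chrom: str
    start: int
    end: int
    deleted_seq: str
    inserted_fragment: str = ""
    left_flank: str = ""
    right_flank: str = ""
    source_line: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deletion_vs_ref", "insertion_vs_ref"):
            raise ValueError(f"unknown InDel kind: {self.kind!r}")
        for name in ("deleted_seq", "inserted_fragment", "left_flank", "right_flank"):
            s = getattr(self, name)
            if s and set(s.upper()) - set("ACGTN"):
                raise ValueError(f"{name} contains non-ACGTN characters")


@dataclass
class BreakpointClass:
    type_code: str  # {"I", "II", "III", "IV"}
    microhomology_len: int
    insert_len: int
    design_excluded: bool = False


@dataclass
class ProbeCandidate:
    """A 35 bp assay candidate.

    ``position`` is the candidate's offset inside the InDel sequence for
    internal (OTV/MONO) probes, or the junction shift for BP probes.
    """

    probe_id: str
    indel_id: str
    ptype: str   # {"BP", "OTV", "MONO"}
    strand: str  # {"FW", "REV"}
    seq: str
    position: int = 0
    par_overlap_frac: float = 0.0
    genome_hits: int = 0
    hit16: int = 0
    score: float = 0.0
    classification: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.seq) != PROBE_LEN:
            raise ValueError(f"probe {self.probe_id}: length {len(self.seq)} != {PROBE_LEN}")


@dataclass
class DesignFailure:
    indel_id: str
    reason: str  # "not_possible"


def _match_len(a: str, b: str) -> int:
    """Length of the common prefix of ``a`` and ``b``; N ends the extension."""
    n = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == "N" or y == "N" or x != y:
            break
        n += 1
    return n


def classify_breakpoint(v: InDelVariant) -> BreakpointClass:
    """Classify an InDel breakpoint into types I-IV.

    Microhomology is scanned on both sides -- the deleted sequence's prefix
    against the right flank and its suffix against the left flank -- and the
    maximum taken.  Extension is case-insensitive and stops at N.

    Raises
    ------
    ValueError
        if ``deleted_seq`` or a flank is empty.
    FlankTooShortError
        if a flank is fully consumed by the homology scan while the deleted
        sequence could extend it further (the true m is then unbounded).
    """
    if not v.deleted_seq:
        raise ValueError(f"{v.id}: empty deleted_seq")
    if not v.left_flank or not v.right_flank:
        raise ValueError(f"{v.id}: empty flank")

    d = v.deleted_seq
    m_right = _match_len(d, v.right_flank)
    m_left = _match_len(d[::-1], v.left_flank[::-1])
    if m_right == len(v.right_flank) and m_right < len(d):
        raise FlankTooShortError(f"{v.id}: right flank shorter than homology run")
    if m_left == len(v.left_flank) and m_left < len(d):
        raise FlankTooShortError(f"{v.id}: left flank shorter than homology run")

    m = max(m_right, m_left)
    i = len(v.inserted_fragment)
    if m == 0 and i == 0:
        code = "I"
    elif m > 0 and i == 0:
        code = "II"
    elif m == 0:
        code = "III"
    else:
        code = "IV"
    excluded = code in ("II", "IV") and m > MAX_DESIGN_MICROHOMOLOGY
    return BreakpointClass(code, m, i, excluded)


def _discriminative_shift(v: InDelVariant, max_shift: int) -> Optional[int]:
    """Smallest junction shift whose interrogated base discriminates alleles.

    At shift ``s`` the presence allele reads ``deleted_seq[s]`` and the
    absence allele reads the s-th base of what replaced it (inserted fragment
    first, then right flank).  The position is discriminative when the two
    differ and neither is N.
    """
    replacement = v.inserted_fragment + v.right_flank
    for s in range(max_shift + 1):
        if s >= len(v.deleted_seq) or s >= len(replacement):
            break
        a, b = v.deleted_seq[s].upper(), replacement[s].upper()
        if a != b and a != "N" and b != "N":
            return s
    return None


def design_bp_probe(v: InDelVariant, bp: BreakpointClass, max_shift: int = 5):
    """Build the FW/REV pair of 35 bp junction probes for an InDel.

    The probe is taken from the absence allele (left flank + inserted
    fragment + right flank) and centred on the first discriminative position,
    shifting one base at a time up to ``max_shift`` (needed for type II
    junctions, whose first m positions read identically on both alleles).

    Returns ``(fw, rev)`` :class:`ProbeCandidate` or a :class:`DesignFailure`
    with reason ``"not_possible"``.
    """
    if bp.design_excluded:
        return DesignFailure(v.id, "not_possible")
    shift = _discriminative_shift(v, max_shift)
    if shift is None:
        return DesignFailure(v.id, "not_possible")

    junction = v.left_flank + v.inserted_fragment + v.right_flank
    idx = len(v.left_flank) + shift  # interrogated base, 0-based in `junction`
    lo, hi = idx - _LEFT_CTX, idx + _RIGHT_CTX + 1
    if lo < 0 or hi > len(junction):
        return DesignFailure(v.id, "not_possible")
    seq = junction[lo:hi].upper()
    fw = ProbeCandidate(f"{v.id}_BP_FW", v.id, "BP", "FW", seq, position=shift)
    rev = ProbeCandidate(f"{v.id}_BP_REV", v.id, "BP", "REV", revcomp(seq), position=shift)
    return fw, rev
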