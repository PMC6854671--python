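"""Internal-probe generation, scoring, filtering and windowed selection.

Internal probes interrogate positions inside an InDel sequence: OTV probes
sit on a known polymorphic site (the off-target cluster then reveals the
InDel's absence), MONO probes on putatively monomorphic sites and are called
by the Hom2OTV algorithm downstream.

The array vendor's conversion-probability model (p-convert) is proprietary;
``score_probe`` substitutes a transparent surrogate with the same range,
thresholds and classification semantics:

    base  = 1 - 0.5*gc_pen - 0.3*homopolymer_pen - 0.2*dinucleotide_pen
    score = clip(base, 0, 1) / (1 + excess_hit16 / n_windows)

where gc_pen = min(1, |GC - 0.45| / 0.45), homopolymer_pen grows linearly
from runs of 3 up to 1.0 at runs of 10, dinucleotide_pen is the fraction of
the probe inside its longest dinucleotide tandem, and excess_hit16 is the
16-mer hit count above the minimum one self-match per window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .breakpoints import PROBE_LEN, ProbeCandidate, revcomp
from .kmers import KmerIndex, PARInterval, build_kmer_index

INTERROGATED_POS = 17  # centre of a 35 bp probe, 0-based


@dataclass
class DesignConfig:
    thr_recommended: float = 0.6
    thr_neutral: float = 0.4
    max_flank_polys_neutral: int = 3    # strictly fewer than this
    min_poly_distance: int = 21         # polymorphisms must be further than this
    flank_window: int = 30
    hit_kmer: int = 16
    max_hits_deletion_probe: int = 1
    max_hits_insertion_probe: int = 0
    max_hits_bp_probe: int = 3          # strictly fewer than this
    min_par_overlap: float = 0.70       # strict inequality
    window_sizes: Tuple[int, ...] = (75, 50, 25)
    min_probes_per_indel: int = 4


def count_substring(haystack: str, needle: str) -> int:
    """Overlapping occurrence count of ``needle`` in ``haystack``."""
    count = start = 0
    while True:
        start = haystack.find(needle, start)
        if start == -1:
            return count
        count += 1
        start += 1


def count_genome_hits(seq: str, genome: str) -> int:
    """Exact double-stranded occurrence count of ``seq`` in ``genome``."""
    seq, genome = seq.upper(), genome.upper()
    rc = revcomp(seq)
    hits = count_substring(genome, seq)
    if rc != seq:
        hits += count_substring(genome, rc)
    return hits


def hit16_windows(seq: str, interrogated: int = INTERROGATED_POS, k: int = 16) -> List[str]:
    """The 16 bp windows of the two flanks of the interrogated base."""
    left, right = seq[:interrogated], seq[interrogated + 1 :]
    wins = [left[i : i + k] for i in range(len(left) - k + 1)]
    wins += [right[i : i + k] for i in range(len(right) - k + 1)]
    return wins


def count_16mer_hits(seq: str, genome_index: KmerIndex) -> int:
    """Sum of genome occurrence counts of the probe's flank 16-mers.

    Windows containing N contribute 0.
    """
    if len(seq) != PROBE_LEN:
        raise ValueError(f"probe length {len(seq)} != {PROBE_LEN}")
    total = 0
    for w in hit16_windows(seq.upper(), k=genome_index.k):
        if "N" in w:
            continue
        total += genome_index.count(w)
    return total


def _longest_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _longest_dinucleotide_run(seq: str) -> int:
    """Length (bp) of the longest tandem of a 2 bp motif with >= 2 units."""
    best = 0
    for phase in (0, 1):
        i = phase
        while i + 2 <= len(seq):
            motif = seq[i : i + 2]
            j = i + 2
            while seq[j : j + 2] == motif:
                j += 2
            if j - i >= 4 and motif[0] != motif[1]:
                best = max(best, j - i)
            i = j if j > i + 2 else i + 2
    return best


def surrogate_score(seq: str, hit16: int = 0) -> float:
    """Transparent p-convert surrogate in [0, 1] (see module docstring)."""
    seq = seq.upper()
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    gc_pen = min(1.0, abs(gc - 0.45) / 0.45)
    hp = _longest_homopolymer(seq)
    hp_pen = min(1.0, max(0, hp - 2) / 8.0)
    din_pen = _longest_dinucleotide_run(seq) / len(seq)
    base = max(0.0, min(1.0, 1.0 - 0.5 * gc_pen - 0.3 * hp_pen - 0.2 * din_pen))
    n_win = len(hit16_windows(seq))
    excess = max(0, hit16 - n_win)
    return base / (1.0 + excess / max(1, n_win))


def score_probe(
    probe: ProbeCandidate,
    known_polymorphisms: Sequence[int] = (),
    cfg: Optional[DesignConfig] = None,
) -> Tuple[float, str]:
    """Score a probe and classify it.

    ``known_polymorphisms`` are distances (bp) of expected flanking
    polymorphisms from the interrogated base.  Classification:

    * ``not_possible``  — N at the interrogated base or homopolymer >= 10
    * ``recommended``   — score >= 0.6 and no flanking polymorphisms
    * ``neutral``       — score >= 0.4, fewer than 3 polymorphisms, all
      further than 21 bp from the interrogated base
    * ``not_recommended`` otherwise
    """
    cfg = cfg or DesignConfig()
    seq = probe.seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError(f"probe {probe.probe_id}: unknown characters in sequence")
    score = surrogate_score(seq, probe.hit16)
    if seq[INTERROGATED_POS] == "N" or _longest_homopolymer(seq) >= 10:
        return score, "not_possible"
    polys = list(known_polymorphisms)
    if score >= cfg.thr_recommended and not polys:
        return score, "recommended"
    if (
        score >= cfg.thr_neutral
        and len(polys) < cfg.max_flank_polys_neutral
        and all(d > cfg.min_poly_distance for d in polys)
    ):
        return score, "neutral"
    return score, "not_recommended"


def par_overlap_fraction(start: int, pars: Sequence[PARInterval], length: int = PROBE_LEN) -> float:
    """Fraction of a probe footprint [start, start+length) inside PARs."""
    covered = 0
    for p in pars:
        covered += max(0, min(start + length, p.end) - max(start, p.start))
    return covered / length


def generate_internal_candidates(
    indel_id: str,
    internal_seq: str,
    pars: Sequence[PARInterval],
    known_snp_positions: Sequence[int] = (),
    stride: int = 1,
) -> List[ProbeCandidate]:
    """Enumerate OTV/MONO candidates over an InDel's internal sequence.

    A candidate is a 35 bp window fully inside ``internal_seq``; it is an OTV
    probe when its interrogated (centre) base sits on a known internal SNP,
    MONO when no known SNP falls inside its footprint, and skipped otherwise
    (a SNP in the flank would corrupt a MONO assay).  FW and REV strands are
    both produced; positions are offsets of the window start in the InDel.
    """
    snps = set(known_snp_positions)
    out: List[ProbeCandidate] = []
    for start in range(0, len(internal_seq) - PROBE_LEN + 1, stride):
        window = internal_seq[start : start + PROBE_LEN].upper()
        centre = start + INTERROGATED_POS
        in_footprint = {s for s in snps if start <= s < start + PROBE_LEN}
        if centre in snps:
            ptype = "OTV"
        elif not in_footprint:
            ptype = "MONO"
        else:
            continue
        for strand, seq in (("FW", window), ("REV", revcomp(window))):
            out.append(
                ProbeCandidate(
                    probe_id=f"{indel_id}_{ptype}_{start:06d}_{strand}",
                    indel_id=indel_id,
                    ptype=ptype,
                    strand=strand,
                    seq=seq,
                    position=start,
                    par_overlap_frac=par_overlap_fraction(start, pars),
                )
            )
    return out


def annotate_candidates(
    cands: Sequence[ProbeCandidate],
    genome: str,
    known_polymorphisms: Optional[Dict[str, Sequence[int]]] = None,
    cfg: Optional[DesignConfig] = None,
    genome_index: Optional[KmerIndex] = None,
) -> List[ProbeCandidate]:
    """Fill genome_hits, hit16, score and classification in place."""
    cfg = cfg or DesignConfig()
    if genome_index is None:
        genome_index = build_kmer_index([genome], k=cfg.hit_kmer)
    polys = known_polymorphisms or {}
    for c in cands:
        c.genome_hits = count_genome_hits(c.seq, genome)
        c.hit16 = count_16mer_hits(c.seq, genome_index)
        c.score, c.classification = score_probe(c, polys.get(c.probe_id, ()), cfg)
    return list(cands)


def _passes_hit_filter(c: ProbeCandidate, is_insertion: bool, cfg: DesignConfig) -> bool:
    if c.ptype == "BP":
        return c.genome_hits < cfg.max_hits_bp_probe
    limit = cfg.max_hits_insertion_probe if is_insertion else cfg.max_hits_deletion_probe
    return c.genome_hits <= limit


def filter_candidates(
    cands: Sequence[ProbeCandidate],
    cfg: Optional[DesignConfig] = None,
    insertion_indels: Sequence[str] = (),
) -> List[ProbeCandidate]:
    """Apply the selection-policy hard filters.

    OTV/MONO candidates must be recommended or neutral, pass the genome-hit
    limit (<=1 for deletion probes, 0 for insertion probes) and have a strict
    >70% PAR overlap.  All BP candidates are kept regardless of score as long
    as they have fewer than 3 genome hits.
    """
    cfg = cfg or DesignConfig()
    ins = set(insertion_indels)
    kept = []
    for c in cands:
        is_ins = c.indel_id in ins
        if not _passes_hit_filter(c, is_ins, cfg):
            continue
        if c.ptype == "BP":
            kept.append(c)
            continue
        if c.classification not in ("recommended", "neutral"):
            continue
        if not c.par_overlap_frac > cfg.min_par_overlap:
            continue
        kept.append(c)
    return kept


def _window_index(c: ProbeCandidate, par: PARInterval, width: int) -> Optional[int]:
    mid = c.position + INTERROGATED_POS
    if not (par.start <= mid < par.end):
        return None
    return (mid - par.start) // width


def select_windowed(
    mono_cands: Sequence[ProbeCandidate],
    pars: Sequence[PARInterval],
    cfg: Optional[DesignConfig] = None,
) -> List[ProbeCandidate]:
    """Window-tile PARs and keep the best MONO candidate per window.

    PARs are tiled with 75 bp windows (last partial window kept) and the
    highest-scoring candidate whose interrogated base falls in each window is
    selected; ties break on probe_id.  If fewer than 4 probes result, the
    selection is discarded and re-run with 50 bp then 25 bp windows; the last
    iteration's selection is returned even if still short.
    """
    cfg = cfg or DesignConfig()
    selection: List[ProbeCandidate] = []
    for width in cfg.window_sizes:
        best: Dict[Tuple[int, int, int], ProbeCandidate] = {}
        for c in mono_cands:
            for pi, par in enumerate(pars):
                wi = _window_index(c, par, width)
                if wi is None:
                    continue
                key = (pi, wi, 0)
                cur = best.get(key)
                if cur is None or (-c.score, c.probe_id) < (-cur.score, cur.probe_id):
                    best[key] = c
        selection = sorted(best.values(), key=lambda c: c.probe_id)
        if len(selection) >= cfg.min_probes_per_indel:
            return selection
    return selection


def rescue_untargeted(
    indels: Sequence[str],
    selected: Sequence[ProbeCandidate],
    rejected: Sequence[ProbeCandidate],
    pars_by_indel: Optional[Dict[str, Sequence[PARInterval]]] = None,
    cfg: Optional[DesignConfig] = None,
    insertion_indels: Sequence[str] = (),
) -> List[ProbeCandidate]:
    """Second-pass selection among not_recommended probes for bare InDels.

    For every InDel with no selected probe, not_recommended OTV/MONO
    candidates that still pass the hit and PAR-overlap filters are pooled;
    MONO rescues go through windowed selection again, OTV rescues are all
    added.  Returns the rescued probes (InDels with no viable candidate stay
    untargeted).
    """
    cfg = cfg or DesignConfig()
    ins = set(insertion_indels)
    targeted = {c.indel_id for c in selected}
    rescued: List[ProbeCandidate] = []
    for indel_id in indels:
        if indel_id in targeted:
            continue
        pool = [
            c
            for c in rejected
            if c.indel_id == indel_id
            and c.ptype in ("OTV", "MONO")
            and c.classification == "not_recommended"
            and _passes_hit_filter(c, indel_id in ins, cfg)
            and c.par_overlap_frac > cfg.min_par_overlap
        ]
        if not pool:
            continue
        monos = [c for c in pool if c.ptype == "MONO"]
        otvs = [c for c in pool if c.ptype == "OTV"]
        pars = (pars_by_indel or {}).get(indel_id)
        if monos and pars:
            rescued.extend(select_windowed(monos, pars, cfg))
        elif monos:
            rescued.append(min(monos, key=lambda c: (-c.score, c.probe_id)))
        rescued.extend(otvs)
    return rescued


def dedupe_probes(selected: Sequence[ProbeCandidate]) -> List[ProbeCandidate]:
    """Collapse exact-sequence duplicates, keeping the best-scoring carrier.

    Ties on score break toward the lexicographically smaller probe_id.
    Input order of first appearance is preserved.
    """
    by_seq: Dict[str, ProbeCandidate] = {}
    order: List[str] = []
    for c in selected:
        key = c.seq.upper()
        cur = by_seq.get(key)
        if cur is None:
            by_seq[key] = c
            order.append(key)
        elif (-c.score, c.probe_id) < (-cur.score, cur.probe_id):
            by_seq[key] = c
    return [by_seq[k] for k in order]
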