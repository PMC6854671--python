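"""Multi-probe consensus genotypes, error simulation and concordance.

Array calls are first reduced to a presence alphabet: AA/BB/AB map to
``present``, OO to ``absent``, OA/OB to ``hemizygous`` and NoCall to
``missing``.  Per InDel and sample the average allelic frequency of presence
is taken over non-missing probes (hemizygous contributes 0.5) and the
consensus is the majority presence allele; an exact 0.5 tie is reported as
missing rather than an error.

``simulate_probe_errors`` reproduces the binomial error design: for every
(line, InDel) cell the number of erroneous probes is a binomial draw with k
trials and per-probe error probability e; the consensus error rate is the
fraction of all cells whose majority allele differs from truth (ties counted
as missing, not as errors), which matches the exact binomial-tail value
P[X > k/2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

PRESENT, ABSENT, HEMI, MISSING = "present", "absent", "hemizygous", "missing"

_CALL_TO_PRESENCE = {
    "AA": PRESENT, "BB": PRESENT, "AB": PRESENT,
    "OO": ABSENT,
    "OA": HEMI, "OB": HEMI,
    "NoCall": MISSING,
}

_PRESENCE_WEIGHT = {PRESENT: 1.0, HEMI: 0.5, ABSENT: 0.0}


def to_presence(call: str) -> str:
    """Map an array call to the presence alphabet."""
    try:
        return _CALL_TO_PRESENCE[call]
    except KeyError:
        raise ValueError(f"unknown call {call!r}") from None


def presence_frequency(calls: Sequence[str]) -> Optional[float]:
    """Average allelic frequency of presence over non-missing probe calls.

    Accepts presence-alphabet or raw array calls.  Returns None when every
    probe is missing.
    """
    if not len(calls):
        raise ValueError("need at least one probe call")
    vals = []
    for c in calls:
        state = c if c in _PRESENCE_WEIGHT or c == MISSING else to_presence(c)
        if state != MISSING:
            vals.append(_PRESENCE_WEIGHT[state])
    if not vals:
        return None
    return float(np.mean(vals))


def consensus_genotype(freq: Optional[float]) -> str:
    """Majority presence allele; exact ties and undefined frequencies are
    missing."""
    if freq is None:
        return MISSING
    if freq > 0.5:
        return PRESENT
    if freq < 0.5:
        return ABSENT
    return MISSING


def freq_diff01(freqs: Iterable[Optional[float]]) -> float:
    """Fraction of samples whose defined presence frequency is neither 0 nor 1."""
    defined = [f for f in freqs if f is not None]
    if not defined:
        return 0.0
    return float(np.mean([0.0 < f < 1.0 for f in defined]))


def consensus_table(call_df: pd.DataFrame, probe_to_indel: Dict[str, str]) -> pd.DataFrame:
    """Per (indel, sample) presence frequency and consensus call.

    ``call_df`` is a probe x sample frame of array or presence calls.
    """
    rows = []
    indels: Dict[str, List[str]] = {}
    for probe in call_df.index:
        indels.setdefault(probe_to_indel[probe], []).append(probe)
    for indel_id, probes in sorted(indels.items()):
        sub = call_df.loc[probes]
        for sample in call_df.columns:
            freq = presence_frequency(sub[sample].tolist())
            rows.append(
                {
                    "indel_id": indel_id,
                    "sample_id": sample,
                    "presence_freq": np.nan if freq is None else freq,
                    "consensus": consensus_genotype(freq),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binomial error simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    n_lines: int = 362
    n_indels: int = 10000
    probes_per_indel: Sequence[int] = tuple(range(2, 51))
    error_rates: Sequence[float] = (0.01, 0.03, 0.05, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= e <= 1 for e in self.error_rates):
            raise ValueError("error rates must be in [0, 1]")


def exact_consensus_error(k: int, e: float) -> float:
    """P[majority of k probes wrong] = P[Binomial(k, e) > k/2] (ties excluded)."""
    return float(sum(math.comb(k, j) * e**j * (1 - e) ** (k - j)
                     for j in range(k // 2 + 1, k + 1)))


def exact_missing_rate(k: int, e: float) -> float:
    """P[exact tie] (0 for odd k)."""
    if k % 2:
        return 0.0
    j = k // 2
    return float(math.comb(k, j) * e**j * (1 - e) ** (k - j))


def exact_freq_diff01(k: int, e: float) -> float:
    """P[at least one but not all probes wrong] = 1 - (1-e)^k - e^k."""
    return float(1.0 - (1 - e) ** k - e**k)


def simulate_probe_errors(spec: SimulationSpec) -> pd.DataFrame:
    """Simulate consensus genotyping under independent per-probe errors.

    For each (k, e) combination, ``n_lines * n_indels`` cells each draw the
    number of erroneous probes from Binomial(k, e).  Returns one row per
    (k, e) with the simulated consensus error rate (fraction of all cells
    where the majority allele is wrong; ties are missing, not errors), the
    missing (tie) rate, the FreqDiff01 fraction, and the matching exact
    values.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lines * spec.n_indels
    rows = []
    for e in spec.error_rates:
        for k in spec.probes_per_indel:
            wrong = rng.binomial(k, e, size=n)
            n_err = int(np.count_nonzero(wrong * 2 > k))
            n_tie = int(np.count_nonzero(wrong * 2 == k)) if k % 2 == 0 else 0
            n_diff01 = int(np.count_nonzero((wrong > 0) & (wrong < k)))
            rows.append(
                {
                    "k": k,
                    "e": e,
                    "n": n,
                    "consensus_error_rate": n_err / n,
                    "missing_rate": n_tie / n,
                    "freq_diff01": n_diff01 / n,
                    "exact_error": exact_consensus_error(k, e),
                    "exact_missing": exact_missing_rate(k, e),
                    "exact_freq_diff01": exact_freq_diff01(k, e),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# concordance and validation
# ---------------------------------------------------------------------------

def concordance(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    strata: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Fraction of matching calls among cells non-missing in both matrices.

    ``calls_a`` and ``calls_b`` are matched probe x sample frames over the
    presence alphabet.  ``strata`` optionally maps probe -> stratum label
    (e.g. probe type); one row per stratum plus an "all" row is returned.
    """
    if not calls_a.index.equals(calls_b.index) or not calls_a.columns.equals(calls_b.columns):
        raise ValueError("call matrices must share probe and sample grids")
    a, b = calls_a.to_numpy(dtype=object), calls_b.to_numpy(dtype=object)
    comparable = (a != MISSING) & (b != MISSING)
    rows = []

    def _rate(mask: np.ndarray) -> Tuple[int, float]:
        n = int(mask.sum())
        if n == 0:
            return 0, float("nan")
        return n, float((a[mask] == b[mask]).mean())

    n, rate = _rate(comparable)
    rows.append({"stratum": "all", "n_compared": n, "concordance": rate})
    if strata is not None:
        for label in sorted(set(strata)):
            probe_mask = np.array([strata.get(p) == label for p in calls_a.index])
            n, rate = _rate(comparable & probe_mask[:, None])
            rows.append({"stratum": label, "n_compared": n, "concordance": rate})
    return pd.DataFrame(rows)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def probe_present_in_sequence(probe: str, sequence: str, max_mismatch: int) -> bool:
    """True iff a full-length alignment of probe (either strand) with at most
    ``max_mismatch`` mismatches exists in ``sequence``."""
    from .breakpoints import revcomp

    L = len(probe)
    if len(sequence) < L:
        return False
    hay = _encode(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(hay, L)
    for s in (probe, revcomp(probe)):
        needle = _encode(s)
        if (windows != needle).sum(axis=1).min() <= max_mismatch:
            return True
    return False


def gbs_from_probe_alignment(
    probe_seqs: Dict[str, str],
    assemblies: Dict[str, str],
    max_mismatch_frac: float = 0.05,
) -> pd.DataFrame:
    """Genotyping-by-sequencing matrix from probe-vs-assembly alignment.

    A probe is present in a line when it aligns full-length with less than
    ``max_mismatch_frac`` mismatches (<= floor(0.05*35) = 1 mismatch for 35 bp
    probes); otherwise absent.  Returns a probe x line frame over
    {present, absent}.
    """
    data = {}
    for line, seq in assemblies.items():
        col = []
        for pid in probe_seqs:
            probe = probe_seqs[pid]
            max_mm = math.floor(max_mismatch_frac * len(probe))
            col.append(PRESENT if probe_present_in_sequence(probe, seq, max_mm) else ABSENT)
        data[line] = col
    return pd.DataFrame(data, index=list(probe_seqs))


def mendelian_check(
    parent1: pd.Series,
    parent2: pd.Series,
    f1: pd.Series,
) -> pd.DataFrame:
    """Mendelian consistency of F1 calls against parental BP calls.

    Predicted F1: present x present -> present, absent x absent -> absent,
    present x absent -> hemizygous.  Probes with a missing or hemizygous
    parental call are excluded.  Returns per-class (homozygous/hemizygous)
    counts and consistency rates.
    """
    counts = {"homozygous": [0, 0], "hemizygous": [0, 0]}  # [consistent, total]
    for probe in parent1.index:
        p1, p2 = parent1[probe], parent2[probe]
        if p1 in (MISSING, HEMI) or p2 in (MISSING, HEMI):
            continue
        obs = f1.get(probe, MISSING)
        if obs == MISSING:
            continue
        if p1 == p2:
            expected, cls = p1, "homozygous"
        else:
            expected, cls = HEMI, "hemizygous"
        counts[cls][1] += 1
        counts[cls][0] += int(obs == expected)
    rows = []
    for cls, (good, total) in counts.items():
        rows.append(
            {
                "class": cls,
                "n": total,
                "consistency": good / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)
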