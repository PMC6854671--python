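"""Synthetic genomes, fluorescence signals and call panels with ground truth.

Everything here is a pure function of (config, seed): two runs with the same
inputs produce identical output.  The generators exist so that every layer of
the pipeline can be exercised against a known truth at desk scale —
breakpoint classification round-trips, PAR detection against brute force,
caller parameter recovery, and the multi-probe consensus error design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .breakpoints import InDelVariant, revcomp
from .calling import SignalMatrix

BASES = np.array(list("ACGT"))

#: cluster geometry in (contrast, intensity) space:
#: label -> (mean_contrast, mean_intensity, sd_contrast, sd_intensity)
DEFAULT_GEOMETRY: Dict[str, Tuple[float, float, float, float]] = {
    "AA": (-1.5, 10.0, 0.2, 0.3),
    "BB": (1.5, 10.0, 0.2, 0.3),
    "AB": (0.0, 10.0, 0.2, 0.3),
    "OO": (0.0, 7.0, 0.5, 0.4),
    "OA": (-0.75, 8.5, 0.3, 0.35),
    "OB": (0.75, 8.5, 0.3, 0.35),
    # MONO probes: presence cluster sits at zero contrast, high intensity
    "MONO_PRESENT": (0.0, 10.0, 0.2, 0.3),
}


@dataclass
class SyntheticConfig:
    genome_length: int = 50_000
    n_indels: int = 10
    indel_size_range: Tuple[int, int] = (100, 2_000)
    breakpoint_type_mix: Dict[str, float] = field(
        default_factory=lambda: {"I": 0.4, "II": 0.3, "III": 0.2, "IV": 0.1}
    )
    microhomology_len_range: Tuple[int, int] = (1, 5)
    insert_len_range: Tuple[int, int] = (3, 20)
    repeat_fraction: float = 0.0
    repeat_unit_len: int = 120
    flank_len: int = 50
    n_samples: int = 50
    allele_freq_range: Tuple[float, float] = (0.1, 0.9)
    geometry: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GEOMETRY)
    )
    probe_error_rate: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("repeat_fraction", "probe_error_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class PlantedInDel:
    variant: InDelVariant
    true_type: str
    true_m: int
    true_i: int
    #: repeat intervals inside the InDel sequence, InDel-local coordinates
    internal_repeats: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class GenomeTruth:
    reference: Dict[str, str]
    alternative: Dict[str, str]
    indels: List[PlantedInDel]
    #: repeats on the reference, (chrom, start, end)
    repeats: List[Tuple[str, int, int]]


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _pick_type(rng: np.random.Generator, mix: Dict[str, float]) -> str:
    types = sorted(mix)
    probs = np.array([mix[t] for t in types], dtype=float)
    return str(rng.choice(types, p=probs / probs.sum()))


def _different_base(rng: np.random.Generator, avoid: str) -> str:
    choices = [b for b in "ACGT" if b != avoid.upper()]
    return str(rng.choice(choices))


def generate_genomes(cfg: SyntheticConfig, chrom: str = "chr1") -> GenomeTruth:
    """Build a reference and an alternative genome differing by planted InDels.

    The reference carries each InDel's sequence; the alternative carries the
    absence allele (with any non-homologous inserted fragment in its place).
    Type II/IV events duplicate the chosen microhomology at both extremities:
    the deleted sequence's first m bases equal the first m bases of the right
    flank, so the junction alignment is m-fold ambiguous.  A repeat motif is
    optionally planted into InDel interiors (and elsewhere) and reported.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_indels
    gap = max(cfg.flank_len * 2 + 10, (cfg.genome_length // (n + 1)) if n else cfg.genome_length)

    repeat_motif = random_seq(rng, cfg.repeat_unit_len)
    ref_parts: List[str] = []
    alt_parts: List[str] = []
    repeats: List[Tuple[str, int, int]] = []
    indels: List[PlantedInDel] = []
    pos = 0

    def emit_backbone(length: int) -> str:
        chunk = random_seq(rng, length)
        ref_parts.append(chunk)
        alt_parts.append(chunk)
        return chunk

    chunk = emit_backbone(gap)
    pos += len(chunk)
    for i in range(n):
        btype = _pick_type(rng, cfg.breakpoint_type_mix)
        m = (
            int(rng.integers(cfg.microhomology_len_range[0], cfg.microhomology_len_range[1] + 1))
            if btype in ("II", "IV")
            else 0
        )
        ins_len = (
            int(rng.integers(cfg.insert_len_range[0], cfg.insert_len_range[1] + 1))
            if btype in ("III", "IV")
            else 0
        )
        size = int(rng.integers(cfg.indel_size_range[0], cfg.indel_size_range[1] + 1))

        right_chunk = random_seq(rng, gap)
        # deleted sequence: prefix duplicates the right flank's first m bases
        core = list(random_seq(rng, size - m))
        core[0] = _different_base(rng, right_chunk[m])  # LCP is exactly m
        left_prev = ref_parts[-1]
        core[-1] = _different_base(rng, left_prev[-1])  # no left-side homology
        deleted = right_chunk[:m] + "".join(core)

        inserted = ""
        if ins_len:
            ins = list(random_seq(rng, ins_len))
            # keep the fragment from extending homology or hiding the junction
            ins[0] = _different_base(rng, deleted[0])
            inserted = "".join(ins)
        elif m == 0 and deleted[0] == right_chunk[0]:
            deleted = _different_base(rng, right_chunk[0]) + deleted[1:]

        internal_repeats: List[Tuple[int, int]] = []
        if cfg.repeat_fraction > 0 and rng.random() < cfg.repeat_fraction:
            r_at = int(rng.integers(m + 1, max(m + 2, size - cfg.repeat_unit_len)))
            if r_at + cfg.repeat_unit_len < size:
                deleted = deleted[:r_at] + repeat_motif + deleted[r_at + cfg.repeat_unit_len :]
                internal_repeats.append((r_at, r_at + cfg.repeat_unit_len))
                repeats.append((chrom, pos + r_at, pos + r_at + cfg.repeat_unit_len))

        start, end = pos, pos + len(deleted)
        variant = InDelVariant(
            id=f"indel_{i:04d}",
            kind="deletion_vs_ref",
            chrom=chrom,
            start=start,
            end=end,
            deleted_seq=deleted,
            inserted_fragment=inserted,
            left_flank=left_prev[-cfg.flank_len :],
            right_flank=right_chunk[: cfg.flank_len],
            source_line="alt",
        )
        indels.append(PlantedInDel(variant, btype, m, ins_len, internal_repeats))
        ref_parts.append(deleted)
        alt_parts.append(inserted)
        pos = end
        ref_parts.append(right_chunk)
        alt_parts.append(right_chunk)
        pos += len(right_chunk)

    return GenomeTruth(
        reference={chrom: "".join(ref_parts)},
        alternative={chrom: "".join(alt_parts)},
        indels=indels,
        repeats=repeats,
    )


def generate_genotypes(
    indel_ids: Sequence[str],
    n_samples: int,
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-InDel x per-sample presence truth (bool), Bernoulli at a per-InDel
    presence frequency drawn uniformly from ``allele_freq_range``."""
    rng = rng or np.random.default_rng(cfg.seed)
    lo, hi = cfg.allele_freq_range
    freqs = rng.uniform(lo, hi, size=len(indel_ids))
    data = rng.random((len(indel_ids), n_samples)) < freqs[:, None]
    samples = [f"line_{j:04d}" for j in range(n_samples)]
    return pd.DataFrame(data, index=list(indel_ids), columns=samples)


def true_cluster_labels(
    presence: pd.DataFrame,
    probe_types: Dict[str, str],
    probe_to_indel: Dict[str, str],
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Expand presence truth into per-probe true cluster labels.

    For BP/OTV probes each sample carries a fixed presence allele (A or B) so
    presence splits into AA/BB clusters; MONO probes have a single presence
    cluster.  Absence is always OO.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    allele_b = pd.DataFrame(
        rng.random((len(presence), presence.shape[1])) < 0.5,
        index=presence.index,
        columns=presence.columns,
    )
    rows = {}
    for probe, ptype in probe_types.items():
        indel = probe_to_indel[probe]
        pres = presence.loc[indel]
        if ptype == "MONO":
            rows[probe] = np.where(pres, "MONO_PRESENT", "OO")
        else:
            b = allele_b.loc[indel]
            rows[probe] = np.where(pres, np.where(b, "BB", "AA"), "OO")
    return pd.DataFrame.from_dict(rows, orient="index", columns=presence.columns)


def generate_signals(
    labels: pd.DataFrame,
    cfg: SyntheticConfig,
    separation_scale: float = 1.0,
) -> Tuple[SignalMatrix, pd.DataFrame]:
    """Draw (contrast, intensity) per probe x sample from true clusters.

    ``labels`` holds true cluster labels (geometry keys).  With probability
    ``probe_error_rate`` a cell's presence state is swapped before drawing
    (present-type label -> OO, OO -> the probe's presence label); with
    probability ``dropout_rate`` the cell is missing (NaN).  Dividing the
    SDs by ``separation_scale`` tightens clusters.  Returns the signal
    matrix and the post-error truth labels.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    probes, samples = list(labels.index), list(labels.columns)
    lab = labels.to_numpy(dtype=object).copy()

    if cfg.probe_error_rate > 0:
        flip = rng.random(lab.shape) < cfg.probe_error_rate
        for i in range(lab.shape[0]):
            present_labels = [l for l in set(lab[i]) if l != "OO"]
            swap_to = present_labels[0] if present_labels else "MONO_PRESENT"
            for j in np.flatnonzero(flip[i]):
                lab[i, j] = "OO" if lab[i, j] != "OO" else swap_to

    contrast = np.empty(lab.shape)
    intensity = np.empty(lab.shape)
    for label, (mc, my, sc, sy) in cfg.geometry.items():
        mask = lab == label
        k = int(mask.sum())
        if not k:
            continue
        contrast[mask] = rng.normal(mc, sc / separation_scale, size=k)
        intensity[mask] = rng.normal(my, sy / separation_scale, size=k)

    if cfg.dropout_rate > 0:
        drop = rng.random(lab.shape) < cfg.dropout_rate
        contrast[drop] = np.nan
        intensity[drop] = np.nan

    sm = SignalMatrix(probes=probes, samples=samples, contrast=contrast, intensity=intensity)
    truth = pd.DataFrame(lab, index=probes, columns=samples)
    return sm, truth


@dataclass
class MultiProbePanel:
    """Presence-call panel with independent per-probe errors.

    ``truth``: (n_indels, n_lines) bool presence truth.
    ``calls``: (n_indels, k, n_lines) bool observed presence per probe.
    """

    truth: np.ndarray
    calls: np.ndarray
    indel_ids: List[str]
    sample_ids: List[str]

    def call_frame(self) -> pd.DataFrame:
        """Probe x sample frame over the presence alphabet (small panels)."""
        n_indels, k, _ = self.calls.shape
        rows = {}
        for i, indel in enumerate(self.indel_ids):
            for p in range(k):
                rows[f"{indel}_p{p}"] = np.where(self.calls[i, p], "present", "absent")
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.sample_ids)

    def probe_to_indel(self) -> Dict[str, str]:
        k = self.calls.shape[1]
        return {f"{indel}_p{p}": indel for indel in self.indel_ids for p in range(k)}


def generate_multiprobe_panel(
    n_lines: int, n_indels: int, k_probes: int, e: float, seed: int = 0
) -> MultiProbePanel:
    """Direct presence-call panel for consensus tests (no clustering layer)."""
    rng = np.random.default_rng(seed)
    truth = rng.random((n_indels, n_lines)) < rng.uniform(0.1, 0.9, size=(n_indels, 1))
    errors = rng.random((n_indels, k_probes, n_lines)) < e
    calls = truth[:, None, :] ^ errors
    return MultiProbePanel(
        truth=truth,
        calls=calls,
        indel_ids=[f"indel_{i:05d}" for i in range(n_indels)],
        sample_ids=[f"line_{j:04d}" for j in range(n_lines)],
    )


def panel_consensus_stats(panel: MultiProbePanel) -> Dict[str, float]:
    """Vectorised consensus error/missing/FreqDiff01 over a panel.

    The consensus is the majority presence allele over the k probes; exact
    ties are missing.  The error rate is the fraction of all (indel, line)
    cells whose consensus differs from truth (ties are not errors).
    """
    k = panel.calls.shape[1]
    n_present = panel.calls.sum(axis=1)  # (n_indels, n_lines)
    n_wrong = np.where(panel.truth, k - n_present, n_present)
    n_cells = n_wrong.size
    return {
        "consensus_error_rate": float(np.count_nonzero(n_wrong * 2 > k) / n_cells),
        "missing_rate": float(np.count_nonzero(n_wrong * 2 == k) / n_cells) if k % 2 == 0 else 0.0,
        "freq_diff01": float(np.count_nonzero((n_wrong > 0) & (n_wrong < k)) / n_cells),
    }
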