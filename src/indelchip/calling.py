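"""Genotype calling from two-channel fluorescence summaries.

Each probe is summarised per sample by a contrast value (x axis, allele
contrast of channel A vs B) and an intensity value (y axis, mean log2
signal).  Presence alleles cluster at high intensity with contrast of either
sign; the off-target (absence) cluster sits at low intensity near zero
contrast; hemizygous samples fall in between.

Three callers are provided:

* :func:`call_bp`   — BP junction probes; codominant SNP-like behaviour with
  an off-target relabel pass and hemizygous (OA/OB) clusters.
* :func:`call_otv`  — internal probes on known SNPs; a putative AB cluster at
  markedly lower intensity than the homozygous clusters is relabelled OO.
* :func:`call_mono_hom2otv` — internal probes on monomorphic sites; two
  homozygous-looking clusters separated primarily in intensity are resolved
  as presence (upper) vs absence (lower).  Never emits AB.

The vendor's inbred penalty is implemented as a prior down-weighting of the
heterozygous component: its mixture weight is multiplied by
``2**(-penalty/4)`` before posteriors are computed (penalty 0 leaves the
heterozygous prior untouched, 16 all but removes it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

CALL_ALPHABET = ("AA", "AB", "BB", "OA", "OB", "OO", "NoCall")

PROBESET_CATEGORIES = (
    "PolyHighResolution",
    "MonoHighResolution",
    "NoMinorHom",
    "OTV",
    "CallRateBelowThreshold",
    "UnexpectedHeterozygosity",
    "Hom2OTV",
    "Other",
)


@dataclass
class CallingConfig:
    inbred_penalty: int = 4
    mono_inbred_penalty: int = 16
    sample_callrate_min: float = 0.9
    probeset_callrate_min: float = 0.97
    het_so_cut: float = -0.3
    het_v_maf_cut: float = 1.9
    ab_vary_z_cut: float = 2.6
    hom2otv_gap_sd: float = 3.0
    confidence: float = 0.85
    max_het_freq: float = 0.15
    mono_intensity_prior: float = 8.5  # Present/absent split for single clusters
    min_samples: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.inbred_penalty <= 16:
            raise ValueError("inbred_penalty must be in [0, 16]")
        if not 0.5 < self.confidence < 1:
            raise ValueError("confidence must be in (0.5, 1)")


@dataclass
class SignalMatrix:
    """Per-probe x per-sample (contrast, intensity) values; NaN = missing."""

    probes: List[str]
    samples: List[str]
    contrast: np.ndarray  # (n_probes, n_samples)
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.contrast = np.asarray(self.contrast, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        expected = (len(self.probes), len(self.samples))
        if self.contrast.shape != expected or self.intensity.shape != expected:
            raise ValueError("signal matrix shapes disagree with probe/sample lists")

    def row(self, probe_id: str) -> Tuple[np.ndarray, np.ndarray]:
        i = self.probes.index(probe_id)
        return self.contrast[i], self.intensity[i]


@dataclass
class Component:
    mean: np.ndarray       # (contrast, intensity)
    cov: np.ndarray        # 2x2
    weight: float
    label: str = ""


@dataclass
class ClusterModel:
    components: List[Component]
    confidence: float = 0.85
    too_few_samples: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def sd_contrast(self) -> float:
        return float(np.sqrt(np.mean([c.cov[0, 0] for c in self.components])))

    def sd_intensity(self) -> float:
        return float(np.sqrt(np.mean([c.cov[1, 1] for c in self.components])))


def fit_clusters(
    contrast: np.ndarray,
    intensity: np.ndarray,
    max_components: int = 4,
    cfg: Optional[CallingConfig] = None,
    seed: int = 0,
) -> ClusterModel:
    """Fit a bivariate Gaussian mixture with BIC model selection.

    Fewer than ``cfg.min_samples`` non-missing samples flags the model so the
    probe can be routed to CallRateBelowThreshold.  Deterministic for a given
    seed.
    """
    cfg = cfg or CallingConfig()
    contrast = np.asarray(contrast, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    ok = np.isfinite(contrast) & np.isfinite(intensity)
    X = np.column_stack([contrast[ok], intensity[ok]])
    if X.shape[0] < cfg.min_samples:
        return ClusterModel(components=[], confidence=cfg.confidence, too_few_samples=True)

    n_distinct = len(np.unique(X.round(9), axis=0))
    best = None
    best_bic = np.inf
    for n in range(1, min(max_components, n_distinct) + 1):
        gm = GaussianMixture(
            n_components=n,
            covariance_type="full",
            reg_covar=1e-4,
            n_init=3,
            random_state=seed,
        )
        gm.fit(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = gm
    comps = [
        Component(mean=best.means_[i].copy(), cov=best.covariances_[i].copy(),
                  weight=float(best.weights_[i]))
        for i in range(best.n_components)
    ]
    return ClusterModel(components=comps, confidence=cfg.confidence)


def _intensity_levels(model: ClusterModel) -> List[List[int]]:
    """Group component indices into intensity levels, top level first.

    Adjacent (intensity-sorted) components are merged into one level when
    their gap is below 3 pooled within-cluster intensity SDs.
    """
    sd_y = max(model.sd_intensity(), 1e-6)
    order = sorted(range(len(model.components)),
                   key=lambda i: -model.components[i].mean[1])
    levels: List[List[int]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        gap = model.components[prev].mean[1] - model.components[cur].mean[1]
        if gap > 3.0 * sd_y:
            levels.append([cur])
        else:
            levels[-1].append(cur)
    return levels


def _label_top_level(model: ClusterModel, idxs: List[int]) -> None:
    """Assign AA/AB/BB within the high-intensity (presence) level by contrast."""
    comps = model.components
    idxs = sorted(idxs, key=lambda i: comps[i].mean[0])
    if len(idxs) == 1:
        i = idxs[0]
        comps[i].label = "AA" if comps[i].mean[0] <= 0 else "BB"
    elif len(idxs) == 2:
        lo, hi = idxs
        cmax = max(abs(comps[lo].mean[0]), abs(comps[hi].mean[0]))
        for i in (lo, hi):
            if abs(comps[i].mean[0]) < 0.33 * cmax:
                comps[i].label = "AB"
            else:
                comps[i].label = "AA" if comps[i].mean[0] < 0 else "BB"
        if comps[lo].label == comps[hi].label:  # degenerate: force a split
            comps[lo].label, comps[hi].label = "AA", "BB"
    else:
        comps[idxs[0]].label = "AA"
        comps[idxs[-1]].label = "BB"
        for i in idxs[1:-1]:
            comps[i].label = "AB"


def label_components_bp(model: ClusterModel, cfg: CallingConfig,
                        hemizygous: bool = True) -> ClusterModel:
    """Label mixture components for the BP (or, with hemizygous=False, OTV)
    caller.

    The top intensity level is labelled AA/AB/BB by contrast.  An AB-labelled
    component whose intensity offset from the homozygous mean falls below
    ``het_so_cut`` is relabelled OO (off-target relabel pass).  Lower
    intensity levels become OO near zero contrast; intermediate levels with
    clearly signed contrast become OA/OB when hemizygous calling is enabled.
    """
    comps = model.components
    if not comps:
        return model
    levels = _intensity_levels(model)
    _label_top_level(model, levels[0])
    if len(levels) == 1 and len(levels[0]) == 1:
        # single cluster: near-zero contrast at low absolute intensity is the
        # off-target (all-absent) pattern, not a presence homozygote
        c = comps[levels[0][0]]
        if abs(c.mean[0]) < 0.5 and c.mean[1] < cfg.mono_intensity_prior:
            c.label = "OO"

    top_c = [abs(comps[i].mean[0]) for i in levels[0] if comps[i].label in ("AA", "BB")]
    cref = max(top_c) if top_c else 0.0
    for depth, level in enumerate(levels[1:], start=1):
        bottom = depth == len(levels) - 1
        for i in level:
            c = comps[i].mean[0]
            if hemizygous and not bottom and abs(c) >= 0.3 * cref and cref > 0:
                comps[i].label = "OA" if c < 0 else "OB"
            elif hemizygous and bottom and abs(c) >= 0.3 * cref and cref > 0 and len(levels) == 2:
                comps[i].label = "OA" if c < 0 else "OB"
            else:
                comps[i].label = "OO"

    # off-target relabel pass: AB cluster sitting well below the homozygotes
    homs = [c for c in comps if c.label in ("AA", "BB")]
    if homs:
        y_hom = float(np.mean([c.mean[1] for c in homs]))
        for c in comps:
            if c.label == "AB" and (c.mean[1] - y_hom) < cfg.het_so_cut:
                c.label = "OO"
                model.meta["otv_relabelled"] = True
    return model


def _posteriors(model: ClusterModel, X: np.ndarray, penalty: int) -> np.ndarray:
    """Posterior responsibilities with the heterozygous prior down-weighted."""
    w = model.weights.astype(float).copy()
    for i, c in enumerate(model.components):
        if c.label == "AB":
            w[i] *= 2.0 ** (-penalty / 4.0)
    w /= w.sum()
    logp = np.empty((X.shape[0], len(model.components)))
    for i, c in enumerate(model.components):
        logp[:, i] = multivariate_normal.logpdf(X, mean=c.mean, cov=c.cov,
                                                allow_singular=True) + np.log(w[i])
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _assign(model: ClusterModel, contrast: np.ndarray, intensity: np.ndarray,
            penalty: int) -> np.ndarray:
    contrast = np.asarray(contrast, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    calls = np.full(contrast.shape, "NoCall", dtype=object)
    ok = np.isfinite(contrast) & np.isfinite(intensity)
    if not ok.any() or not model.components:
        return calls
    X = np.column_stack([contrast[ok], intensity[ok]])
    post = _posteriors(model, X, penalty)
    best = post.argmax(axis=1)
    conf = post[np.arange(len(best)), best]
    labels = np.array([c.label for c in model.components], dtype=object)
    assigned = labels[best]
    assigned[conf < model.confidence] = "NoCall"
    calls[ok] = assigned
    return calls


def call_bp(model: ClusterModel, contrast: np.ndarray, intensity: np.ndarray,
            cfg: Optional[CallingConfig] = None) -> np.ndarray:
    """Call BP probes over {AA, AB, BB, OA, OB, OO, NoCall}."""
    cfg = cfg or CallingConfig()
    if model.too_few_samples:
        return np.full(np.shape(contrast), "NoCall", dtype=object)
    label_components_bp(model, cfg, hemizygous=True)
    return _assign(model, contrast, intensity, cfg.inbred_penalty)


def call_otv(model: ClusterModel, contrast: np.ndarray, intensity: np.ndarray,
             cfg: Optional[CallingConfig] = None) -> np.ndarray:
    """Call OTV probes over {AA, AB, BB, OO, NoCall}."""
    cfg = cfg or CallingConfig()
    if model.too_few_samples:
        return np.full(np.shape(contrast), "NoCall", dtype=object)
    label_components_bp(model, cfg, hemizygous=False)
    if any(c.label == "OO" for c in model.components):
        model.meta["otv_relabelled"] = True
    return _assign(model, contrast, intensity, cfg.inbred_penalty)


def call_mono_hom2otv(model: ClusterModel, contrast: np.ndarray,
                      intensity: np.ndarray,
                      cfg: Optional[CallingConfig] = None) -> Tuple[np.ndarray, str]:
    """Call MONO probes; returns (calls, category_hint).  Never emits AB.

    Two homozygous-looking clusters whose separation is at least
    ``hom2otv_gap_sd`` pooled intensity SDs and primarily along the intensity
    axis are resolved as presence (upper, AA) vs absence (lower, OO) with
    hint "Hom2OTV".  Clusters separated mainly in contrast are SNP-like and
    labelled by contrast sign with hint "OTV".  A single cluster is
    monomorphic: all Present or all OO by its intensity against
    ``mono_intensity_prior`` (hint "MonoHighResolution").
    """
    cfg = cfg or CallingConfig()
    if model.too_few_samples:
        return np.full(np.shape(contrast), "NoCall", dtype=object), "CallRateBelowThreshold"
    comps = model.components
    if len(comps) == 1:
        comps[0].label = "AA" if comps[0].mean[1] >= cfg.mono_intensity_prior else "OO"
        hint = "MonoHighResolution"
    elif len(comps) == 2:
        a, b = comps
        dy = abs(a.mean[1] - b.mean[1])
        dc = abs(a.mean[0] - b.mean[0])
        sd_y = max(model.sd_intensity(), 1e-6)
        if dy >= cfg.hom2otv_gap_sd * sd_y and dy > dc:
            lo, hi = (a, b) if a.mean[1] < b.mean[1] else (b, a)
            lo.label, hi.label = "OO", "AA"
            hint = "Hom2OTV"
        elif dc > dy:
            lo, hi = (a, b) if a.mean[0] < b.mean[0] else (b, a)
            lo.label, hi.label = "AA", "BB"
            hint = "OTV"
        else:
            for c in comps:
                c.label = "AA" if c.mean[1] >= cfg.mono_intensity_prior else "OO"
            hint = "MonoHighResolution"
    else:
        label_components_bp(model, cfg, hemizygous=False)
        for c in comps:  # MONO caller never emits AB
            if c.label == "AB":
                c.label = "OO"
        hint = "OTV"
    calls = _assign(model, contrast, intensity, cfg.mono_inbred_penalty)
    return calls, hint


def sample_qc(calls: np.ndarray, samples: Sequence[str],
              cfg: Optional[CallingConfig] = None) -> Dict[str, bool]:
    """Per-sample call-rate QC over a (n_probes, n_samples) call matrix.

    Samples with call rate below ``sample_callrate_min`` fail.  Raises if no
    sample passes.
    """
    cfg = cfg or CallingConfig()
    calls = np.asarray(calls, dtype=object)
    rates = (calls != "NoCall").mean(axis=0)
    result = {s: bool(r >= cfg.sample_callrate_min) for s, r in zip(samples, rates)}
    if not any(result.values()):
        raise ValueError("no samples pass QC")
    return result


@dataclass
class ProbesetReport:
    probe_id: str
    category: str
    call_rate: float = float("nan")
    het_freq: float = float("nan")
    n_clusters: int = 0

    def __post_init__(self) -> None:
        if self.category not in PROBESET_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_probeset(probe_id: str, calls: np.ndarray,
                      cfg: Optional[CallingConfig] = None,
                      category_hint: str = "",
                      otv_relabelled: bool = False) -> ProbesetReport:
    """Assign one quality category to a probeset from its calls.

    Precedence: CallRateBelowThreshold, then UnexpectedHeterozygosity, then
    the caller hint (Hom2OTV), then the cluster-pattern categories:
    PolyHighResolution (two or more homozygous classes, i.e. a minor
    homozygote exists), OTV (an AB cluster was relabelled off-target),
    NoMinorHom (one homozygous class plus heterozygotes),
    MonoHighResolution (a single called class), Other.
    """
    cfg = cfg or CallingConfig()
    calls = np.asarray(calls, dtype=object)
    called = calls[calls != "NoCall"]
    call_rate = len(called) / len(calls) if len(calls) else 0.0
    het_freq = float((called == "AB").mean()) if len(called) else 0.0
    classes = set(called.tolist())
    homs = classes & {"AA", "BB", "OO"}

    if call_rate < cfg.probeset_callrate_min:
        cat = "CallRateBelowThreshold"
    elif het_freq > cfg.max_het_freq:
        cat = "UnexpectedHeterozygosity"
    elif category_hint == "Hom2OTV":
        cat = "Hom2OTV"
    elif otv_relabelled:
        cat = "OTV"
    elif len(homs) >= 2:
        cat = "PolyHighResolution"
    elif len(homs) == 1 and "AB" in classes:
        cat = "NoMinorHom"
    elif len(classes) == 1:
        cat = "MonoHighResolution"
    elif category_hint == "MonoHighResolution" and len(homs) == 1:
        cat = "MonoHighResolution"
    else:
        cat = "Other"
    return ProbesetReport(probe_id, cat, call_rate, het_freq, len(classes))
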