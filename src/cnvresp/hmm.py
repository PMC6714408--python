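"""Hidden Markov model copy-number caller for SNP-array fluorescence summaries.

Decodes an integer copy-number state path (CN 0–4, diploid CN=2) from ordered
per-probe Log R Ratio (LRR) and B-allele frequency (BAF) values, in the style
of array-based CNV callers: Gaussian LRR emissions per state, a
population-B-allele-frequency-weighted BAF cluster mixture, and
inter-probe-distance-dependent transitions. Maximal non-diploid runs of the
decoded path become CNV calls, subject to a minimum probe-support filter and a
per-sample call-count quality screen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

#: Copy-number states decoded by the model.
STATES: tuple[int, ...] = (0, 1, 2, 3, 4)

#: BAF cluster means per copy-number state: with k copies a locus carrying
#: j B alleles clusters at j/k. CN=0 has no allelic signal (uniform BAF).
BAF_CLUSTER_MEANS: dict[int, tuple[float, ...] | None] = {
    0: None,
    1: (0.0, 1.0),
    2: (0.0, 0.5, 1.0),
    3: (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0),
    4: (0.0, 0.25, 0.5, 0.75, 1.0),
}


@dataclass(frozen=True)
class ProbeInfo:
    """A SNP-array probe: name, genomic location and population B-allele frequency."""

    name: str
    chromosome: str
    position: int  # 1-based
    pfb: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pfb <= 1.0:
            raise ValueError(
                f"pfb must lie in [0, 1]; got {self.pfb} for probe {self.name}"
            )
        if self.position < 1:
            raise ValueError(
                f"probe positions are 1-based; got {self.position} for {self.name}"
            )


@dataclass(frozen=True)
class ProbeSignal:
    """Observed fluorescence summaries at one probe (BAF clipped to [0, 1])."""

    probe: ProbeInfo
    lrr: float
    baf: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "baf", float(min(1.0, max(0.0, self.baf))))
        object.__setattr__(self, "lrr", float(self.lrr))


@dataclass(frozen=True)
class HmmModel:
    """Emission and transition parameters of the copy-number HMM.

    LRR state means default to the widely used array-CNV values
    (−3.5, −0.66, 0, 0.40, 0.68); BAF clusters are truncated normals of
    common width ``baf_sd`` at the state's cluster means, weighted by the
    binomial genotype probabilities implied by the probe's population
    B-allele frequency. The off-diagonal transition mass grows with
    inter-probe distance d as ``base_transition_prob * (1 - exp(-d / D))``.
    """

    lrr_means: tuple[float, ...] = (-3.5, -0.66, 0.0, 0.40, 0.68)
    lrr_sds: tuple[float, ...] = (1.30, 0.28, 0.18, 0.21, 0.24)
    baf_sd: float = 0.04
    base_transition_prob: float = 0.01
    distance_scale_d: float = 100_000.0
    start_prob_cn2: float = 0.99
    min_sd: float = 1e-3

    def __post_init__(self) -> None:
        if len(self.lrr_means) != 5 or len(self.lrr_sds) != 5:
            raise ValueError("lrr_means and lrr_sds must each have 5 entries (CN 0..4)")
        if any(b <= a for a, b in zip(self.lrr_means[1:], self.lrr_means[2:])):
            raise ValueError("lrr_means must be strictly increasing for CN >= 1")
        if not 0.0 < self.base_transition_prob < 1.0:
            raise ValueError("base_transition_prob must lie in (0, 1)")
        if self.distance_scale_d <= 0:
            raise ValueError("distance_scale_d must be positive")
        if not 0.0 < self.start_prob_cn2 <= 1.0:
            raise ValueError("start_prob_cn2 must lie in (0, 1]")

    def start_log_probs(self) -> np.ndarray:
        rest = (1.0 - self.start_prob_cn2) / 4.0
        p = np.full(5, rest)
        p[2] = self.start_prob_cn2
        return np.log(p)


@dataclass(frozen=True)
class CnvCall:
    """One sample's called copy-number variant (1-based inclusive coordinates)."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    copy_number: int
    num_snps: int
    start_probe: str = ""
    end_probe: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"call start must be <= end; got {self.start} > {self.end} "
                f"for sample {self.sample_id}"
            )
        if self.copy_number == 2 or self.copy_number not in STATES:
            raise ValueError(
                f"copy_number must be in {{0,1,3,4}}; got {self.copy_number}"
            )
        if self.num_snps < 4:
            raise ValueError(
                f"calls require support from more than three probes; got "
                f"num_snps={self.num_snps}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _truncnorm01_pdf(x: float | np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Density of a normal truncated to [0, 1] (boundary clusters ~double)."""
    z = norm.cdf(1.0, loc=mean, scale=sd) - norm.cdf(0.0, loc=mean, scale=sd)
    return norm.pdf(x, loc=mean, scale=sd) / z


def _baf_mixture_density(
    baf: float | np.ndarray, pfb: float | np.ndarray, state: int, model: HmmModel
) -> np.ndarray:
    means = BAF_CLUSTER_MEANS[state]
    if means is None:  # CN=0: no allelic signal, BAF uniform on [0, 1]
        return np.ones_like(np.asarray(baf, dtype=float))
    sd = max(model.baf_sd, model.min_sd)
    k = state
    dens = np.zeros_like(np.asarray(baf, dtype=float))
    for j, m in enumerate(means):
        w = comb(k, j) * np.asarray(pfb) ** j * (1.0 - np.asarray(pfb)) ** (k - j)
        dens = dens + w * _truncnorm01_pdf(baf, m, sd)
    return dens


def emission_loglik(signal: ProbeSignal, state: int, model: HmmModel | None = None) -> float:
    """Log density of one probe's (LRR, BAF) under a copy-number state.

    The LRR term is Normal(lrr_mean[state], lrr_sd[state]); the BAF term is
    the pfb-weighted truncated-normal cluster mixture for the state. Always
    finite: standard deviations are floored at ``model.min_sd`` and the
    mixture density at a tiny positive constant.
    """
    model = model or HmmModel()
    if state not in STATES:
        raise ValueError(f"unknown copy-number state {state}")
    sd = max(model.lrr_sds[state], model.min_sd)
    ll_lrr = norm.logpdf(signal.lrr, loc=model.lrr_means[state], scale=sd)
    dens = _baf_mixture_density(signal.baf, signal.probe.pfb, state, model)
    return float(ll_lrr + np.log(np.maximum(dens, 1e-300)))


def emission_matrix(signals: Sequence[ProbeSignal], model: HmmModel) -> np.ndarray:
    """(n_probes, 5) matrix of per-state emission log-likelihoods."""
    lrr = np.array([s.lrr for s in signals])
    baf = np.array([s.baf for s in signals])
    pfb = np.array([s.probe.pfb for s in signals])
    out = np.empty((len(signals), 5))
    for st in STATES:
        sd = max(model.lrr_sds[st], model.min_sd)
        ll = norm.logpdf(lrr, loc=model.lrr_means[st], scale=sd)
        dens = _baf_mixture_density(baf, pfb, st, model)
        out[:, st] = ll + np.log(np.maximum(dens, 1e-300))
    return out


def transition_prob(
    distance: float, from_state: int, to_state: int, model: HmmModel | None = None
) -> float:
    """Inter-probe transition probability at a given genomic distance (bp).

    Off-diagonal mass ``base_transition_prob * (1 - exp(-d/D))`` is split
    equally among the four other states; the diagonal takes the remainder,
    so each row sums to one at every distance.
    """
    model = model or HmmModel()
    if distance < 1:
        raise ValueError(f"inter-probe distance must be >= 1 bp; got {distance}")
    if from_state not in STATES or to_state not in STATES:
        raise ValueError("states must be copy numbers 0..4")
    off = model.base_transition_prob * (1.0 - np.exp(-distance / model.distance_scale_d))
    return float(1.0 - off) if from_state == to_state else float(off / 4.0)


def transition_log_matrix(distance: float, model: HmmModel) -> np.ndarray:
    """(5, 5) log transition matrix (row = from-state) at one distance."""
    off = model.base_transition_prob * (1.0 - np.exp(-distance / model.distance_scale_d))
    off = max(off, 1e-300)
    mat = np.full((5, 5), np.log(off / 4.0))
    np.fill_diagonal(mat, np.log(1.0 - off))
    return mat


def viterbi_decode(
    signals: Sequence[ProbeSignal], model: HmmModel | None = None
) -> np.ndarray:
    """Most probable joint copy-number path for one chromosome's probes.

    Probes must lie on a single chromosome, sorted with strictly increasing
    positions. Decoding is in log space under the start distribution
    (CN=2 with probability ``start_prob_cn2``, remainder uniform).
    """
    model = model or HmmModel()
    sigs = list(signals)
    if not sigs:
        raise ValueError("viterbi_decode requires at least one probe")
    chroms = {s.probe.chromosome for s in sigs}
    if len(chroms) != 1:
        raise ValueError(f"probes must lie on a single chromosome; got {sorted(chroms)}")
    pos = np.array([s.probe.position for s in sigs], dtype=np.int64)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("probes must be sorted with strictly increasing positions")

    emit = emission_matrix(sigs, model)
    n = len(sigs)
    delta = model.start_log_probs() + emit[0]
    back = np.zeros((n, 5), dtype=np.int8)
    for t in range(1, n):
        log_t = transition_log_matrix(float(pos[t] - pos[t - 1]), model)
        cand = delta[:, None] + log_t  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(5)] + emit[t]

    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_log_prob(
    path: Sequence[int], signals: Sequence[ProbeSignal], model: HmmModel | None = None
) -> float:
    """Joint log probability of a given state path and the observations."""
    model = model or HmmModel()
    sigs = list(signals)
    pos = [s.probe.position for s in sigs]
    lp = model.start_log_probs()[path[0]] + emission_loglik(sigs[0], path[0], model)
    for t in range(1, len(sigs)):
        lp += np.log(transition_prob(pos[t] - pos[t - 1], path[t - 1], path[t], model))
        lp += emission_loglik(sigs[t], path[t], model)
    return float(lp)


def calls_from_path(
    path: Sequence[int],
    signals: Sequence[ProbeSignal],
    sample_id: str,
    min_snps: int = 4,
) -> list[CnvCall]:
    """Collapse a decoded state path into CNV calls.

    Maximal runs of constant copy number different from 2 become calls whose
    start/end are the first/last probe positions of the run; runs supported
    by fewer than ``min_snps`` probes are dropped (the default keeps only
    calls supported by more than three probes).
    """
    if len(path) != len(signals):
        raise ValueError("path and signals must have equal length")
    calls: list[CnvCall] = []
    sigs = list(signals)
    for state, group in itertools.groupby(range(len(sigs)), key=lambda i: int(path[i])):
        idx = list(group)
        if state == 2 or len(idx) < min_snps:
            continue
        first, last = sigs[idx[0]], sigs[idx[-1]]
        calls.append(
            CnvCall(
                sample_id=sample_id,
                chromosome=first.probe.chromosome,
                start=first.probe.position,
                end=last.probe.position,
                copy_number=state,
                num_snps=len(idx),
                start_probe=first.probe.name,
                end_probe=last.probe.name,
            )
        )
    return calls


def call_sample(
    sample_id: str,
    signals: Iterable[ProbeSignal],
    model: HmmModel | None = None,
    min_snps: int = 4,
) -> list[CnvCall]:
    """Decode one sample genome-wide: chromosomes are decoded independently."""
    model = model or HmmModel()
    by_chrom: dict[str, list[ProbeSignal]] = {}
    for s in signals:
        by_chrom.setdefault(s.probe.chromosome, []).append(s)
    calls: list[CnvCall] = []
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        sigs = sorted(by_chrom[chrom], key=lambda s: s.probe.position)
        path = viterbi_decode(sigs, model)
        calls.extend(calls_from_path(path, sigs, sample_id, min_snps=min_snps))
    return calls


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (10_000, chrom)


def sample_cnv_qc(
    calls: Iterable[CnvCall], max_calls: int = 100
) -> tuple[list[str], dict[str, int]]:
    """Per-sample call-count screen: samples with more than ``max_calls``
    CNV calls are excluded (exactly ``max_calls`` is kept).

    Returns (kept sample ids, excluded sample -> call count).
    """
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    kept = sorted(sid for sid, n in counts.items() if n <= max_calls)
    excluded = {sid: n for sid, n in sorted(counts.items()) if n > max_calls}
    return kept, excluded
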