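"""Seeded synthetic cohorts for the CNV–treatment-response pipeline.

Emulates a TNF-alpha-blocker-treated rheumatoid arthritis cohort: a
low-frequency causal deletion locus whose carriers have elevated odds of
EULAR non-response, recurrent polymorphic background CNV loci plus rare
singleton CNVs (both with per-sample boundary jitter), clinical covariates
(BMI, sex, blocker, methotrexate, genetic principal components), and
baseline / month-6 disease-activity components constructed so that the EULAR
class recomputed from them equals the drawn response label. Optionally the
CNV calls can be rendered down to per-probe LRR/BAF signal for the HMM
caller.

All randomness flows from ``SimConfig.seed`` through fixed named substreams,
so identical configurations yield byte-identical outputs and each stage can
be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import activity
from .activity import eular_response_bulk
from .hmm import BAF_CLUSTER_MEANS, CnvCall, HmmModel

#: Approximate autosome lengths (bp, GRCh37) for placing background CNVs.
AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}

_SUBSTREAMS = ("genotypes", "covariates", "outcome", "clinical", "cnv", "loci", "signal")


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class TrueGenotype:
    """Latent deletion genotype at the causal locus."""

    sample_id: str
    deleted_allele_count: int  # 0, 1 or 2

    def __post_init__(self) -> None:
        if self.deleted_allele_count not in (0, 1, 2):
            raise ValueError(
                f"deleted_allele_count must be 0, 1 or 2; got {self.deleted_allele_count}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the target cohort: 357 patients, a ~5.6%-carrier
    deletion at 2q14.3 with a non-response odds ratio of 8.44, a ~9%
    marginal non-response rate, baseline DAS28 ~ N(6.24, 0.89), and blocker
    proportions etanercept 72.8% / adalimumab 16.8% / golimumab 5.3% /
    infliximab 5.0%.
    """

    n_samples: int = 357
    causal_carrier_freq: float = 0.056
    causal_region: tuple[str, int, int] = ("2", 129_457_798, 129_461_606)
    effect_log_or: float = float(np.log(8.44))
    baseline_nr_prob: float = 0.09
    background_cnv_rate: float = 8.0
    n_background_loci: int = 40
    boundary_jitter_sd: float = 250.0
    n_pcs: int = 5
    seed: int = 2019
    # clinical structure
    das28_baseline_mean: float = 6.24
    das28_baseline_sd: float = 0.89
    good_given_responder: float = 117.0 / 325.0
    drug_props: Mapping[str, float] = field(
        default_factory=lambda: {
            "etanercept": 0.728, "adalimumab": 0.168, "golimumab": 0.053, "infliximab": 0.051,
        }
    )
    mtx_prob: float = 0.70
    female_prob: float = 0.85
    bmi_mean: float = 23.0
    bmi_sd: float = 3.2
    #: logit-scale covariate effects on non-response (centered contributions)
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "bmi": 0.03, "sex": 0.2, "mtx": -0.2, "baseline_das28": 0.1, "pc": 0.05,
            "adalimumab": 0.15, "golimumab": 0.10, "infliximab": 0.10,
        }
    )
    probe_spacing: float = 800.0
    genome: Mapping[str, int] = field(default_factory=lambda: dict(AUTOSOME_LENGTHS))
    background_avoid_causal: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise SimConfigError(f"n_samples must be >= 2; got {self.n_samples}")
        if not 0.0 < self.causal_carrier_freq < 1.0:
            raise SimConfigError(
                f"causal_carrier_freq must lie in (0, 1); got {self.causal_carrier_freq}"
            )
        if not 0.0 < self.baseline_nr_prob < 1.0:
            raise SimConfigError(
                f"baseline_nr_prob must lie in (0, 1); got {self.baseline_nr_prob}"
            )
        if self.boundary_jitter_sd < 0:
            raise SimConfigError(
                f"boundary_jitter_sd must be >= 0; got {self.boundary_jitter_sd}"
            )
        if self.background_cnv_rate < 0:
            raise SimConfigError(
                f"background_cnv_rate must be >= 0; got {self.background_cnv_rate}"
            )
        if self.n_background_loci < 0:
            raise SimConfigError(
                f"n_background_loci must be >= 0; got {self.n_background_loci}"
            )
        if self.n_pcs < 0:
            raise SimConfigError(f"n_pcs must be >= 0; got {self.n_pcs}")
        chrom, start, end = self.causal_region
        if start > end or start < 1:
            raise SimConfigError(f"causal_region is not a valid interval: {self.causal_region}")
        if chrom not in self.genome:
            raise SimConfigError(f"causal_region chromosome {chrom!r} not in genome map")
        if abs(sum(self.drug_props.values()) - 1.0) > 1e-6:
            raise SimConfigError("drug_props must sum to 1")

    @property
    def allele_freq(self) -> float:
        """Per-allele deletion frequency implied by the carrier fraction."""
        return 1.0 - float(np.sqrt(1.0 - self.causal_carrier_freq))


@dataclass
class SimulatedCohort:
    """Bundle of everything simulate_cohort generates."""

    visits: pd.DataFrame  # sample_id, visit, tjc28, sjc28, esr, gh, ptga, phga
    covariates: pd.DataFrame  # indexed by sample_id
    genotypes: list[TrueGenotype]
    labels: pd.DataFrame  # indexed by sample_id; includes eular_class

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    idx = _SUBSTREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(len(_SUBSTREAMS))[idx])


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _causal_genotypes(n: int, carrier_freq: float, rng: np.random.Generator) -> np.ndarray:
    """Deletion allele counts with the configured *realized* carrier fraction.

    The causal locus emulates a segment the study ascertained as common, so
    the cohort carries it at the configured frequency by construction:
    round(n * carrier_freq) carriers are assigned by permutation, and each
    carrier is a deletion homozygote with the conditional HWE probability
    q / (2 − q), q being the implied allele frequency.
    """
    n_carriers = int(round(n * carrier_freq))
    q = 1.0 - float(np.sqrt(1.0 - carrier_freq))
    counts = np.zeros(n, dtype=np.int64)
    idx = rng.permutation(n)[:n_carriers]
    hom = rng.random(n_carriers) < q / (2.0 - q)
    counts[idx] = np.where(hom, 2, 1)
    return counts


def _das28_components_for_targets(
    target: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw (tjc, sjc, esr, gh) whose DAS28 lands (very nearly) on target.

    The target score is allocated across the four terms with random
    fractions; integer rounding of the joint counts is compensated through
    the continuous ESR term, so the achieved score equals the target except
    when ESR hits its clips.
    """
    n = target.shape[0]
    gh = np.clip(np.round(target * rng.uniform(0.15, 0.25, n) / 0.014), 0, 100)
    esr = np.clip(np.exp(target * rng.uniform(0.35, 0.50, n) / 0.70), 1.0, 150.0)
    rem = np.maximum(target - 0.014 * gh - 0.70 * np.log(esr), 0.0)
    f = rng.uniform(0.45, 0.75, n)
    tjc = np.clip(np.round((rem * f / 0.56) ** 2), 0, 28)
    rem2 = np.maximum(rem - 0.56 * np.sqrt(tjc), 0.0)
    sjc = np.clip(np.round((rem2 / 0.28) ** 2), 0, 28)
    achieved = 0.56 * np.sqrt(tjc) + 0.28 * np.sqrt(sjc) + 0.70 * np.log(esr) + 0.014 * gh
    esr = np.clip(esr * np.exp((target - achieved) / 0.70), 1.0, 400.0)
    return tjc.astype(int), sjc.astype(int), esr, gh


def _global_assessments(
    das28: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Patient / physician global assessments loosely tracking DAS28 severity."""
    base = das28 / 9.4 * 10.0
    ptga = np.clip(np.round((base + rng.normal(0, 1.2, das28.shape[0])) * 2) / 2, 0, 10)
    phga = np.clip(np.round((base + rng.normal(0, 1.0, das28.shape[0])) * 2) / 2, 0, 10)
    return ptga, phga


def _sample_month6_targets(
    baseline: np.ndarray, classes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw month-6 DAS28 targets inside the requested EULAR cell.

    Targets keep a small buffer from every cell boundary so that the tiny
    residual error of the component construction cannot flip the class.
    """
    n = baseline.shape[0]
    m6 = np.empty(n)
    for i in range(n):
        b, cls = baseline[i], classes[i]
        if cls == "good":
            hi = min(3.1, b - 1.4)
            m6[i] = rng.uniform(0.8, max(hi, 0.9))
        elif cls == "moderate":
            feas_high = b - 1.4 > 3.4  # cell: delta > 1.2, attained > 3.2
            feas_low = b - 0.7 <= 5.0  # cell: 0.6 < delta <= 1.2, attained <= 5.1
            if feas_high and (not feas_low or rng.random() < 0.75):
                m6[i] = rng.uniform(3.4, min(b - 1.4, 6.2))
            else:
                m6[i] = rng.uniform(max(0.8, b - 1.1), b - 0.7)
        else:  # none: delta <= 0.6 with buffer
            m6[i] = rng.uniform(max(0.7, b - 0.45), b + 0.9)
    return m6


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate one synthetic cohort.

    Non-response is drawn from a logistic model
    ``logit(P) = logit(baseline_nr_prob) + effect_log_or * carrier +
    centered covariate effects``; responders split into good/moderate with the
    cohort's conditional proportion. Clinical components at both visits are
    constructed so that the EULAR class recomputed from them equals the drawn
    label for every patient.
    """
    n = config.n_samples
    ids = [f"S{i:05d}" for i in range(n)]

    g_rng = _rng(config, "genotypes")
    allele_counts = _causal_genotypes(n, config.causal_carrier_freq, g_rng)
    genotypes = [TrueGenotype(sid, int(c)) for sid, c in zip(ids, allele_counts)]
    carrier = (allele_counts >= 1).astype(float)

    c_rng = _rng(config, "covariates")
    bmi = np.clip(c_rng.normal(config.bmi_mean, config.bmi_sd, n), 15.0, 42.0)
    sex = (c_rng.random(n) < config.female_prob).astype(int)  # 1 = female
    drugs = list(config.drug_props)
    drug = c_rng.choice(drugs, size=n, p=[config.drug_props[d] for d in drugs])
    mtx = (c_rng.random(n) < config.mtx_prob).astype(int)
    pcs = c_rng.normal(0.0, 1.0, (n, config.n_pcs))

    cl_rng = _rng(config, "clinical")
    b_target = np.clip(
        cl_rng.normal(config.das28_baseline_mean, config.das28_baseline_sd, n), 4.2, 9.2
    )
    tjc_b, sjc_b, esr_b, gh_b = _das28_components_for_targets(b_target, cl_rng)
    das_b = activity.das28_esr(tjc_b, sjc_b, esr_b, gh_b)
    ptga_b, phga_b = _global_assessments(das_b, cl_rng)

    eff = config.covariate_effects
    eta = np.full(n, _logit(config.baseline_nr_prob))
    eta += config.effect_log_or * carrier
    eta += eff.get("bmi", 0.0) * (bmi - config.bmi_mean)
    eta += eff.get("sex", 0.0) * (sex - config.female_prob)
    eta += eff.get("mtx", 0.0) * (mtx - config.mtx_prob)
    eta += eff.get("baseline_das28", 0.0) * (das_b - config.das28_baseline_mean)
    for d, prop in config.drug_props.items():
        if d == "etanercept":
            continue
        eta += eff.get(d, 0.0) * ((drug == d).astype(float) - prop)
    for k in range(config.n_pcs):
        eta += eff.get("pc", 0.0) * pcs[:, k]

    o_rng = _rng(config, "outcome")
    non_resp = o_rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    good = o_rng.random(n) < config.good_given_responder
    classes = np.where(non_resp, "none", np.where(good, "good", "moderate")).astype(object)

    # month-6 components: draw a target inside the class cell, construct
    # components, verify the recomputed class, retry any mismatches
    m6_t = _sample_month6_targets(das_b, classes, cl_rng)
    tjc_m, sjc_m, esr_m, gh_m = _das28_components_for_targets(m6_t, cl_rng)
    das_m = activity.das28_esr(tjc_m, sjc_m, esr_m, gh_m)
    for _ in range(200):
        mism = np.nonzero(eular_response_bulk(das_b, das_m) != classes)[0]
        if mism.size == 0:
            break
        m6_retry = _sample_month6_targets(das_b[mism], classes[mism], cl_rng)
        t2, s2, e2, g2 = _das28_components_for_targets(m6_retry, cl_rng)
        tjc_m[mism], sjc_m[mism], esr_m[mism], gh_m[mism] = t2, s2, e2, g2
        das_m = activity.das28_esr(tjc_m, sjc_m, esr_m, gh_m)
    else:
        raise RuntimeError("could not realize EULAR classes in clinical components")
    ptga_m, phga_m = _global_assessments(das_m, cl_rng)

    visits = pd.DataFrame(
        {
            "sample_id": ids * 2,
            "visit": ["baseline"] * n + ["month6"] * n,
            "tjc28": np.concatenate([tjc_b, tjc_m]),
            "sjc28": np.concatenate([sjc_b, sjc_m]),
            "esr": np.round(np.concatenate([esr_b, esr_m]), 2),
            "gh": np.concatenate([gh_b, gh_m]),
            "ptga": np.concatenate([ptga_b, ptga_m]),
            "phga": np.concatenate([phga_b, phga_m]),
        }
    )
    # recompute scores from the rounded, stored components so labels and
    # phenotype table can never disagree
    esr_b_r, esr_m_r = np.round(esr_b, 2), np.round(esr_m, 2)
    das_b = activity.das28_esr(tjc_b, sjc_b, esr_b_r, gh_b)
    das_m = activity.das28_esr(tjc_m, sjc_m, esr_m_r, gh_m)
    final_classes = eular_response_bulk(das_b, das_m)
    if not np.array_equal(final_classes, classes):
        raise RuntimeError("rounding moved a patient across an EULAR boundary")
    cdai_b = activity.cdai(tjc_b, sjc_b, ptga_b, phga_b)
    cdai_m = activity.cdai(tjc_m, sjc_m, ptga_m, phga_m)

    covariates = pd.DataFrame(
        {
            "sample_id": ids, "bmi": np.round(bmi, 2), "sex": sex, "drug": drug, "mtx": mtx,
            **{f"pc{k + 1}": np.round(pcs[:, k], 4) for k in range(config.n_pcs)},
        }
    ).set_index("sample_id")

    labels = pd.DataFrame(
        {
            "sample_id": ids,
            "das28_baseline": das_b,
            "das28_month6": das_m,
            "delta_das28": das_b - das_m,
            "cdai_baseline": cdai_b,
            "cdai_month6": cdai_m,
            "delta_cdai": cdai_b - cdai_m,
            "eular_class": classes,
            "is_responder": classes != "none",
        }
    ).set_index("sample_id")

    return SimulatedCohort(visits=visits, covariates=covariates, genotypes=genotypes, labels=labels)


def _jitter_interval(
    start: int, end: int, sd: float, rng: np.random.Generator,
    chrom_len: int, must_overlap: tuple[int, int] | None = None,
    spacing: float = 1.0,
) -> tuple[int, int]:
    # boundary error is quantized to whole probe steps: an array call can
    # only start or end at a probe, so most samples share exact boundaries
    def offset() -> int:
        if sd <= 0:
            return 0
        steps = np.round(rng.normal(0.0, sd) / spacing)
        return int(steps * spacing)

    s = start + offset()
    e = end + offset()
    if must_overlap is not None:
        lo, hi = must_overlap
        s = min(s, hi - 1)
        e = max(e, lo + 1)
    if s > e:
        s, e = e, s
    s = max(1, s)
    e = min(chrom_len, max(e, s))
    return s, e


def _num_snps(length: int, spacing: float) -> int:
    return max(4, int(round(length / spacing)))


@dataclass(frozen=True)
class BackgroundLocus:
    chromosome: str
    start: int
    end: int
    copy_number: int
    carrier_freq: float


def background_loci(config: SimConfig) -> list[BackgroundLocus]:
    """Deterministic panel of recurrent polymorphic background CNV loci."""
    rng = _rng(config, "loci")
    chroms = list(config.genome)
    lengths = np.array([config.genome[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    c_chrom, c_start, c_end = config.causal_region
    loci: list[BackgroundLocus] = []
    while len(loci) < config.n_background_loci:
        chrom = str(rng.choice(chroms, p=weights))
        size = int(np.clip(rng.lognormal(np.log(4000.0), 0.6), 1200, 60_000))
        start = int(rng.integers(1, config.genome[chrom] - size))
        end = start + size - 1
        if (
            config.background_avoid_causal
            and chrom == c_chrom
            and start <= c_end + 50_000
            and end >= c_start - 50_000
        ):
            continue
        cn = int(rng.choice([0, 1, 3, 4], p=[0.05, 0.55, 0.30, 0.10]))
        freq = float(rng.uniform(0.05, 0.30))
        loci.append(BackgroundLocus(chrom, start, end, cn, freq))
    return loci


def simulate_cnv_calls(
    genotypes: Sequence[TrueGenotype], config: SimConfig
) -> list[CnvCall]:
    """Render latent genotypes into per-sample CNV calls.

    Causal-locus carriers receive a call at CN = 2 − deleted_allele_count
    whose endpoints are jittered by rounded Normal(0, boundary_jitter_sd)
    but always still overlap the causal region. Background calls come from
    the recurrent locus panel (per-sample Bernoulli carriage, jittered
    boundaries) plus per-sample Poisson singletons placed uniformly on the
    genome map; by default neither overlaps the causal region.
    """
    if not genotypes:
        raise ValueError("genotypes must be nonempty")
    rng = _rng(config, "cnv")
    loci = background_loci(config)
    c_chrom, c_start, c_end = config.causal_region
    chrom_len = config.genome[c_chrom]
    chroms = list(config.genome)
    lengths = np.array([config.genome[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    calls: list[CnvCall] = []
    for g in genotypes:
        if g.deleted_allele_count >= 1:
            s, e = _jitter_interval(
                c_start, c_end, config.boundary_jitter_sd, rng, chrom_len,
                must_overlap=(c_start, c_end), spacing=config.probe_spacing,
            )
            calls.append(
                CnvCall(
                    sample_id=g.sample_id, chromosome=c_chrom, start=s, end=e,
                    copy_number=2 - g.deleted_allele_count,
                    num_snps=_num_snps(e - s + 1, config.probe_spacing),
                )
            )
        for locus in loci:
            if rng.random() >= locus.carrier_freq:
                continue
            s, e = _jitter_interval(
                locus.start, locus.end, config.boundary_jitter_sd, rng,
                config.genome[locus.chromosome], must_overlap=(locus.start, locus.end),
                spacing=config.probe_spacing,
            )
            calls.append(
                CnvCall(
                    sample_id=g.sample_id, chromosome=locus.chromosome, start=s, end=e,
                    copy_number=locus.copy_number,
                    num_snps=_num_snps(e - s + 1, config.probe_spacing),
                )
            )
        for _ in range(rng.poisson(config.background_cnv_rate)):
            for _attempt in range(50):
                chrom = str(rng.choice(chroms, p=weights))
                size = int(np.clip(rng.lognormal(np.log(4000.0), 0.8), 1200, 100_000))
                start = int(rng.integers(1, config.genome[chrom] - size))
                end = start + size - 1
                if (
                    config.background_avoid_causal
                    and chrom == c_chrom
                    and start <= c_end + 50_000
                    and end >= c_start - 50_000
                ):
                    continue
                cn = int(rng.choice([0, 1, 3, 4], p=[0.05, 0.55, 0.30, 0.10]))
                calls.append(
                    CnvCall(
                        sample_id=g.sample_id, chromosome=chrom, start=start, end=end,
                        copy_number=cn, num_snps=_num_snps(size, config.probe_spacing),
                    )
                )
                break
    calls.sort(key=lambda c: (c.sample_id, c.chromosome, c.start))
    return _drop_same_sample_overlaps(calls)


def _drop_same_sample_overlaps(calls: list[CnvCall]) -> list[CnvCall]:
    """Drop later calls that overlap an earlier call of the same sample.

    Uniformly placed singletons can in principle collide with each other or
    with a locus call; segmentation treats conflicting same-sample overlaps
    as corrupt input, so the generator never emits them.
    """
    kept: list[CnvCall] = []
    last_end: dict[tuple[str, str], int] = {}
    for c in calls:  # sorted by (sample, chrom, start)
        key = (c.sample_id, c.chromosome)
        if key in last_end and c.start <= last_end[key]:
            continue
        kept.append(c)
        last_end[key] = c.end
    return kept


def make_probe_map(
    chromosome: str = "2",
    start: int = 129_450_000,
    end: int = 129_470_000,
    spacing: int = 800,
    seed: int = 0,
) -> pd.DataFrame:
    """Evenly spaced probe map with random population B-allele frequencies."""
    rng = np.random.default_rng(seed)
    positions = np.arange(start, end + 1, spacing, dtype=np.int64)
    return pd.DataFrame(
        {
            "name": [f"rs{chromosome}_{p}" for p in positions],
            "chromosome": chromosome,
            "position": positions,
            "pfb": np.round(rng.uniform(0.05, 0.95, positions.shape[0]), 4),
        }
    )


def simulate_signal(
    calls: Sequence[CnvCall],
    probe_map: pd.DataFrame,
    noise_sd: float,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
    model: HmmModel | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-sample probe-level LRR/BAF consistent with the caller's emissions.

    LRR ~ Normal(state mean of the local copy number, ``noise_sd``); BAF is
    drawn from the copy-number-specific cluster mixture: the B-allele count
    is Binomial(CN, pfb), the cluster mean is count/CN, and Gaussian noise of
    width ``noise_sd / 4`` is added then clipped to [0, 1] (CN=0 probes draw
    BAF uniformly). Probes outside any call are diploid.
    """
    model = model or HmmModel()
    required = {"name", "chromosome", "position", "pfb"}
    if required - set(probe_map.columns):
        raise ValueError(f"probe map must have columns {sorted(required)}")
    pm = probe_map.reset_index(drop=True)
    key = pm[["chromosome", "position"]].astype({"position": np.int64})
    for chrom, grp in key.groupby("chromosome", sort=False):
        if np.any(np.diff(grp["position"].to_numpy()) <= 0):
            raise ValueError("probe map must be sorted by (chromosome, position)")
    rng = np.random.default_rng(seed)
    baf_sd = noise_sd / 4.0

    if sample_ids is None:
        sample_ids = sorted({c.sample_id for c in calls})
    by_sample: dict[str, list[CnvCall]] = {sid: [] for sid in sample_ids}
    for c in calls:
        if c.sample_id in by_sample:
            by_sample[c.sample_id].append(c)

    n_probes = len(pm)
    positions = pm["position"].to_numpy(dtype=np.int64)
    chrom_arr = pm["chromosome"].to_numpy()
    pfb = pm["pfb"].to_numpy(dtype=float)
    out: dict[str, pd.DataFrame] = {}
    for sid in sample_ids:
        cn = np.full(n_probes, 2, dtype=np.int64)
        for c in by_sample[sid]:
            mask = (chrom_arr == c.chromosome) & (positions >= c.start) & (positions <= c.end)
            cn[mask] = c.copy_number
        lrr_mean = np.array(model.lrr_means)[cn]
        lrr = lrr_mean + (rng.normal(0.0, noise_sd, n_probes) if noise_sd > 0 else 0.0)
        baf = np.empty(n_probes)
        zero = cn == 0
        baf[zero] = rng.uniform(0.0, 1.0, int(zero.sum()))
        nz = ~zero
        b_count = rng.binomial(cn[nz], pfb[nz])
        mean = b_count / cn[nz]
        noise = rng.normal(0.0, baf_sd, int(nz.sum())) if noise_sd > 0 else 0.0
        baf[nz] = np.clip(mean + noise, 0.0, 1.0)
        out[sid] = pd.DataFrame({"probe": pm["name"], "lrr": lrr, "baf": baf})
    return out
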