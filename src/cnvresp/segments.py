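"""Multi-sample CNV boundary segmentation and segment-level filters.

Overlapping per-sample CNV calls are fragmented at every observed call
boundary so that within each resulting segment every sample has a constant
integer copy number (samples without an overlapping call are diploid, CN=2).
Segments are then classified (deletion-only / duplication-only / multi-class),
annotated with the abnormal-copy carrier frequency, tested for
Hardy–Weinberg equilibrium of the implied biallelic CNV genotype, and
filtered to the common (carrier frequency >= 5%), HWE-consistent set used for
association testing.

Coordinates are 1-based inclusive throughout; cut points are call starts and
(end + 1) positions, so printed regions that share an endpoint abut without
internal overlap.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .hmm import CnvCall, _chrom_sort_key

SEGMENT_CLASSES = ("deletion_only", "duplication_only", "multi_class")


@dataclass
class CnvSegment:
    """A boundary-derived interval with one copy number per sample."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int
    copy_numbers: np.ndarray  # aligned to SegmentMatrix.sample_ids
    n_supporting_boundaries: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def segment_id(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


@dataclass(frozen=True)
class HweResult:
    """Genotype counts and Hardy–Weinberg test p-value for one segment."""

    n_hom_ref: int  # CN=2
    n_het: int  # CN=1 (deletion) or CN=3 (duplication)
    n_hom_alt: int  # CN=0 (deletion) or CN=4 (duplication)
    p_value: float
    method: str  # "exact" | "chi2"


@dataclass
class SegmentMatrix:
    """Samples x segments copy-number matrix with per-segment annotations."""

    sample_ids: list[str]
    segments: list[CnvSegment]
    classes: list[str] | None = None
    carrier_freqs: np.ndarray | None = None
    hwe_ps: list[float | None] | None = None

    @property
    def segment_ids(self) -> list[str]:
        return [s.segment_id for s in self.segments]

    def to_frame(self) -> pd.DataFrame:
        """Copy-number matrix as a DataFrame (rows samples, columns segments)."""
        data = (
            np.column_stack([s.copy_numbers for s in self.segments])
            if self.segments
            else np.empty((len(self.sample_ids), 0), dtype=int)
        )
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.segment_ids)

    def annotate(self, hwe_method: str = "exact") -> "SegmentMatrix":
        """Compute class, carrier frequency and HWE p per segment (in place)."""
        classes, freqs, ps = [], [], []
        for seg in self.segments:
            col = seg.copy_numbers
            cls = classify_segment(col)
            classes.append(cls)
            freqs.append(carrier_frequency(col))
            res = hwe_test(col, cls, method=hwe_method)
            ps.append(res.p_value if res is not None else None)
        self.classes = classes
        self.carrier_freqs = np.array(freqs)
        self.hwe_ps = ps
        return self

    def annotation_frame(self) -> pd.DataFrame:
        if self.classes is None:
            self.annotate()
        return pd.DataFrame(
            {
                "segment_id": self.segment_ids,
                "chromosome": [s.chromosome for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "length": [s.length for s in self.segments],
                "n_supporting_boundaries": [s.n_supporting_boundaries for s in self.segments],
                "class": self.classes,
                "carrier_freq": self.carrier_freqs,
                "hwe_p": [p if p is not None else np.nan for p in self.hwe_ps],
            }
        ).set_index("segment_id")

    def n_regions(self) -> int:
        """Number of merged CNV regions (maximal runs of abutting segments)."""
        n = 0
        prev: CnvSegment | None = None
        for seg in self.segments:
            if prev is None or seg.chromosome != prev.chromosome or seg.start != prev.end + 1:
                n += 1
            prev = seg
        return n


def segment_cnvs(calls: Iterable[CnvCall], sample_ids: Sequence[str]) -> SegmentMatrix:
    """Split overlapping CNV calls at every observed boundary.

    For each chromosome the distinct call starts and (end + 1) positions are
    cut points; the union of call footprints is partitioned into maximal
    intervals between consecutive cut points. Every segment records each
    sample's copy number (from its overlapping call, else the diploid 2).
    Same-sample overlapping calls with conflicting copy number are an input
    error.
    """
    sample_ids = list(sample_ids)
    sample_index = {sid: i for i, sid in enumerate(sample_ids)}
    calls = list(calls)
    for c in calls:
        if c.sample_id not in sample_index:
            raise ValueError(f"call sample {c.sample_id!r} not in sample_ids")

    by_chrom: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chromosome, []).append(c)

    segments: list[CnvSegment] = []
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cuts = sorted({c.start for c in chrom_calls} | {c.end + 1 for c in chrom_calls})

        # merged union footprint (abutting calls merge; the cut points still
        # split them back apart below)
        regions: list[list[int]] = []
        for c in chrom_calls:
            if regions and c.start <= regions[-1][1] + 1:
                regions[-1][1] = max(regions[-1][1], c.end)
            else:
                regions.append([c.start, c.end])

        chrom_segments: list[CnvSegment] = []
        seg_starts: list[int] = []
        for rs, re in regions:
            bounds = [b for b in cuts[bisect_left(cuts, rs): bisect_right(cuts, re + 1)]]
            for a, b in zip(bounds[:-1], bounds[1:]):
                chrom_segments.append(
                    CnvSegment(
                        chromosome=chrom,
                        start=a,
                        end=b - 1,
                        copy_numbers=np.full(len(sample_ids), 2, dtype=np.int64),
                        n_supporting_boundaries=len(bounds),
                    )
                )
                seg_starts.append(a)

        for c in chrom_calls:
            i = bisect_left(seg_starts, c.start)
            si = sample_index[c.sample_id]
            while i < len(chrom_segments) and chrom_segments[i].start <= c.end:
                seg = chrom_segments[i]
                current = seg.copy_numbers[si]
                if current != 2 and current != c.copy_number:
                    raise ValueError(
                        f"conflicting copy numbers {current} and {c.copy_number} for "
                        f"sample {c.sample_id} at {chrom}:{seg.start}-{seg.end}"
                    )
                seg.copy_numbers[si] = c.copy_number
                i += 1
        segments.extend(chrom_segments)

    return SegmentMatrix(sample_ids=sample_ids, segments=segments)


def classify_segment(cn_column: np.ndarray) -> str:
    """deletion_only / duplication_only / multi_class from a CN column."""
    col = np.asarray(cn_column)
    abnormal = col[col != 2]
    if abnormal.size == 0:
        raise ValueError("segment has no abnormal copy numbers to classify")
    if np.all(abnormal < 2):
        return "deletion_only"
    if np.all(abnormal > 2):
        return "duplication_only"
    return "multi_class"


def carrier_frequency(cn_column: np.ndarray) -> float:
    """Fraction of samples with abnormal (CN != 2) copy number."""
    col = np.asarray(cn_column)
    if col.size == 0:
        raise ValueError("empty copy-number column")
    return float(np.mean(col != 2))


def deletion_carrier_frequency(cn_column: np.ndarray) -> float:
    """Fraction of samples carrying a deletion (CN < 2)."""
    col = np.asarray(cn_column)
    if col.size == 0:
        raise ValueError("empty copy-number column")
    return float(np.mean(col < 2))


def hwe_exact_p(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact conditional Hardy–Weinberg test for biallelic genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (two-sided by probability ordering). Returns 1.0 for monomorphic data.
    """
    if min(n_het, n_hom_rare, n_hom_common) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_rare + n_hom_common
    n_rare = 2 * n_hom_rare + n_het
    if n_rare > n:  # orient to the minor allele
        n_rare = 2 * n - n_rare
    if n == 0 or n_rare == 0:
        return 1.0

    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_homs = (n_rare - hets) // 2
    common_homs = n - hets - rare_homs
    logp = (
        gammaln(n + 1)
        - gammaln(rare_homs + 1)
        - gammaln(hets + 1)
        - gammaln(common_homs + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.nonzero(hets == n_het)[0][0]]
    p = float(probs[probs <= obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def hwe_chi2_p(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """One-degree-of-freedom chi-square Hardy–Weinberg test."""
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    q = (2 * n_hom_rare + n_het) / (2 * n)
    if q in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    obs = np.array([n_hom_common, n_het, n_hom_rare], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(chi2_dist.sf(stat, df=1))


def hwe_test(
    cn_column: np.ndarray,
    segment_class: str,
    method: str = "exact",
    multi_class_mode: str = "na",
) -> HweResult | None:
    """Hardy–Weinberg test of the biallelic genotype implied by a CN column.

    Deletion-only segments map CN 2/1/0 to the reference-homozygote /
    heterozygote / deletion-homozygote genotypes; duplication-only segments
    map CN 2/3/4 symmetrically. Multi-class segments are not testable under a
    biallelic model and return None, unless ``multi_class_mode="deletion"``
    requests the reporting variant that drops CN>2 carriers and tests the
    deletion allele.
    """
    col = np.asarray(cn_column)
    if method not in ("exact", "chi2"):
        raise ValueError(f"unknown HWE method {method!r}")
    if segment_class == "multi_class":
        if multi_class_mode == "na":
            return None
        if multi_class_mode != "deletion":
            raise ValueError(f"unknown multi_class_mode {multi_class_mode!r}")
        col = col[col <= 2]
        segment_class = "deletion_only"

    if segment_class == "deletion_only":
        if np.any(col > 2):
            raise ValueError("deletion-only segment contains CN > 2")
        n_ref, n_het, n_alt = int(np.sum(col == 2)), int(np.sum(col == 1)), int(np.sum(col == 0))
    elif segment_class == "duplication_only":
        if np.any(col < 2):
            raise ValueError("duplication-only segment contains CN < 2")
        n_ref, n_het, n_alt = int(np.sum(col == 2)), int(np.sum(col == 3)), int(np.sum(col == 4))
    else:
        raise ValueError(f"unknown segment class {segment_class!r}")

    p = hwe_exact_p(n_het, n_alt, n_ref) if method == "exact" else hwe_chi2_p(n_het, n_alt, n_ref)
    return HweResult(n_hom_ref=n_ref, n_het=n_het, n_hom_alt=n_alt, p_value=p, method=method)


def filter_segments(
    matrix: SegmentMatrix,
    min_carrier_freq: float = 0.05,
    hwe_alpha: float = 0.05,
) -> tuple[SegmentMatrix, pd.DataFrame]:
    """Keep common, HWE-consistent segments.

    A segment is kept iff its abnormal-carrier frequency is >= ``min_carrier_freq``
    AND (it is multi-class OR its HWE p-value exceeds ``hwe_alpha``); single-class
    segments with p <= hwe_alpha are excluded. Returns the filtered matrix and a
    per-segment decision log.
    """
    if matrix.classes is None:
        matrix.annotate()
    kept_idx: list[int] = []
    decisions = []
    for i, seg in enumerate(matrix.segments):
        freq = float(matrix.carrier_freqs[i])
        cls = matrix.classes[i]
        hwe_p = matrix.hwe_ps[i]
        reasons = []
        if freq < min_carrier_freq:
            reasons.append(f"carrier_freq {freq:.4f} < {min_carrier_freq}")
        if cls != "multi_class" and hwe_p is not None and hwe_p <= hwe_alpha:
            reasons.append(f"hwe_p {hwe_p:.4g} <= {hwe_alpha}")
        kept = not reasons
        if kept:
            kept_idx.append(i)
        decisions.append(
            {
                "segment_id": seg.segment_id,
                "class": cls,
                "carrier_freq": freq,
                "hwe_p": hwe_p if hwe_p is not None else np.nan,
                "kept": kept,
                "reason": "; ".join(reasons),
            }
        )
    filtered = SegmentMatrix(
        sample_ids=matrix.sample_ids,
        segments=[matrix.segments[i] for i in kept_idx],
        classes=[matrix.classes[i] for i in kept_idx],
        carrier_freqs=matrix.carrier_freqs[kept_idx],
        hwe_ps=[matrix.hwe_ps[i] for i in kept_idx],
    )
    return filtered, pd.DataFrame(decisions).set_index("segment_id")


def segments_to_calls(matrix: SegmentMatrix, min_snps: int = 4) -> list[CnvCall]:
    """Re-express each segment's abnormal entries as per-sample calls.

    Used to check that segmentation is idempotent (segmenting the segments
    reproduces them); num_snps is a nominal floor since segments do not carry
    probe support.
    """
    calls: list[CnvCall] = []
    for seg in matrix.segments:
        for si, cn in enumerate(seg.copy_numbers):
            if cn != 2:
                calls.append(
                    CnvCall(
                        sample_id=matrix.sample_ids[si],
                        chromosome=seg.chromosome,
                        start=seg.start,
                        end=seg.end,
                        copy_number=int(cn),
                        num_snps=min_snps,
                    )
                )
    return calls
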