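"""End-to-end workflow: calls -> QC -> segmentation -> filters -> scoring -> association.

Mirrors the study design: per-sample CNV calls (simulated, read from file, or
HMM-decoded from probe signal) pass the >100-calls-per-sample screen, are
split at all observed boundaries into a copy-number segment matrix, filtered
to common Hardy–Weinberg-consistent segments, and tested for association with
EULAR non-response (logistic) and the six-month CDAI change (linear) under
Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import io as cio
from .activity import build_response_labels, labels_to_frame, visits_from_frame
from .assoc import associate_segments
from .hmm import call_sample, sample_cnv_qc
from .segments import SegmentMatrix, filter_segments, segment_cnvs
from .simulate import simulate_cnv_calls, simulate_cohort

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunReport:
    """Stage-by-stage counts and the association tables of one pipeline run."""

    counts: dict
    logistic: pd.DataFrame
    linear: pd.DataFrame
    filter_decisions: pd.DataFrame
    excluded_qc: dict
    excluded_visits: list
    significant_logistic: list
    significant_linear: list
    planted_locus_significant: bool | None = None  # simulate mode only

    def check_monotonicity(self) -> None:
        """Counts must shrink along the pipeline; raises on violation."""
        c = self.counts
        ok = (
            c["n_segments"] >= c["n_regions"]
            and c["n_common_segments"] <= c["n_segments"]
            and c["n_significant_logistic"] <= c["n_common_segments"]
            and c["n_significant_linear"] <= c["n_common_segments"]
        )
        if not ok:
            raise AssertionError(f"stage counts violate monotonicity: {c}")


def run_pipeline(config: cio.PipelineConfig) -> RunReport:
    """Execute the full workflow described by ``config``.

    Returns a RunReport; when ``config.out_dir`` is set, all intermediate
    tables (calls, labels, segment matrix + BED + annotation, association
    results, run report counts) are written there as text files.
    """
    config.validate()
    logger.info("pipeline start: mode=%s", config.mode)

    if config.mode == "simulate":
        cohort = simulate_cohort(config.sim)
        calls = simulate_cnv_calls(cohort.genotypes, config.sim)
        visits = cohort.visits
        covariates = cohort.covariates
        all_samples = cohort.sample_ids
        logger.info(
            "simulated cohort: %d samples, %d CNV calls (seed %d)",
            len(all_samples), len(calls), config.sim.seed,
        )
    else:
        if config.mode == "signal":
            probe_map = cio.read_probe_map(config.probe_map_path)
            from .hmm import ProbeInfo, ProbeSignal

            probes = [
                ProbeInfo(str(r.name), str(r.chromosome), int(r.position), float(r.pfb))
                for r in probe_map.itertuples(index=False)
            ]
            probe_by_name = {p.name: p for p in probes}
            calls = []
            for sig_path in sorted(Path(config.signal_dir).glob("*.tsv")):
                sid = sig_path.stem
                sig_df = cio.read_signal(sig_path)
                signals = [
                    ProbeSignal(probe_by_name[str(r.probe)], float(r.lrr), float(r.baf))
                    for r in sig_df.itertuples(index=False)
                ]
                calls.extend(
                    call_sample(sid, signals, config.hmm, min_snps=config.min_snps_per_call)
                )
        else:
            calls = cio.read_penncnv(config.calls_path)
        visits = cio.read_phenotypes(config.phenotypes_path)
        covariates = cio.read_covariates(config.covariates_path)
        all_samples = sorted(set(visits["sample_id"].astype(str)))

    n_calls_raw = len(calls)

    kept_with_calls, excluded_qc = sample_cnv_qc(calls, max_calls=config.max_calls_per_sample)
    calls = [c for c in calls if c.sample_id not in excluded_qc]
    if excluded_qc:
        logger.info(
            "excluded %d sample(s) with > %d CNV calls",
            len(excluded_qc), config.max_calls_per_sample,
        )

    labels_list, excluded_visits = build_response_labels(visits_from_frame(visits))
    labels = labels_to_frame(labels_list)

    analysis_samples = [
        s for s in all_samples if s not in excluded_qc and s not in set(excluded_visits)
    ]
    labels = labels.loc[analysis_samples]
    calls = [c for c in calls if c.sample_id in set(analysis_samples)]
    if config.mode != "simulate":
        missing_cov = set(analysis_samples) - set(covariates.index.astype(str))
        if missing_cov:
            raise RuntimeError(
                f"covariate table missing {len(missing_cov)} analysis sample(s): "
                f"{sorted(missing_cov)[:5]}..."
            )
    covariates = covariates.loc[analysis_samples]

    matrix = segment_cnvs(calls, analysis_samples)
    matrix.annotate()
    n_regions = matrix.n_regions()
    filtered, decisions = filter_segments(
        matrix, min_carrier_freq=config.min_carrier_freq, hwe_alpha=config.hwe_alpha
    )
    logger.info(
        "%d calls -> %d regions -> %d segments -> %d common segments",
        len(calls), n_regions, len(matrix.segments), len(filtered.segments),
    )

    logistic = associate_segments(
        filtered, labels, covariates, model="logistic",
        n_pcs=config.n_pcs, fdr_q=config.fdr_q,
    )
    linear = associate_segments(
        filtered, labels, covariates, model="linear",
        n_pcs=config.n_pcs, fdr_q=config.fdr_q, orientation=config.delta_orientation,
    )

    sig_logistic = logistic.index[logistic["fdr_significant"].astype(bool)].tolist()
    sig_linear = linear.index[linear["fdr_significant"].astype(bool)].tolist()

    planted = None
    if config.mode == "simulate":
        chrom, c_start, c_end = config.sim.causal_region
        planted = any(
            seg.chromosome == chrom and seg.start <= c_end and seg.end >= c_start
            for seg, sid in zip(filtered.segments, filtered.segment_ids)
            if sid in set(sig_logistic)
        )

    counts = {
        "n_samples": len(all_samples),
        "n_analysis_samples": len(analysis_samples),
        "n_calls_raw": n_calls_raw,
        "n_calls": len(calls),
        "n_samples_excluded_qc": len(excluded_qc),
        "n_samples_excluded_visits": len(excluded_visits),
        "n_regions": n_regions,
        "n_segments": len(matrix.segments),
        "n_common_segments": len(filtered.segments),
        "n_significant_logistic": len(sig_logistic),
        "n_significant_linear": len(sig_linear),
    }
    report = RunReport(
        counts=counts,
        logistic=logistic,
        linear=linear,
        filter_decisions=decisions,
        excluded_qc=excluded_qc,
        excluded_visits=excluded_visits,
        significant_logistic=sig_logistic,
        significant_linear=sig_linear,
        planted_locus_significant=planted,
    )
    report.check_monotonicity()

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_penncnv(calls, out / "calls.rawcnv")
        cio.write_phenotypes(visits, out / "phenotypes.tsv")
        cio.write_covariates(covariates, out / "covariates.tsv")
        cio.write_labels(labels, out / "labels.tsv")
        cio.write_segment_matrix(filtered, out / "segment_matrix.tsv")
        cio.write_segments_bed(filtered, out / "segments.bed")
        filtered.annotation_frame().to_csv(out / "segment_annotation.tsv", sep="\t")
        cio.write_association(logistic, out / "assoc_logistic.tsv")
        cio.write_association(linear, out / "assoc_linear.tsv")
        pd.Series(counts).to_csv(out / "run_report.tsv", sep="\t", header=False)
        logger.info("outputs written to %s", out)

    return report
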