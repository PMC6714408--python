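"""File formats and pipeline configuration.

Tabular files are UTF-8 TSV with header rows ('.' marks a missing value,
which is an error once association is reached — the analysis is
complete-case). CNV calls use the PennCNV "rawcnv" text dialect::

    chr2:129457798-129461606  numsnp=5  length=3,809  state2,cn=1  SAMPLE  startsnp=rsA endsnp=rsB

Internally all coordinates are 1-based inclusive; the BED writer converts to
0-based half-open on output only.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .hmm import CnvCall, HmmModel
from .segments import CnvSegment, SegmentMatrix
from .simulate import SimConfig

#: PennCNV HMM state labels for the copy numbers this pipeline emits.
_CN_TO_STATE = {0: "state1", 1: "state2", 3: "state5", 4: "state6"}

_RAWCNV_RE = re.compile(
    r"^chr(?P<chrom>\S+?):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+"
    r"length=(?P<length>[\d,]+)\s+"
    r"state\d+,cn=(?P<cn>\d)\s+"
    r"(?P<sample>\S+)\s+"
    r"startsnp=(?P<startsnp>\S+)\s+"
    r"endsnp=(?P<endsnp>\S+)\s*$"
)


def read_penncnv(path: str | Path) -> list[CnvCall]:
    """Parse a PennCNV rawcnv file (comma-grouped lengths tolerated)."""
    calls: list[CnvCall] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _RAWCNV_RE.match(line)
        if m is None:
            raise ValueError(f"{path}:{lineno}: malformed rawcnv line: {line!r}")
        start, end = int(m["start"]), int(m["end"])
        cn = int(m["cn"])
        if cn == 2:
            raise ValueError(f"{path}:{lineno}: cn=2 record is not a CNV call")
        length = int(m["length"].replace(",", ""))
        if length != end - start + 1:
            raise ValueError(
                f"{path}:{lineno}: length {length} != end - start + 1 "
                f"({end - start + 1})"
            )
        calls.append(
            CnvCall(
                sample_id=m["sample"],
                chromosome=m["chrom"],
                start=start,
                end=end,
                copy_number=cn,
                num_snps=int(m["numsnp"]),
                start_probe="" if m["startsnp"] == "NA" else m["startsnp"],
                end_probe="" if m["endsnp"] == "NA" else m["endsnp"],
            )
        )
    return calls


def write_penncnv(calls: Iterable[CnvCall], path: str | Path) -> None:
    lines = []
    for c in calls:
        lines.append(
            f"chr{c.chromosome}:{c.start}-{c.end}\tnumsnp={c.num_snps}\t"
            f"length={c.length:,}\t{_CN_TO_STATE[c.copy_number]},cn={c.copy_number}\t"
            f"{c.sample_id}\tstartsnp={c.start_probe or 'NA'} endsnp={c.end_probe or 'NA'}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_segments_bed(matrix: SegmentMatrix, path: str | Path) -> None:
    """Segments as BED (0-based half-open): chrom, start-1, end, id, class."""
    if matrix.classes is None and matrix.segments:
        matrix.annotate()
    rows = ["#chrom\tstart\tend\tsegment_id\tclass"]
    for i, seg in enumerate(matrix.segments):
        cls = matrix.classes[i] if matrix.classes else "."
        rows.append(f"{seg.chromosome}\t{seg.start - 1}\t{seg.end}\t{seg.segment_id}\t{cls}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_segments_bed(path: str | Path) -> pd.DataFrame:
    """BED back to 1-based inclusive coordinates (chromosome, start, end, id, class)."""
    df = pd.read_csv(
        path, sep="\t", comment=None, header=0,
        names=["chromosome", "start", "end", "segment_id", "class"],
        dtype={"chromosome": str},
    )
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    return df


# --- TSV tables ----------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path, index: bool) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=".")


def write_phenotypes(visits: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(visits, path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["."])
    required = {"sample_id", "visit", "tjc28", "sjc28", "esr", "gh", "ptga", "phga"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    return df


def write_covariates(covariates: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(covariates.reset_index(), path, index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "drug": str}, na_values=["."])
    required = {"sample_id", "bmi", "sex", "drug", "mtx"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: covariate table missing columns {sorted(missing)}")
    return df.set_index("sample_id")


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(labels.reset_index(), path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["."])
    return df.set_index("sample_id")


def write_segment_matrix(matrix: SegmentMatrix, path: str | Path) -> None:
    _write_tsv(matrix.to_frame().reset_index(), path, index=False)


def read_segment_matrix(path: str | Path) -> pd.DataFrame:
    """Samples x segments integer CN matrix, indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return df.set_index("sample_id")


def segment_matrix_from_frame(cn: pd.DataFrame) -> SegmentMatrix:
    """Rebuild a SegmentMatrix from a samples x segments CN frame.

    Column names must be segment ids of the form ``chrom:start-end``.
    """
    segments = []
    for col in cn.columns:
        m = re.match(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$", col)
        if m is None:
            raise ValueError(f"column {col!r} is not a segment id (chrom:start-end)")
        segments.append(
            CnvSegment(
                chromosome=m["chrom"],
                start=int(m["start"]),
                end=int(m["end"]),
                copy_numbers=cn[col].to_numpy(dtype=np.int64),
            )
        )
    return SegmentMatrix(sample_ids=[str(s) for s in cn.index], segments=segments)


def write_probe_map(probe_map: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(probe_map, path, index=False)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"name", "chromosome", "position", "pfb"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: probe map missing columns {sorted(missing)}")
    return df


def write_signal(signal: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(signal, path, index=False)


def read_signal(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe", "lrr", "baf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: signal table missing columns {sorted(missing)}")
    return df


def write_association(results: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(results.reset_index(), path, index=False)


# --- pipeline configuration ----------------------------------------------

class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the field."""


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run configuration.

    ``mode`` selects the input stage: "simulate" generates a synthetic
    cohort; "calls" starts from a rawcnv file plus phenotype and covariate
    tables; "signal" additionally runs the HMM caller on probe-level signal
    files first.
    """

    mode: str = "simulate"
    out_dir: str | None = None
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    hmm: HmmModel = dataclasses.field(default_factory=HmmModel)
    calls_path: str | None = None
    phenotypes_path: str | None = None
    covariates_path: str | None = None
    probe_map_path: str | None = None
    signal_dir: str | None = None
    min_carrier_freq: float = 0.05
    hwe_alpha: float = 0.05
    max_calls_per_sample: int = 100
    min_snps_per_call: int = 4
    n_pcs: int = 5
    fdr_q: float = 0.05
    delta_orientation: str = "improvement"

    def validate(self) -> "PipelineConfig":
        if self.mode not in ("simulate", "calls", "signal"):
            raise ConfigError(f"mode must be simulate|calls|signal; got {self.mode!r}")
        for name, lo, hi, val in (
            ("min_carrier_freq", 0.0, 1.0, self.min_carrier_freq),
            ("hwe_alpha", 0.0, 1.0, self.hwe_alpha),
            ("fdr_q", 0.0, 1.0, self.fdr_q),
        ):
            if not lo <= val <= hi:
                raise ConfigError(f"{name} must lie in [{lo}, {hi}]; got {val}")
        if self.max_calls_per_sample < 1:
            raise ConfigError(f"max_calls_per_sample must be >= 1; got {self.max_calls_per_sample}")
        if self.min_snps_per_call < 1:
            raise ConfigError(f"min_snps_per_call must be >= 1; got {self.min_snps_per_call}")
        if self.delta_orientation not in ("improvement", "worsening"):
            raise ConfigError(
                f"delta_orientation must be improvement|worsening; got {self.delta_orientation!r}"
            )
        needed: list[tuple[str, str | None]] = []
        if self.mode == "calls":
            needed = [
                ("calls_path", self.calls_path),
                ("phenotypes_path", self.phenotypes_path),
                ("covariates_path", self.covariates_path),
            ]
        elif self.mode == "signal":
            needed = [
                ("signal_dir", self.signal_dir),
                ("probe_map_path", self.probe_map_path),
                ("phenotypes_path", self.phenotypes_path),
                ("covariates_path", self.covariates_path),
            ]
        for name, p in needed:
            if p is None:
                raise ConfigError(f"mode {self.mode!r} requires {name}")
            if not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        return self


def _dataclass_from_mapping(cls, data: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown {where} option(s): {sorted(unknown)}")
    for tup_field in ("causal_region",):
        if tup_field in data and isinstance(data[tup_field], list):
            data[tup_field] = tuple(data[tup_field])
    for tup_field in ("lrr_means", "lrr_sds"):
        if tup_field in data and isinstance(data[tup_field], list):
            data[tup_field] = tuple(data[tup_field])
    return cls(**data)


def load_pipeline_config(path: str | Path, seed: int | None = None) -> PipelineConfig:
    """Load a YAML pipeline configuration; ``seed`` overrides the file's."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    sim_data = raw.pop("sim", {}) or {}
    hmm_data = raw.pop("hmm", {}) or {}
    if seed is not None:
        sim_data["seed"] = seed
    try:
        sim = _dataclass_from_mapping(SimConfig, dict(sim_data), "sim")
        hmm = _dataclass_from_mapping(HmmModel, dict(hmm_data), "hmm")
        cfg = _dataclass_from_mapping(
            PipelineConfig, {**raw, "sim": sim, "hmm": hmm}, "pipeline"
        )
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg.validate()
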