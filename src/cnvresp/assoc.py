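"""Covariate-adjusted association of CNV segments with treatment response.

Each common CNV segment is tested against EULAR non-response by multivariate
logistic regression (covariates: genetic principal components, BMI, sex,
baseline DAS28, TNF-alpha blocker indicators, methotrexate use) and against
the six-month CDAI change by multivariate linear regression (baseline CDAI in
place of baseline DAS28). Deletion carriers (CN <= 1) form the default
predictor coding, with duplication carriers in the reference class.
Multiple testing across segments is controlled by Benjamini–Hochberg FDR.
Quasi-separated logistic fits fall back to Firth's penalized likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

DRUGS = ("etanercept", "adalimumab", "golimumab", "infliximab")  # reference first
Z95 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class LogisticFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    method: str  # "mle" | "firth"
    converged: bool


@dataclass(frozen=True)
class AssociationResult:
    """Effect of one segment's carrier indicator on the response outcome."""

    segment_id: str
    coding: str  # "deletion_carrier" | "duplication_carrier"
    model: str  # "logistic_eular" | "linear_cdai"
    beta: float
    se: float
    p_value: float
    ci_low: float  # 95% Wald bounds on beta
    ci_high: float
    or_: float | None = None  # exp(beta), logistic only
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    n: int = 0
    n_carriers: int = 0
    method: str = "mle"
    fdr_q: float | None = None
    fdr_significant: bool | None = None


@dataclass(frozen=True)
class TaggingResult:
    """Squared correlation between one SNP's dosage and the deletion dosage."""

    segment_id: str
    snp_id: str
    r2: float
    window: float
    monomorphic: bool = False


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.isnan(arr).any():
        bad = X.columns[np.isnan(arr).any(axis=0)].tolist()
        raise ValueError(f"design matrix contains missing values in columns {bad}")
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = X.columns[diag < 1e-8 * max(diag.max(), 1.0)].tolist()
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    if arr.shape[0] <= arr.shape[1]:
        raise ValueError("need more observations than predictors")


def firth_logistic(y: np.ndarray, X: pd.DataFrame, max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Firth's bias-reduced logistic regression (Jeffreys-prior penalty).

    Newton iterations on the modified score U*(b) = X'(y - p + h(1/2 - p)),
    where h are the leverages of the weighted hat matrix. Finite estimates
    exist even under complete separation.
    """
    _check_design(X)
    Xa = X.to_numpy(dtype=float)
    n, k = Xa.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = Xa @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        xw = Xa * w[:, None]
        info = Xa.T @ xw
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", xw, info_inv, Xa)
        score = Xa.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # damped step for stability far from the optimum
        while np.abs(step).max() > 5.0:
            step = step / 2.0
        beta = beta + step
        if np.abs(score).max() < tol:
            converged = True
            break
    eta = Xa @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-12, None)
    info = Xa.T @ (Xa * w[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    return LogisticFit(list(X.columns), beta, se, pvals, method="firth", converged=converged)


def fit_logistic(y, X: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald z-tests.

    Fits by Newton-type iteratively reweighted least squares; when the fit is
    quasi-separated (fitted probabilities within 1e-8 of 0/1 alongside a
    diverging coefficient, or non-convergence) the model is refitted with
    Firth penalization.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    _check_design(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0, maxiter=200, method="newton")
        phat = res.predict()
        separated = ((phat < 1e-8).any() or (phat > 1.0 - 1e-8).any()) and np.abs(
            res.params
        ).max() > 10.0
        if separated or not res.mle_retvals.get("converged", False):
            logger.info("quasi-separation or non-convergence detected; refitting with Firth penalty")
            return firth_logistic(y, X)
        return LogisticFit(
            list(X.columns),
            np.asarray(res.params),
            np.asarray(res.bse),
            np.asarray(res.pvalues),
            method="mle",
            converged=True,
        )
    except (PerfectSeparationError, np.linalg.LinAlgError):
        logger.info("separation error in MLE fit; refitting with Firth penalty")
        return firth_logistic(y, X)


def build_covariate_design(covariates: pd.DataFrame, n_pcs: int | None = None) -> pd.DataFrame:
    """Reference-code the covariate table for regression.

    The drug category expands to indicators against the etanercept reference
    (the most frequent blocker); principal-component columns are taken as
    pc1..pcK. Missing values are an error (complete-case analysis).
    """
    required = {"bmi", "sex", "drug", "mtx"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    unknown = set(covariates["drug"].unique()) - set(DRUGS)
    if unknown:
        raise ValueError(f"unknown drug categories: {sorted(unknown)}; expected {DRUGS}")
    X = pd.DataFrame(index=covariates.index)
    X["bmi"] = covariates["bmi"].astype(float)
    X["sex"] = covariates["sex"].astype(float)
    X["mtx"] = covariates["mtx"].astype(float)
    observed = set(covariates["drug"].unique())
    for d in DRUGS[1:]:
        if d in observed:  # absent categories would be all-zero columns
            X[f"drug_{d}"] = (covariates["drug"] == d).astype(float)
    pc_cols = sorted(
        (c for c in covariates.columns if c.startswith("pc") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    if n_pcs is not None:
        if n_pcs > len(pc_cols):
            raise ValueError(f"requested {n_pcs} PCs but table has {len(pc_cols)}")
        pc_cols = pc_cols[:n_pcs]
    for c in pc_cols:
        X[c] = covariates[c].astype(float)
    return X


def carrier_indicator(cn_column: pd.Series, coding: str = "deletion_carrier") -> pd.Series:
    """Binary predictor from a segment CN column.

    "deletion_carrier": CN <= 1 (duplication carriers count as reference);
    "duplication_carrier": CN >= 3.
    """
    if coding == "deletion_carrier":
        return (cn_column <= 1).astype(float)
    if coding == "duplication_carrier":
        return (cn_column >= 3).astype(float)
    raise ValueError(f"unknown coding {coding!r}")


def _assemble(
    cn_column: pd.Series,
    labels: pd.DataFrame,
    covariates: pd.DataFrame | None,
    baseline_col: str,
    n_pcs: int | None,
    coding: str,
) -> tuple[pd.DataFrame, pd.Series]:
    if not cn_column.index.equals(labels.index):
        cn_column = cn_column.reindex(labels.index)
        if cn_column.isna().any():
            raise ValueError("segment column and labels are not aligned on sample_id")
    carrier = carrier_indicator(cn_column, coding)
    if carrier.nunique() < 2:
        raise ValueError(
            f"degenerate predictor: all samples have carrier={int(carrier.iloc[0])} "
            f"under coding {coding!r}"
        )
    X = pd.DataFrame(index=labels.index)
    X["intercept"] = 1.0
    X["carrier"] = carrier
    if covariates is not None:
        if set(covariates.index) != set(labels.index):
            raise ValueError("covariate table and labels cover different samples")
        cov = build_covariate_design(covariates.loc[labels.index], n_pcs=n_pcs)
        X[baseline_col] = labels[baseline_col].astype(float)
        X = pd.concat([X, cov], axis=1)
    return X, carrier


def assoc_segment_logistic(
    cn_column: pd.Series,
    labels: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_pcs: int | None = None,
    segment_id: str = "segment",
    coding: str = "deletion_carrier",
    inference: str = "auto",
) -> AssociationResult:
    """Adjusted odds of EULAR non-response for segment carriers.

    Outcome 1 = non-responder (EULAR class "none"). ``covariates=None`` fits
    the carrier-only model, whose OR equals the crude contingency-table OR.

    ``inference="auto"`` applies the sparse-cell rule: when any cell of the
    carrier x outcome 2x2 table holds fewer than 5 samples, Wald intervals
    from the unpenalized MLE are unreliable and the segment is fitted with
    Firth penalization instead; "mle" and "firth" force either path ("mle"
    still falls back to Firth under quasi-separation).
    """
    X, carrier = _assemble(cn_column, labels, covariates, "das28_baseline", n_pcs, coding)
    y = (labels["eular_class"] == "none").astype(float).to_numpy()
    if inference not in ("auto", "mle", "firth"):
        raise ValueError(f"unknown inference {inference!r}")
    use_firth = inference == "firth"
    if inference == "auto":
        cells = [
            ((carrier.to_numpy() == c) & (y == o)).sum() for c in (0, 1) for o in (0, 1)
        ]
        use_firth = min(cells) < 5
    fit = firth_logistic(y, X) if use_firth else fit_logistic(y, X)
    i = fit.names.index("carrier")
    beta, se, p = float(fit.beta[i]), float(fit.se[i]), float(fit.p_values[i])
    return AssociationResult(
        segment_id=segment_id,
        coding=coding,
        model="logistic_eular",
        beta=beta,
        se=se,
        p_value=max(p, np.finfo(float).tiny),
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        or_=float(np.exp(beta)),
        or_ci_low=float(np.exp(beta - Z95 * se)),
        or_ci_high=float(np.exp(beta + Z95 * se)),
        n=len(labels),
        n_carriers=int(carrier.sum()),
        method=fit.method,
    )


def assoc_segment_linear(
    cn_column: pd.Series,
    labels: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_pcs: int | None = None,
    segment_id: str = "segment",
    coding: str = "deletion_carrier",
    orientation: str = "improvement",
) -> AssociationResult:
    """Adjusted effect of segment carriage on the six-month CDAI change.

    The outcome is delta CDAI with configurable orientation: "improvement"
    (baseline − month6, the default) or "worsening" (month6 − baseline, which
    only flips the coefficient sign).
    """
    if orientation not in ("improvement", "worsening"):
        raise ValueError(f"unknown orientation {orientation!r}")
    X, carrier = _assemble(cn_column, labels, covariates, "cdai_baseline", n_pcs, coding)
    y = labels["delta_cdai"].astype(float).to_numpy()
    if orientation == "worsening":
        y = -y
    _check_design(X)
    res = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    i = list(X.columns).index("carrier")
    beta, se, p = float(res.params[i]), float(res.bse[i]), float(res.pvalues[i])
    ci = res.conf_int(alpha=0.05)
    return AssociationResult(
        segment_id=segment_id,
        coding=coding,
        model="linear_cdai",
        beta=beta,
        se=se,
        p_value=max(p, np.finfo(float).tiny),
        ci_low=float(ci[i][0]),
        ci_high=float(ci[i][1]),
        n=len(labels),
        n_carriers=int(carrier.sum()),
        method="ols",
    )


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (significance flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted


@dataclass(frozen=True)
class CrudeOr:
    or_: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane–Anscombe 0.5 added to every cell


def crude_or(n11: int, n10: int, n01: int, n00: int) -> CrudeOr:
    """Unadjusted odds ratio from a 2x2 table with a Woolf 95% CI.

    Cell layout: n11 = exposed cases, n10 = unexposed cases, n01 = exposed
    controls, n00 = unexposed controls. Any zero cell triggers the
    Haldane–Anscombe correction (0.5 added to all cells, flagged).
    """
    cells = np.array([n11, n10, n01, n00], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = float(np.sqrt((1 / cells).sum()))
    return CrudeOr(
        or_=float(or_),
        ci_low=float(np.exp(np.log(or_) - Z95 * se)),
        ci_high=float(np.exp(np.log(or_) + Z95 * se)),
        corrected=corrected,
    )


def snp_cnv_r2(
    snp_dosages: pd.DataFrame,
    snp_positions: pd.Series,
    deletion_dosage: pd.Series,
    segment_id: str,
    segment_start: int,
    segment_end: int,
    window: float = 1_000_000.0,
) -> list[TaggingResult]:
    """Squared Pearson correlation of each nearby SNP with the deletion dosage.

    SNPs whose position lies within ``window`` bp of the segment are tested;
    monomorphic SNPs report r2 = 0 with a flag. Dosages must be aligned by
    sample (snp_dosages rows = samples, columns = SNP ids).
    """
    if not snp_dosages.index.equals(deletion_dosage.index):
        raise ValueError("SNP dosages and deletion dosage are not aligned on sample_id")
    lo, hi = segment_start - window, segment_end + window
    results: list[TaggingResult] = []
    dd = deletion_dosage.to_numpy(dtype=float)
    dd_var = dd.var()
    for snp in snp_dosages.columns:
        pos = snp_positions.get(snp)
        if pos is None or not lo <= pos <= hi:
            continue
        x = snp_dosages[snp].to_numpy(dtype=float)
        if x.var() == 0 or dd_var == 0:
            results.append(TaggingResult(segment_id, snp, 0.0, window, monomorphic=True))
            continue
        r = np.corrcoef(x, dd)[0, 1]
        results.append(TaggingResult(segment_id, snp, float(r**2), window))
    return results


def associate_segments(
    matrix,
    labels: pd.DataFrame,
    covariates: pd.DataFrame | None,
    model: str = "logistic",
    n_pcs: int | None = None,
    fdr_q: float = 0.05,
    orientation: str = "improvement",
    coding: str = "auto",
) -> pd.DataFrame:
    """Test every segment of a SegmentMatrix; control FDR across segments.

    ``coding="auto"`` uses the deletion-carrier indicator when the segment has
    any deletion carrier and the duplication-carrier indicator otherwise
    (duplication-only segments have no deletion carriers to code). Segments
    that remain degenerate are skipped with a warning.
    """
    cn = matrix.to_frame()
    results: list[AssociationResult] = []
    for seg_id in cn.columns:
        col = cn[seg_id]
        use_coding = coding
        if coding == "auto":
            use_coding = "deletion_carrier" if (col <= 1).any() else "duplication_carrier"
        try:
            if model == "logistic":
                res = assoc_segment_logistic(
                    col, labels, covariates, n_pcs=n_pcs, segment_id=seg_id, coding=use_coding
                )
            elif model == "linear":
                res = assoc_segment_linear(
                    col, labels, covariates, n_pcs=n_pcs, segment_id=seg_id,
                    coding=use_coding, orientation=orientation,
                )
            else:
                raise ValueError(f"unknown model {model!r}")
        except ValueError as exc:
            if "degenerate predictor" in str(exc):
                logger.warning("segment %s skipped: %s", seg_id, exc)
                continue
            raise
        results.append(res)
    if not results:
        return pd.DataFrame(
            columns=["segment_id", "coding", "model", "beta", "se", "p_value", "ci_low",
                     "ci_high", "or_", "or_ci_low", "or_ci_high", "n", "n_carriers",
                     "method", "fdr_q", "fdr_significant"]
        ).set_index("segment_id")
    flags, adjusted = bh_fdr([r.p_value for r in results], q=fdr_q)
    results = [
        replace(r, fdr_q=float(qv), fdr_significant=bool(f))
        for r, qv, f in zip(results, adjusted, flags)
    ]
    frame = pd.DataFrame([r.__dict__ for r in results]).set_index("segment_id")
    return frame
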