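"""Imprinted-transcript calling from allelic expression ratios.

The caller builds a transcripts x samples matrix of paternal expression
ratios, ``paternal / (paternal + maternal)`` allelic coverage, with
sentinel codes for cells that fail expression filters: ``-2`` for
transcripts not expressed (RPKM below threshold) and ``-1`` for
transcripts without sufficient allele-resolved coverage (both allelic
RPM below threshold).  Per transcript, valid cells (those in [0, 1]) are
tested against the balanced ratio 0.5 with a two-sided one-sample t test
and Bonferroni correction across the tested family.  Replicates of both
reciprocal crosses are pooled into one sample set, so a strain-biased
gene — whose per-sample ratio flips around 0.5 between crosses — is not
called.  A final filter drops maternally expressed calls in
extraembryonic (EPC) samples whose transcript is expressed in adult
blood, the signature of maternal decidua contamination.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NOT_EXPRESSED = -2.0       # RPKM below threshold
NO_ALLELIC_COVERAGE = -1.0  # both allelic RPM below threshold


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def compute_rpkm(reads, exonic_kb, library_size):
    """Reads per kilobase of exon per million aligned reads."""
    exonic_kb = np.asarray(exonic_kb, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(exonic_kb <= 0):
        raise ValueError("exonic_kb must be positive")
    if np.any(library_size <= 0):
        raise ValueError("library_size must be positive")
    return np.asarray(reads, dtype=float) / (library_size / 1e6 * exonic_kb)


def compute_rpm(reads, library_size):
    """Reads per million aligned reads."""
    library_size = np.asarray(library_size, dtype=float)
    if np.any(library_size <= 0):
        raise ValueError("library_size must be positive")
    return np.asarray(reads, dtype=float) / (library_size / 1e6)


def annotate_expression(counts: pd.DataFrame, annotation) -> pd.DataFrame:
    """Attach rpkm / maternal_rpm / paternal_rpm columns to a count table."""
    kb = counts["transcript_id"].map(
        lambda t: annotation[t].exonic_kb if t in annotation else np.nan)
    if kb.isna().any():
        missing = counts.loc[kb.isna(), "transcript_id"].iloc[0]
        raise KeyError(f"transcript {missing!r} absent from annotation")
    out = counts.copy()
    out["rpkm"] = compute_rpkm(counts["total_reads"], kb, counts["library_size"])
    out["maternal_rpm"] = compute_rpm(counts["maternal_reads"], counts["library_size"])
    out["paternal_rpm"] = compute_rpm(counts["paternal_reads"], counts["library_size"])
    return out


# ---------------------------------------------------------------------------
# ratio matrix with sentinels
# ---------------------------------------------------------------------------

def paternal_ratio(rpkm: float, maternal_rpm: float, paternal_rpm: float,
                   maternal_reads: int, paternal_reads: int,
                   rpkm_min: float = 1.0, allelic_rpm_min: float = 0.5) -> float:
    """Ratio-or-sentinel for a single transcript x sample cell."""
    if rpkm < rpkm_min:
        return NOT_EXPRESSED
    if max(maternal_rpm, paternal_rpm) < allelic_rpm_min:
        return NO_ALLELIC_COVERAGE
    denom = maternal_reads + paternal_reads
    # the allelic-RPM filter guarantees denom > 0
    return paternal_reads / denom


def build_ratio_matrix(records: pd.DataFrame, rpkm_min: float = 1.0,
                       allelic_rpm_min: float = 0.5) -> pd.DataFrame:
    """Transcripts x samples matrix of paternal ratios and sentinels.

    ``records`` must carry rpkm / maternal_rpm / paternal_rpm (see
    :func:`annotate_expression`).
    """
    df = records.copy()
    denom = (df["maternal_reads"] + df["paternal_reads"]).to_numpy(dtype=float)
    ratio = np.divide(df["paternal_reads"].to_numpy(dtype=float), denom,
                      out=np.full(len(df), 0.5), where=denom > 0)
    cell = np.where(
        df["rpkm"].to_numpy() < rpkm_min, NOT_EXPRESSED,
        np.where(np.maximum(df["maternal_rpm"], df["paternal_rpm"]) < allelic_rpm_min,
                 NO_ALLELIC_COVERAGE, ratio))
    df["cell"] = cell
    mat = df.pivot_table(index="transcript_id", columns="sample_id",
                         values="cell", aggfunc="first")
    return mat.fillna(NOT_EXPRESSED).sort_index()


def valid_mask(matrix: pd.DataFrame) -> pd.DataFrame:
    """True where a cell is a real ratio (in [0, 1]), not a sentinel."""
    return (matrix >= 0.0) & (matrix <= 1.0)


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------

def bonferroni_adjust(p, m: int):
    """min(1, p * m)."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def _one_sample_t(values: np.ndarray, null: float = 0.5) -> float:
    """Two-sided one-sample t p-value against ``null``.

    Zero-variance limit: p = 0 when the common value differs from the
    null, p = 1 when it equals it.
    """
    n = len(values)
    if n < 2:
        return np.nan
    if np.ptp(values) == 0.0:
        return 0.0 if values[0] != null else 1.0
    return float(stats.ttest_1samp(values, null).pvalue)


def call_imprinted_ttest(matrix: pd.DataFrame, tissue: str = "",
                         min_valid: int = 6, alpha: float = 0.05,
                         family: str = "tested") -> pd.DataFrame:
    """Per-transcript one-sample t tests of paternal ratio against 0.5.

    Transcripts with at least one valid cell are tested; the Bonferroni
    family size ``m`` is, by default, the number of transcripts with
    ``>= min_valid`` valid samples (``family="tested"``); with
    ``family="filtered"`` it is every transcript with >= 1 valid sample.
    Status ``paternal``/``maternal`` requires adjusted p < ``alpha`` AND
    ``n_valid_samples >= min_valid``; transcripts with fewer valid
    samples are ``not_testable``; the rest are ``biallelic``.
    """
    valid = valid_mask(matrix)
    n_valid = valid.sum(axis=1)

    rows = []
    for tid in matrix.index:
        cells = matrix.loc[tid, valid.loc[tid]].to_numpy(dtype=float)
        if len(cells) == 0:
            continue
        rows.append((tid, len(cells), float(np.mean(cells)),
                     _one_sample_t(cells)))
    calls = pd.DataFrame(rows, columns=["transcript_id", "n_valid_samples",
                                        "mean_ratio", "raw_p"])
    if calls.empty:
        calls["adj_p"] = calls["status"] = calls["tissue"] = calls["test"] = None
        return calls

    if family == "tested":
        m = int((calls["n_valid_samples"] >= min_valid).sum())
    elif family == "filtered":
        m = len(calls)
    else:
        raise ValueError(f"unknown Bonferroni family {family!r}")
    m = max(m, 1)
    logger.info("Bonferroni family size m=%d (%s)", m, family)
    calls["adj_p"] = bonferroni_adjust(calls["raw_p"], m)

    testable = calls["n_valid_samples"] >= min_valid
    significant = testable & (calls["adj_p"] < alpha) & calls["raw_p"].notna()
    status = np.where(~testable, "not_testable",
                      np.where(~significant, "biallelic",
                               np.where(calls["mean_ratio"] > 0.5,
                                        "paternal", "maternal")))
    # a significant mean exactly at 0.5 cannot occur (t statistic is 0)
    calls["status"] = status
    calls["tissue"] = tissue
    calls["test"] = "t_test"
    calls["flags"] = ""
    return calls


def decidua_filter(calls: pd.DataFrame, blood_rpkm: pd.Series,
                   threshold: float = 1.0) -> pd.DataFrame:
    """Flag maternal EPC calls expressed in adult blood.

    Maternal calls in EPC with blood RPKM above ``threshold`` receive the
    ``blood_expressed`` flag and are excluded from the final maternal
    list (rows are retained, flagged).  Transcripts absent from the blood
    table are treated as unexpressed (RPKM 0) and logged.
    """
    out = calls.copy()
    missing = ~out["transcript_id"].isin(blood_rpkm.index)
    if missing.any():
        logger.warning("%d transcripts missing from blood table; treated as "
                       "RPKM 0", int(missing.sum()))
    rpkm = out["transcript_id"].map(blood_rpkm).fillna(0.0)
    hit = ((out["status"] == "maternal") & (out["tissue"] == "EPC")
           & (rpkm > threshold))
    out.loc[hit, "flags"] = out.loc[hit, "flags"].where(
        out.loc[hit, "flags"] == "", out.loc[hit, "flags"] + ",")
    out.loc[hit, "flags"] = out.loc[hit, "flags"] + "blood_expressed"
    return out


def final_imprinted(calls: pd.DataFrame) -> pd.DataFrame:
    """Imprinted calls after removing blood-flagged maternal EPC calls."""
    keep = calls["status"].isin(["paternal", "maternal"])
    keep &= ~calls["flags"].str.contains("blood_expressed", na=False)
    return calls[keep].reset_index(drop=True)
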