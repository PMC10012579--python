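"""X chromosome inactivation skew from paternal-ratio distributions.

For each sample the paternal expression ratios of X-linked transcripts
are compared to autosomal ones (sentinel cells excluded).  Imprinted
paternal-X inactivation — the silencing of the paternal X in rodent
extraembryonic lineages — shows as an X distribution shifted well below
the autosomal centre of 0.5.  A Wilcoxon rank-sum location test makes
the skew call assertable; samples with near-zero valid X coverage (an
XO-genotype signature) are flagged for QC rather than auto-excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allelic_expression import valid_mask

logger = logging.getLogger(__name__)


@dataclass
class XciSummary:
    sample_id: str
    mean_autosome: float
    median_autosome: float
    n_autosome: int
    mean_x: float
    median_x: float
    n_x: int
    statistic: float
    p: float
    direction: str            # paternal_X_inactivated / maternal_X_inactivated / none
    flags: str = ""


def chrom_class_ratios(matrix: pd.DataFrame, annotation,
                       x_chrom: str = "chrX") -> dict[str, dict[str, np.ndarray]]:
    """Valid paternal ratios per sample split into autosomal vs X-linked."""
    chrom = pd.Series({t: annotation[t].chrom for t in matrix.index
                       if t in annotation})
    missing = matrix.index.difference(chrom.index)
    if len(missing):
        raise KeyError(f"transcript {missing[0]!r} absent from annotation")
    is_x = (chrom == x_chrom).reindex(matrix.index).to_numpy()
    valid = valid_mask(matrix)
    out: dict[str, dict[str, np.ndarray]] = {}
    for sample in matrix.columns:
        v = valid[sample].to_numpy()
        cells = matrix[sample].to_numpy(dtype=float)
        out[sample] = {
            "autosome": cells[v & ~is_x],
            "x": cells[v & is_x],
        }
    return out


def xci_skew_test(autosome: np.ndarray, x: np.ndarray, alpha: float = 0.05,
                  min_x: int = 10, min_autosome: int = 50
                  ) -> tuple[float, float, str]:
    """Rank-sum location test of X vs autosomal per-transcript ratios.

    Returns (statistic, p, direction); direction is
    ``paternal_X_inactivated`` when significant with the X mean below the
    autosomal mean, ``maternal_X_inactivated`` for the mirror, ``none``
    otherwise.  Raises when transcript counts are insufficient.
    """
    if len(x) < min_x or len(autosome) < min_autosome:
        raise ValueError(
            f"insufficient transcripts (X {len(x)} < {min_x} or autosome "
            f"{len(autosome)} < {min_autosome})")
    res = stats.mannwhitneyu(x, autosome, alternative="two-sided")
    direction = "none"
    if res.pvalue < alpha:
        direction = ("paternal_X_inactivated"
                     if np.mean(x) < np.mean(autosome)
                     else "maternal_X_inactivated")
    return float(res.statistic), float(res.pvalue), direction


def summarize_xci(matrix: pd.DataFrame, annotation, x_chrom: str = "chrX",
                  alpha: float = 0.05, min_x: int = 10, min_autosome: int = 50
                  ) -> list[XciSummary]:
    """Per-sample XCI summaries over a paternal-ratio matrix."""
    classes = chrom_class_ratios(matrix, annotation, x_chrom=x_chrom)
    summaries = []
    for sample, d in classes.items():
        auto, x = d["autosome"], d["x"]
        flags = ""
        if len(x) == 0:
            logger.warning("%s: no valid X-linked cells (possible XO genotype)",
                           sample)
            flags = "no_valid_x"
        try:
            statistic, p, direction = xci_skew_test(
                auto, x, alpha=alpha, min_x=min_x, min_autosome=min_autosome)
        except ValueError:
            statistic, p, direction = float("nan"), float("nan"), "not_testable"
            if len(x) < min_x and not flags:
                flags = "low_x_coverage"
        summaries.append(XciSummary(
            sample_id=sample,
            mean_autosome=float(np.mean(auto)) if len(auto) else float("nan"),
            median_autosome=float(np.median(auto)) if len(auto) else float("nan"),
            n_autosome=len(auto),
            mean_x=float(np.mean(x)) if len(x) else float("nan"),
            median_x=float(np.median(x)) if len(x) else float("nan"),
            n_x=len(x),
            statistic=statistic, p=p, direction=direction, flags=flags))
    return summaries


def xci_table(summaries: list[XciSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
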