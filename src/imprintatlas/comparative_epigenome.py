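"""Cross-species comparison of oocyte epigenomes over syntenic 1-kb bins.

Tracks from two genomes are joined through a synteny map into one row
per syntenic bin pair, compared by Spearman rank correlation, screened
for species-specific H3K27me3 (a K27 excess in one genome with a
reciprocal DNA-methylation excess in the other), and segmented into
mark domains by thresholding and 3-kb gap grouping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError


# ---------------------------------------------------------------------------
# paired bins
# ---------------------------------------------------------------------------

def pair_tracks(synteny: pd.DataFrame,
                tracks_a: dict[str, pd.DataFrame],
                tracks_b: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """One row per syntenic pair with ``<mark>_a`` / ``<mark>_b`` levels.

    Pairs missing a value for any provided mark are dropped; the count of
    dropped pairs is stored in ``.attrs["n_dropped"]``.
    """
    out = synteny.copy()
    n = len(out)
    for side, tracks in (("a", tracks_a), ("b", tracks_b)):
        for mark, track in tracks.items():
            key = track.set_index(["chrom", "start"])["value"]
            idx = pd.MultiIndex.from_frame(out[[f"chrom_{side}", f"start_{side}"]])
            out[f"{mark}_{side}"] = key.reindex(idx).to_numpy()
    out = out.dropna().reset_index(drop=True)
    out.attrs["n_dropped"] = n - len(out)
    return out


def spearman_corr(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def species_specific_bins(paired: pd.DataFrame, k27_delta_min: float = 0.5,
                          dname_delta_min: float = 75.0,
                          k27: str = "H3K27me3", dname: str = "DNAme"
                          ) -> tuple[int, int, float]:
    """Counts of genome-specific H3K27me3 bins and their ratio.

    A bin is A-specific when K27(A) - K27(B) > ``k27_delta_min`` RPKM and
    DNAme(B) - DNAme(A) > ``dname_delta_min`` points; B-specific is the
    mirror.  Ratio is countA / countB (nan when countB is 0).
    """
    dk27 = paired[f"{k27}_a"] - paired[f"{k27}_b"]
    ddna = paired[f"{dname}_a"] - paired[f"{dname}_b"]
    count_a = int(((dk27 > k27_delta_min) & (-ddna > dname_delta_min)).sum())
    count_b = int(((-dk27 > k27_delta_min) & (ddna > dname_delta_min)).sum())
    ratio = count_a / count_b if count_b else float("nan")
    return count_a, count_b, ratio


# ---------------------------------------------------------------------------
# domain calling
# ---------------------------------------------------------------------------

def call_domains(track: pd.DataFrame, level_min: float | None = None,
                 level_percentile: float = 90.0,
                 group_gap: int = 3000) -> pd.DataFrame:
    """Maximal runs of enriched bins, merged across gaps <= ``group_gap``.

    ``level_min`` defaults to the ``level_percentile``-th percentile of
    nonzero bin levels.  Returns (chrom, start, end, mean_level) with a
    size summary in ``.attrs`` (mean/median width in bp).
    """
    if level_min is None:
        nonzero = track.loc[track["value"] > 0, "value"]
        if nonzero.empty:
            out = pd.DataFrame(columns=["chrom", "start", "end", "mean_level"])
            out.attrs.update(mean_size=float("nan"), median_size=float("nan"))
            return out
        level_min = float(np.percentile(nonzero, level_percentile))
    rows = []
    for chrom, sub in track.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        enr = sub[sub["value"] >= level_min]
        if enr.empty:
            continue
        starts = enr["start"].to_numpy()
        ends = enr["end"].to_numpy()
        vals = enr["value"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        cur_vals = [vals[0]]
        for s, e, v in zip(starts[1:], ends[1:], vals[1:]):
            if s - cur_e <= group_gap:
                cur_e = max(cur_e, int(e))
                cur_vals.append(v)
            else:
                rows.append((chrom, cur_s, cur_e, float(np.mean(cur_vals))))
                cur_s, cur_e, cur_vals = int(s), int(e), [v]
        rows.append((chrom, cur_s, cur_e, float(np.mean(cur_vals))))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_level"])
    widths = (out["end"] - out["start"]).to_numpy()
    out.attrs["mean_size"] = float(np.mean(widths)) if len(widths) else float("nan")
    out.attrs["median_size"] = float(np.median(widths)) if len(widths) else float("nan")
    return out


def compare_domain_sizes(domains_a: pd.DataFrame, domains_b: pd.DataFrame
                         ) -> tuple[float, float]:
    """(mean_A - mean_B in bp, percent smaller relative to A).

    Positive values mean B's domains are smaller: a (10000, 37.0) result
    reads "B's domains are on average 10 kb (37%) smaller than A's".
    """
    if domains_a.empty or domains_b.empty:
        raise ValueError("both domain sets must be non-empty")
    mean_a = float((domains_a["end"] - domains_a["start"]).mean())
    mean_b = float((domains_b["end"] - domains_b["start"]).mean())
    return mean_a - mean_b, 100.0 * (mean_a - mean_b) / mean_a
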