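"""Parent-of-origin DMR calling from allele-resolved CpG methylation.

Replicates and reciprocal crosses are assumed pooled upstream (counts
summed per CpG per allele).  Per CpG the caller computes a
coverage-weighted smoothed methylation fraction per parental allele
(moving window, +/- span/2), the smoothed maternal-paternal delta in
percentage points, and a Fisher exact p-value on the pooled raw counts.
Candidate CpGs (delta above threshold, p below threshold) are grouped
greedily along each chromosome into DMRs; per-tissue DMR sets are then
interval-union merged.  Each DMR is summarised against gamete (oocyte,
sperm) and tissue-allele methylomes and classified by origin:

``gametic_maternal``/``gametic_paternal``
    the gamete delta and tissue allelic delta both reach the threshold in
    the same direction — a germline imprint maintained in the embryo;
``gametes_hypermethylated``
    both gametes above the hypermethylation cutoff (no gametic asymmetry
    to inherit);
``somatic_maternal``/``somatic_paternal``
    no gametic asymmetry, but a tissue allelic delta — methylation
    acquired after fertilization, the DNAme signature of non-canonical
    imprinting;
``ambiguous`` otherwise.

Precedence: gametic > gametes_hypermethylated > somatic > ambiguous.
A final filter keeps DMRs where every required sample is covered by at
least 2 CpGs and the tissue parental delta is >= 50 percentage points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Dmr

GAMETIC_ORIGINS = ("gametic_maternal", "gametic_paternal")
SOMATIC_ORIGINS = ("somatic_maternal", "somatic_paternal")


# ---------------------------------------------------------------------------
# per-CpG statistics
# ---------------------------------------------------------------------------

def pool_counts(cpgs: pd.DataFrame, allele: str) -> pd.DataFrame:
    """Sum meth/unmeth counts per (chrom, pos) for one allele label."""
    sub = cpgs[cpgs["allele"] == allele]
    return (sub.groupby(["chrom", "pos"], sort=True)
            [["meth_reads", "unmeth_reads"]].sum().reset_index())


def smooth_methylation(pos: np.ndarray, meth: np.ndarray, cov: np.ndarray,
                       span: int = 500) -> np.ndarray:
    """Coverage-weighted moving-average methylation fraction.

    Each CpG's smoothed fraction is the coverage-weighted mean of raw
    fractions of CpGs within +/- span/2 (inclusive); an isolated CpG
    keeps its raw fraction.  Positions must be sorted; coverage must be
    positive for included CpGs.
    """
    pos = np.asarray(pos, dtype=np.int64)
    meth = np.asarray(meth, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if len(pos) == 0:
        return np.zeros(0)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    half = span / 2.0
    cm = np.concatenate([[0.0], np.cumsum(meth)])
    cc = np.concatenate([[0.0], np.cumsum(cov)])
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    wm = cm[hi] - cm[lo]
    wc = cc[hi] - cc[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(wc > 0, wm / wc, 0.0)


def cpg_stats(maternal: pd.DataFrame, paternal: pd.DataFrame,
              span: int = 500, delta_min: float = 10.0,
              p_max: float = 1e-3) -> pd.DataFrame:
    """Join pooled allelic counts, smooth, test, and flag candidate CpGs.

    Only CpGs covered on both alleles are testable.  The delta is
    computed on smoothed fractions; the p-value is a two-sided Fisher
    exact test on the pooled raw 2x2 counts, evaluated only where the
    delta passes (candidacy requires both).
    """
    m = maternal.rename(columns={"meth_reads": "m_meth", "unmeth_reads": "m_unmeth"})
    p = paternal.rename(columns={"meth_reads": "p_meth", "unmeth_reads": "p_unmeth"})
    df = m.merge(p, on=["chrom", "pos"], how="inner")
    df["m_cov"] = df["m_meth"] + df["m_unmeth"]
    df["p_cov"] = df["p_meth"] + df["p_unmeth"]
    df = df[(df["m_cov"] > 0) & (df["p_cov"] > 0)].reset_index(drop=True)

    parts = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("pos").reset_index(drop=True)
        sm = smooth_methylation(sub["pos"].to_numpy(),
                                sub["m_meth"].to_numpy(),
                                sub["m_cov"].to_numpy(), span)
        sp = smooth_methylation(sub["pos"].to_numpy(),
                                sub["p_meth"].to_numpy(),
                                sub["p_cov"].to_numpy(), span)
        sub["m_smooth"] = sm
        sub["p_smooth"] = sp
        sub["delta"] = np.abs(sm - sp) * 100.0
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True) if parts else df.assign(
        m_smooth=[], p_smooth=[], delta=[])

    pvals = np.ones(len(out))
    over = out.index[out["delta"] > delta_min]
    for i in over:
        r = out.loc[i]
        table = [[int(r["m_meth"]), int(r["m_unmeth"])],
                 [int(r["p_meth"]), int(r["p_unmeth"])]]
        pvals[i] = stats.fisher_exact(table).pvalue
    out["p"] = pvals
    out["candidate"] = (out["delta"] > delta_min) & (out["p"] < p_max)
    return out


def test_cpg_diff(m_meth: int, m_unmeth: int, p_meth: int, p_unmeth: int,
                  m_smooth: float | None = None, p_smooth: float | None = None
                  ) -> tuple[float, float]:
    """(p, delta) for one CpG: Fisher exact on raw counts, delta (percent)
    on smoothed fractions when given, raw fractions otherwise."""
    if m_meth + m_unmeth < 1 or p_meth + p_unmeth < 1:
        raise ValueError("both alleles need coverage >= 1")
    if m_smooth is None:
        m_smooth = m_meth / (m_meth + m_unmeth)
    if p_smooth is None:
        p_smooth = p_meth / (p_meth + p_unmeth)
    delta = abs(m_smooth - p_smooth) * 100.0
    p = stats.fisher_exact([[m_meth, m_unmeth], [p_meth, p_unmeth]]).pvalue
    return float(p), float(delta)


# ---------------------------------------------------------------------------
# grouping into DMRs
# ---------------------------------------------------------------------------

def call_dmrs(cpg_stats_df: pd.DataFrame, min_cpgs: int = 3,
              max_gap: int = 300, min_len: int = 50) -> list[Dmr]:
    """Group candidate CpGs into DMRs along each chromosome.

    Candidates separated by <= ``max_gap`` bp join one group; groups with
    >= ``min_cpgs`` candidates spanning >= ``min_len`` bp become DMRs
    with interval [first candidate, last candidate + 2) (the CpG dyad).
    Output order is (chrom, start) regardless of input row order.
    """
    cand = cpg_stats_df[cpg_stats_df["candidate"]]
    dmrs: list[Dmr] = []
    for chrom, sub in cand.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.where(np.diff(pos) > max_gap)[0] + 1
        for block_idx in np.split(np.arange(len(pos)), breaks):
            bpos = pos[block_idx]
            if len(bpos) < min_cpgs:
                continue
            start, end = int(bpos[0]), int(bpos[-1]) + 2
            if end - start < min_len:
                continue
            dmrs.append(Dmr(chrom=str(chrom), start=start, end=end,
                            n_cpg=len(bpos),
                            max_delta=float(delta[block_idx].max())))
    return dmrs


def merge_dmr_sets(*dmr_sets: list[Dmr]) -> list[Dmr]:
    """Interval-union merge of per-tissue DMR sets (bedtools-merge style)."""
    by_chrom: dict[str, list[Dmr]] = {}
    for dset in dmr_sets:
        for d in dset:
            by_chrom.setdefault(d.chrom, []).append(d)
    merged: list[Dmr] = []
    for chrom in sorted(by_chrom):
        ds = sorted(by_chrom[chrom], key=lambda d: (d.start, d.end))
        cur = ds[0]
        cur_start, cur_end = cur.start, cur.end
        cur_n, cur_delta = cur.n_cpg, cur.max_delta
        tissues = set(cur.tissues)
        for d in ds[1:]:
            if d.start <= cur_end:
                cur_end = max(cur_end, d.end)
                cur_n = max(cur_n, d.n_cpg)
                cur_delta = max(cur_delta, d.max_delta)
                tissues.update(d.tissues)
            else:
                merged.append(Dmr(chrom=chrom, start=cur_start, end=cur_end,
                                  n_cpg=cur_n, max_delta=cur_delta,
                                  tissues=tuple(sorted(tissues))))
                cur_start, cur_end = d.start, d.end
                cur_n, cur_delta = d.n_cpg, d.max_delta
                tissues = set(d.tissues)
        merged.append(Dmr(chrom=chrom, start=cur_start, end=cur_end,
                          n_cpg=cur_n, max_delta=cur_delta,
                          tissues=tuple(sorted(tissues))))
    return merged


# ---------------------------------------------------------------------------
# summarising and classifying
# ---------------------------------------------------------------------------

def summarize_dmr_allelic_meth(dmr: Dmr, cpgs: pd.DataFrame,
                               min_total_cov: int = 5,
                               min_allelic_cov: int = 1) -> Dmr:
    """Attach per-sample mean methylation (percent) over the DMR interval.

    CpGs contribute when covered by at least ``min_total_cov`` reads for
    total tracks or ``min_allelic_cov`` for allele-resolved tracks
    (gametes count as allelic).  Means are unweighted across contributing
    CpGs; a sample with no covered CpG gets count 0 and no mean.
    """
    sub = cpgs[(cpgs["chrom"] == dmr.chrom) & (cpgs["pos"] >= dmr.start)
               & (cpgs["pos"] < dmr.end)]
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for (sample, allele), grp in sub.groupby(["sample_id", "allele"], sort=True):
        cov = grp["meth_reads"] + grp["unmeth_reads"]
        min_cov = min_total_cov if allele == "total" else min_allelic_cov
        covered = grp[cov >= min_cov]
        key = sample if sample == allele else f"{sample}_{allele}"
        counts[key] = len(covered)
        if len(covered):
            frac = covered["meth_reads"] / (covered["meth_reads"]
                                            + covered["unmeth_reads"])
            means[key] = float(frac.mean() * 100.0)
    dmr.means = means
    dmr.cpg_counts = counts
    return dmr


def classify_dmr_origin(dmr: Dmr, tissues: tuple[str, ...] = ("epiblast", "EPC"),
                        gamete_delta_min: float = 50.0,
                        hyper_min: float = 75.0) -> str:
    """Origin class from gamete and tissue-allele methylation means."""
    m = dmr.means
    if "oocyte" not in m or "sperm" not in m:
        dmr.origin = "ambiguous"
        dmr.tissues = dmr.tissues or ()
        return dmr.origin
    oo, sp = m["oocyte"], m["sperm"]
    gamete_delta = oo - sp

    def tissue_delta(tissue: str) -> float | None:
        mk, pk = f"{tissue}_maternal", f"{tissue}_paternal"
        if mk in m and pk in m:
            return m[mk] - m[pk]
        return None

    deltas = {t: tissue_delta(t) for t in tissues}
    support_mat = [t for t, dl in deltas.items()
                   if dl is not None and dl >= gamete_delta_min]
    support_pat = [t for t, dl in deltas.items()
                   if dl is not None and -dl >= gamete_delta_min]

    if gamete_delta >= gamete_delta_min and support_mat:
        dmr.origin = "gametic_maternal"
        dmr.tissues = tuple(support_mat)
    elif -gamete_delta >= gamete_delta_min and support_pat:
        dmr.origin = "gametic_paternal"
        dmr.tissues = tuple(support_pat)
    elif oo >= hyper_min and sp >= hyper_min:
        dmr.origin = "gametes_hypermethylated"
    elif abs(gamete_delta) < gamete_delta_min and support_mat:
        dmr.origin = "somatic_maternal"
        dmr.tissues = tuple(support_mat)
    elif abs(gamete_delta) < gamete_delta_min and support_pat:
        dmr.origin = "somatic_paternal"
        dmr.tissues = tuple(support_pat)
    else:
        dmr.origin = "ambiguous"
    return dmr.origin


def final_filter(dmrs: list[Dmr], required_samples: tuple[str, ...],
                 tissues: tuple[str, ...] = ("epiblast", "EPC"),
                 min_cpgs_all: int = 2, delta_min: float = 50.0) -> list[Dmr]:
    """Keep DMRs with >= ``min_cpgs_all`` covered CpGs in every required
    sample and a tissue parental delta >= ``delta_min`` in some tissue."""
    kept = []
    for d in dmrs:
        if any(d.cpg_counts.get(s, 0) < min_cpgs_all for s in required_samples):
            continue
        deltas = []
        for t in tissues:
            mk, pk = f"{t}_maternal", f"{t}_paternal"
            if mk in d.means and pk in d.means:
                deltas.append(abs(d.means[mk] - d.means[pk]))
        if deltas and max(deltas) >= delta_min:
            kept.append(d)
    return kept


# ---------------------------------------------------------------------------
# pipeline convenience
# ---------------------------------------------------------------------------

def call_parent_of_origin_dmrs(cpgs: pd.DataFrame,
                               tissues: tuple[str, ...] = ("epiblast", "EPC"),
                               span: int = 500, delta_min: float = 10.0,
                               p_max: float = 1e-3, min_cpgs: int = 3,
                               max_gap: int = 300, min_len: int = 50,
                               gamete_delta_min: float = 50.0,
                               hyper_min: float = 75.0,
                               final_min_cpgs: int = 2,
                               final_delta_min: float = 50.0,
                               apply_final_filter: bool = True) -> list[Dmr]:
    """End-to-end caller: per-tissue DMRs, union merge, gamete
    integration, origin classification, final coverage/delta filter."""
    per_tissue = []
    for tissue in tissues:
        sub = cpgs[cpgs["sample_id"] == tissue]
        st = cpg_stats(pool_counts(sub, "maternal"), pool_counts(sub, "paternal"),
                       span=span, delta_min=delta_min, p_max=p_max)
        ds = call_dmrs(st, min_cpgs=min_cpgs, max_gap=max_gap, min_len=min_len)
        for d in ds:
            d.tissues = (tissue,)
        per_tissue.append(ds)
    merged = merge_dmr_sets(*per_tissue)
    for d in merged:
        summarize_dmr_allelic_meth(d, cpgs)
        classify_dmr_origin(d, tissues=tissues,
                            gamete_delta_min=gamete_delta_min,
                            hyper_min=hyper_min)
    if not apply_final_filter:
        return merged
    required = ["oocyte", "sperm"]
    for t in tissues:
        required += [f"{t}_maternal", f"{t}_paternal"]
    return final_filter(merged, tuple(required), tissues=tissues,
                        min_cpgs_all=final_min_cpgs, delta_min=final_delta_min)
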