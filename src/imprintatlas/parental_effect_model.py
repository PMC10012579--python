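"""Per-gene linear model of allelic log-expression with variance moderation.

Each expressed allele of each sample contributes one observation of
``log2(allelic RPM + pseudocount)``.  The design codes parent of origin
(paternal +1 / maternal -1) and strain identity (+1 / -1); because the
strain of a fixed parental allele flips between reciprocal crosses, the
two covariates are identifiable jointly — this is exactly what the
reciprocal design buys.  ``beta_parent`` is reported as the paternal
minus maternal log2 difference (twice the +/-1 coefficient), so a
4-fold allelic change corresponds to ``|beta_parent| >= 2``.

Residual variances are shrunk toward a common prior by empirical Bayes:
gene variances are modelled as scaled inverse chi-square draws around a
prior ``s0^2`` with prior degrees of freedom ``d0``, both estimated by
method of moments on log variances (the classic moderated-t
construction).  Moderated statistics use the posterior variance
``(d0 s0^2 + d s^2) / (d0 + d)`` on ``d0 + d`` degrees of freedom; with
a single parent contrast the F statistic equals the squared moderated t,
so a two-sided moderated t is used.  Benjamini-Hochberg control and a
>= 4-fold allelic-change gate produce the final calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def build_design(records: pd.DataFrame, pseudocount: float = 0.5,
                 allelic_rpm_min: float = 0.5, min_reps_per_cross: int = 2
                 ) -> pd.DataFrame:
    """Long table of allelic observations for genes passing the filter.

    A gene is kept when at least ``min_reps_per_cross`` replicates in
    *both* crosses have allelic RPM >= ``allelic_rpm_min`` on either
    allele.  Each passing (gene, sample) yields two rows, one per
    allele, with parent and strain covariates coded +/-1.  ``records``
    must carry maternal_rpm / paternal_rpm (see
    :func:`imprintatlas.allelic_expression.annotate_expression`).
    """
    df = records.copy()
    df["covered"] = (np.maximum(df["maternal_rpm"], df["paternal_rpm"])
                     >= allelic_rpm_min)
    per_cross = (df[df["covered"]]
                 .groupby(["transcript_id", "cross"])["sample_id"].nunique()
                 .unstack(fill_value=0))
    n_crosses = df["cross"].nunique()
    if per_cross.empty:
        passing: set = set()
    else:
        ok = (per_cross >= min_reps_per_cross).sum(axis=1) == n_crosses
        passing = set(per_cross.index[ok])

    kept = df[df["transcript_id"].isin(passing) & df["covered"]]
    rows = []
    for r in kept.itertuples(index=False):
        maternal_strain = r.cross.split("x")[0]
        paternal_strain = r.cross.split("x")[1]
        for parent, strain, rpm in (
                ("maternal", maternal_strain, r.maternal_rpm),
                ("paternal", paternal_strain, r.paternal_rpm)):
            rows.append((r.transcript_id, r.sample_id, r.cross, r.tissue,
                         parent, strain,
                         1.0 if parent == "paternal" else -1.0,
                         1.0 if strain == sorted({maternal_strain,
                                                  paternal_strain})[1] else -1.0,
                         np.log2(rpm + pseudocount)))
    return pd.DataFrame(rows, columns=[
        "gene_id", "sample_id", "cross", "tissue", "allele_parent",
        "allele_strain", "x_parent", "x_strain", "log2_expr"])


# ---------------------------------------------------------------------------
# per-gene least squares
# ---------------------------------------------------------------------------

@dataclass
class GeneFit:
    gene_id: str
    beta_parent: float      # log2 paternal - maternal
    beta_strain: float      # log2 strain B - strain A
    s2: float               # residual variance
    df_resid: int
    se2_unscaled: float     # Var(beta_parent) / sigma^2 (design leverage x 4)
    testable: bool = True


def fit_parental_model(obs: pd.DataFrame) -> GeneFit:
    """Ordinary least squares of log2 allelic expression on parent + strain."""
    gene = str(obs["gene_id"].iloc[0])
    X = np.column_stack([np.ones(len(obs)),
                         obs["x_parent"].to_numpy(),
                         obs["x_strain"].to_numpy()])
    y = obs["log2_expr"].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1] or len(y) <= X.shape[1]:
        return GeneFit(gene, np.nan, np.nan, np.nan, 0, np.nan, testable=False)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    d = len(y) - rank
    s2 = float(resid @ resid / d)
    xtx_inv = np.linalg.inv(X.T @ X)
    # contrast (paternal - maternal) = 2 * coef_parent -> leverage x 4
    return GeneFit(gene, 2.0 * float(coef[1]), 2.0 * float(coef[2]), s2, d,
                   4.0 * float(xtx_inv[1, 1]))


def fit_all_genes(design: pd.DataFrame) -> list[GeneFit]:
    return [fit_parental_model(g) for _, g in design.groupby("gene_id", sort=True)]


# ---------------------------------------------------------------------------
# empirical Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(s2, d) -> tuple[float, float, np.ndarray]:
    """Estimate prior df ``d0`` and prior variance ``s0^2``; shrink.

    Method of moments on ``log s^2``: for s^2 ~ s0^2 * (chi2_d / d) *
    (d0 / chi2_d0), ``e = log s2 - digamma(d/2) + log(d/2)`` has mean
    ``log s0^2 + digamma(d0/2) - log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` over ``trigamma(d/2)``.  Returns
    ``(d0, s0^2, posterior variances)``; ``d0 = inf`` (all variances
    identical, or no excess spread) collapses every posterior variance to
    ``s0^2``.
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    ok = (d > 0) & np.isfinite(s2)
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with positive residual df")
    z = np.log(np.maximum(s2[ok], 1e-300))
    e = z - special.digamma(d[ok] / 2.0) + np.log(d[ok] / 2.0)
    n = len(e)
    evar = float(np.var(e, ddof=1)) - float(
        np.mean(special.polygamma(1, d[ok] / 2.0)))
    if evar <= 0:
        # no excess spread over sampling noise: infinite prior df, full
        # shrinkage; with literally identical variances s0^2 is that value
        d0 = np.inf
        if np.ptp(s2[ok]) == 0.0:
            s0_2 = float(s2[ok][0])
        else:
            s0_2 = float(np.exp(np.mean(e)))
        post = np.full_like(s2, s0_2)
        return d0, s0_2, post
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0)
                        - np.log(d0 / 2.0)))
    post = (d0 * s0_2 + d * s2) / (d0 + d)
    return float(d0), s0_2, post


def moderated_tests(fits: list[GeneFit]) -> pd.DataFrame:
    """Moderated t statistics and raw/BH-adjusted p-values per gene."""
    rows = [f for f in fits if f.testable]
    if len(rows) < 2:
        raise ValueError("too few testable genes for variance moderation")
    s2 = np.array([f.s2 for f in rows])
    d = np.array([f.df_resid for f in rows], dtype=float)
    d0, s0_2, post = moderate_variances(s2, d)
    beta = np.array([f.beta_parent for f in rows])
    lev = np.array([f.se2_unscaled for f in rows])
    t = beta / np.sqrt(post * lev)
    if np.isfinite(d0):
        df_total = d + d0
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        df_total = np.full_like(d, np.inf)
        p = 2.0 * stats.norm.sf(np.abs(t))
    out = pd.DataFrame({
        "gene_id": [f.gene_id for f in rows],
        "beta_parent": beta,
        "beta_strain": [f.beta_strain for f in rows],
        "s2": s2, "df_resid": d, "s2_post": post,
        "moderated_t": t, "df_total": df_total, "raw_p": p,
    })
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    out["adj_p"] = bh_adjust(out["raw_p"].to_numpy())
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_imprinted_lm(tests: pd.DataFrame, alpha: float = 0.05,
                      min_fc: float = 4.0) -> pd.DataFrame:
    """Final linear-model calls: BH-adjusted p < alpha AND >= min_fc-fold
    allelic change; direction by the sign of the parental effect."""
    min_lfc = np.log2(min_fc)
    out = tests.copy()
    called = (out["adj_p"] < alpha) & (np.abs(out["beta_parent"]) >= min_lfc)
    out["status"] = np.where(~called, "biallelic",
                             np.where(out["beta_parent"] > 0,
                                      "paternal", "maternal"))
    out["test"] = "linear_model"
    return out
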