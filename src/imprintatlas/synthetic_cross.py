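"""Synthetic reciprocal F1 hybrid datasets with known truth.

Three generators emulate the data structures the imprinting inference
consumes:

* ``simulate_reciprocal_expression`` — per-transcript allelic read counts
  for two reciprocal crosses of two inbred strains, two tissues
  (embryonic epiblast and extraembryonic ectoplacental cone, EPC), with
  negative-binomial totals and beta-binomial allelic splits;
* ``simulate_methylomes`` — allele-resolved CpG methylation for gametes
  (oocyte, sperm) and both tissues, with planted gametic and
  post-fertilization (somatic) differentially methylated regions;
* ``simulate_mark_tracks`` — paired 1-kb binned histone-mark/DNAme tracks
  for two genomes joined by a synteny map, with planted species-specific
  H3K27me3 domains.

Every generator is deterministic under ``SimConfig.seed`` and returns a
``SimTruth`` describing exactly what was planted.

Imprinted classes follow the biology being modelled: a paternally
expressed imprint has paternal ratio ~0.95 in both crosses; a
strain-biased gene favours one strain, so its paternal ratio flips
between reciprocal crosses (0.8 vs 0.2) and its parent-of-origin mean
stays 0.5 — the signal the reciprocal design exists to separate.
Decidua-contaminated genes receive additive maternal reads in EPC
samples only (maternal tissue carry-over) and are expressed in adult
blood, which is what the blood filter keys on.  X-linked transcripts in
EPC samples are skewed toward the maternal allele (paternal ratio 0.2),
emulating imprinted paternal-X inactivation in the extraembryonic
lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_formats import TranscriptModel, validate_allelic_counts


class ConfigError(ValueError):
    """Raised for an inconsistent simulation configuration."""


GENE_CLASSES = ("biallelic", "paternal_imprint", "maternal_imprint",
                "strain_biased", "decidua_contaminated", "chrx")

DMR_KINDS = ("gametic_maternal", "gametic_paternal", "somatic_maternal",
             "somatic_paternal")


@dataclass
class PlantedDmr:
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in DMR_KINDS:
            raise ConfigError(f"unknown planted DMR kind {self.kind!r}")
        if self.start >= self.end:
            raise ConfigError("planted DMR start >= end")


def _default_planted_dmrs() -> list[PlantedDmr]:
    # 2-kb regions, well separated on the 400-kb methylome chromosome
    return [
        PlantedDmr(40_000, 42_000, "gametic_maternal"),
        PlantedDmr(120_000, 122_000, "gametic_maternal"),
        PlantedDmr(200_000, 202_000, "gametic_maternal"),
        PlantedDmr(260_000, 262_000, "gametic_paternal"),
        PlantedDmr(300_000, 302_000, "somatic_maternal"),
        PlantedDmr(340_000, 342_000, "somatic_maternal"),
        PlantedDmr(380_000, 382_000, "somatic_maternal"),
    ]


@dataclass
class SimConfig:
    """All tunable parameters of the synthetic study.

    Defaults reproduce the reciprocal-cross design the inference assumes:
    two crosses x three replicates per tissue, strong monoallelic classes
    (paternal ratio 0.95 / 0.05), beta-binomial concentration 200, and an
    extraembryonic paternal-X ratio of 0.2.
    """

    seed: int = 0

    # --- expression ---
    n_biallelic: int = 200
    n_paternal_imprint: int = 10
    n_maternal_imprint: int = 10
    n_strain_biased: int = 20
    n_decidua_contaminated: int = 10
    n_chrx: int = 60
    replicates_per_cross: int = 3          # per tissue
    crosses: tuple[str, str] = ("AxB", "BxA")   # maternal strain listed first
    tissues: tuple[str, str] = ("epiblast", "EPC")
    nb_mean: float = 500.0                 # negative-binomial total-count mean
    nb_dispersion: float = 0.05            # var = mu + disp * mu^2
    allelic_rate: float = 0.3              # fraction of reads with informative variants
    concentration: float = 200.0           # beta-binomial concentration of allelic split
    ratio_biallelic: float = 0.5
    ratio_paternal_imprint: float = 0.95
    ratio_maternal_imprint: float = 0.05
    strain_bias: float = 0.8               # fraction toward the favoured strain
    xci_paternal_ratio: float = 0.2        # EPC chrX paternal expression ratio
    decidua_scale: float = 40.0            # maternal decidua reads per blood RPKM per exonic kb
    library_size: int = 20_000_000
    blood_rpkm_contaminated: tuple[float, float] = (2.0, 20.0)
    blood_rpkm_background: tuple[float, float] = (0.0, 0.5)

    # --- methylome ---
    meth_chrom: str = "chr1"
    meth_chrom_length: int = 400_000
    n_cpgs: int = 8_000
    planted_dmrs: list[PlantedDmr] = field(default_factory=_default_planted_dmrs)
    meth_high: float = 0.90                # hypermethylated-side fraction
    meth_low: float = 0.08                 # hypomethylated-side fraction
    bg_high_frac: float = 0.7              # genome background: mostly methylated
    # per-CpG Poisson coverage means; tissue alleles represent replicate- and
    # cross-merged counts, hence the higher mean
    cov_gamete: float = 20.0
    cov_allelic: float = 16.0
    cov_total: float = 24.0

    # --- mark tracks ---
    n_bins: int = 50_000
    bin_width: int = 1_000
    k27_k36_rho: float = -0.5              # latent Gaussian anticorrelation
    k27_scale: float = 0.5                 # exponential RPKM scale
    k36_scale: float = 0.5
    n_domains_a: int = 30                  # planted genome-A-specific K27 domains
    n_domains_b: int = 10
    domain_bins: int = 5                   # bins per planted domain
    domain_k27_boost: float = 1.5          # added RPKM inside planted domains

    def validate(self) -> None:
        for name in ("n_biallelic", "n_paternal_imprint", "n_maternal_imprint",
                     "n_strain_biased", "n_decidua_contaminated", "n_chrx"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.replicates_per_cross < 1:
            raise ConfigError("replicates_per_cross must be >= 1 in each cross")
        for name in ("ratio_biallelic", "ratio_paternal_imprint",
                     "ratio_maternal_imprint", "strain_bias",
                     "xci_paternal_ratio", "allelic_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.concentration <= 0:
            raise ConfigError("concentration must be positive")
        dmrs = sorted(self.planted_dmrs, key=lambda d: d.start)
        for a, b in zip(dmrs, dmrs[1:]):
            if b.start < a.end:
                raise ConfigError(
                    f"planted DMRs overlap: [{a.start},{a.end}) and "
                    f"[{b.start},{b.end})")
        for d in dmrs:
            if d.end > self.meth_chrom_length:
                raise ConfigError("planted DMR outside chromosome bounds")


@dataclass
class SimTruth:
    """What the generators planted: one row per simulated entity."""

    genes: pd.DataFrame | None = None      # gene_id, class, ratio, blood_rpkm, chrom
    dmrs: pd.DataFrame | None = None       # chrom, start, end, kind, tissues
    domains: pd.DataFrame | None = None    # genome, chrom, start, end


class ExpressionSim(NamedTuple):
    counts: pd.DataFrame
    annotation: dict[str, TranscriptModel]
    blood: pd.Series
    truth: SimTruth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mu, disp: float, size: int):
    """Negative binomial via gamma-Poisson mixture; Poisson when disp == 0.

    ``mu`` may be a scalar or a per-element array of means.
    """
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (size,))
    if disp <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
    return rng.poisson(lam)


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                   concentration: float) -> np.ndarray:
    """Draw successes from BetaBin(n, p*c, (1-p)*c), elementwise."""
    p = np.clip(p, 1e-9, 1 - 1e-9)
    q = rng.beta(p * concentration, (1 - p) * concentration)
    return rng.binomial(n, q)


def _gene_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    counts = {
        "biallelic": config.n_biallelic,
        "paternal_imprint": config.n_paternal_imprint,
        "maternal_imprint": config.n_maternal_imprint,
        "strain_biased": config.n_strain_biased,
        "decidua_contaminated": config.n_decidua_contaminated,
        "chrx": config.n_chrx,
    }
    idx = 0
    for cls in GENE_CLASSES:
        for _ in range(counts[cls]):
            chrom = "chrX" if cls == "chrx" else ("chr1" if idx % 2 == 0 else "chr2")
            rows.append((f"g{idx:05d}", cls, chrom))
            idx += 1
    return pd.DataFrame(rows, columns=["gene_id", "class", "chrom"])


def _paternal_ratio_for(cls: str, cross_idx: int, tissue: str,
                        config: SimConfig) -> float:
    """Target paternal ratio of a gene class in one cross x tissue."""
    if cls == "paternal_imprint":
        return config.ratio_paternal_imprint
    if cls == "maternal_imprint":
        return config.ratio_maternal_imprint
    if cls == "strain_biased":
        # favoured strain is the sire in cross 0 (AxB -> father B), the dam in
        # cross 1: the paternal ratio flips between reciprocal crosses
        return config.strain_bias if cross_idx == 0 else 1.0 - config.strain_bias
    if cls == "chrx" and tissue == "EPC":
        return config.xci_paternal_ratio
    return config.ratio_biallelic


def simulate_reciprocal_expression(config: SimConfig | None = None) -> ExpressionSim:
    """Generate the allelic count table, annotation, blood RPKM and truth."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_table(config)
    n_genes = len(genes)

    # one single-exon transcript per gene, 20-kb spacing per chromosome
    annotation: dict[str, TranscriptModel] = {}
    offsets: dict[str, int] = {}
    exonic_kb = rng.uniform(0.5, 4.0, size=n_genes)
    tss = np.zeros(n_genes, dtype=int)
    for i, r in enumerate(genes.itertuples(index=False)):
        start = offsets.get(r.chrom, 10_000)
        offsets[r.chrom] = start + 20_000
        length = int(exonic_kb[i] * 1000)
        strand = "+" if i % 3 else "-"
        tm = TranscriptModel(
            transcript_id=r.gene_id, gene_id=r.gene_id, chrom=r.chrom,
            strand=strand, tx_start=start, tx_end=start + length,
            exons=((start, start + length),))
        annotation[r.gene_id] = tm
        tss[i] = tm.tss

    blood = np.where(
        genes["class"] == "decidua_contaminated",
        rng.uniform(*config.blood_rpkm_contaminated, size=n_genes),
        rng.uniform(*config.blood_rpkm_background, size=n_genes))

    rows = []
    for tissue in config.tissues:
        for ci, cross in enumerate(config.crosses):
            for rep in range(1, config.replicates_per_cross + 1):
                sample = f"{tissue}_{cross}_r{rep}"
                # expected totals scale with transcript length so RPKM is
                # roughly length-independent across genes
                total = _nb_counts(rng, config.nb_mean * exonic_kb,
                                   config.nb_dispersion, n_genes)
                allelic = rng.binomial(total, config.allelic_rate)
                target = np.array([
                    _paternal_ratio_for(c, ci, tissue, config)
                    for c in genes["class"]])
                pat = _beta_binomial(rng, allelic, target, config.concentration)
                mat = allelic - pat
                if tissue == "EPC" and config.n_decidua_contaminated:
                    mask = (genes["class"] == "decidua_contaminated").to_numpy()
                    # contamination proportional to adult-blood expression
                    extra = rng.poisson(config.decidua_scale * blood[mask]
                                        * exonic_kb[mask])
                    mat = mat.copy()
                    total = total.copy()
                    mat[mask] += extra
                    total[mask] += extra
                for g, t, m, p in zip(genes["gene_id"], total, mat, pat):
                    rows.append((g, sample, cross, tissue, int(t), int(m),
                                 int(p), config.library_size))

    counts = pd.DataFrame(rows, columns=[
        "transcript_id", "sample_id", "cross", "tissue",
        "total_reads", "maternal_reads", "paternal_reads", "library_size"])
    counts = validate_allelic_counts(counts, source="simulate_reciprocal_expression")

    truth_genes = genes.assign(
        true_paternal_ratio=[
            0.5 if c in ("biallelic", "strain_biased", "decidua_contaminated")
            else (config.ratio_paternal_imprint if c == "paternal_imprint"
                  else (config.ratio_maternal_imprint if c == "maternal_imprint"
                        else config.xci_paternal_ratio))
            for c in genes["class"]],
        blood_rpkm=blood, tss=tss)
    blood_series = pd.Series(blood, index=genes["gene_id"], name="rpkm")
    return ExpressionSim(counts, annotation, blood_series,
                         SimTruth(genes=truth_genes))


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def _region_fraction(kind: str, group: str, tissue: str | None,
                     config: SimConfig) -> float:
    """True methylation fraction inside a planted DMR for one data group."""
    hi, lo = config.meth_high, config.meth_low
    if kind == "gametic_maternal":
        table = {"oocyte": hi, "sperm": lo, "maternal": hi, "paternal": lo}
    elif kind == "gametic_paternal":
        table = {"oocyte": lo, "sperm": hi, "maternal": lo, "paternal": hi}
    elif kind == "somatic_maternal":
        table = {"oocyte": lo, "sperm": lo,
                 "maternal": hi if tissue == "EPC" else lo, "paternal": lo}
    else:  # somatic_paternal
        table = {"oocyte": lo, "sperm": lo,
                 "maternal": lo, "paternal": hi if tissue == "EPC" else lo}
    return table[group]


def simulate_methylomes(config: SimConfig | None = None
                        ) -> tuple[pd.DataFrame, SimTruth]:
    """Generate allele-resolved CpG reports for gametes and both tissues.

    Background CpGs share a common per-CpG methylation fraction across all
    groups (mostly-methylated bimodal background); planted gametic DMRs are
    asymmetric already in the gametes and on the tissue alleles, planted
    somatic DMRs acquire maternal methylation only in EPC.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    # background CpGs uniform; planted DMRs are CpG-island-like, so they get
    # additional dense CpGs (~25-bp spacing) on top of the background
    bg_pos = rng.choice(config.meth_chrom_length, size=config.n_cpgs,
                        replace=False)
    island = [np.arange(d.start + 5, d.end - 5, 25) + rng.integers(0, 10)
              for d in config.planted_dmrs]
    pos = np.unique(np.concatenate([bg_pos, *island])) if island else np.sort(bg_pos)
    n_cpgs = len(pos)
    high = rng.random(n_cpgs) < config.bg_high_frac
    base = np.where(high, rng.beta(16, 3, n_cpgs), rng.beta(2, 16, n_cpgs))

    region_of = np.full(n_cpgs, -1)
    for i, d in enumerate(config.planted_dmrs):
        region_of[(pos >= d.start) & (pos < d.end)] = i

    rows: list[tuple] = []

    def emit(sample_id: str, allele: str, group: str, tissue: str | None,
             cov_mean: float) -> None:
        cov = rng.poisson(cov_mean, size=n_cpgs)
        frac = base.copy()
        for i, d in enumerate(config.planted_dmrs):
            sel = region_of == i
            frac[sel] = _region_fraction(d.kind, group, tissue, config)
        meth = rng.binomial(cov, frac)
        keep = cov > 0
        for p, m, u in zip(pos[keep], meth[keep], (cov - meth)[keep]):
            rows.append((config.meth_chrom, int(p), sample_id, allele,
                         int(m), int(u)))

    emit("oocyte", "oocyte", "oocyte", None, config.cov_gamete)
    emit("sperm", "sperm", "sperm", None, config.cov_gamete)
    for tissue in config.tissues:
        emit(tissue, "maternal", "maternal", tissue, config.cov_allelic)
        emit(tissue, "paternal", "paternal", tissue, config.cov_allelic)
        emit(tissue, "total", "maternal", tissue, config.cov_total / 2)

    cpgs = pd.DataFrame(rows, columns=[
        "chrom", "pos", "sample_id", "allele", "meth_reads", "unmeth_reads"])
    cpgs = cpgs.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    truth_dmrs = pd.DataFrame(
        [(config.meth_chrom, d.start, d.end, d.kind,
          "EPC" if d.kind.startswith("somatic") else "epiblast,EPC")
         for d in config.planted_dmrs],
        columns=["chrom", "start", "end", "kind", "tissues"])
    return cpgs, SimTruth(dmrs=truth_dmrs)


# ---------------------------------------------------------------------------
# mark tracks
# ---------------------------------------------------------------------------

class MarkTrackSim(NamedTuple):
    tracks: dict[tuple[str, str], pd.DataFrame]   # (genome, mark) -> bedGraph frame
    synteny: pd.DataFrame
    truth: SimTruth


def simulate_mark_tracks(config: SimConfig | None = None) -> MarkTrackSim:
    """Paired binned tracks for genomes "A" and "B" over syntenic 1-kb bins.

    Within a genome, H3K27me3 and H3K36me3 levels are exponential margins
    of a latent bivariate Gaussian with correlation ``k27_k36_rho``.
    Between genomes, syntenic bins share most of their latent signal
    (epigenomes of close relatives are conserved over syntenic regions),
    so background cross-species deltas are small and the planted
    species-specific H3K27me3 domains stand out.
    """
    from scipy.stats import norm

    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_bins
    w = config.bin_width
    rho = config.k27_k36_rho
    share = np.sqrt(0.8)      # cross-species latent signal sharing
    noise = np.sqrt(1.0 - 0.8)

    # shared latent pair with the configured K27-K36 anticorrelation
    z27_shared = rng.standard_normal(n)
    z36_shared = rho * z27_shared + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    zdna_shared = rng.standard_normal(n)

    levels: dict[tuple[str, str], np.ndarray] = {}
    for genome in ("A", "B"):
        e27 = rng.standard_normal(n)
        e36 = rho * e27 + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        z27 = share * z27_shared + noise * e27
        z36 = share * z36_shared + noise * e36
        k27 = -config.k27_scale * norm.logsf(z27)
        k36 = -config.k36_scale * norm.logsf(z36)
        # DNAme anticorrelated with K27, conserved across genomes
        zdna = share * zdna_shared + noise * rng.standard_normal(n)
        dname = 100.0 * norm.cdf(0.8 * zdna - 0.8 * z27 + 0.8)
        levels[(genome, "H3K27me3")] = k27
        levels[(genome, "H3K36me3")] = k36
        levels[(genome, "DNAme")] = dname

    # plant species-specific K27 domains on non-overlapping bin blocks
    total_domains = config.n_domains_a + config.n_domains_b
    block = config.domain_bins
    if total_domains * block * 4 > n:
        raise ConfigError("too many planted domains for the number of bins")
    starts = rng.choice(n // (4 * block), size=total_domains, replace=False)
    starts = np.sort(starts) * 4 * block
    assign = np.array(["A"] * config.n_domains_a + ["B"] * config.n_domains_b)
    rng.shuffle(assign)
    dom_truth = []
    for s, genome in zip(starts, assign):
        other = "B" if genome == "A" else "A"
        sel = slice(s, s + block)
        boost = config.domain_k27_boost + rng.random(block)
        levels[(genome, "H3K27me3")][sel] = (
            levels[(other, "H3K27me3")][sel] + boost)
        levels[(genome, "DNAme")][sel] = rng.uniform(0.0, 5.0, block)
        levels[(other, "DNAme")][sel] = rng.uniform(88.0, 99.0, block)
        dom_truth.append((genome, "chr1", int(s) * w, int(s + block) * w))

    bin_start = np.arange(n, dtype=np.int64) * w
    tracks = {
        key: pd.DataFrame({"chrom": "chr1", "start": bin_start,
                           "end": bin_start + w, "value": vals})
        for key, vals in levels.items()
    }
    synteny = pd.DataFrame({
        "chrom_a": "chr1", "start_a": bin_start, "end_a": bin_start + w,
        "chrom_b": "chr1", "start_b": bin_start, "end_b": bin_start + w})
    truth = SimTruth(domains=pd.DataFrame(
        dom_truth, columns=["genome", "chrom", "start", "end"]))
    return MarkTrackSim(tracks, synteny, truth)
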