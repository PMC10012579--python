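"""Tabular and interval I/O for the imprinting pipeline.

All genomic coordinates are 0-based half-open, both in memory and on disk
(BED convention).  CpGs are keyed to the + strand cytosine of the CpG
dyad; strand-symmetric collapsing is assumed done upstream.  TSV dialect:
tab separated, ``#``-prefixed comment lines allowed, UTF-8, no quoting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml


class FormatError(ValueError):
    """Raised when a file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Raised when well-formed input violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its exon structure.

    Exons are non-overlapping, sorted, half-open intervals within
    ``[tx_start, tx_end)``.  ``exonic_kb`` (sum of exon lengths / 1000) is
    the length term of the RPKM normalisation.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(
                    f"{self.transcript_id}: empty exon [{start},{end})")
            if start < self.tx_start or end > self.tx_end:
                raise ValidationError(
                    f"{self.transcript_id}: exon [{start},{end}) outside transcript")
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def tss(self) -> int:
        """Transcription start site (strand aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def exonic_kb(self) -> float:
        return sum(end - start for start, end in self.exons) / 1000.0


@dataclass
class Dmr:
    """A parent-of-origin differentially methylated region.

    ``means`` holds per-sample mean methylation (percent) over the
    interval, keyed e.g. ``oocyte``, ``sperm``, ``EPC_maternal``;
    ``cpg_counts`` the number of covered CpGs contributing to each mean.
    """

    chrom: str
    start: int
    end: int
    n_cpg: int = 0
    max_delta: float = 0.0
    origin: str = "unassigned"
    tissues: tuple[str, ...] = ()
    means: dict = field(default_factory=dict)
    cpg_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"DMR {self.chrom}:{self.start}-{self.end}: start >= end")

    @property
    def dmr_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


ALLELIC_COUNT_COLUMNS = [
    "transcript_id", "sample_id", "cross", "tissue",
    "total_reads", "maternal_reads", "paternal_reads", "library_size",
]

CPG_REPORT_COLUMNS = [
    "chrom", "pos", "sample_id", "allele", "meth_reads", "unmeth_reads",
]

CPG_ALLELES = {"maternal", "paternal", "total", "oocyte", "sperm"}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


# ---------------------------------------------------------------------------
# allelic expression counts
# ---------------------------------------------------------------------------

def read_allelic_counts(path) -> pd.DataFrame:
    """Read a per-transcript allelic count table.

    Validates the count invariants (non-negative, maternal + paternal <=
    total); errors cite the first offending data row (1-based, header
    excluded).
    """
    df = _read_tsv(path)
    for col in ALLELIC_COUNT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    int_cols = ["total_reads", "maternal_reads", "paternal_reads", "library_size"]
    try:
        df[int_cols] = df[int_cols].astype("int64")
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer count field ({exc})") from exc
    return validate_allelic_counts(df, source=str(path))


def validate_allelic_counts(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    neg = (df[["total_reads", "maternal_reads", "paternal_reads"]] < 0).any(axis=1)
    if neg.any():
        row = int(neg.idxmax()) + 1
        raise ValidationError(f"{source}: negative count in row {row}")
    over = df["maternal_reads"] + df["paternal_reads"] > df["total_reads"]
    if over.any():
        row = int(over.idxmax()) + 1
        raise ValidationError(
            f"{source}: maternal+paternal exceed total in row {row}")
    if (df["library_size"] <= 0).any():
        row = int((df["library_size"] <= 0).idxmax()) + 1
        raise ValidationError(f"{source}: non-positive library size in row {row}")
    return df.reset_index(drop=True)


def write_allelic_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ALLELIC_COUNT_COLUMNS)


# ---------------------------------------------------------------------------
# CpG reports
# ---------------------------------------------------------------------------

def read_cpg_report(path) -> pd.DataFrame:
    """Read a per-CpG allelic methylation report, sorted by (chrom, pos).

    Duplicate (chrom, pos, sample_id, allele) keys are rejected.
    """
    df = _read_tsv(path)
    for col in CPG_REPORT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    try:
        df[["pos", "meth_reads", "unmeth_reads"]] = (
            df[["pos", "meth_reads", "unmeth_reads"]].astype("int64"))
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer field ({exc})") from exc
    return validate_cpg_report(df, source=str(path))


def validate_cpg_report(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    if (df[["meth_reads", "unmeth_reads"]] < 0).any().any():
        raise ValidationError(f"{source}: negative methylation count")
    bad_allele = ~df["allele"].isin(CPG_ALLELES)
    if bad_allele.any():
        raise ValidationError(
            f"{source}: unknown allele label "
            f"{df.loc[bad_allele, 'allele'].iloc[0]!r}")
    key = ["chrom", "pos", "sample_id", "allele"]
    dup = df.duplicated(subset=key)
    if dup.any():
        r = df.loc[dup.idxmax()]
        raise ValidationError(
            f"{source}: duplicate CpG key at {r['chrom']}:{r['pos']} "
            f"({r['sample_id']}/{r['allele']})")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_cpg_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CPG_REPORT_COLUMNS)


# ---------------------------------------------------------------------------
# DMR BED6+
# ---------------------------------------------------------------------------

DMR_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                   "n_cpg", "origin", "max_delta"]


def write_dmr_bed(dmrs, path) -> None:
    """Write DMRs as BED6+3 (name=id, score=0, strand='.'), sorted by
    (chrom, start)."""
    rows = [
        (d.chrom, d.start, d.end, d.dmr_id, 0, ".", d.n_cpg, d.origin,
         round(float(d.max_delta), 4))
        for d in sorted(dmrs, key=lambda d: (d.chrom, d.start, d.end))
    ]
    pd.DataFrame(rows, columns=DMR_BED_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False)


def read_dmr_bed(path) -> list[Dmr]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=DMR_BED_COLUMNS)
    except pd.errors.EmptyDataError:
        return []
    return [
        Dmr(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            n_cpg=int(r.n_cpg), origin=str(r.origin),
            max_delta=float(r.max_delta))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# bedGraph bin tracks and synteny maps
# ---------------------------------------------------------------------------

BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]


def read_bedgraph(path) -> pd.DataFrame:
    """Read a (chrom, start, end, value) track, e.g. 1-kb binned RPKM."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=BEDGRAPH_COLUMNS)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BEDGRAPH_COLUMNS)
    df[["start", "end"]] = df[["start", "end"]].astype("int64")
    df["value"] = df["value"].astype(float)
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: interval with start >= end")
    if (df["value"] < 0).any():
        raise ValidationError(f"{path}: negative track value")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False,
              columns=BEDGRAPH_COLUMNS)


SYNTENY_COLUMNS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"]


def read_synteny_map(path) -> pd.DataFrame:
    """Read a paired-BED synteny map (1-kb bin pairs across two genomes)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=SYNTENY_COLUMNS)
    for c in ("start_a", "end_a", "start_b", "end_b"):
        df[c] = df[c].astype("int64")
    if ((df["start_a"] >= df["end_a"]) | (df["start_b"] >= df["end_b"])).any():
        raise ValidationError(f"{path}: invalid half-open interval in synteny map")
    if df.duplicated().any():
        raise ValidationError(f"{path}: duplicate synteny pair")
    return df.reset_index(drop=True)


def write_synteny_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False,
              columns=SYNTENY_COLUMNS)


# ---------------------------------------------------------------------------
# transcript annotation (BED12-like TSV)
# ---------------------------------------------------------------------------

ANNOT_COLUMNS = ["transcript_id", "gene_id", "chrom", "strand",
                 "tx_start", "tx_end", "exon_starts", "exon_ends"]


def read_transcript_annotation(path) -> dict[str, TranscriptModel]:
    """Read a BED12-like transcript table into TranscriptModel objects.

    ``exon_starts``/``exon_ends`` are comma-separated absolute coordinates.
    """
    df = _read_tsv(path)
    for col in ANNOT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    models: dict[str, TranscriptModel] = {}
    for r in df.itertuples(index=False):
        starts = [int(x) for x in str(r.exon_starts).rstrip(",").split(",")]
        ends = [int(x) for x in str(r.exon_ends).rstrip(",").split(",")]
        if len(starts) != len(ends):
            raise FormatError(
                f"{path}: exon start/end count mismatch for {r.transcript_id}")
        tm = TranscriptModel(
            transcript_id=str(r.transcript_id), gene_id=str(r.gene_id),
            chrom=str(r.chrom), strand=str(r.strand),
            tx_start=int(r.tx_start), tx_end=int(r.tx_end),
            exons=tuple(zip(starts, ends)))
        if tm.transcript_id in models:
            raise ValidationError(f"{path}: duplicate transcript {tm.transcript_id}")
        models[tm.transcript_id] = tm
    return models


def write_transcript_annotation(models, path) -> None:
    rows = []
    for tm in models.values() if isinstance(models, dict) else models:
        rows.append((
            tm.transcript_id, tm.gene_id, tm.chrom, tm.strand,
            tm.tx_start, tm.tx_end,
            ",".join(str(s) for s, _ in tm.exons),
            ",".join(str(e) for _, e in tm.exons)))
    pd.DataFrame(rows, columns=ANNOT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# blood expression and YAML config
# ---------------------------------------------------------------------------

def read_blood_expression(path) -> pd.Series:
    """Adult-blood RPKM per transcript (used by the maternal-decidua filter)."""
    df = _read_tsv(path)
    for col in ("transcript_id", "rpkm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    s = df.set_index("transcript_id")["rpkm"].astype(float)
    if s.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate transcript id")
    return s


def write_blood_expression(s: pd.Series, path) -> None:
    s.rename("rpkm").rename_axis("transcript_id").reset_index().to_csv(
        path, sep="\t", index=False)


def load_config(path) -> dict:
    """Load a YAML threshold/configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config root must be a mapping")
    return cfg
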