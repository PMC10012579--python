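"""Joining expression calls, DMRs, oocyte H3K27me3 and sequence features
into a per-gene imprinting atlas with canonical / non-canonical labels.

Canonical imprints are driven by a germline (gametic) DMR; non-canonical
imprints show paternal-specific expression restricted to extraembryonic
(EPC) tissue with no germline DMR, the maternal allele instead carrying
oocyte H3K27me3 that is replaced by post-fertilization (somatic) DNA
methylation.  Genes whose promoters overlap oocyte H3K27me3 but are
biallelic in both tissues are flagged as transient-imprinting candidates
("primed" loci whose asymmetry is lost by this stage).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Dmr, TranscriptModel
from .dmr_caller import GAMETIC_ORIGINS

ZFP57_HEXAMER = "TGCCGC"
ZFP57_HEXAMER_RC = "GCGGCA"

MODES = ("canonical", "non_canonical", "transient_candidate", "unclassified")


# ---------------------------------------------------------------------------
# DMR-to-gene assignment
# ---------------------------------------------------------------------------

def _interval_distance(start: int, end: int, point: int) -> int:
    if start <= point < end:
        return 0
    return start - point if point < start else point - (end - 1)


def assign_dmr_to_gene(gene: TranscriptModel, dmrs: list[Dmr],
                       promoter_window: int = 5000
                       ) -> tuple[Dmr | None, str, int]:
    """Nearest DMR to the gene's TSS with its relation.

    Relation is ``promoter`` when the DMR overlaps the TSS or the
    ``promoter_window`` bp immediately upstream (strand aware),
    ``intragenic`` when it overlaps the gene body, else ``distal``.
    Ties in distance break toward the smaller start coordinate.
    """
    tss = gene.tss
    candidates = [d for d in dmrs if d.chrom == gene.chrom]
    if not candidates:
        return None, "none", 0
    best = min(candidates,
               key=lambda d: (_interval_distance(d.start, d.end, tss), d.start))
    dist = _interval_distance(best.start, best.end, tss)

    if gene.strand == "+":
        prom_lo, prom_hi = tss - promoter_window, tss + 1
    else:
        prom_lo, prom_hi = tss, tss + promoter_window + 1
    overlaps_promoter = best.start < prom_hi and best.end > prom_lo
    overlaps_body = best.start < gene.tx_end and best.end > gene.tx_start
    if overlaps_promoter:
        relation = "promoter"
    elif overlaps_body:
        relation = "intragenic"
    else:
        relation = "distal"
        if best.end <= tss:   # signed distance: upstream of the TSS is negative
            dist = -dist
    return best, relation, int(dist)


def overlaps_any(gene: TranscriptModel, intervals: pd.DataFrame,
                 promoter_window: int = 5000) -> bool:
    """Does the gene promoter region overlap any (chrom, start, end) row?"""
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - promoter_window, tss + 1
    else:
        lo, hi = tss, tss + promoter_window + 1
    sub = intervals[(intervals["chrom"] == gene.chrom)
                    & (intervals["start"] < hi) & (intervals["end"] > lo)]
    return len(sub) > 0


# ---------------------------------------------------------------------------
# ZFP57 motif scan
# ---------------------------------------------------------------------------

def scan_zfp57_motifs(sequence: str) -> list[tuple[int, str]]:
    """All occurrences of the ZFP57 hexamer TGCCGC on either strand.

    Returns (offset, strand) pairs; a '-' strand hit is the reverse
    complement GCGGCA read on the given (+) sequence.  Overlapping
    matches are all reported.
    """
    seq = sequence.upper()
    if re.search(r"[^ACGTN]", seq):
        raise ValueError("sequence may contain only A, C, G, T, N")
    hits: list[tuple[int, str]] = []
    for motif, strand in ((ZFP57_HEXAMER, "+"), (ZFP57_HEXAMER_RC, "-")):
        start = seq.find(motif)
        while start != -1:
            hits.append((start, strand))
            start = seq.find(motif, start + 1)
    return sorted(hits)


# ---------------------------------------------------------------------------
# mode classification
# ---------------------------------------------------------------------------

@dataclass
class ModeInputs:
    status_epiblast: str            # paternal/maternal/biallelic/not_testable
    status_epc: str
    dmr_origin: str | None          # origin of the assigned DMR, or None
    oocyte_k27_overlap: bool
    epiblast_mean_ratio: float | None = None


def classify_imprinting_mode(inp: ModeInputs,
                             weak_epiblast_ratio: float = 0.7) -> str:
    """Canonical / non-canonical / transient-candidate / unclassified.

    * canonical: imprinted in >= 1 tissue with an assigned gametic DMR;
    * non_canonical: paternal in EPC, not paternal in epiblast (a weak,
      non-significant same-direction epiblast bias above
      ``weak_epiblast_ratio`` does not block the label), no gametic DMR,
      and either a somatic-maternal DMR or oocyte H3K27me3 overlap;
    * transient_candidate: oocyte H3K27me3 overlap with biallelic
      expression in both tissues;
    * unclassified otherwise.
    """
    imprinted_somewhere = (inp.status_epiblast in ("paternal", "maternal")
                           or inp.status_epc in ("paternal", "maternal"))
    if imprinted_somewhere and inp.dmr_origin in GAMETIC_ORIGINS:
        return "canonical"
    epiblast_not_paternal = inp.status_epiblast != "paternal"
    if (inp.status_epc == "paternal" and epiblast_not_paternal
            and inp.dmr_origin not in GAMETIC_ORIGINS
            and (inp.dmr_origin == "somatic_maternal" or inp.oocyte_k27_overlap)):
        return "non_canonical"
    if (inp.oocyte_k27_overlap and inp.status_epiblast == "biallelic"
            and inp.status_epc == "biallelic"):
        return "transient_candidate"
    return "unclassified"


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

ATLAS_COLUMNS = ["gene_id", "status_epiblast", "status_epc", "dmr_id",
                 "dmr_relation", "dmr_distance", "dmr_origin",
                 "oocyte_k27_overlap", "zfp57_motifs", "mode", "flags"]


def build_atlas(calls: pd.DataFrame, annotation: dict[str, TranscriptModel],
                dmrs: list[Dmr], k27_domains: pd.DataFrame | None = None,
                sequences: dict[str, str] | None = None,
                promoter_window: int = 5000) -> pd.DataFrame:
    """One atlas row per gene that is imprinted or flagged in any tissue.

    ``calls`` is the concatenated per-tissue call table (columns
    transcript_id, tissue, status, mean_ratio, flags); ``k27_domains`` a
    (chrom, start, end) frame of oocyte H3K27me3 domains; ``sequences``
    optional DMR-id -> DNA string for motif counting.
    """
    dup = calls.duplicated(subset=["transcript_id", "tissue"])
    if dup.any():
        raise ValueError("duplicate (gene, tissue) rows in call table")

    by_gene = {}
    for r in calls.itertuples(index=False):
        by_gene.setdefault(r.transcript_id, {})[r.tissue] = r

    rows = []
    for gene_id in sorted(by_gene):
        per_tissue = by_gene[gene_id]
        epi = per_tissue.get("epiblast")
        epc = per_tissue.get("EPC")
        status_epi = epi.status if epi is not None else "not_testable"
        status_epc = epc.status if epc is not None else "not_testable"
        flags = ",".join(sorted({
            f for r in per_tissue.values()
            for f in str(r.flags).split(",")
            if f and not pd.isna(r.flags)}))
        blood_flagged = "blood_expressed" in flags
        # blood-flagged maternal EPC calls do not count as imprinted
        eff_epc = ("biallelic" if (status_epc == "maternal" and blood_flagged)
                   else status_epc)
        imprinted = (status_epi in ("paternal", "maternal")
                     or eff_epc in ("paternal", "maternal"))
        if not (imprinted or flags):
            continue
        gene = annotation[gene_id]
        dmr, relation, distance = assign_dmr_to_gene(gene, dmrs, promoter_window)
        k27 = (overlaps_any(gene, k27_domains, promoter_window)
               if k27_domains is not None and len(k27_domains) else False)
        n_motifs = 0
        if sequences and dmr is not None and dmr.dmr_id in sequences:
            n_motifs = len(scan_zfp57_motifs(sequences[dmr.dmr_id]))
        epi_ratio = float(epi.mean_ratio) if epi is not None else None
        mode = classify_imprinting_mode(ModeInputs(
            status_epiblast=status_epi, status_epc=eff_epc,
            dmr_origin=dmr.origin if dmr is not None else None,
            oocyte_k27_overlap=k27, epiblast_mean_ratio=epi_ratio))
        if not imprinted:
            mode = "unclassified" if mode != "transient_candidate" else mode
        rows.append((gene_id, status_epi, eff_epc,
                     dmr.dmr_id if dmr is not None else "",
                     relation if dmr is not None else "none",
                     distance, dmr.origin if dmr is not None else "",
                     bool(k27), n_motifs, mode, flags))
    atlas = pd.DataFrame(rows, columns=ATLAS_COLUMNS)
    return atlas.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
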