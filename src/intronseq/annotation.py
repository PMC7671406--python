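"""Gene-model flattening and SAF (simplified annotation format) I/O.

A GENCODE-style GTF is reduced to three gene-level annotations: *exon parts*
(the per-gene union of all transcript exons), *intron parts* (the gaps between
exon parts) and the *genebody* (first to last exonic base).  Every genomic
position inside an annotated gene is thereby classified as exon or intron.

SAF files carry GeneID/Chr/Start/End/Strand columns with 1-based inclusive
coordinates; conversion from the internal 0-based half-open convention happens
here and nowhere else.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .intervals import GeneParts, GenomicInterval, union_intervals

logger = logging.getLogger(__name__)

SAF_COLUMNS = ["GeneID", "Chr", "Start", "End", "Strand"]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    pass


def parse_gtf(path: str | Path) -> Iterator[dict]:
    """Stream records from a GTF file (GENCODE attribute dialect).

    Yields dicts with keys chrom, feature, start, end (0-based half-open),
    strand and the parsed attribute map.  Raises :class:`GtfParseError` naming
    the offending line number on malformed input.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise GtfParseError(f"{path}:{lineno}: invalid coordinates {start}-{end}")
            yield {
                "chrom": chrom,
                "feature": feature,
                "start": start_i - 1,  # GTF is 1-based inclusive
                "end": end_i,
                "strand": strand,
                "attributes": dict(_ATTR_RE.findall(attrs)),
                "line": lineno,
            }


def flatten_gene_models(
    source: str | Path | Iterable[dict],
    gene_type_filter: set[str] | None = None,
) -> list[GeneParts]:
    """Flatten transcript exons into one :class:`GeneParts` per gene.

    Exon records of all transcripts of a gene are unioned (per gene, never
    across genes); gene_type is taken from the gene-level attribute, falling
    back to the majority transcript_type with a warning.  Gene groups whose
    exons span multiple chromosomes or strands are rejected with a warning.
    """
    records = parse_gtf(source) if isinstance(source, (str, Path)) else source
    exons: dict[str, list[dict]] = defaultdict(list)
    gene_types: dict[str, str] = {}
    tx_types: dict[str, Counter] = defaultdict(Counter)
    order: list[str] = []
    for rec in records:
        gid = rec["attributes"].get("gene_id")
        if gid is None:
            raise GtfParseError(f"line {rec.get('line', '?')}: record lacks gene_id")
        if rec["feature"] == "gene":
            if "gene_type" in rec["attributes"]:
                gene_types[gid] = rec["attributes"]["gene_type"]
        elif rec["feature"] == "exon":
            if gid not in exons:
                order.append(gid)
            exons[gid].append(rec)
            # gene_type may be carried on exon records too (GENCODE does this)
            gene_types.setdefault(gid, rec["attributes"].get("gene_type"))
            tt = rec["attributes"].get("transcript_type")
            if tt:
                tx_types[gid][tt] += 1

    out: list[GeneParts] = []
    for gid in order:
        recs = exons[gid]
        chroms = {r["chrom"] for r in recs}
        strands = {r["strand"] for r in recs}
        if len(chroms) > 1 or len(strands) > 1:
            logger.warning(
                "gene %s has exons on multiple chromosomes/strands; skipped", gid
            )
            continue
        gtype = gene_types.get(gid)
        if not gtype:
            if tx_types[gid]:
                gtype = tx_types[gid].most_common(1)[0][0]
                logger.warning(
                    "gene %s lacks gene_type; using majority transcript_type %r", gid, gtype
                )
            else:
                gtype = ""
        if gene_type_filter is not None and gtype not in gene_type_filter:
            continue
        chrom, strand = chroms.pop(), strands.pop()
        merged = union_intervals([(r["start"], r["end"]) for r in recs])
        parts = [GenomicInterval(chrom, s, e, strand) for s, e in merged]
        out.append(GeneParts(gene_id=gid, gene_type=gtype, chrom=chrom, strand=strand,
                             exon_parts=parts))
    return out


def write_saf(parts: list[GeneParts], level: str, path: str | Path) -> None:
    """Write one annotation level (exon, intron or genebody) as SAF.

    Genes with nothing at the requested level (e.g. introns of a single-exon
    gene) are simply omitted from that file.
    """
    if not parts:
        raise ValueError("no gene parts to write")
    rows = []
    for gene in parts:
        if level == "exon":
            ivs = gene.exon_parts
        elif level == "intron":
            ivs = gene.intron_parts
        elif level == "genebody":
            ivs = [gene.genebody]
        else:
            raise ValueError(f"unknown annotation level {level!r}")
        for iv in ivs:
            rows.append((gene.gene_id, iv.chrom, iv.start + 1, iv.end, iv.strand))
    df = pd.DataFrame(rows, columns=SAF_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_saf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: SAF missing columns {sorted(missing)}")
    return df


def parts_from_saf(exon_saf: pd.DataFrame, gene_types: dict[str, str] | None = None
                   ) -> list[GeneParts]:
    """Reconstruct :class:`GeneParts` from an exon-level SAF table.

    Intron parts and the genebody are implied by the exon parts, so the exon
    SAF alone round-trips the full structure.
    """
    out = []
    for gid, grp in exon_saf.groupby("GeneID", sort=False):
        grp = grp.sort_values("Start")
        chrom = grp["Chr"].iloc[0]
        strand = grp["Strand"].iloc[0]
        ivs = [GenomicInterval(chrom, int(s) - 1, int(e), strand)
               for s, e in zip(grp["Start"], grp["End"])]
        out.append(GeneParts(gene_id=str(gid),
                             gene_type=(gene_types or {}).get(str(gid), ""),
                             chrom=chrom, strand=strand, exon_parts=ivs))
    return out


def select_isolated_genes(
    parts: list[GeneParts],
    gene_type: str | None = "protein_coding",
    contigs: set[str] | None = None,
) -> list[GeneParts]:
    """Keep genes of one type, on given contigs, overlapping no other gene.

    Overlap is tested on genebody spans ignoring strand, against *all* genes
    of the flatten pass (an antisense neighbour still disqualifies a gene):
    unstranded coverage cannot attribute shared bases to either gene.
    """
    by_chrom: dict[str, list[GeneParts]] = defaultdict(list)
    for g in parts:
        by_chrom[g.chrom].append(g)
    overlapped: set[str] = set()
    for genes in by_chrom.values():
        genes = sorted(genes, key=lambda g: g.genebody.start)
        active: list[GeneParts] = []
        for g in genes:
            active = [a for a in active if a.genebody.end > g.genebody.start]
            for a in active:
                overlapped.add(a.gene_id)
                overlapped.add(g.gene_id)
            active.append(g)
    kept = []
    for g in parts:
        if g.gene_id in overlapped:
            continue
        if gene_type is not None and g.gene_type != gene_type:
            continue
        if contigs is not None and g.chrom not in contigs:
            continue
        kept.append(g)
    return kept
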