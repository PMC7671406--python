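"""Synthetic annotations, alignments and count matrices for intron analysis.

The generator emulates the read regimes that intron-aware analyses have to
distinguish:

* mature-mRNA fragments — sampled on transcript (exon-only) coordinates and
  emitted as spliced alignments with skipped-region gaps;
* pre-mRNA fragments — unspliced molecules sampled along the whole genebody,
  uniformly for total-RNA libraries and with an exponential 3' position bias
  for poly(A) libraries (fragment selection from the polyadenylated end);
* intron-retention fragments — contiguous reads within one designated intron
  at a depth tied to the gene's exon depth;

plus negative-binomial gene×sample count matrices with group-wise fold
changes applied independently to intron and exon counts, the input structure
the differential-expression workflow assumes.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GeneParts, GenomicInterval

CATEGORY_FROM_SIGNS = {
    (1, 1): "+", (-1, -1): "-",
    (1, 0): "exon+", (-1, 0): "exon-",
    (0, 1): "intron+", (0, -1): "intron-",
    (1, -1): "mixed+-", (-1, 1): "mixed-+",
    (0, 0): "0",
}


@dataclass
class SimSpec:
    """Parameters of the toy genome and read simulation.

    Gene architecture defaults give multi-exon protein-coding-like genes
    (3–8 exons of 100–300 bp separated by 200–3000 bp introns).  Reads are
    75 bp, single-end by default, 200 fragments per gene (exon depth around
    15–20×).  ``premrna_fraction`` is the fraction of fragments drawn from
    unspliced molecules (default 0.2, a total-RNA-like regime);
    ``three_prime_bias`` is the exponential rate of the poly(A) position
    bias, in units of molecule lengths.  ``ir_genes`` plants retention
    events as (gene_id, intron index, depth factor relative to exon depth).
    """

    seed: int = 0
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (200, 3000)
    protocol: str = "totalRNA"  # or "polyA"
    premrna_fraction: float = 0.2
    three_prime_bias: float = 3.0
    ir_genes: list[tuple[str, int, float]] = field(default_factory=list)
    read_length: int = 75
    paired: bool = False
    fragment_length: int = 200
    fragments_per_gene: int = 200
    overlap_pairs: int = 0
    contig: str = "chr1"
    intergenic_gap: tuple[int, int] = (500, 3000)

    def __post_init__(self) -> None:
        if not 0.0 <= self.premrna_fraction <= 1.0:
            raise ValueError("premrna_fraction must be in [0, 1]")
        if self.three_prime_bias < 0:
            raise ValueError("three_prime_bias must be >= 0")
        if self.protocol not in ("polyA", "totalRNA"):
            raise ValueError("protocol must be 'polyA' or 'totalRNA'")
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length):
            if lo <= 0 or hi < lo:
                raise ValueError("length/count ranges must be positive and ordered")

    @classmethod
    def from_json(cls, path) -> "SimSpec":
        data = json.loads(open(path).read())
        if "ir_genes" in data:
            data["ir_genes"] = [tuple(x) for x in data["ir_genes"]]
        for key in ("exons_per_gene", "exon_length", "intron_length",
                    "intergenic_gap"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def make_toy_annotation(spec: SimSpec) -> str:
    """Deterministic GENCODE-dialect GTF text for a toy gene set.

    Genes are laid left to right on one contig with random intergenic gaps;
    ``overlap_pairs`` consecutive pairs are shifted to overlap (to exercise
    multi-gene read exclusion and clamping).  Genes with at least three
    exons get a second transcript missing one internal exon, so flattening
    has real unions to take without changing the exon-part truth.
    """
    rng = np.random.default_rng(spec.seed)
    lines = []
    pos = 1000
    prev_span: tuple[int, int] | None = None
    overlaps_left = spec.overlap_pairs
    for i in range(spec.n_genes):
        gid = f"G{i + 1:04d}"
        n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exon_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1, n_ex)
        intron_lens = rng.integers(spec.intron_length[0], spec.intron_length[1] + 1,
                                   max(n_ex - 1, 0))
        strand = "+" if rng.random() < 0.5 else "-"
        start = pos + int(rng.integers(spec.intergenic_gap[0], spec.intergenic_gap[1]))
        if overlaps_left > 0 and prev_span is not None and i % 2 == 1:
            start = (prev_span[0] + prev_span[1]) // 2  # overlap previous gene
            overlaps_left -= 1
        exons = []
        cur = start
        for k in range(n_ex):
            exons.append((cur, cur + int(exon_lens[k])))
            cur = exons[-1][1] + (int(intron_lens[k]) if k < n_ex - 1 else 0)
        end = exons[-1][1]
        attrs = f'gene_id "{gid}"; gene_type "protein_coding"; gene_name "{gid}";'

        def _feat(feature, s, e, extra=""):
            lines.append("\t".join([
                spec.contig, "sim", feature, str(s + 1), str(e), ".", strand, ".",
                attrs + extra,
            ]))

        _feat("gene", start, end)
        for t, keep in enumerate(_transcript_plans(n_ex)):
            extra = f' transcript_id "{gid}.t{t + 1}"; transcript_type "protein_coding";'
            _feat("transcript", exons[keep[0]][0], exons[keep[-1]][1], extra)
            for k in keep:
                _feat("exon", exons[k][0], exons[k][1], extra)
        prev_span = (start, end)
        pos = max(pos, end)
    return "\n".join(lines) + "\n"


def _transcript_plans(n_ex: int) -> list[list[int]]:
    full = list(range(n_ex))
    if n_ex >= 3:
        return [full, [k for k in full if k != n_ex // 2]]
    return [full]


# ---------------------------------------------------------------------------
# read simulation


def _biased_start(rng: np.random.Generator, max_start: int, molecule_len: int,
                  bias: float) -> int:
    """Fragment start offset from the 5' end, optionally 3'-weighted.

    With bias b > 0, start positions are drawn with density proportional to
    exp(b·t/L) over the feasible range — an inverse-CDF draw from a
    truncated exponential, pushing fragments toward the 3' end the way
    poly(A) selection does.
    """
    if max_start <= 0:
        return 0
    if bias <= 0:
        return int(rng.integers(0, max_start + 1))
    u = rng.random()
    b = bias / molecule_len
    t = np.log1p(u * np.expm1(b * max_start)) / b
    return min(int(t), max_start)


def _transcript_to_blocks(exons: list[GenomicInterval], strand: str,
                          t_start: int, t_end: int) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to genomic blocks.

    Transcript coordinates run 5'→3' along the strand; returned genomic
    blocks are ascending.
    """
    segs = exons if strand == "+" else list(reversed(exons))
    blocks = []
    off = 0
    for iv in segs:
        seg_len = iv.length
        lo, hi = max(t_start, off), min(t_end, off + seg_len)
        if lo < hi:
            if strand == "+":
                blocks.append((iv.start + (lo - off), iv.start + (hi - off)))
            else:
                blocks.append((iv.end - (hi - off), iv.end - (lo - off)))
        off += seg_len
    return sorted(blocks)


def _cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for k, (s, e) in enumerate(blocks):
        if k:
            gap = s - blocks[k - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def simulate_fragments(
    spec: SimSpec, parts: list[GeneParts]
) -> tuple[str, pd.DataFrame]:
    """Simulate aligned fragments over a flattened toy annotation as SAM text.

    Returns the coordinate-sorted SAM and a per-gene truth table with the
    generator's own fragment tallies (total, overlapping exons, fully
    intronic) for cross-checking counters on non-overlapping gene sets.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rl = spec.read_length
    ir_map = {(g, idx): f for g, idx, f in spec.ir_genes}
    records: list[tuple[str, int, list[str]]] = []
    truth_rows = []
    contig_len = max(g.genebody.end for g in parts) + 1000
    for gene in parts:
        T = gene.total_exon_length
        L = gene.length
        if rl > T or rl > L:
            raise ValueError(f"read length {rl} exceeds gene {gene.gene_id} extent")
        n = spec.fragments_per_gene
        n_pre = int(rng.binomial(n, spec.premrna_fraction))
        n_mat = n - n_pre
        frags: list[tuple[list[tuple[int, int]], bool]] = []
        bias = spec.three_prime_bias if spec.protocol == "polyA" else 0.0
        flen = min(spec.fragment_length, rl) if not spec.paired else min(
            spec.fragment_length, T)
        for _ in range(n_mat):
            span = flen if spec.paired else rl
            t0 = _biased_start(rng, T - span, T, bias)
            frags.append((_mate_blocks(gene.exon_parts, gene.strand, t0, span, rl,
                                       spec.paired), True))
        for _ in range(n_pre):
            span = min(flen if spec.paired else rl, L)
            t0 = _biased_start(rng, L - span, L, bias)
            if gene.strand == "+":
                g0 = gene.genebody.start + t0
            else:
                g0 = gene.genebody.end - t0 - span
            if spec.paired:
                blocks = [(g0, g0 + rl), (g0 + span - rl, g0 + span)]
                blocks = _merge(blocks)
            else:
                blocks = [(g0, g0 + rl)]
            frags.append((blocks, False))
        for idx, intron in enumerate(gene.intron_parts):
            factor = ir_map.get((gene.gene_id, idx))
            if factor is None:
                continue
            if intron.length <= rl:
                raise ValueError(
                    f"retained intron {idx} of {gene.gene_id} shorter than read length")
            exon_depth = n_mat * rl / T
            n_ir = int(round(factor * exon_depth * intron.length / rl))
            for _ in range(n_ir):
                g0 = int(rng.integers(intron.start, intron.end - rl + 1))
                frags.append(([(g0, g0 + rl)], False))
        # truth tallies: brute-force block vs exon-part overlap for this gene
        n_exon = n_intron = 0
        for blocks, _spliced in frags:
            hit = any(s < iv.end and iv.start < e
                      for s, e in blocks for iv in gene.exon_parts)
            if hit:
                n_exon += 1
            else:
                n_intron += 1
        truth_rows.append({"gene_id": gene.gene_id, "n_fragments": len(frags),
                           "exon": n_exon, "genebody": len(frags),
                           "intron": n_intron})
        flag_single = 16 if gene.strand == "-" else 0
        for i, (blocks, _spliced) in enumerate(frags):
            qname = f"{gene.gene_id}_f{i}"
            if spec.paired:
                records.extend(_paired_records(qname, gene, blocks, rl, spec.contig))
            else:
                pos = blocks[0][0]
                records.append((spec.contig, pos, [
                    qname, str(flag_single), spec.contig, str(pos + 1), "60",
                    _cigar(blocks), "*", "0", "0",
                    "A" * sum(e - s for s, e in blocks), "*",
                ]))
    records.sort(key=lambda r: (r[0], r[1]))
    header = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{spec.contig}\tLN:{contig_len}",
        "@PG\tID:intronseq-sim\tPN:intronseq-sim",
    ]
    sam = "\n".join(header + ["\t".join(r[2]) for r in records]) + "\n"
    return sam, pd.DataFrame(truth_rows)


def _merge(blocks):
    blocks = sorted(blocks)
    out = [list(blocks[0])]
    for s, e in blocks[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _mate_blocks(exons, strand, t0, span, rl, paired):
    if not paired:
        return _transcript_to_blocks(exons, strand, t0, t0 + rl)
    b1 = _transcript_to_blocks(exons, strand, t0, t0 + rl)
    b2 = _transcript_to_blocks(exons, strand, t0 + span - rl, t0 + span)
    return _merge(b1 + b2)


def _paired_records(qname, gene, blocks, rl, contig):
    """Split merged fragment blocks back into two mate alignments."""
    total = sum(e - s for s, e in blocks)
    m1 = _clip_blocks(blocks, 0, rl)
    m2 = _clip_blocks(blocks, max(total - rl, 0), total)
    p1, p2 = m1[0][0], m2[0][0]
    tlen = max(b[1] for b in blocks) - blocks[0][0]
    recs = []
    for mate, (bl, pos, pnext, flag) in enumerate(
        ((m1, p1, p2, 0x1 | 0x2 | 0x40 | 0x20),
         (m2, p2, p1, 0x1 | 0x2 | 0x80 | 0x10))
    ):
        recs.append((contig, pos, [
            qname, str(flag), contig, str(pos + 1), "60", _cigar(bl), "=",
            str(pnext + 1), str(tlen if mate == 0 else -tlen),
            "A" * sum(e - s for s, e in bl), "*",
        ]))
    return recs


def _clip_blocks(blocks, lo, hi):
    """Sub-blocks covering block-coordinate (cumulative base) range [lo, hi)."""
    out = []
    off = 0
    for s, e in blocks:
        ln = e - s
        a, b = max(lo, off), min(hi, off + ln)
        if a < b:
            out.append((s + (a - off), s + (b - off)))
        off += ln
    return out


# ---------------------------------------------------------------------------
# direct count simulation


def simulate_counts(
    n_genes: int = 2000,
    group_sizes: Sequence[int] = (3, 3),
    dispersion: float = 0.05,
    exon_mean_log: float = np.log(150.0),
    exon_mean_sd: float = 1.0,
    intron_mean_ratio: float | np.ndarray = 0.3,
    exon_fc: np.ndarray | None = None,
    intron_fc: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Negative-binomial exon and intron count matrices with planted truth.

    Per-gene baseline exon means are log-normal; intron means are a fixed
    ratio of them (introns accumulate fewer reads than exons at equal
    expression).  Fold changes (second group vs first) are applied
    independently to exon and intron counts; the truth table records each
    gene's implied joint category.  Counts are NB with the given dispersion
    (variance m + φm²).
    """
    rng = np.random.default_rng(seed)
    groups = [f"grp{i + 1}" for i, n in enumerate(group_sizes) for _ in range(n)]
    samples = [f"s{j + 1}" for j in range(len(groups))]
    base_exon = rng.lognormal(exon_mean_log, exon_mean_sd, n_genes)
    base_intron = base_exon * np.broadcast_to(
        np.asarray(intron_mean_ratio, dtype=float), (n_genes,))
    exon_fc = np.ones(n_genes) if exon_fc is None else np.asarray(exon_fc, float)
    intron_fc = np.ones(n_genes) if intron_fc is None else np.asarray(intron_fc, float)

    def _draw(base, fc):
        mat = np.empty((n_genes, len(groups)), dtype=np.int64)
        for j, grp in enumerate(groups):
            mean = base * np.where(grp == "grp2", fc, 1.0)
            if dispersion > 0:
                r = 1.0 / dispersion
                p = r / (r + mean)
                mat[:, j] = rng.negative_binomial(r, p)
            else:
                mat[:, j] = rng.poisson(mean)
        return mat

    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    exon_df = pd.DataFrame(_draw(base_exon, exon_fc), index=gene_ids, columns=samples)
    intron_df = pd.DataFrame(_draw(base_intron, intron_fc), index=gene_ids,
                             columns=samples)
    sign = lambda fc: np.sign(np.log2(fc)).astype(int)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "exon_fc": exon_fc,
        "intron_fc": intron_fc,
        "category": [CATEGORY_FROM_SIGNS[(se, si)]
                     for se, si in zip(sign(exon_fc), sign(intron_fc))],
        "base_exon_mean": base_exon,
        "base_intron_mean": base_intron,
    }).set_index("gene_id")
    return exon_df, intron_df, truth, groups
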