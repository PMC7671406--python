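import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from intronseq import GeneParts, GenomicInterval
from intronseq import annotation as ann
from intronseq import synthetic as syn


def make_gene(gene_id, exons, chrom="chr1", strand="+", gene_type="protein_coding"):
    parts = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    return GeneParts(gene_id=gene_id, gene_type=gene_type, chrom=chrom,
                     strand=strand, exon_parts=parts)


@pytest.fixture
def toy_gene():
    # exons [100,200) and [300,400), intron [200,300)
    return make_gene("GA", [(100, 200), (300, 400)])


@pytest.fixture
def toy_parts(tmp_path):
    spec = syn.SimSpec(seed=11, n_genes=6)
    gtf = tmp_path / "toy.gtf"
    gtf.write_text(syn.make_toy_annotation(spec))
    return ann.flatten_gene_models(gtf)


def write_sam(path, records, contigs=(("chr1", 100000),)):
    """records: list of (qname, flag, chrom, pos0, cigar)."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in contigs:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for qname, flag, chrom, pos0, cigar in records:
        rl = _read_len(cigar)
        lines.append("\t".join([qname, str(flag), chrom, str(pos0 + 1), "60",
                                cigar, "*", "0", "0", "A" * rl, "*"]))
    Path(path).write_text("\n".join(lines) + "\n")
    return str(path)


def _read_len(cigar):
    import re
    return sum(int(n) for n, op in re.findall(r"(\d+)([MIS=X])", cigar))


def random_fixture(rng, n_genes=10, n_fragments=200, overlap_frac=0.2,
                   contig_len=200000):
    """Random genes (some overlapping) + random fragments, for oracle tests."""
    genes = []
    pos = 100
    for i in range(n_genes):
        n_ex = int(rng.integers(1, 5))
        exons = []
        start = pos + int(rng.integers(0, 500))
        cur = start
        for k in range(n_ex):
            e = cur + int(rng.integers(50, 300))
            exons.append((cur, e))
            cur = e + int(rng.integers(50, 800))
        if rng.random() < overlap_frac and genes:
            # shift back to overlap the previous gene
            prev_end = genes[-1].genebody.end
            shift = exons[0][0] - max(genes[-1].genebody.start,
                                      prev_end - int(rng.integers(50, 400)))
            exons = [(s - shift, e - shift) for s, e in exons]
        genes.append(make_gene(f"G{i}", exons))
        pos = max(pos, genes[-1].genebody.end)
    lo = min(g.genebody.start for g in genes)
    hi = max(g.genebody.end for g in genes)
    fragments = []
    for _ in range(n_fragments):
        s = int(rng.integers(max(lo - 100, 0), hi + 100))
        if rng.random() < 0.3:  # spliced
            l1 = int(rng.integers(20, 60))
            gap = int(rng.integers(30, 500))
            l2 = int(rng.integers(20, 60))
            fragments.append([(s, s + l1), (s + l1 + gap, s + l1 + gap + l2)])
        else:
            fragments.append([(s, s + int(rng.integers(30, 120)))])
    return genes, fragments


def fragments_to_sam(path, fragments, contig="chr1", contig_len=300000):
    recs = []
    for i, blocks in enumerate(fragments):
        cigar = ""
        for k, (s, e) in enumerate(blocks):
            if k:
                cigar += f"{s - blocks[k - 1][1]}N"
            cigar += f"{e - s}M"
        recs.append((f"r{i}", 0, contig, blocks[0][0], cigar))
    recs.sort(key=lambda r: r[3])
    return write_sam(path, recs, contigs=((contig, contig_len),))
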