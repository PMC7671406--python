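"""Genebody coverage profiles under total-RNA vs poly(A) library protocols.

Simulates pure pre-mRNA reads over nine genes under both protocols and
aggregates 20-window relative log-coverage profiles by gene-length tertile.
Total-RNA intron coverage is uniform along the gene; poly(A) selection
biases fragments toward the 3' end, so long genes lose 5' intron coverage.
"""

import tempfile
from pathlib import Path

import pandas as pd

from intronseq import annotation as ann
from intronseq import coverage as cov
from intronseq import synthetic as syn


def aggregate(protocol: str) -> pd.DataFrame:
    spec = syn.SimSpec(seed=9, n_genes=9, exons_per_gene=(4, 6),
                       exon_length=(120, 250), intron_length=(500, 8000),
                       premrna_fraction=1.0, protocol=protocol,
                       three_prime_bias=3.0, fragments_per_gene=12000)
    with tempfile.TemporaryDirectory() as d:
        gtf = Path(d) / "g.gtf"
        gtf.write_text(syn.make_toy_annotation(spec))
        parts = ann.flatten_gene_models(gtf)
        sam = Path(d) / "r.sam"
        sam.write_text(syn.simulate_fragments(spec, parts)[0])
        track = cov.compute_coverage(str(sam))
        profiles = pd.concat([cov.window_profile(track, g) for g in parts],
                             ignore_index=True)
        return cov.aggregate_by_length(profiles,
                                       {g.gene_id: g.length for g in parts})


for protocol in ("totalRNA", "polyA"):
    agg = aggregate(protocol)
    lng = agg[(agg.region_type == "intron")
              & (agg.length_category == "long")].set_index("window")
    w1, w20 = lng.loc[1, "mean_rel_logcov"], lng.loc[20, "mean_rel_logcov"]
    print(f"{protocol:>9s}: long-gene intron profile  "
          f"window 1 (5') = {w1:.3f}   window 20 (3') = {w20:.3f}")
print()
print("Values are mean relative log-coverage (per-base log2(depth+0.5)")
print("scaled by each gene's intron maximum).  The flat total-RNA profile")
print("and the 3'-rising poly(A) profile reproduce the two intron-coverage")
print("regimes expected of unspliced pre-mRNA under each protocol.")
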