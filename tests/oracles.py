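"""Independent brute-force / literal-transcription oracles.

Everything here is written directly from first principles (per-base loops,
O(fragments × genes) scans, textbook formula transcriptions) and shares no
code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats


# ---------------------------------------------------------------------------
# annotation


def per_base_gene_labels(exon_intervals: list[tuple[int, int]]) -> dict[int, str]:
    """Label every base of a gene's span as exon or intron, one base at a time."""
    exonic = set()
    for s, e in exon_intervals:
        exonic.update(range(s, e))
    lo, hi = min(exonic), max(exonic) + 1
    return {b: ("exon" if b in exonic else "intron") for b in range(lo, hi)}


def brute_force_isolated(spans: dict[str, tuple[str, int, int]]) -> set[str]:
    """Gene ids whose span overlaps no other gene's span (all pairs checked)."""
    out = set()
    for g, (c, s, e) in spans.items():
        if all(g2 == g or c2 != c or not (s < e2 and s2 < e)
               for g2, (c2, s2, e2) in spans.items()):
            out.add(g)
    return out


# ---------------------------------------------------------------------------
# counting


def brute_force_assign(blocks, features_by_gene) -> str | None:
    """Unique-gene assignment by scanning every feature of every gene."""
    hits = set()
    for gene, ivs in features_by_gene.items():
        for s, e in ivs:
            if any(bs < e and s < be for bs, be in blocks):
                hits.add(gene)
    return hits.pop() if len(hits) == 1 else None


def brute_force_counts(fragments, parts) -> dict[str, dict[str, int]]:
    """Exon/genebody/intron counts via O(fragments×genes) scans.

    fragments: list of block lists; parts: list of GeneParts.  Intron counts
    are the clamped difference, recomputed here from scratch.
    """
    exon_feats = {g.gene_id: [(iv.start, iv.end) for iv in g.exon_parts]
                  for g in parts}
    body_feats = {g.gene_id: [(g.genebody.start, g.genebody.end)] for g in parts}
    exon = {g.gene_id: 0 for g in parts}
    body = {g.gene_id: 0 for g in parts}
    for blocks in fragments:
        ge = brute_force_assign(blocks, exon_feats)
        if ge is not None:
            exon[ge] += 1
        gb = brute_force_assign(blocks, body_feats)
        if gb is not None:
            body[gb] += 1
    intron = {g: max(body[g] - exon[g], 0) for g in exon}
    clamped = {g: body[g] - exon[g] < 0 for g in exon}
    return {"exon": exon, "genebody": body, "intron": intron, "clamped": clamped}


# ---------------------------------------------------------------------------
# coverage


def naive_pileup(fragments, length: int) -> np.ndarray:
    """Per-base depth by incrementing one base at a time."""
    depth = np.zeros(length, dtype=int)
    for blocks in fragments:
        for s, e in blocks:
            for b in range(s, min(e, length)):
                depth[b] += 1
    return depth


def naive_region_stats(depth: np.ndarray, intervals, offset=0.5, threshold=2.0):
    """Mean/sd/max/bases-above over the per-base log-coverage of intervals."""
    vals = []
    for s, e in intervals:
        for b in range(s, e):
            vals.append(np.log2(depth[b] + offset))
    vals = np.array(vals)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return {
        "mean": float(vals.mean()),
        "sd": sd,
        "max": float(vals.max()),
        "bases_above": int((vals > threshold).sum()),
        "n_bases": vals.size,
    }


def naive_window_means(values_by_base: dict[int, float], length: int,
                       n_windows: int, strand: str) -> dict[int, float]:
    """Window means computed base by base from a {genebody offset: value} map."""
    acc: dict[int, list[float]] = {}
    for off, v in values_by_base.items():
        w = off * n_windows // length + 1
        if strand == "-":
            w = n_windows + 1 - w
        acc.setdefault(w, []).append(v)
    return {w: float(np.mean(v)) for w, v in acc.items()}


# ---------------------------------------------------------------------------
# statistics


def tmm_oracle(counts: np.ndarray, lib: np.ndarray,
               logratio_trim=0.3, sum_trim=0.05) -> np.ndarray:
    """Literal transcription of the trimmed-mean-of-M-values definition."""
    counts = np.asarray(counts, float)
    lib = np.asarray(lib, float)
    nsam = counts.shape[1]
    f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(nsam)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    logfac = np.zeros(nsam)
    for k in range(nsam):
        yk, yr = counts[:, k], counts[:, ref]
        nk, nr = lib[k], lib[ref]
        use = (yk > 0) & (yr > 0)
        M = np.log2((yk[use] / nk) / (yr[use] / nr))
        A = 0.5 * np.log2(yk[use] / nk * yr[use] / nr)
        n = M.size
        lo_m = np.floor(n * logratio_trim) + 1
        lo_a = np.floor(n * sum_trim) + 1
        rm = stats.rankdata(M)
        ra = stats.rankdata(A)
        keep = ((rm >= lo_m) & (rm <= n + 1 - lo_m)
                & (ra >= lo_a) & (ra <= n + 1 - lo_a))
        w = 1.0 / ((nk - yk[use]) / (nk * yk[use]) + (nr - yr[use]) / (nr * yr[use]))
        logfac[k] = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    factors = 2.0 ** logfac
    return factors / stats.gmean(factors)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up BH by explicit sort / cumulative minimum / unsort."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def wls_oracle(y, X, w, c):
    """Weighted least squares through explicit normal equations."""
    W = np.diag(w)
    A = X.T @ W @ X
    beta = np.linalg.solve(A, X.T @ W @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ W @ resid) / df
    se_unscaled = float(np.sqrt(c @ np.linalg.inv(A) @ c))
    return float(c @ beta), sigma2, df, se_unscaled


def prior_oracle(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the log-variance model, inverting trigamma with brentq."""
    s2 = np.asarray(s2, float)
    G = s2.size
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    ebar = e.mean()
    rhs = np.sum((e - ebar) ** 2) / (G - 1) - special.polygamma(1, df / 2)
    if rhs <= 0:
        return np.inf, float(np.exp(ebar))
    half_d0 = optimize.brentq(lambda x: special.polygamma(1, x) - rhs, 1e-8, 1e8)
    d0 = 2 * half_d0
    s0 = float(np.exp(ebar + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def filter_oracle(counts: np.ndarray, groups, min_count=10, min_total=15):
    """Literal transcription of the expression-filter rule."""
    counts = np.asarray(counts, float)
    lib = counts.sum(axis=0)
    cpm_cutoff = min_count / np.median(lib) * 1e6
    from collections import Counter
    sizes = Counter(groups)
    n = min(sizes.values())
    if n > 10:
        n = 10 + (n - 10) * 0.7
    keep = []
    for g in range(counts.shape[0]):
        cpm = counts[g] / lib * 1e6
        keep.append((cpm >= cpm_cutoff).sum() >= n - 1e-14
                    and counts[g].sum() >= min_total - 1e-14)
    return np.array(keep)
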