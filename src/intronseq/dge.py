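"""Joint intron/exon differential-expression workflow.

Intron and exon count sets for the same genes are analysed side by side:
genes are filtered for expression in each set, both sets are normalised with
trimmed-mean-of-M-values (TMM) factors computed against the *combined*
library size (per-sample sum of the filtered intron plus exon counts, a
better proxy for sequencing depth than either set alone), modelled with
precision-weighted linear models on log-CPM, moderated with empirical-Bayes
variance shrinkage, and FDR-adjusted.  Each gene then receives one of nine
categories describing joint significance and direction:

    +        up in both intron and exon counts
    -        down in both
    exon+/-  significant in exon counts only
    intron+/-significant in intron counts only
    mixed+-  up in exons, down in introns
    mixed-+  down in exons, up in introns
    0        significant in neither

Intron counts track pre-mRNA abundance while exon counts mix mRNA and
pre-mRNA, so the categories separate early-transcriptional from mature-RNA
changes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CATEGORIES = ["+", "-", "exon+", "exon-", "intron+", "intron-",
              "mixed+-", "mixed-+", "0"]


@dataclass
class DesignSpec:
    """A design matrix, a contrast over its columns, and sample group labels."""

    design_matrix: np.ndarray
    contrast: np.ndarray
    sample_groups: list[str]

    def __post_init__(self) -> None:
        X = np.asarray(self.design_matrix, dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if not np.any(np.asarray(self.contrast)):
            raise ValueError("contrast vector is all zero")
        self.design_matrix = X
        self.contrast = np.asarray(self.contrast, dtype=float)


def design_from_groups(groups: list[str], contrast: str) -> DesignSpec:
    """Group-means design with a ``"B-A"`` style contrast string."""
    levels = sorted(set(groups))
    X = np.array([[1.0 if g == lv else 0.0 for lv in levels] for g in groups])
    try:
        pos, neg = contrast.split("-")
    except ValueError as exc:
        raise ValueError(f"cannot parse contrast {contrast!r}; expected 'B-A'") from exc
    pos, neg = pos.strip(), neg.strip()
    for name in (pos, neg):
        if name not in levels:
            raise ValueError(f"contrast group {name!r} not among groups {levels}")
    c = np.array([1.0 if lv == pos else -1.0 if lv == neg else 0.0 for lv in levels])
    return DesignSpec(X, c, list(groups))


@dataclass
class FitResult:
    """Per-gene linear-model estimates and moderated statistics."""

    gene_ids: list[str]
    logFC: np.ndarray
    sigma2: np.ndarray
    df_resid: np.ndarray
    stdev_unscaled: np.ndarray
    d0: float = np.nan
    s0_sq: float = np.nan
    t_mod: np.ndarray | None = None
    p: np.ndarray | None = None
    p_adj: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "logFC": self.logFC,
                "t_mod": self.t_mod,
                "p": self.p,
                "p_adj": self.p_adj,
                "sigma2": self.sigma2,
                "df_resid": self.df_resid,
            }
        ).set_index("gene_id")


# ---------------------------------------------------------------------------
# filtering and normalisation


def filter_expressed(
    counts: np.ndarray,
    groups: list[str],
    min_count: float = 10,
    min_total: float = 15,
    large_n: int = 10,
    min_prop: float = 0.7,
) -> np.ndarray:
    """Keep-mask for genes with worthwhile counts, given the group structure.

    A gene is kept when its CPM exceeds ``min_count`` (re-expressed on the
    CPM scale of the median library) in at least as many samples as the
    smallest group holds — damped to ``large_n + (n − large_n)·min_prop``
    for groups larger than ``large_n`` — and its total count reaches
    ``min_total``.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    cutoff = min_count / np.median(lib) * 1e6
    cpm = counts / lib * 1e6
    sizes = pd.Series(groups).value_counts()
    n = float(sizes.min())
    if n > large_n:
        n = large_n + (n - large_n) * min_prop
    tol = 1e-14
    keep_cpm = (cpm >= cutoff).sum(axis=1) >= n - tol
    keep_total = counts.sum(axis=1) >= min_total - tol
    return keep_cpm & keep_total


def combined_library_sizes(intron_counts: np.ndarray, exon_counts: np.ndarray
                           ) -> np.ndarray:
    """Per-sample sum of the (filtered) intron and exon count matrices."""
    if intron_counts.shape[1] != exon_counts.shape[1]:
        raise ValueError("sample dimensions differ between count sets")
    lib = intron_counts.sum(axis=0) + exon_counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("zero combined library size for at least one sample")
    return np.asarray(lib, dtype=float)


def tmm_factors(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors (geometric mean 1).

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean of those fractions.  Per sample, log-ratios (M) and
    average log-abundances (A) against the reference — over genes positive in
    both — are doubly trimmed, then averaged with inverse approximate
    binomial variances.
    """
    counts = np.asarray(counts, dtype=float)
    lib = np.asarray(lib_sizes, dtype=float)
    nsam = counts.shape[1]
    if nsam < 2:
        warnings.warn("fewer than 2 samples; all TMM factors set to 1")
        return np.ones(nsam)
    f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(nsam)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(nsam)
    for j in range(nsam):
        factors[j] = _tmm_pair(counts[:, j], counts[:, ref], lib[j], lib[ref],
                               logratio_trim, sum_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, sum_trim) -> float:
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    M = np.log2((obs / n_obs) / (ref / n_ref))
    A = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # double trim on rank, matching the classic definition
    n = M.size
    loM = np.floor(n * logratio_trim) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * sum_trim) + 1
    hiA = n + 1 - loA
    rM = stats.rankdata(M)
    rA = stats.rankdata(A)
    keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not np.any(keep):
        return 1.0
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def log_cpm(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    tmm: np.ndarray | None = None,
    offset: float = 2.0,
) -> np.ndarray:
    """log2 counts-per-million with a pseudo-count offset.

    Offset 2 is used for exploratory values and MDS; 0.5 inside the
    precision-weight computation; correlation analyses use plain log-counts
    with offset 1 instead.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    lib = np.asarray(lib_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    eff = lib * (tmm if tmm is not None else 1.0)
    return np.log2((np.asarray(counts, dtype=float) + offset) * 1e6 / eff)


def log_rpkm(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    region_lengths: np.ndarray,
    tmm: np.ndarray | None = None,
    offset: float = 2.0,
) -> np.ndarray:
    """log2 reads per kilobase per million; zero-length regions become NaN."""
    lengths = np.asarray(region_lengths, dtype=float)
    bad = lengths <= 0
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} zero-length regions excluded from log-RPKM")
        lengths = np.where(bad, np.nan, lengths)
    lc = log_cpm(counts, lib_sizes, tmm, offset)
    return lc - np.log2(lengths / 1e3)[:, None]


# ---------------------------------------------------------------------------
# model fitting


def voom_weights(
    counts: np.ndarray,
    design: np.ndarray,
    lib_sizes: np.ndarray,
    tmm: np.ndarray | None = None,
    span: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-CPM (offset 0.5) and inverse mean-variance-trend precision weights.

    Unweighted per-gene fits give residual standard deviations whose square
    roots are smoothed (lowess, given span) against average log2 count; each
    observation's predicted log2 count is looked up on that trend (linear
    interpolation, constant beyond the range) and the fourth inverse power of
    the trend value becomes its weight.
    """
    counts = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    n_genes, n_samples = counts.shape
    eff = np.asarray(lib_sizes, dtype=float) * (tmm if tmm is not None else 1.0)
    y = np.log2((counts + 0.5) * 1e6 / eff)
    if n_samples <= X.shape[1]:
        raise ValueError("no residual degrees of freedom for the design")
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    fitted = (X @ beta).T
    resid = y - fitted
    df = n_samples - X.shape[1]
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df)
    if n_genes < 10:
        warnings.warn("fewer than 10 genes; using constant precision weights")
        return y, np.ones_like(y)
    sx = y.mean(axis=1) + np.mean(np.log2(eff)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = lowess(sy, sx, frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    fitted_logcount = fitted + np.log2(eff)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_logcount, tx, ty)  # constant beyond range
    weights = pred ** -4
    return y, weights


def fit_linear_models(
    logcpm: np.ndarray,
    weights: np.ndarray,
    design: DesignSpec | np.ndarray,
    contrast: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
) -> FitResult:
    """Per-gene weighted least squares and the contrast estimate."""
    if isinstance(design, DesignSpec):
        X, c = design.design_matrix, design.contrast
    else:
        X = np.asarray(design, dtype=float)
        c = np.asarray(contrast, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    y = np.asarray(logcpm, dtype=float)
    w = np.asarray(weights, dtype=float)
    n_genes, n_samples = y.shape
    if n_samples < X.shape[1] + 1:
        raise ValueError("need at least one residual degree of freedom")
    ids = gene_ids if gene_ids is not None else [str(i) for i in range(n_genes)]
    logFC = np.empty(n_genes)
    sigma2 = np.empty(n_genes)
    stdev_unscaled = np.empty(n_genes)
    df = float(n_samples - X.shape[1])
    for g in range(n_genes):
        wg = w[g]
        Xw = X * wg[:, None]
        xtx = X.T @ Xw
        xty = Xw.T @ y[g]
        beta = np.linalg.solve(xtx, xty)
        cov_unscaled = np.linalg.inv(xtx)
        r = y[g] - X @ beta
        logFC[g] = c @ beta
        sigma2[g] = float((wg * r ** 2).sum() / df)
        stdev_unscaled[g] = float(np.sqrt(c @ cov_unscaled @ c))
    return FitResult(ids, logFC, sigma2, np.full(n_genes, df), stdev_unscaled)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def estimate_prior(sigma2: np.ndarray, df_resid: np.ndarray) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0²) from the residual variances.

    Log variances are matched to a scaled-F model via digamma/trigamma
    moments; the prior degrees of freedom come from inverting the trigamma
    function on the excess variance of the log variances, and become
    infinite when no excess remains.
    """
    ok = (df_resid > 0) & (sigma2 > 0) & np.isfinite(sigma2)
    s2, d = sigma2[ok], df_resid[ok]
    G = s2.size
    if G < 2:
        raise ValueError("need at least two genes with positive residual variance")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = np.sum((e - emean) ** 2) / (G - 1) - np.mean(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return float(d0), s0_sq


def ebayes_moderate(fit: FitResult) -> FitResult:
    """Moderated t-statistics via variance shrinkage toward the prior.

    Posterior variances blend each gene's residual variance with the prior
    in proportion to their degrees of freedom; t-statistics use the posterior
    variance with d0 + df residual degrees of freedom.  BH-adjusted p-values
    are attached.
    """
    if np.all(fit.sigma2 <= 0):
        raise ValueError("all residual variances are zero; cannot moderate")
    d0, s0_sq = estimate_prior(fit.sigma2, fit.df_resid)
    fit.d0, fit.s0_sq = d0, s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(fit.sigma2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + fit.df_resid * fit.sigma2) / (d0 + fit.df_resid)
    fit.t_mod = fit.logFC / (fit.stdev_unscaled * np.sqrt(s2_post))
    df_total = fit.df_resid + d0
    fit.p = 2.0 * stats.t.sf(np.abs(fit.t_mod), df_total)
    fit.p_adj = bh_adjust(fit.p)
    return fit


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment; NaNs pass through, excluded from n."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# classification and exploratory statistics


def classify_genes(
    exon_fit: FitResult, intron_fit: FitResult, alpha: float = 0.01
) -> pd.DataFrame:
    """Nine-way joint significance/direction category per gene.

    A test contributes only if adjusted p < alpha *and* its logFC has a
    direction (an exactly-zero logFC is treated as non-significant).
    """
    if exon_fit.gene_ids != intron_fit.gene_ids:
        raise ValueError("exon and intron fits cover different gene sets")
    sigE = (exon_fit.p_adj < alpha) & (exon_fit.logFC != 0)
    sigI = (intron_fit.p_adj < alpha) & (intron_fit.logFC != 0)
    upE = exon_fit.logFC > 0
    upI = intron_fit.logFC > 0
    cats = []
    for se, si, ue, ui in zip(sigE, sigI, upE, upI):
        if se and si:
            if ue and ui:
                cats.append("+")
            elif not ue and not ui:
                cats.append("-")
            elif ue:
                cats.append("mixed+-")
            else:
                cats.append("mixed-+")
        elif se:
            cats.append("exon+" if ue else "exon-")
        elif si:
            cats.append("intron+" if ui else "intron-")
        else:
            cats.append("0")
    df = pd.DataFrame(
        {
            "gene_id": exon_fit.gene_ids,
            "category": pd.Categorical(cats, categories=CATEGORIES),
            "exon_logFC": exon_fit.logFC,
            "exon_t": exon_fit.t_mod,
            "exon_p_adj": exon_fit.p_adj,
            "intron_logFC": intron_fit.logFC,
            "intron_t": intron_fit.t_mod,
            "intron_p_adj": intron_fit.p_adj,
        }
    ).set_index("gene_id")
    return df


def correlation_exon_intron(
    exon_counts: pd.DataFrame,
    intron_counts: pd.DataFrame,
    min_count: int = 3,
    offset: float = 1.0,
) -> pd.Series:
    """Per-sample Pearson correlation of exon vs intron log2 counts.

    Restricted per sample to genes with both counts at or above
    ``min_count``; returns NaN (with a warning) when fewer than three genes
    qualify.
    """
    common = exon_counts.index.intersection(intron_counts.index)
    ex = exon_counts.loc[common]
    it = intron_counts.loc[common]
    rs = {}
    for sample in ex.columns:
        mask = (ex[sample] >= min_count) & (it[sample] >= min_count)
        if mask.sum() < 3:
            warnings.warn(f"sample {sample}: fewer than 3 co-expressed genes")
            rs[sample] = np.nan
            continue
        x = np.log2(ex.loc[mask, sample] + offset)
        y = np.log2(it.loc[mask, sample] + offset)
        rs[sample] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(rs, name="pearson_r")


def expression_pattern(
    exon_counts: pd.DataFrame, intron_counts: pd.DataFrame, min_count: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each gene per library as both / exon_only / intron_only / unexpressed.

    A count of ``min_count`` or more marks a region as expressed; the
    summary reports, per library and averaged across libraries, the
    percentage of expressed genes in each label.
    """
    common = exon_counts.index.intersection(intron_counts.index)
    ex = exon_counts.loc[common].to_numpy()
    it = intron_counts.loc[common].to_numpy()
    hi_e, hi_i = ex >= min_count, it >= min_count
    labels = np.where(hi_e & hi_i, "both",
                      np.where(hi_e, "exon_only",
                               np.where(hi_i, "intron_only", "unexpressed")))
    lab_df = pd.DataFrame(labels, index=common, columns=exon_counts.columns)
    pct_rows = []
    for sample in lab_df.columns:
        col = lab_df[sample]
        expressed = col != "unexpressed"
        denom = max(int(expressed.sum()), 1)
        pct_rows.append({
            "sample_id": sample,
            **{lab: 100.0 * float((col[expressed] == lab).sum()) / denom
               for lab in ("both", "exon_only", "intron_only")},
        })
    pct = pd.DataFrame(pct_rows).set_index("sample_id")
    pct.loc["mean"] = pct.mean()
    return lab_df, pct.reset_index()


def mds_leading_logfc(
    logcpm: np.ndarray,
    top: int = 500,
    dims: int = 2,
    sample_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical MDS of samples on leading-logFC distances.

    The distance between two samples is the root-mean-square of their
    ``top`` largest absolute log-expression differences, with the top genes
    chosen per pair.  Returns coordinates and the eigenvalue fractions
    (variance explained) of the retained dimensions.
    """
    y = np.asarray(logcpm, dtype=float)
    n_genes, n_samples = y.shape
    if n_samples < 3:
        raise ValueError("MDS needs at least 3 samples")
    if n_genes < top:
        warnings.warn(f"only {n_genes} genes available; using all for MDS")
        top = n_genes
    D2 = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            d2 = (y[:, i] - y[:, j]) ** 2
            sel = np.sort(d2)[::-1][:top]
            D2[i, j] = D2[j, i] = sel.mean()
    J = np.eye(n_samples) - np.ones((n_samples, n_samples)) / n_samples
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 0
    var_explained = np.where(pos, vals, 0.0) / vals[pos].sum()
    coords = vecs[:, :dims] * np.sqrt(np.maximum(vals[:dims], 0.0))
    ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    cdf = pd.DataFrame(coords, index=ids,
                       columns=[f"dim{k + 1}" for k in range(dims)])
    return cdf, var_explained[:dims]


# ---------------------------------------------------------------------------
# the full workflow


@dataclass
class JointDGEResult:
    category_table: pd.DataFrame
    exon_fit: FitResult
    intron_fit: FitResult
    kept_genes: list[str]
    side_table: pd.DataFrame
    combined_lib_sizes: np.ndarray
    tmm_exon: np.ndarray = field(default_factory=lambda: np.array([]))
    tmm_intron: np.ndarray = field(default_factory=lambda: np.array([]))


def run_joint_dge(
    exon_counts: pd.DataFrame,
    intron_counts: pd.DataFrame,
    design: DesignSpec,
    alpha: float = 0.01,
    libsize: str = "filtered",
    span: float = 0.5,
) -> JointDGEResult:
    """Run the full workflow on exon and intron gene×sample count tables.

    Filtering is applied to each set independently; only genes expressed in
    *both* sets are carried into modelling and classification, the rest are
    reported in a side table.  ``libsize`` selects whether combined library
    sizes sum the filtered ("filtered", default) or raw ("raw") matrices.
    """
    common = exon_counts.index.intersection(intron_counts.index)
    ex = exon_counts.loc[common]
    it = intron_counts.loc[common]
    groups = design.sample_groups
    keep_e = filter_expressed(ex.to_numpy(), groups)
    keep_i = filter_expressed(it.to_numpy(), groups)
    keep = keep_e & keep_i
    if not keep.any():
        raise ValueError("no genes pass expression filtering in both count sets; "
                         "lower min_count/min_total")
    kept_genes = list(common[keep])
    side = pd.DataFrame(
        {"expressed_exon": keep_e, "expressed_intron": keep_i}, index=common
    ).loc[keep_e ^ keep_i]
    ex_f = ex.loc[kept_genes].to_numpy().astype(float)
    it_f = it.loc[kept_genes].to_numpy().astype(float)
    if libsize == "filtered":
        lib = combined_library_sizes(it.to_numpy()[keep_i], ex.to_numpy()[keep_e])
    elif libsize == "raw":
        lib = combined_library_sizes(it.to_numpy(), ex.to_numpy())
    else:
        raise ValueError("libsize must be 'filtered' or 'raw'")
    tmm_e = tmm_factors(ex_f, lib)
    tmm_i = tmm_factors(it_f, lib)
    fits = {}
    for name, mat, tmm in (("exon", ex_f, tmm_e), ("intron", it_f, tmm_i)):
        y, w = voom_weights(mat, design.design_matrix, lib, tmm, span=span)
        fit = fit_linear_models(y, w, design, gene_ids=kept_genes)
        fits[name] = ebayes_moderate(fit)
    table = classify_genes(fits["exon"], fits["intron"], alpha=alpha)
    logger.info("classified %d genes: %s", len(table),
                table["category"].value_counts().to_dict())
    return JointDGEResult(table, fits["exon"], fits["intron"], kept_genes, side,
                          lib, tmm_e, tmm_i)
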