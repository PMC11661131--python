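"""Genome-wide association of longitudinal endpoints under the kinship LMM.

Variance components are estimated once by REML under the no-SNP null and
plugged into every per-SNP Wald test (the strategy of standard mixed-model
GWAS software). Because the strain-level SNP dosage is constant within a
mouse and across days, each test reduces — after the one-off eigenrotation
of the mouse kinship matrix — to a handful of inner products, so a scan is
a single matrix product plus vector arithmetic. Genome-wide 5% thresholds
come from permuting the strain-to-genotype assignment while keeping each
mouse's longitudinal record, covariates, and phenotype-side covariance
intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import _design_matrix
from .lmm import LmmFit, _KronEngine, _unpack_theta, fit_longitudinal_lmm
from .panel import GenotypePanel, KinshipMatrix, compute_grm

MERGE_BP = 2_000_000
CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def filter_snps(
    panel: GenotypePanel, maf_min: float = 0.05, miss_max: float = 0.10
) -> GenotypePanel:
    """Drop SNPs with minor allele frequency < maf_min or missingness > miss_max."""
    maf = panel.maf()
    miss = panel.missing_fraction()
    keep = (maf >= maf_min) & (miss <= miss_max) & ~np.isnan(maf)
    if not keep.any():
        raise ValueError("no SNP passes the MAF/missingness filter")
    out = panel.subset_snps(keep)
    out.filter_log = {  # type: ignore[attr-defined]
        "n_input": panel.n_snps,
        "n_removed_maf": int((maf < maf_min).sum() + np.isnan(maf).sum()),
        "n_removed_missing": int((miss > miss_max).sum()),
        "n_kept": out.n_snps,
    }
    return out


@dataclass
class NullModel:
    """Null-model fit plus the aligned arrays a scan needs."""

    fit: LmmFit
    day: np.ndarray
    Y: np.ndarray  # (n_mice, T)
    X: np.ndarray  # (n_mice, T, p)
    fixef_names: list
    strains_used: list
    mouse_strain_idx: np.ndarray  # (n_mice,) into strains_used
    K_mouse: np.ndarray
    endpoint: str = "value"
    n_dropped_mice: int = 0


def fit_null_model(
    table: pd.DataFrame,
    grm: KinshipMatrix,
    endpoint_col: str = "value",
    normalized: bool = True,
    theta0: np.ndarray | None = None,
) -> NullModel:
    """REML fit of the no-SNP longitudinal model on a balanced table.

    ``endpoint_col`` must already be normalized (use
    :func:`longqtl.behavior.normalize_endpoint` first) unless
    ``normalized=False`` in which case values are used as-is. Mice with any
    missing endpoint cell are dropped listwise so the day grid is complete.
    """
    tab = table.dropna(subset=[endpoint_col]).copy()
    days = np.sort(tab["day"].unique()).astype(float)
    counts = tab.groupby("mouse_id")["day"].count()
    complete = counts[counts == len(days)].index
    n_dropped = tab["mouse_id"].nunique() - len(complete)
    tab = tab[tab["mouse_id"].isin(complete)]
    if tab["strain"].nunique() < 2:
        raise ValueError("need at least two strains")
    tab = tab.sort_values(["mouse_id", "day"], kind="stable").reset_index(drop=True)

    X, names = _design_matrix(tab)
    fit = fit_longitudinal_lmm(
        y=tab[endpoint_col].to_numpy(dtype=float),
        X=X,
        day=tab["day"].to_numpy(dtype=float),
        mouse=tab["mouse_id"].to_numpy(),
        K=grm.expand(
            tab.drop_duplicates("mouse_id")["strain"].tolist()
        ),
        include_genetic=True,
        fixef_names=names,
        theta0=theta0,
    )
    mice = tab.drop_duplicates("mouse_id")
    strains_used = list(dict.fromkeys(mice["strain"]))
    s_index = {s: i for i, s in enumerate(strains_used)}
    n, T = len(mice), len(days)
    return NullModel(
        fit=fit,
        day=days,
        Y=tab[endpoint_col].to_numpy(dtype=float).reshape(n, T),
        X=X.reshape(n, T, X.shape[1]),
        fixef_names=names,
        strains_used=strains_used,
        mouse_strain_idx=mice["strain"].map(s_index).to_numpy(),
        K_mouse=grm.expand(mice["strain"].tolist()),
        endpoint=endpoint_col,
        n_dropped_mice=n_dropped,
    )


@dataclass
class _ScanContext:
    """Per-dataset quantities for testing mouse-constant regressors with V plugged in."""

    U: np.ndarray | None
    cy: np.ndarray  # (n,)
    cX: np.ndarray  # (n, p)
    tvec: np.ndarray  # (n,)
    XVX_inv: np.ndarray
    beta: np.ndarray
    strain_idx: np.ndarray
    n_strains: int
    n_obs: int
    C: np.ndarray = field(default=None, repr=False)  # (n, n_strains) rotated incidence

    def stats(self, G_strain: np.ndarray):
        """Wald statistics for strain-level dosage columns (no missing)."""
        Ug = self.C @ G_strain
        XtG = Ug.T @ self.cX  # (m, p)
        num = Ug.T @ self.cy - XtG @ self.beta
        den = (Ug**2).T @ self.tvec - np.einsum(
            "mp,pq,mq->m", XtG, self.XVX_inv, XtG, optimize=True
        )
        return num, den


def _make_context(Y, X, day, K_mouse, strain_idx, n_strains, theta, engine=None) -> _ScanContext:
    eng = engine if engine is not None else _KronEngine(Y, X, day, K_mouse)
    Sg, Se, s2 = _unpack_theta(theta, True)
    out = eng._gls(Sg, Se, s2)
    if out is None:
        raise ValueError("plugged variance components give a singular covariance")
    _, _, XVy, XVX, Q = out
    h1 = eng.F.T @ np.ones(eng.T)
    cy = (eng.ysum - np.einsum("f,nfg,ng->n", h1, Q, eng.FtY, optimize=True)) / s2
    cX = (eng.Xsum - np.einsum("f,nfg,ngp->np", h1, Q, eng.FtX, optimize=True)) / s2
    tvec = (eng.T - np.einsum("f,nfg,g->n", h1, Q, h1, optimize=True)) / s2
    # pinv: a per-SNP strain subset can zero out a covariate level (e.g. a
    # whole cohort dropped), which is equivalent to dropping that column
    XVX_inv = np.linalg.pinv(XVX)
    E = np.zeros((eng.n, n_strains))
    E[np.arange(eng.n), strain_idx] = 1.0
    C = E if eng.U is None else eng.U.T @ E
    return _ScanContext(
        U=eng.U,
        cy=cy,
        cX=cX,
        tvec=tvec,
        XVX_inv=XVX_inv,
        beta=XVX_inv @ XVy,
        strain_idx=strain_idx,
        n_strains=n_strains,
        n_obs=eng.N,
        C=C,
    )


def _full_context(null: NullModel) -> _ScanContext:
    """Scan context for the complete data, caching on the null model.

    Reuses the REML fit's engine (and its eigendecomposition) when the fit
    ran on the fast balanced path.
    """
    cached = getattr(null, "_ctx_cache", None)
    if cached is not None:
        return cached
    engine = null.fit.engine if isinstance(null.fit.engine, _KronEngine) else None
    ctx = _make_context(
        null.Y, null.X, null.day, null.K_mouse, null.mouse_strain_idx,
        len(null.strains_used), null.fit.theta, engine=engine,
    )
    null._ctx_cache = ctx
    return ctx


def _results_frame(snp_meta, beta, se, z, p, n_used, flags):
    return pd.DataFrame(
        {
            "snp": snp_meta.index,
            "chrom": snp_meta["chrom"].to_numpy(),
            "bp": snp_meta["bp"].to_numpy(),
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "n_used": n_used,
            "flag": flags,
        }
    ).reset_index(drop=True)


def wald_scan(
    null: NullModel, panel: GenotypePanel, missing_policy: str = "drop"
) -> pd.DataFrame:
    """Per-SNP Wald test of the SNP fixed effect with plugged-in null covariance.

    Missing genotype calls drop the affected strains' mice for that SNP
    (``missing_policy='drop'``, exact) or are imputed to the per-SNP mean
    (``'mean'``). Monomorphic SNPs (after dropping) are emitted with p = 1
    and a flag.
    """
    theta = null.fit.theta
    sidx = {s: i for i, s in enumerate(null.strains_used)}
    rows_in_panel = np.array([panel.strain_ids.index(s) for s in null.strains_used])
    G = panel.genotypes[rows_in_panel, :]  # (n_used_strains, m)
    m = G.shape[1]
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    z = np.zeros(m)
    p = np.ones(m)
    n_used = np.zeros(m, dtype=int)
    flags = np.array([""] * m, dtype=object)

    ctx_full = _full_context(null)

    if missing_policy == "mean":
        Gi = G.copy()
        mu = np.nanmean(Gi, axis=0)
        ind = np.where(np.isnan(Gi))
        Gi[ind] = mu[ind[1]]
        groups = {(): np.arange(m)}
        G_use = Gi
    elif missing_policy == "drop":
        G_use = G
        miss = np.isnan(G)
        patterns: dict[tuple, list] = {}
        for j in range(m):
            key = tuple(np.where(miss[:, j])[0])
            patterns.setdefault(key, []).append(j)
        groups = {k: np.array(v) for k, v in patterns.items()}
    else:
        raise ValueError("missing_policy must be 'drop' or 'mean'")

    for key, cols in groups.items():
        if len(key) == 0:
            ctx = ctx_full
            Gs = G_use[:, cols]
        else:
            keep_strains = np.setdiff1d(np.arange(len(null.strains_used)), np.array(key))
            mouse_mask = np.isin(null.mouse_strain_idx, keep_strains)
            remap = -np.ones(len(null.strains_used), dtype=int)
            remap[keep_strains] = np.arange(len(keep_strains))
            ctx = _make_context(
                null.Y[mouse_mask],
                null.X[mouse_mask],
                null.day,
                null.K_mouse[np.ix_(mouse_mask, mouse_mask)],
                remap[null.mouse_strain_idx[mouse_mask]],
                len(keep_strains),
                theta,
            )
            Gs = G_use[np.ix_(keep_strains, cols)]
        mono = np.nanstd(Gs, axis=0) == 0
        num, den = ctx.stats(np.nan_to_num(Gs))
        ok = (den > 1e-10) & ~mono
        beta[cols] = np.where(ok, num / np.where(den > 0, den, 1.0), 0.0)
        se[cols] = np.where(ok, 1.0 / np.sqrt(np.where(den > 0, den, 1.0)), np.nan)
        z[cols] = np.where(ok, num / np.sqrt(np.where(den > 0, den, 1.0)), 0.0)
        p[cols] = np.where(ok, 2.0 * stats.norm.sf(np.abs(z[cols])), 1.0)
        n_used[cols] = ctx.n_obs
        flags[cols[~ok]] = "monomorphic"

    res = _results_frame(panel.snps, beta, se, z, p, n_used, flags)
    return res.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)


class _PermScanner:
    """Permutation rescans for one (null model, SNP set) pair.

    Uses projected sufficient statistics: for a strain permutation with
    inverse ``inv``, the per-SNP numerator is G' ccy[inv], the covariate
    term G' ccX[inv], and the denominator diag(G' T[inv,inv] G), where
    ccy/ccX/T are the strain-level projections of the scan context — so a
    full rescan costs a few small matrix products.
    """

    def __init__(self, null: NullModel, panel: GenotypePanel):
        ctx = _full_context(null)
        rows = np.array([panel.strain_ids.index(s) for s in null.strains_used])
        G = panel.genotypes[rows, :].copy()
        mu = np.nanmean(G, axis=0)
        ind = np.where(np.isnan(G))
        G[ind] = mu[ind[1]]
        keep = G.std(axis=0) > 0
        self.G = G[:, keep]
        C = ctx.C
        self.ccy = C.T @ ctx.cy
        self.ccX = C.T @ ctx.cX
        self.Tm = C.T @ (ctx.tvec[:, None] * C)
        self.XVX_inv = ctx.XVX_inv
        self.beta = ctx.beta
        self.n_strains = self.G.shape[0]

    def max_abs_z(self, inv: np.ndarray) -> float:
        G = self.G
        num = G.T @ self.ccy[inv]
        Xterm = G.T @ self.ccX[inv]
        den = (G * (self.Tm[np.ix_(inv, inv)] @ G)).sum(axis=0)
        den = den - np.einsum("mp,pq,mq->m", Xterm, self.XVX_inv, Xterm, optimize=True)
        resid = num - Xterm @ self.beta
        ok = den > 1e-10
        if not ok.any():
            return 0.0
        return float((np.abs(resid[ok]) / np.sqrt(den[ok])).max())


def _check_perm_args(alpha, n_perm):
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if np.floor(alpha * (n_perm + 1)) < 1:
        raise ValueError(
            f"n_perm={n_perm} too small for alpha={alpha}: needs floor(alpha*(n_perm+1)) >= 1"
        )


def permutation_threshold(
    null: NullModel,
    panel: GenotypePanel,
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
    return_maxima: bool = False,
):
    """Genome-wide |Z| threshold at familywise level ``alpha`` by permutation.

    Shuffles the strain-to-genotype assignment (each mouse keeps its
    longitudinal record, covariates and the phenotype-side covariance) and
    rescans; the threshold is the (1 - alpha) empirical quantile of the
    per-permutation max |Z|. Genotype columns are mean-imputed inside the
    permutations so the same observations enter every permutation replicate.
    """
    _check_perm_args(alpha, n_perm)
    rng = np.random.default_rng(seed)
    scanner = _PermScanner(null, panel)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(scanner.n_strains)
        inv = np.argsort(perm)
        maxima[b] = scanner.max_abs_z(inv)
    thr = float(np.quantile(maxima, 1.0 - alpha))
    if return_maxima:
        return thr, maxima
    return thr


# --- leave-one-chromosome-out (LOCO) mode ----------------------------------

def fit_loco_nulls(
    table: pd.DataFrame,
    panel: GenotypePanel,
    endpoint_col: str = "value",
    grm_panel: GenotypePanel | None = None,
) -> dict:
    """Per-chromosome null models with the tested chromosome left out of the GRM.

    Including a strong QTL's own chromosome in the relatedness matrix lets
    the kinship variance component absorb part of the QTL signal and
    deflates its Wald statistic (proximal contamination); leave-one-
    chromosome-out kinship is the standard remedy. Null fits after the
    first are warm-started from the previous chromosome's estimates.
    """
    grm_panel = grm_panel or panel
    chroms = list(dict.fromkeys(grm_panel.snps["chrom"].astype(str)))
    if len(chroms) < 2:
        raise ValueError("LOCO needs at least two chromosomes")
    nulls = {}
    theta0 = None
    for c in chroms:
        mask = (grm_panel.snps["chrom"].astype(str) != c).to_numpy()
        grm_c = compute_grm(grm_panel.subset_snps(mask))
        nm = fit_null_model(table, grm_c, endpoint_col=endpoint_col, theta0=theta0)
        theta0 = nm.fit.theta
        nulls[c] = nm
    return nulls


def wald_scan_loco(
    nulls: dict, panel: GenotypePanel, missing_policy: str = "drop"
) -> pd.DataFrame:
    """Per-SNP Wald scan where each chromosome uses its LOCO null model."""
    parts = []
    for c, null in nulls.items():
        mask = (panel.snps["chrom"].astype(str) == c).to_numpy()
        if mask.any():
            parts.append(wald_scan(null, panel.subset_snps(mask), missing_policy))
    res = pd.concat(parts, ignore_index=True)
    return res.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)


def permutation_threshold_loco(
    nulls: dict,
    panel: GenotypePanel,
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
    return_maxima: bool = False,
):
    """Genome-wide permutation threshold for the LOCO scan.

    One strain permutation per replicate is applied across all chromosomes
    (each rescanned under its own LOCO null); the genome-wide max |Z| feeds
    the (1 - alpha) empirical quantile.
    """
    _check_perm_args(alpha, n_perm)
    rng = np.random.default_rng(seed)
    scanners = []
    for c, null in nulls.items():
        mask = (panel.snps["chrom"].astype(str) == c).to_numpy()
        if mask.any():
            scanners.append(_PermScanner(null, panel.subset_snps(mask)))
    n_s = scanners[0].n_strains
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n_s)
        inv = np.argsort(perm)
        maxima[b] = max(s.max_abs_z(inv) for s in scanners)
    thr = float(np.quantile(maxima, 1.0 - alpha))
    if return_maxima:
        return thr, maxima
    return thr


def genomic_inflation(results) -> float:
    """Genomic inflation factor lambda = median(Z^2) / median(chi2_1)."""
    z = results["z"].to_numpy() if isinstance(results, pd.DataFrame) else np.asarray(results)
    z = z[~np.isnan(z)]
    if len(z) < 100:
        raise ValueError("need at least 100 association results")
    return float(np.median(z**2) / CHI2_MEDIAN)


def merge_loci(
    results: pd.DataFrame,
    threshold: float,
    merge_bp: int = MERGE_BP,
    endpoint: str = "value",
) -> pd.DataFrame:
    """Chain suprathreshold SNPs (< merge_bp apart on a chromosome) into loci.

    Threshold is on |Z|. The peak SNP of a locus has the smallest p, ties
    broken by lowest bp.
    """
    hits = results[np.abs(results["z"]) >= threshold].sort_values(
        ["chrom", "bp"], kind="stable"
    )
    loci = []
    for chrom, grp in hits.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        start = 0
        bp = grp["bp"].to_numpy()
        for i in range(1, len(grp) + 1):
            if i == len(grp) or bp[i] - bp[i - 1] >= merge_bp:
                block = grp.iloc[start:i]
                peak = block.sort_values(["p", "bp"], kind="stable").iloc[0]
                loci.append(
                    (chrom, int(block["bp"].min()), int(block["bp"].max()),
                     peak["snp"], float(peak["p"]), endpoint)
                )
                start = i
    return pd.DataFrame(
        loci, columns=["chrom", "start_bp", "end_bp", "peak_snp", "peak_p", "endpoint"]
    )
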