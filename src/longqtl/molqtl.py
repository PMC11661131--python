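"""Molecular QTL mapping (expression, exon inclusion, RNA editing) and
downstream hotspot / coincidence statistics.

Traits are filtered with the study-style rules (read/TPM support for
transcripts, read support and non-degenerate psi for exons, detection
fraction for editing sites), quantile-normalized per trait, and mapped with
a single-random-effect kinship LMM: the spectral decomposition of the
sample-level relatedness matrix is computed once and reused across traits,
so each trait/SNP test is a rotated weighted regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .behavior import blom_transform
from .panel import GenotypePanel, KinshipMatrix

CIS_WINDOW_BP = 2_000_000


# --- trait-level filters ---------------------------------------------------

def filter_transcripts(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    min_reads: int = 6,
    min_tpm: float = 0.1,
    min_frac: float = 0.2,
) -> list:
    """Keep transcripts with >= min_reads reads AND TPM > min_tpm in >= min_frac of samples."""
    if not counts.index.equals(tpm.index) or not counts.columns.equals(tpm.columns):
        raise ValueError("counts and TPM matrices must share rows and columns")
    ok = (counts.to_numpy() >= min_reads) & (tpm.to_numpy() > min_tpm)
    frac = ok.mean(axis=1)
    return list(counts.index[frac >= min_frac])


def compute_psi(inclusion, exclusion):
    """Percent-spliced-in: inclusion / (inclusion + exclusion); NaN when no reads."""
    inclusion = np.asarray(inclusion, dtype=float)
    exclusion = np.asarray(exclusion, dtype=float)
    total = inclusion + exclusion
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, inclusion / total, np.nan)
    return out if out.ndim else (float(out) if total > 0 else np.nan)


def quantile_normalize_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-trait rank-based inverse normal transform (preserves within-row order)."""
    out = values.copy()
    for i in range(len(out)):
        out.iloc[i] = blom_transform(out.iloc[i].to_numpy(dtype=float))
    return out


def select_exon_per_transcript(
    psi: pd.DataFrame,
    reads: pd.DataFrame,
    exon_to_transcript: dict,
    min_reads: int = 5,
) -> pd.DataFrame:
    """Per transcript, keep the exon with max SD of psi among well-supported exons.

    An exon survives only with >= min_reads total reads in every sample and
    non-zero SD of psi; transcripts with no surviving exon are absent from
    the output. Retained rows are quantile normalized.
    """
    supported = (reads.to_numpy() >= min_reads).all(axis=1)
    sd = psi.to_numpy(dtype=float).std(axis=1)
    keep = supported & (sd > 0)
    chosen = {}
    for pos, exon in enumerate(psi.index):
        if not keep[pos]:
            continue
        tx = exon_to_transcript[exon]
        if tx not in chosen or sd[pos] > chosen[tx][1] or (
            sd[pos] == chosen[tx][1] and False
        ):
            chosen[tx] = (exon, sd[pos])
    rows = [exon for exon, _ in chosen.values()]
    if not rows:
        return psi.iloc[:0].copy()
    return quantile_normalize_rows(psi.loc[rows])


def filter_editing(
    ratios: pd.DataFrame, detected: pd.DataFrame, min_detect_frac: float = 0.10
) -> pd.DataFrame:
    """Retain editing sites detected in >= min_detect_frac of samples; quantile normalize."""
    if len(ratios) == 0:
        return ratios.copy()
    frac = detected.to_numpy(dtype=bool).mean(axis=1)
    kept = ratios.loc[frac >= min_detect_frac]
    if len(kept) == 0:
        return kept
    return quantile_normalize_rows(kept)


def ascertainment_rate(detected: pd.DataFrame) -> float:
    """Mean over sites of the fraction of samples with detectable editing, as percent."""
    if len(detected) == 0:
        raise ValueError("no retained editing sites")
    return float(detected.to_numpy(dtype=bool).mean(axis=1).mean() * 100.0)


# --- kinship LMM mapping ---------------------------------------------------

class _EmmaContext:
    """Shared spectral decomposition for single-random-effect LMM mapping."""

    def __init__(self, K_sample: np.ndarray, X: np.ndarray):
        w, U = np.linalg.eigh(K_sample)
        self.s = np.clip(w, 0.0, None)
        self.U = U
        self.X = X
        self.Xr = U.T @ X
        self.n, self.p = X.shape

    def reml_delta(self, yr: np.ndarray) -> float:
        """REML estimate of delta = sigma_g^2 / sigma_e^2 via profile likelihood."""

        def neg_reml(log_delta):
            d = np.exp(log_delta)
            w = d * self.s + 1.0
            Xw = self.Xr / w[:, None]
            XWX = self.Xr.T @ Xw
            sign, ld = np.linalg.slogdet(XWX)
            if sign <= 0:
                return 1e30  # finite penalty keeps the bounded minimizer stable
            beta = np.linalg.solve(XWX, Xw.T @ yr)
            r = yr - self.Xr @ beta
            rss = float(r @ (r / w))
            return (
                (self.n - self.p) * np.log(rss)
                + np.log(w).sum()
                + ld
            )

        grid = np.linspace(-8.0, 8.0, 17)
        vals = [neg_reml(g) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            neg_reml, bounds=(g0 - 1.0, g0 + 1.0), method="bounded"
        )
        return float(np.exp(res.x))


def map_qtl(
    values: pd.DataFrame,
    traits: pd.DataFrame,
    samples: pd.DataFrame,
    panel: GenotypePanel,
    grm: KinshipMatrix,
    cis_window_bp: int = CIS_WINDOW_BP,
) -> pd.DataFrame:
    """Map each molecular trait against all SNPs with a kinship LMM.

    ``values``: traits x samples; ``traits``: trait metadata (gene_id, chrom,
    anchor_bp); ``samples``: sample metadata (strain, sex, batch) used as
    covariates. Missing genotype calls are imputed to the per-SNP mean.
    Returns one row per trait x SNP with Z, p, cis flag and distance to the
    trait anchor.
    """
    if not values.columns.equals(pd.Index(samples["sample_id"])):
        raise ValueError("value columns must align with sample metadata")
    strains = samples["strain"].tolist()
    K = grm.expand(strains)
    X_parts = [np.ones(len(samples)), samples["sex"].to_numpy(dtype=float)]
    batch = pd.get_dummies(samples["batch"].astype("category"), drop_first=True)
    for c in batch.columns:
        X_parts.append(batch[c].to_numpy(dtype=float))
    X = np.column_stack(X_parts)
    ctx = _EmmaContext(K, X)

    rows_in_panel = np.array([panel.strain_ids.index(s) for s in strains])
    G = panel.genotypes[rows_in_panel, :].copy()
    mu = np.nanmean(G, axis=0)
    ind = np.where(np.isnan(G))
    G[ind] = mu[ind[1]]
    Gr = ctx.U.T @ G  # rotated once, shared across traits

    snp_chrom = panel.snps["chrom"].to_numpy()
    snp_bp = panel.snps["bp"].to_numpy()
    out = []
    for trait_id in values.index:
        y = values.loc[trait_id].to_numpy(dtype=float)
        if np.std(y) == 0:
            continue  # zero-variance trait: skipped
        yr = ctx.U.T @ y
        delta = ctx.reml_delta(yr)
        w = delta * ctx.s + 1.0
        Xw = ctx.Xr / w[:, None]
        XWX_inv = np.linalg.inv(ctx.Xr.T @ Xw)
        Xwy = Xw.T @ yr
        beta0 = XWX_inv @ Xwy
        Gw = Gr / w[:, None]
        gy = Gw.T @ yr  # (m,)
        gX = Gw.T @ ctx.Xr  # (m, p)
        gg = (Gr * Gw).sum(axis=0)
        den = gg - np.einsum("mp,pq,mq->m", gX, XWX_inv, gX, optimize=True)
        num = gy - gX @ beta0
        # residual variance with SNP projected out, profiled per SNP
        ok = den > 1e-12
        gamma = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
        yWy = float(yr @ (yr / w))
        rss0 = yWy - Xwy @ beta0
        rss = np.maximum(rss0 - gamma * num, 1e-12)
        dof = ctx.n - ctx.p - 1
        sig2 = rss / dof
        se = np.where(ok, np.sqrt(sig2 / np.where(ok, den, 1.0)), np.nan)
        z = np.where(ok, gamma / np.where(ok, se, 1.0), 0.0)
        p = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), 1.0)

        anchor_chrom = str(traits.loc[trait_id, "chrom"])
        anchor_bp = int(traits.loc[trait_id, "anchor_bp"])
        same = snp_chrom == anchor_chrom
        dist = np.where(same, np.abs(snp_bp - anchor_bp), np.iinfo(np.int64).max)
        cis = same & (dist < cis_window_bp)
        df = pd.DataFrame(
            {
                "trait_id": trait_id,
                "gene_id": traits.loc[trait_id, "gene_id"],
                "snp": panel.snps.index,
                "chrom": snp_chrom,
                "bp": snp_bp,
                "beta": gamma,
                "se": se,
                "z": z,
                "p": p,
                "cis": cis,
                "distance_bp": np.where(same, dist, -1),
            }
        )
        out.append(df)
    if not out:
        return pd.DataFrame(
            columns=["trait_id", "gene_id", "snp", "chrom", "bp", "beta", "se",
                     "z", "p", "cis", "distance_bp"]
        )
    return pd.concat(out, ignore_index=True)


# --- hotspots and enrichment ----------------------------------------------

def poisson_tail(k: int, lam: float) -> float:
    """Upper-tail Poisson probability P(X >= k)."""
    return float(stats.poisson.sf(k - 1, lam))


def detect_hotspots(
    qtls: pd.DataFrame,
    chrom_lengths,
    bin_bp: int = 2_000_000,
    min_genes: int = 20,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Bins of the genome whose count of distinct trans-regulated genes beats a Poisson null.

    ``qtls`` must hold suprathreshold trans associations (columns gene_id,
    chrom, bp). The null mean is the genome-wide average count per bin
    (including empty bins); upper-tail p per bin, Benjamini-Hochberg q, and
    bins with q < fdr and count >= min_genes are reported.
    """
    bins = []
    for chrom, length in chrom_lengths:
        starts = np.arange(0, length, bin_bp)
        for s in starts:
            bins.append((str(chrom), int(s), int(min(s + bin_bp, length))))
    bin_df = pd.DataFrame(bins, columns=["chrom", "start", "end"])
    counts = np.zeros(len(bin_df), dtype=int)
    if len(qtls):
        trans = qtls[~qtls["cis"]] if "cis" in qtls.columns else qtls
        for i, (chrom, s, e) in enumerate(zip(bin_df["chrom"], bin_df["start"], bin_df["end"])):
            hit = trans[(trans["chrom"].astype(str) == chrom) & (trans["bp"] >= s) & (trans["bp"] < e)]
            counts[i] = hit["gene_id"].nunique()
    bin_df["n_genes"] = counts
    lam = counts.mean() if len(counts) else 0.0
    pvals = np.array([poisson_tail(k, lam) if k > 0 else 1.0 for k in counts])
    bin_df["p"] = pvals
    bin_df["q"] = multipletests(pvals, method="fdr_bh")[1]
    out = bin_df[(bin_df["q"] < fdr) & (bin_df["n_genes"] >= min_genes)]
    return out.reset_index(drop=True)


def _fisher_2x2(a: int, b: int, c: int, d: int) -> dict:
    table = np.array([[a, b], [c, d]])
    if table.min() < 0:
        raise ValueError("contingency counts must be non-negative")
    _, p = stats.fisher_exact(table)
    zero_cell = (table == 0).any()
    if zero_cell:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        odds = (aa * dd) / (bb * cc)
    else:
        odds = (a * d) / (b * c)
    return {
        "a": a, "b": b, "c": c, "d": d,
        "odds_ratio": float(odds),
        "p": float(p),
        "continuity_corrected": bool(zero_cell),
    }


def coincidence_enrichment(
    cis_a: pd.DataFrame,
    cis_b: pd.DataFrame,
    universe,
    window_bp: int = CIS_WINDOW_BP,
    labels: tuple = ("setA", "setB"),
) -> dict:
    """Gene-level Fisher test for coincident cis QTLs across two trait types.

    ``cis_a``/``cis_b`` hold one row per gene with a significant cis QTL
    (columns gene_id, chrom, bp = peak SNP position); ``universe`` is the
    set of genes assayed in both trait types. A gene counts as coincident
    when it has cis peaks in both sets on the same chromosome < window_bp
    apart.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty gene universe")
    pa = cis_a.set_index("gene_id")
    pb = cis_b.set_index("gene_id")
    a = b = c = d = 0
    for gene in universe:
        in_a = gene in pa.index
        in_b = gene in pb.index
        coincident = False
        if in_a and in_b:
            ra, rb = pa.loc[gene], pb.loc[gene]
            dist = abs(int(ra["bp"]) - int(rb["bp"]))
            # window 0 degenerates to exact co-location
            close = dist == 0 if window_bp == 0 else dist < window_bp
            coincident = str(ra["chrom"]) == str(rb["chrom"]) and close
        if in_a and coincident:
            a += 1
        elif in_a:
            b += 1
        elif in_b:
            c += 1
        else:
            d += 1
    out = _fisher_2x2(a, b, c, d)
    out["labels"] = labels
    return out


def region_enrichment(sites: pd.DataFrame) -> dict:
    """Fisher test of editing-site region class vs coincidence with cis eQTLs.

    ``sites`` needs a ``region`` column (5utr/3utr/cds = mature mRNA vs
    intronic/intergenic) and boolean ``coincident``.
    """
    mature = {"5utr", "3utr", "cds"}
    cls = sites["region"].str.lower().isin(mature)
    if cls.nunique() < 2:
        raise ValueError("need sites in both mature-mRNA and intronic/intergenic classes")
    coin = sites["coincident"].astype(bool)
    a = int((cls & coin).sum())
    b = int((cls & ~coin).sum())
    c = int((~cls & coin).sum())
    d = int((~cls & ~coin).sum())
    out = _fisher_2x2(a, b, c, d)
    out["labels"] = ("mature_mRNA", "coincident_cis_eQTL")
    return out
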