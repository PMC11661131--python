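"""Synthetic strain-panel generator.

Emulates a hybrid-mouse-diversity-panel style design: a fixed set of inbred
strains plus recombinant-inbred (RI) lines that are per-chromosome mosaics of
two founder inbred genomes, genotyped at SNPs organized into exchangeable
linkage-disequilibrium blocks. Longitudinal phenotypes are drawn exactly from
the mapping model used downstream (kinship-structured random intercepts and
day slopes plus fixed covariate effects), and molecular traits carry planted
cis effects, so every ground-truth quantity is recorded for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .panel import GenotypePanel, KinshipMatrix, compute_grm

CIS_WINDOW_BP = 2_000_000


@dataclass
class PanelDesign:
    """Design of a synthetic strain panel.

    Defaults mirror the emulated study: 32 inbred + 52 RI strains, ~6 mice
    per strain, 10 daily sessions, mouse age ~ N(11.3, 0.5^2) weeks, and a
    desk-scale genome of 4 chromosomes x 50 Mb at 100 kb SNP spacing
    (~2,000 SNPs) with 20-SNP LD blocks of within-block latent correlation
    0.8.
    """

    n_inbred: int = 32
    n_ri: int = 52
    n_founders: int = 8
    mice_per_strain: int = 6
    n_days: int = 10
    chrom_lengths: tuple = (
        ("1", 50_000_000),
        ("2", 50_000_000),
        ("3", 50_000_000),
        ("4", 50_000_000),
    )
    snp_spacing: int = 100_000
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.02
    ld_block_snps: int = 20
    ld_rho: float = 0.8
    ri_crossovers: float = 2.0
    n_chambers: int = 4
    strains_per_cohort: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inbred + self.n_ri < 2:
            raise ValueError("panel needs at least two strains")
        if self.n_ri > 0 and not (2 <= self.n_founders <= self.n_inbred):
            raise ValueError("RI lines need 2..n_inbred founder strains")
        if self.n_days < 2:
            raise ValueError("need at least two testing days")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if any(length <= 0 for _, length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_strains(self) -> int:
        return self.n_inbred + self.n_ri

    @property
    def days(self) -> np.ndarray:
        return np.arange(1, self.n_days + 1, dtype=float)


@dataclass
class TruthRecord:
    """Ground truth of a simulated panel.

    ``variance_components`` holds (s1, s2, s3, s4, s5, s6, resid): kinship
    and individual variances of the random intercept (s1, s2) and day slope
    (s3, s4), the corresponding intercept-slope covariances (s5, s6), and
    the residual variance. ``fixed_effects`` holds the scalar coefficients
    (intercept, age, sex, lever, chamber, cohort, day) used on coded
    covariates during generation.
    """

    qtl_effects: list = field(default_factory=list)  # (snp_id, effect_intercept, effect_slope)
    variance_components: tuple = (0.15, 0.15, 0.004, 0.004, 0.01, 0.01, 0.5)
    fixed_effects: tuple = (0.0, 0.02, 0.10, 0.05, 0.03, 0.01, 0.02)
    cis_eqtl_truth: list = field(default_factory=list)  # (gene_id, snp_id, effect)

    def __post_init__(self) -> None:
        s1, s2, s3, s4, s5, s6, resid = self.variance_components
        for v in (s1, s2, s3, s4, resid):
            if v < 0:
                raise ValueError("variance components must be non-negative")
        for name, mat in (("kinship", [[s1, s5], [s5, s3]]), ("individual", [[s2, s6], [s6, s4]])):
            if np.linalg.eigvalsh(np.array(mat)).min() < -1e-10:
                raise ValueError(f"{name} intercept-slope covariance block is not PSD")

    @property
    def sigma_g(self) -> np.ndarray:
        s1, _, s3, _, s5, _, _ = self.variance_components
        return np.array([[s1, s5], [s5, s3]])

    @property
    def sigma_e(self) -> np.ndarray:
        _, s2, _, s4, _, s6, _ = self.variance_components
        return np.array([[s2, s6], [s6, s4]])

    @property
    def resid_var(self) -> float:
        return float(self.variance_components[6])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(
            qtl_effects=[tuple(x) for x in d["qtl_effects"]],
            variance_components=tuple(d["variance_components"]),
            fixed_effects=tuple(d["fixed_effects"]),
            cis_eqtl_truth=[tuple(x) for x in d["cis_eqtl_truth"]],
        )


def _snp_map(design: PanelDesign) -> pd.DataFrame:
    rows = []
    for chrom, length in design.chrom_lengths:
        for bp in range(design.snp_spacing, length + 1, design.snp_spacing):
            rows.append((str(chrom), bp))
    if not rows:
        raise ValueError("design yields zero SNPs")
    df = pd.DataFrame(rows, columns=["chrom", "bp"])
    df.index = pd.Index([f"snp_{c}_{b}" for c, b in rows], name="snp")
    return df


def simulate_genotypes(design: PanelDesign) -> GenotypePanel:
    """Draw a genotype panel: independent inbred strains + RI founder mosaics.

    Inbred strains are drawn independently per LD block: within a block each
    SNP's latent Gaussian shares a block factor with correlation ``ld_rho``
    and is thresholded at its MAF quantile (minor allele coded 2). RI strains
    copy one of two founder genomes per chromosome segment, with
    Poisson-distributed crossover counts, producing the blended relatedness
    the GRM must capture. Deterministic under ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    snps = _snp_map(design)
    m = len(snps)
    maf = rng.uniform(design.maf_range[0], design.maf_range[1], size=m)
    thresh = norm.ppf(maf)

    # block ids: consecutive SNPs within a chromosome
    block_id = np.empty(m, dtype=int)
    nxt = 0
    for _, grp in snps.groupby("chrom", sort=False):
        k = len(grp)
        ids = nxt + np.arange(k) // design.ld_block_snps
        block_id[snps.index.get_indexer(grp.index)] = ids
        nxt = ids[-1] + 1
    n_blocks = nxt

    n_inb = design.n_inbred
    rho = design.ld_rho
    common = rng.standard_normal((n_inb, n_blocks))
    noise = rng.standard_normal((n_inb, m))
    latent = np.sqrt(rho) * common[:, block_id] + np.sqrt(1.0 - rho) * noise
    geno_inb = np.where(latent < thresh[None, :], 2.0, 0.0)

    strains = [f"I{i:03d}" for i in range(n_inb)] + [f"RI{i:03d}" for i in range(design.n_ri)]
    geno = np.empty((design.n_strains, m))
    geno[:n_inb] = geno_inb

    chrom_codes = snps["chrom"].to_numpy()
    for r in range(design.n_ri):
        f1, f2 = rng.choice(n_inb, size=2, replace=False)
        row = np.empty(m)
        for chrom, length in design.chrom_lengths:
            sel = chrom_codes == str(chrom)
            bp = snps.loc[sel, "bp"].to_numpy()
            n_xo = rng.poisson(design.ri_crossovers)
            cuts = np.sort(rng.uniform(0, length, size=n_xo))
            seg = np.searchsorted(cuts, bp)  # segment index per SNP
            first = rng.integers(2)
            src = np.where((seg + first) % 2 == 0, f1, f2)
            vals = np.where(src == f1, geno_inb[f1, sel], geno_inb[f2, sel])
            row[sel] = vals
        geno[n_inb + r] = row

    if design.missing_rate > 0:
        mask = rng.uniform(size=geno.shape) < design.missing_rate
        geno[mask] = np.nan

    return GenotypePanel(strain_ids=strains, snps=snps, genotypes=geno)


def _assign_covariates(design: PanelDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Per-mouse covariates: sex balanced within strain, lever counterbalanced
    across strain x sex, chamber cycled, cohorts in blocks of strains,
    age ~ N(11.3, 0.5^2) weeks."""
    rows = []
    mouse = 0
    for s_idx in range(design.n_strains):
        for k in range(design.mice_per_strain):
            sex = k % 2
            lever = (s_idx + sex) % 2
            chamber = int(rng.integers(design.n_chambers))
            cohort = s_idx // design.strains_per_cohort
            rows.append((mouse, s_idx, sex, lever, chamber, cohort))
            mouse += 1
    df = pd.DataFrame(rows, columns=["mouse", "strain_idx", "sex", "lever", "chamber", "cohort"])
    df["age_weeks"] = rng.normal(11.3, 0.5, size=len(df))
    return df


def _sample_random_effects(
    K: np.ndarray, sigma_g: np.ndarray, sigma_e: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw (b0, b1) per unit with Cov = sigma_g (x) K + sigma_e (x) I.

    Uses the eigenrotation of K: in the rotated basis components are
    independent 2-vectors with covariance s_i * sigma_g + sigma_e.
    """
    n = K.shape[0]
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    draws = np.empty((n, 2))
    z = rng.standard_normal((n, 2))
    for i in range(n):
        C = w[i] * sigma_g + sigma_e
        cw, cv = np.linalg.eigh(C)
        L = cv * np.sqrt(np.clip(cw, 0.0, None))
        draws[i] = L @ z[i]
    return U @ draws


def simulate_longitudinal(
    panel: GenotypePanel,
    truth: TruthRecord,
    design: PanelDesign,
    grm: KinshipMatrix | None = None,
    seed: int | None = None,
    endpoint: str = "value",
) -> pd.DataFrame:
    """Draw per-mouse per-day phenotypes exactly from the longitudinal model.

    Y_ij = a0 + a1 age + a2 sex + a3 lever + a4 chamber + a5 cohort + a6 day
           + sum_k gamma_k SNP_k (+ slope effects * day) + b0_i + b1_i day + eps,
    with (b0, b1) jointly Gaussian across mice: kinship block sigma_g (x) K
    plus individual block sigma_e (x) I, and eps ~ N(0, resid).
    Categorical chamber/cohort effects are generated as scalar coefficients
    on centered level codes (representable in the dummy space the fitter
    uses). Deterministic under the seed. Also attaches count endpoints
    (infusions, active/inactive presses) as monotone maps of the latent
    value so the rank-based normalization pipeline can be exercised.
    """
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    if grm is None:
        grm = compute_grm(panel)
    cov = _assign_covariates(design, rng)
    cov["strain"] = [panel.strain_ids[i] for i in cov["strain_idx"]]
    n_mice = len(cov)
    days = design.days
    T = len(days)

    a0, a_age, a_sex, a_lever, a_chamber, a_cohort, a_day = truth.fixed_effects
    mouse_base = (
        a0
        + a_age * (cov["age_weeks"].to_numpy() - 11.3)
        + a_sex * cov["sex"].to_numpy()
        + a_lever * cov["lever"].to_numpy()
        + a_chamber * (cov["chamber"].to_numpy() - cov["chamber"].mean())
        + a_cohort * (cov["cohort"].to_numpy() - cov["cohort"].mean())
    )

    g_int = np.zeros(n_mice)
    g_slope = np.zeros(n_mice)
    for snp_id, eff_int, eff_slope in truth.qtl_effects:
        g = panel.dosage(snp_id).copy()
        g[np.isnan(g)] = np.nanmean(g)  # generation-side mean fill for missing calls
        gm = g[cov["strain_idx"].to_numpy()]
        g_int += eff_int * gm
        g_slope += eff_slope * gm

    K_mouse = grm.expand(cov["strain"].tolist())
    b = _sample_random_effects(K_mouse, truth.sigma_g, truth.sigma_e, rng)
    eps = rng.normal(0.0, np.sqrt(truth.resid_var), size=(n_mice, T))

    Y = (
        (mouse_base + g_int + b[:, 0])[:, None]
        + (a_day + g_slope + b[:, 1])[:, None] * days[None, :]
        + eps
    )

    table = cov.loc[cov.index.repeat(T)].reset_index(drop=True)
    table["day"] = np.tile(days, n_mice).astype(int)
    table[endpoint] = Y.ravel()
    table["mouse_id"] = [f"m{m:04d}" for m in table["mouse"]]

    # count endpoints as monotone (infusions) / noisy (presses) transforms of the latent
    lat = table[endpoint].to_numpy()
    infusions = np.floor(12.0 * np.exp(0.5 * lat)).astype(int)
    active = infusions + rng.poisson(4.0, size=len(table))
    inactive = rng.poisson(6.0, size=len(table))
    table["infusions"] = infusions
    table["active_presses"] = active
    table["inactive_presses"] = inactive

    cols = [
        "mouse_id",
        "strain",
        "cohort",
        "sex",
        "age_weeks",
        "lever",
        "chamber",
        "day",
        endpoint,
        "infusions",
        "active_presses",
        "inactive_presses",
    ]
    return table[cols]


def simulate_expression(
    panel: GenotypePanel,
    truth: TruthRecord,
    samples_per_strain: int = 2,
    strain_var: float = 0.2,
    batch_var: float = 0.05,
    sex_effect: float = 0.1,
    noise_var: float = 0.3,
    n_batches: int = 4,
    grm: KinshipMatrix | None = None,
    seed: int = 0,
    n_background_genes: int = 0,
):
    """Per-sample molecular trait values with planted cis effects.

    Each gene in ``truth.cis_eqtl_truth`` gets a trait whose value is
    cis-genotype effect + kinship-structured strain effect + batch + sex
    effects + i.i.d. noise; background genes carry no cis effect. Samples
    emulate sex-pooled libraries: ``samples_per_strain`` per strain (default
    one male, one female pool). Returns (values, traits, samples) frames.
    """
    rng = np.random.default_rng(seed)
    if grm is None:
        grm = compute_grm(panel)
    for gene_id, snp_id, _ in truth.cis_eqtl_truth:
        if snp_id not in panel.snps.index:
            raise ValueError(f"cis SNP {snp_id} for {gene_id} is not on the simulated map")

    n_s = panel.n_strains
    sample_rows = []
    for i, strain in enumerate(panel.strain_ids):
        for k in range(samples_per_strain):
            sample_rows.append(
                (f"{strain}_s{k}", strain, k % 2, int(rng.integers(n_batches)))
            )
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "strain", "sex", "batch"])
    n_samp = len(samples)
    strain_idx = samples["strain"].map({s: i for i, s in enumerate(panel.strain_ids)}).to_numpy()

    trait_rows = []
    genes = list(truth.cis_eqtl_truth)
    for b in range(n_background_genes):
        j = int(rng.integers(panel.n_snps))
        genes.append((f"bg_gene_{b}", panel.snps.index[j], 0.0))
    values = np.empty((len(genes), n_samp))
    batch_eff = rng.normal(0.0, np.sqrt(batch_var), size=n_batches)
    K = grm.values
    for t, (gene_id, snp_id, eff) in enumerate(genes):
        chrom = panel.snps.loc[snp_id, "chrom"]
        anchor = int(panel.snps.loc[snp_id, "bp"])  # gene anchored at its cis SNP's position
        g = panel.dosage(snp_id).copy()
        g[np.isnan(g)] = np.nanmean(g)
        u = _sample_random_effects(K, np.diag([strain_var, 0.0]), np.zeros((2, 2)), rng)[:, 0]
        vals = (
            eff * g[strain_idx]
            + u[strain_idx]
            + batch_eff[samples["batch"].to_numpy()]
            + sex_effect * samples["sex"].to_numpy()
            + rng.normal(0.0, np.sqrt(noise_var), size=n_samp)
        )
        values[t] = vals
        trait_rows.append((gene_id, "expression", gene_id, chrom, anchor))
    traits = pd.DataFrame(
        trait_rows, columns=["trait_id", "trait_type", "gene_id", "chrom", "anchor_bp"]
    ).set_index("trait_id")
    vdf = pd.DataFrame(values, index=traits.index, columns=samples["sample_id"])
    return vdf, traits, samples


def plant_qtl(
    panel: GenotypePanel,
    design: PanelDesign,
    base_truth: TruthRecord | None = None,
    frac_var: float = 0.10,
    maf_min: float = 0.15,
    seed: int = 0,
) -> tuple[TruthRecord, str]:
    """Plant one intercept QTL explaining ``frac_var`` of per-day phenotypic variance.

    The SNP is chosen at random among complete-call SNPs with MAF >=
    ``maf_min``; the intercept effect gamma is calibrated against the
    analytic per-day variance of the longitudinal model averaged over days
    (using the SNP's empirical strain-level dosage variance), so the planted
    locus explains the requested fraction regardless of its MAF.
    """
    truth = base_truth or TruthRecord()
    rng = np.random.default_rng(seed)
    maf = panel.maf()
    complete = panel.missing_fraction() == 0
    ok = np.where((maf >= maf_min) & complete)[0]
    if len(ok) == 0:
        raise ValueError("no complete SNP with sufficient MAF to plant a QTL")
    j = int(rng.choice(ok))
    snp_id = panel.snps.index[j]
    g = panel.genotypes[:, j]
    v_g = float(np.var(g))
    s1, s2, s3, s4, s5, s6, resid = truth.variance_components
    days = design.days
    v_day = np.mean((s1 + s2) + days**2 * (s3 + s4) + 2 * days * (s5 + s6) + resid)
    gamma = np.sqrt(frac_var * v_day / ((1.0 - frac_var) * v_g))
    planted = TruthRecord(
        qtl_effects=truth.qtl_effects + [(snp_id, float(gamma), 0.0)],
        variance_components=truth.variance_components,
        fixed_effects=truth.fixed_effects,
        cis_eqtl_truth=list(truth.cis_eqtl_truth),
    )
    return planted, snp_id
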