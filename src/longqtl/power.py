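"""Study-design power simulation for the longitudinal mixed-model scan.

Replicates the design question the panel was sized for: how often is a
single additive QTL explaining a given fraction of phenotypic variance
detected at the permutation-derived 5% genome-wide threshold?
"""

from __future__ import annotations

import numpy as np

from .behavior import normalize_endpoint
from .gwas import filter_snps, fit_null_model, permutation_threshold, wald_scan
from .panel import compute_grm
from .simulate import PanelDesign, plant_qtl, simulate_genotypes, simulate_longitudinal


def default_power_design(seed: int = 0) -> PanelDesign:
    """100-strain panel (~6 mice, 10 days) with ~2,000 LD-block SNPs."""
    return PanelDesign(
        n_inbred=40,
        n_ri=60,
        n_founders=8,
        mice_per_strain=6,
        n_days=10,
        missing_rate=0.0,
        seed=seed,
    )


def qtl_detection_power(
    n_reps: int = 200,
    frac_var: float = 0.10,
    alpha: float = 0.05,
    n_perm: int = 100,
    detect_window_bp: int = 2_000_000,
    seed: int = 0,
    design_factory=default_power_design,
) -> dict:
    """Fraction of replicates in which a planted QTL beats its own
    permutation genome-wide threshold.

    Each replicate draws a fresh panel, plants one intercept QTL calibrated
    to ``frac_var`` of per-day phenotypic variance, Blom-normalizes the
    endpoint per day, fits the single-GRM null REML model, scans, and
    derives the alpha-level threshold by strain-label permutation.
    Detection = some suprathreshold SNP within ``detect_window_bp`` of the
    planted SNP. The single-GRM scan is the correctly specified (and
    familywise-calibrated) analysis for panels whose polygenic background
    is kinship-structured genome-wide; see the methods note for why the
    LOCO variant trades calibration for power here.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(4 * n_reps).reshape(n_reps, 4) % (2**31 - 1)
    detected = 0
    z_planted = np.empty(n_reps)
    thresholds = np.empty(n_reps)
    for rep in range(n_reps):
        s_panel, s_qtl, s_pheno, s_perm = (int(v) for v in rep_seeds[rep])
        design = design_factory(seed=s_panel)
        panel = simulate_genotypes(design)
        grm = compute_grm(panel)
        panel_f = filter_snps(panel)
        truth, snp = plant_qtl(panel_f, design, frac_var=frac_var, seed=s_qtl)
        table = simulate_longitudinal(panel_f, truth, design, grm=grm, seed=s_pheno)
        table = normalize_endpoint(table, "value")
        null = fit_null_model(table, grm, endpoint_col="value_norm")
        scan = wald_scan(null, panel_f)
        thr = permutation_threshold(
            null, panel_f, alpha=alpha, n_perm=n_perm, seed=s_perm
        )
        pos = panel_f.snps.loc[snp]
        near = scan[
            (scan["chrom"].astype(str) == str(pos["chrom"]))
            & ((scan["bp"] - int(pos["bp"])).abs() < detect_window_bp)
        ]
        zmax = float(np.abs(near["z"]).max())
        detected += zmax >= thr
        z_planted[rep] = float(np.abs(scan.set_index("snp").loc[snp, "z"]))
        thresholds[rep] = thr
    return {
        "power": detected / n_reps,
        "n_reps": n_reps,
        "mean_threshold": float(thresholds.mean()),
        "mean_planted_abs_z": float(z_planted.mean()),
    }
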