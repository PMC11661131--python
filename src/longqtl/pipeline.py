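"""Pipeline orchestration: configuration, staging, manifest.

Interchange dialect is TSV with a header row and '.' for missing values;
the manifest is JSON carrying the config hash, seed, package version, and
per-stage status / row counts so a run is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, gwas, molqtl, twas
from .panel import GenotypePanel, compute_grm, MISSING_TOKEN
from .simulate import PanelDesign, TruthRecord, plant_qtl, simulate_expression, simulate_genotypes, simulate_longitudinal


@dataclass
class PipelineConfig:
    """Paths, stage toggles, thresholds and the run seed."""

    genotype_tsv: str | None = None
    behavior_tsv: str | None = None
    expression_tsv: str | None = None
    endpoint: str = "infusions"
    run_prep: bool = True
    run_gwas: bool = True
    run_molqtl: bool = True
    run_twas: bool = True
    run_coloc: bool = True
    maf_min: float = 0.05
    miss_max: float = 0.10
    alpha: float = 0.05
    n_perm: int = 100
    loco: bool = False  # leave-one-chromosome-out GRMs for the behavioral scan
    cis_window_bp: int = 2_000_000
    pip_threshold: float = 0.8
    clpp_threshold: float = 0.01
    seed: int = 0
    design_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 <= self.maf_min <= 0.5) or not (0 <= self.miss_max <= 1):
            raise ValueError("filter thresholds out of range")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING_TOKEN)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute prep -> gwas -> molqtl -> twas -> coloc per the config toggles.

    Missing inputs are synthesized from the panel generator under the config
    seed. A stage failure marks that stage failed in the manifest and skips
    dependent stages. Returns the manifest dict (also written as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.digest()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": chash,
        "stages": {},
    }

    def record(stage, status, **info):
        manifest["stages"][stage] = {"status": status, **info}

    design = PanelDesign(seed=config.seed, **config.design_kwargs)
    try:
        if config.genotype_tsv:
            panel = GenotypePanel.from_tsv(config.genotype_tsv)
        else:
            panel = simulate_genotypes(design)
            panel.to_tsv(outdir / "genotypes.tsv")
        grm = compute_grm(panel)
        grm.to_tsv(outdir / "grm.tsv")
        if config.behavior_tsv:
            table = pd.read_csv(config.behavior_tsv, sep="\t", comment="#",
                                na_values=[MISSING_TOKEN])
            truth = None
        else:
            truth, planted_snp = plant_qtl(panel, design, seed=config.seed)
            truth.to_json(outdir / "truth.json")
            table = simulate_longitudinal(panel, truth, design, grm=grm,
                                          seed=config.seed + 1)
            _write_tsv(table, outdir / "behavior.tsv", chash)
        record("inputs", "ok", n_strains=panel.n_strains, n_snps=panel.n_snps,
               n_behavior_rows=len(table))
    except Exception as err:  # noqa: BLE001
        record("inputs", "failed", error=str(err))
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1))
        return manifest

    norm_col = None
    if config.run_prep:
        try:
            table = behavior.normalize_endpoint(table, config.endpoint)
            norm_col = f"{config.endpoint}_norm"
            tc = behavior.time_course_test(table, config.endpoint)
            _write_tsv(table, outdir / "behavior_normalized.tsv", chash)
            record("prep", "ok", endpoint=config.endpoint,
                   time_course_p=tc["p"], n_rows=len(table))
        except Exception as err:  # noqa: BLE001
            record("prep", "failed", error=str(err))

    scan = None
    threshold = None
    panel_f = None
    if config.run_gwas:
        if norm_col is None:
            record("gwas", "skipped", reason="missing dependency: prep output")
        else:
            try:
                panel_f = gwas.filter_snps(panel, config.maf_min, config.miss_max)
                if config.loco:
                    nulls = gwas.fit_loco_nulls(table, panel_f, endpoint_col=norm_col,
                                                grm_panel=panel)
                    scan = gwas.wald_scan_loco(nulls, panel_f)
                    threshold = gwas.permutation_threshold_loco(
                        nulls, panel_f, alpha=config.alpha, n_perm=config.n_perm,
                        seed=config.seed + 2,
                    )
                else:
                    null = gwas.fit_null_model(table, grm, endpoint_col=norm_col)
                    scan = gwas.wald_scan(null, panel_f)
                    threshold = gwas.permutation_threshold(
                        null, panel_f, alpha=config.alpha, n_perm=config.n_perm,
                        seed=config.seed + 2,
                    )
                loci = gwas.merge_loci(scan, threshold, endpoint=config.endpoint)
                lam = gwas.genomic_inflation(scan) if len(scan) >= 100 else None
                _write_tsv(scan, outdir / "gwas.tsv", chash)
                _write_tsv(loci, outdir / "loci.tsv", chash)
                record("gwas", "ok", threshold=threshold, n_snps=panel_f.n_snps,
                       n_loci=len(loci), lambda_gc=lam,
                       filter_log=getattr(panel_f, "filter_log", {}))
            except Exception as err:  # noqa: BLE001
                record("gwas", "failed", error=str(err))

    qtl_records = None
    expr = None
    if config.run_molqtl:
        try:
            if truth is not None and not truth.cis_eqtl_truth:
                rng = np.random.default_rng(config.seed + 3)
                snps = panel.snps.index[rng.choice(panel.n_snps, size=5, replace=False)]
                truth = TruthRecord(
                    qtl_effects=truth.qtl_effects,
                    variance_components=truth.variance_components,
                    fixed_effects=truth.fixed_effects,
                    cis_eqtl_truth=[(f"gene_{i}", s, 0.8) for i, s in enumerate(snps)],
                )
            expr = simulate_expression(panel, truth, seed=config.seed + 4,
                                       n_background_genes=5)
            values, traits, samples = expr
            qtl_records = molqtl.map_qtl(values, traits, samples, panel, grm,
                                         cis_window_bp=config.cis_window_bp)
            _write_tsv(qtl_records, outdir / "molqtl.tsv", chash)
            record("molqtl", "ok", n_traits=len(values), n_records=len(qtl_records))
        except Exception as err:  # noqa: BLE001
            record("molqtl", "failed", error=str(err))

    if config.run_twas:
        if scan is None or expr is None:
            record("twas", "skipped", reason="missing dependency: gwas/molqtl output")
        else:
            try:
                values, traits, samples = expr
                rows = []
                scan_ix = scan.set_index("snp")
                for gene in traits["gene_id"]:
                    try:
                        wm = twas.fit_cis_weights(values, traits, samples, panel_f,
                                                  grm, gene,
                                                  window_bp=config.cis_window_bp)
                    except ValueError:
                        continue
                    if not np.any(wm.weights):
                        continue  # no predictive cis model for this gene
                    keep = [s for s in wm.snp_ids if s in scan_ix.index]
                    if not keep:
                        continue
                    sel = [wm.snp_ids.index(s) for s in keep]
                    wm.snp_ids, wm.weights = keep, wm.weights[sel]
                    R = twas.ld_matrix(panel_f, keep)
                    res = twas.twas_z(wm, scan_ix.loc[keep, "z"].to_numpy(), R)
                    res.update(cv_r2=wm.cv_r2, method=wm.method)
                    rows.append(res)
                tdf = pd.DataFrame(rows)
                if len(tdf):
                    tdf["bonferroni_sig"] = twas.bonferroni_flags(tdf["p"])
                _write_tsv(tdf, outdir / "twas.tsv", chash)
                record("twas", "ok", n_genes=len(tdf))
            except Exception as err:  # noqa: BLE001
                record("twas", "failed", error=str(err))

    if config.run_coloc:
        if scan is None or qtl_records is None or len(qtl_records) == 0:
            record("coloc", "skipped", reason="missing dependency: gwas/molqtl output")
        else:
            try:
                rows = []
                scan_ix = scan.set_index("snp")
                for trait_id, grp in qtl_records[qtl_records["cis"]].groupby("trait_id"):
                    grp = grp.sort_values("p")
                    peak = grp.iloc[0]
                    near = qtl_records[
                        (qtl_records["trait_id"] == trait_id)
                        & (qtl_records["chrom"] == peak["chrom"])
                    ].sort_values("bp")
                    center = near.index[near["snp"] == peak["snp"]][0]
                    pos = near.index.get_loc(center)
                    lo = max(0, pos - twas.COLOC_WINDOW_SNPS)
                    win = near.iloc[lo: pos + twas.COLOC_WINDOW_SNPS + 1]
                    win = win[win["snp"].isin(scan_ix.index)]
                    if win.empty:
                        continue
                    R = twas.ld_matrix(panel_f, list(win["snp"]))
                    cc = twas.clpp(scan_ix.loc[win["snp"], "z"].to_numpy(),
                                   win["z"].to_numpy(), R, snp_ids=list(win["snp"]))
                    snp, value = twas.max_clpp(cc)
                    rows.append({"trait_id": trait_id, "snp": snp, "max_clpp": value,
                                 "supported": value > config.clpp_threshold})
                cdf = pd.DataFrame(rows)
                _write_tsv(cdf, outdir / "coloc.tsv", chash)
                record("coloc", "ok", n_traits=len(cdf))
            except Exception as err:  # noqa: BLE001
                record("coloc", "failed", error=str(err))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
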