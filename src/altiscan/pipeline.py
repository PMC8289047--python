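"""End-to-end pipeline orchestration and the run configuration.

A single :class:`RunConfig` (YAML on disk) drives the whole analysis chain in
dependency order: obtain variants (read a VCF or simulate a panel) ->
filter -> windowed statistics -> folded joint SFS -> optional demographic fit
-> null calibration -> divergence scan -> adaptive-allele dosage -> optional
phenotype/expression correlation.  Every artifact is written under the output
directory and hashed into a manifest, so a run is reproducible bit-for-bit
from (config, seed).

Stage seeds derive from the global seed by hashing with the stage name
(``_stream_seed(seed, stage)``), so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .demography import compare_models, fit_models
from .dosage import run_dosage
from .phenoexpr import correlate_expression, phenotype_pca
from .scan import calibrate_null, run_scan
from .simulate import (_stream_seed, make_expression, make_phenotypes,
                       simulate_dataset, spike_divergent_sites)
from .stats import filter_variants, fold_joint_sfs, genotype_pca, site_fst, window_table
from .types import DemographySpec, FilterConfig, SampleConfig, ScanConfig

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Defaults carry the published analysis constants: 50-kb windows, >= 13
    HD-SNPs per outlier window, at most 1000 outlier windows, FST cutoff at
    the 99% simulated quantile, pi-ratio cutoff at 95%, MAF 0.1, 10%
    missingness, HWE p 0.01, LD r^2 0.5 within 20 kb, mutation rate 3.3e-9,
    one-year generations, 100 bootstrap replicates, 20-80 ECM cycles, and
    alpha 0.05 for expression correlation.
    """

    seed: int = 0
    out_dir: str = "altiscan_out"
    # input paths (optional; simulation fills the gaps)
    vcf: str = None
    popmap: str = None
    genes_bed: str = None
    phenotypes: str = None
    expression: str = None
    # synthetic-data generation
    demography: dict = field(default_factory=dict)
    sample: dict = field(default_factory=dict)
    spike: dict = None
    make_pheno: dict = None
    # stage switches and parameters
    apply_filters: bool = False
    filter: dict = field(default_factory=dict)
    fit_models: list = None            # e.g. ["M1", "M3", "M5"]
    fit_options: dict = field(default_factory=dict)
    boot: int = 0                      # bootstrap replicates for the best fit
    calibration: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    alpha: float = 0.05

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def spec(self) -> DemographySpec:
        return DemographySpec.from_dict(
            {**DemographySpec().to_dict(), **self.demography}
        )

    def scan_config(self) -> ScanConfig:
        return ScanConfig(**self.scan)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(**self.filter)

    def canonical_json(self) -> str:
        """Configuration serialization for hashing; the output location is
        not part of the scientific configuration and is excluded."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def save(name, writer):
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)
        return path

    spec = cfg.spec()

    # ---- variants -------------------------------------------------
    if cfg.vcf:
        pops = aio.read_popmap(cfg.popmap) if cfg.popmap else None
        vt = aio.read_vcf(cfg.vcf, populations=pops)
    else:
        sample = SampleConfig(
            seed=_stream_seed(cfg.seed, "simulate"),
            **{k: v for k, v in cfg.sample.items() if k != "seed"},
        )
        vt = simulate_dataset(spec, sample)
        if cfg.spike:
            sp = dict(cfg.spike)
            vt = spike_divergent_sites(
                vt, sp["n_spiked"], sp["delta_freq"],
                tuple(sp["region"]), _stream_seed(cfg.seed, "spike"),
            )
        save("simulated.vcf", lambda p: aio.write_vcf(vt, p))
        save("popmap.tsv", lambda p: aio.write_popmap(vt, p))
        save("provenance.json", lambda p: Path(p).write_text(
            json.dumps(vt.metadata, default=str) + "\n"
        ))

    if cfg.apply_filters:
        vt, filter_report = filter_variants(vt, cfg.filter_config())
        save("filter_report.json", lambda p: Path(p).write_text(
            json.dumps(filter_report) + "\n"
        ))

    pops_pair = tuple(vt.pop_labels[:2])

    # ---- per-site and windowed statistics -------------------------
    scfg = cfg.scan_config()
    fst = site_fst(vt, pops=pops_pair)
    site_table = pd.DataFrame({
        "contig": vt.contig, "pos": vt.pos, "fst": fst,
    })
    save("site_fst.tsv", lambda p: site_table.to_csv(p, sep="\t", index=False))

    windows = window_table(vt, scfg.window_bp, pops=pops_pair)
    save("windows.tsv", lambda p: windows.to_csv(p, sep="\t", index=False))

    scores, frac = (None, None)
    try:
        scores, frac = genotype_pca(vt)
        pca_payload = {
            "variance_fractions": frac[:10].tolist(),
            "scores_pc1": scores[:, 0].tolist(),
            "samples": list(vt.samples),
        }
        save("genotype_pca.json", lambda p: Path(p).write_text(
            json.dumps(pca_payload) + "\n"
        ))
    except ValueError:
        pass

    sfs = fold_joint_sfs(vt, pops=pops_pair)
    save("sfs.json", lambda p: sfs.to_json(p))

    # ---- demographic fitting (optional) ---------------------------
    fit_summary = None
    best_spec = spec
    if cfg.fit_models:
        opts = dict(cfg.fit_options)
        fixed = opts.pop("fixed", None)
        n_draws = opts.pop("n_draws", 10_000)
        fits = fit_models(
            sfs, cfg.fit_models, seed=_stream_seed(cfg.seed, "fit"),
            fixed=fixed, model_kwargs={"n_draws": n_draws, "mu": spec.mu}, **opts,
        )
        table = compare_models(fits)
        save("aic_table.tsv", lambda p: table.to_csv(p, sep="\t", index=False))
        best = min(fits, key=lambda r: r.aic)
        fit_summary = {r.model_id: r.params for r in fits}
        save("fit_results.json", lambda p: Path(p).write_text(
            json.dumps(fit_summary, default=float) + "\n"
        ))
        if best.model_id.startswith("M") and best.model_id not in ("M1", "M2"):
            best_spec = best.spec
        if cfg.boot:
            ci = best.bootstrap_ci(
                n_boot=cfg.boot, seed=_stream_seed(cfg.seed, "boot")
            )
            save("bootstrap_ci.tsv", lambda p: ci.to_csv(p, sep="\t", index=False))

    # ---- null calibration and scan --------------------------------
    cal_kwargs = dict(cfg.calibration)
    cal = calibrate_null(
        best_spec,
        n_high=int((vt.populations == pops_pair[0]).sum()),
        n_low=int((vt.populations == pops_pair[1]).sum()),
        fst_quantile=scfg.fst_quantile,
        pi_ratio_quantile=scfg.pi_ratio_quantile,
        seed=_stream_seed(cfg.seed, "calibration"),
        **cal_kwargs,
    )
    save("calibration.json", lambda p: cal.to_json(p))

    genes = aio.read_bed(cfg.genes_bed) if cfg.genes_bed else None
    scan_res = run_scan(vt, cal, scfg, genes=genes, pops=pops_pair)
    save("regions.bed", lambda p: aio.write_bed(scan_res.regions, p))
    if scan_res.genes is not None:
        save("candidate_genes.tsv", lambda p: scan_res.genes.to_csv(
            p, sep="\t", index=False
        ))
    win_aug = scan_res.windows.copy()
    win_aug["outlier"] = scan_res.outlier_flags
    win_aug["pi_ratio_flag"] = scan_res.ratio_flags
    save("scan_windows.tsv", lambda p: win_aug.to_csv(p, sep="\t", index=False))

    # ---- dosage ----------------------------------------------------
    if scan_res.hd_flags.any():
        dres = run_dosage(vt, hd_site_mask=scan_res.hd_flags,
                          highland_pop=pops_pair[0], lowland_pop=pops_pair[1])
        save("dosages.tsv", lambda p: dres.dosages.to_csv(p, sep="\t", index=False))
        save("dosage_test.json", lambda p: Path(p).write_text(
            json.dumps(dres.test) + "\n"
        ))

    # ---- phenotype / expression -----------------------------------
    pheno = expr = None
    if cfg.phenotypes and cfg.expression:
        pheno = pd.read_csv(cfg.phenotypes, sep="\t")
        expr = aio.read_tsv_matrix(cfg.expression)
    elif cfg.make_pheno:
        mp = dict(cfg.make_pheno)
        n_high = mp.pop("n_high", 4)
        n_low = mp.pop("n_low", 4)
        expr_kwargs = {
            k: mp.pop(k) for k in ("n_genes", "n_coupled", "coupling_r")
            if k in mp
        }
        pheno = make_phenotypes(
            n_high, n_low, seed=_stream_seed(cfg.seed, "pheno"), **mp
        )
        pc1 = phenotype_pca(pheno)[0][:, 0]
        expr, _ = make_expression(
            pc1, seed=_stream_seed(cfg.seed, "expr"), **expr_kwargs
        )
    if pheno is not None:
        scores_p, frac_p = phenotype_pca(pheno)
        ranked = correlate_expression(scores_p[:, 0], expr, alpha=cfg.alpha)
        save("pheno_pca.json", lambda p: Path(p).write_text(json.dumps({
            "variance_fractions": frac_p.tolist(),
            "pc1_scores": scores_p[:, 0].tolist(),
        }) + "\n"))
        save("expression_correlation.tsv", lambda p: ranked.to_csv(
            p, sep="\t", index=False
        ))

    # ---- manifest --------------------------------------------------
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "artifacts": dict(sorted(artifacts.items())),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
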