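"""End-to-end pipeline: simulate -> callroh -> froh -> landscape ->
depression -> gwas, driven by one YAML config with a manifest of seeds,
parameters and output digests.

The config has one top-level block per stage (each with an ``enabled``
flag) plus global ``seed`` and ``outdir``.  Identical config + seed
reproduces identical outputs, which the manifest's SHA-256 digests make
checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .froh import froh_table
from .io import read_genotypes, write_genotypes, write_hom, write_table
from .landscape import RohDensityModel, classify_extremes, make_windows, snp_heterozygosity, snp_roh_density
from .roh import RohParams, call_roh
from .simulate import (
    ChromosomeSpec,
    SimConfig,
    TraitModelParams,
    gene_drop,
    make_snp_table,
    simulate_pedigree,
    simulate_survival,
)
from .survival import AnnualSurvivalModel, PoissonSurvivalModel
from .association import RohStatusScan, effective_tests, significance_threshold

log = logging.getLogger("rohdep")

STAGES = ["simulate", "callroh", "froh", "landscape", "depression", "gwas"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "seconds": round(seconds, 3),
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - set(STAGES) - {"seed", "outdir"}
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    return cfg


def _chrom_lengths_mb(snps: pd.DataFrame, chromosomes: list[ChromosomeSpec] | None = None) -> dict:
    if chromosomes is not None:
        return {c + 1: spec.length_mb for c, spec in enumerate(chromosomes)}
    return {
        int(c): float(sub["bp"].max()) / 1e6 for c, sub in snps.groupby("chromosome")
    }


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> RunManifest:
    """Run the enabled stages in dependency order.

    Any stage failure aborts with the stage name in the exception;
    previously completed stages remain in the (partial) manifest
    attached to the exception where possible.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    seed = int(cfg.get("seed", 0))
    out = Path(outdir or cfg.get("outdir", "rohdep_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)

    def enabled(stage: str) -> bool:
        block = cfg.get(stage, {})
        return bool(block.get("enabled", stage in cfg))

    state: dict = {}
    for stage in STAGES:
        if not enabled(stage):
            log.info("stage %s disabled", stage)
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](cfg.get(stage, {}) or {}, seed, out, state)
        except Exception as exc:
            (out / "manifest.json").write_text(manifest.to_json())
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, outputs, time.time() - t0)
        log.info("stage %s done (%.1fs)", stage, time.time() - t0)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# -- stage implementations -------------------------------------------------

def _stage_simulate(block: dict, seed: int, out: Path, state: dict) -> list[Path]:
    chroms = [
        ChromosomeSpec(c["length_mb"], c["length_cm"], c["n_snps"])
        for c in block.get(
            "chromosomes",
            [{"length_mb": 50.0, "length_cm": 64.0, "n_snps": 2000}] * 2,
        )
    ]
    sim_cfg = SimConfig(
        n_founders=block.get("n_founders", 60),
        n_generations=block.get("n_generations", 4),
        n_per_generation=block.get("n_per_generation", 60),
        mating_scheme=block.get("mating_scheme", "full_sib_enriched"),
        inbred_pair_fraction=block.get("inbred_pair_fraction", 0.2),
        chromosomes=chroms,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(sim_cfg, rng)
    snps = make_snp_table(chroms)
    g, truth = gene_drop(ped, snps, sim_cfg, rng)
    ind = pd.DataFrame(
        {
            "id": g.ids,
            "froh": truth.realised_ibd.loc[ped["id"]].to_numpy(),
            "sex": ped["sex"].to_numpy(),
            "twin": (rng.random(len(g.ids)) < 0.3).astype(int),
        }
    )
    params = TraitModelParams(**block.get("survival_params", {}))
    surv = simulate_survival(ind, params, n_years=block.get("n_years", 8), rng=rng)
    write_genotypes(g, out / "genotypes")
    ped_path, surv_path = out / "pedigree.tsv", out / "survival.tsv"
    write_table(ped, ped_path)
    write_table(surv, surv_path)
    truth_path = out / "truth_ibd_tracts.tsv"
    write_table(truth.ibd_tracts, truth_path)
    state.update(genotypes=g, pedigree=ped, survival=surv, truth=truth, chromosomes=chroms)
    return [out / "genotypes.bed", out / "genotypes.bim", out / "genotypes.fam", ped_path, surv_path, truth_path]


def _require_genotypes(block: dict, out: Path, state: dict):
    if "genotypes" not in state:
        prefix = block.get("input_prefix", out / "genotypes")
        state["genotypes"] = read_genotypes(prefix)
    return state["genotypes"]


def _stage_callroh(block: dict, seed: int, out: Path, state: dict) -> list[Path]:
    g = _require_genotypes(block, out, state)
    params = RohParams(
        **{k: v for k, v in block.items() if k in RohParams.__dataclass_fields__}
    )
    segments = call_roh(g, params)
    state["segments"] = segments
    seg_path, hom_path = out / "roh_segments.tsv", out / "roh.hom"
    write_table(segments, seg_path)
    write_hom(segments, g, hom_path)
    return [seg_path, hom_path]


def _stage_froh(block: dict, seed: int, out: Path, state: dict) -> list[Path]:
    g = _require_genotypes(block, out, state)
    if "segments" not in state:
        raise ValueError("froh stage requires callroh output")
    lengths = _chrom_lengths_mb(g.snps, state.get("chromosomes"))
    table = froh_table(state["segments"], g.ids, lengths)
    state["froh"] = table
    path = out / "froh.tsv"
    write_table(table, path)
    return [path]


def _stage_landscape(block: dict, seed: int, out: Path, state: dict) -> list[Path]:
    g = _require_genotypes(block, out, state)
    segments = state["segments"]
    density = snp_roh_density(segments, g.snps, g.n_individuals)
    het = snp_heterozygosity(g)
    windows = make_windows(g.snps, density, het, window_kb=block.get("window_kb", 500.0))
    windows = classify_extremes(
        windows, q=block.get("q", 0.005), min_snps=block.get("min_snps", 35)
    )
    win_path = out / "windows.tsv"
    write_table(windows, win_path)
    outputs = [win_path]
    if block.get("fit", True):
        res = RohDensityModel(windows).fit(n_boot=block.get("n_boot", 100), seed=seed)
        fit_path = out / "density_model.txt"
        fit_path.write_text(res.summary() + "\n")
        outputs.append(fit_path)
    state["windows"] = windows
    return outputs


def _stage_depression(block: dict, seed: int, out: Path, state: dict) -> list[Path]:
    surv = state["survival"] if "survival" in state else pd.read_csv(block["survival_table"], sep="\t")
    froh = state["froh"]
    ped = state.get("pedigree") if block.get("include_pedigree", False) else None
    model = AnnualSurvivalModel.from_tables(surv, froh, ped)
    res = model.fit(include_pedigree=ped is not None)
    coef_path = out / "survival_coefficients.tsv"
    write_table(res.coefficient_table(), coef_path)
    le = PoissonSurvivalModel.from_tables(surv, froh, ped).fit(include_pedigree=ped is not None)
    le_path = out / "lethal_equivalents.txt"
    lo, hi = le.lethal_equivalents_conf_int()
    le_path.write_text(
        f"2B\t{le.lethal_equivalents:.4f}\nci_low\t{lo:.4f}\nci_high\t{hi:.4f}\n"
    )
    state["survival_fit"] = res
    return [coef_path, le_path]


def _stage_gwas(block: dict, seed: int, out: Path, state: dict) -> list[Path]:
    g = _require_genotypes(block, out, state)
    surv = state["survival"]
    lengths = _chrom_lengths_mb(g.snps, state.get("chromosomes"))
    scan = RohStatusScan(
        surv,
        g,
        state["segments"],
        lengths,
        n_pcs=block.get("n_pcs", 7),
        min_carriers=block.get("min_carriers", 5),
        vc=block.get("vc", "null-fit"),
    )
    thin = block.get("thin", 1)
    snp_ids = g.snps["snp_id"].iloc[::thin] if thin > 1 else None
    results = scan.run(snp_ids=snp_ids)
    eff = effective_tests(g, C=block.get("C", 0.995), block_size=block.get("block_size", 1000))
    thr = significance_threshold(eff, alpha=block.get("alpha", 0.05))
    scan_path = out / "gwas.tsv"
    write_table(results.table, scan_path)
    enr = results.sign_enrichment()
    rep_path = out / "gwas_report.txt"
    rep_path.write_text(
        f"n_eff\t{eff.n_eff}\nn_tests_total\t{eff.n_tests_total}\n"
        f"threshold\t{thr:.4g}\n{enr.summary()}\n"
    )
    return [scan_path, rep_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "callroh": _stage_callroh,
    "froh": _stage_froh,
    "landscape": _stage_landscape,
    "depression": _stage_depression,
    "gwas": _stage_gwas,
}
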