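"""Staged pipeline over an on-disk workspace.

Each stage reads the outputs of the previous stages from a workspace
directory and writes tab-separated tables (plus compressed numpy archives
for matrices), so stages can be re-run in isolation.  A manifest records
the configuration and derived per-stage seeds.  The command-line interface
in :mod:`polylife.cli` is a thin wrapper over these functions.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import gibbs_lmm
from .adjustment import adjust_lifestyle, cohort_design
from .datatypes import Kernel, ValidationError
from .evaluation import (build_model_spec, genetic_correlation,
                         rnd_validation_mask, run_split,
                         variance_decomposition, yo_validation_mask)
from .gibbs_lmm import McmcConfig
from .kernels import compute_grm, eigen_summary, lifestyle_kernel, truncated_grm
from .plink_io import (read_dosage_tsv, read_plink, write_dosage_tsv,
                       write_gcta_grm, write_plink)
from .preprocess import derive_phenotypes, prune_relatedness, qc_variants, standardize
from .synthetic_data import SimulationConfig, simulate_dataset

DEFAULT_CONFIG = {
    "simulate": {"n_individuals": 800, "n_variants": 1500, "seed": 0},
    "genotype_format": "tsv",            # "tsv" or "plink"
    "qc": {"maf_min": 0.01, "mac_min": 5, "miss_max": 0.1, "hwe_p_min": 1e-10},
    # the study threshold of 0.025 presupposes ~6e5 variants; at desk-scale
    # variant counts the GRM's sampling noise alone exceeds it, so the demo
    # default is looser (it still catches planted duplicates at ~1)
    "relatedness_threshold": 0.2,
    "mcmc": {"n_iter": 3000, "burn_in": 500, "thin": 5},
    "models": ["M0", "M11", "M02"],
    "split": "RND",                      # "RND" or "Y-O"
    "traits": ["SP", "DP", "PP"],
    "standardize_adjusted": True,
    "truncated_rank": 20,
    "seed": 0,
}


def stage_seed(config: dict, stage: str) -> int:
    """Derive a deterministic per-stage sub-seed from the global seed."""
    h = hashlib.sha256(f"{config.get('seed', 0)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _write_manifest(workdir: Path, stage: str, config: dict):
    path = workdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest[stage] = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.get("seed", 0),
        "stage_seed": stage_seed(config, stage),
    }
    path.write_text(json.dumps(manifest, indent=2))


def _mcmc(config: dict, stage: str) -> McmcConfig:
    m = config["mcmc"]
    return McmcConfig(n_iter=m["n_iter"], burn_in=m["burn_in"],
                      thin=m["thin"], seed=stage_seed(config, stage))


def stage_simulate(config: dict, workdir) -> None:
    """Generate and persist a synthetic study."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(config["simulate"])
    sim_kwargs.setdefault("seed", stage_seed(config, "simulate"))
    ds = simulate_dataset(SimulationConfig(**sim_kwargs))
    if config.get("genotype_format") == "plink":
        write_plink(ds.genotypes, workdir / "genotypes")
    else:
        write_dosage_tsv(ds.genotypes, workdir / "genotypes.tsv")
    ds.demographics.to_csv(workdir / "demographics.tsv", sep="\t", index=False)
    m = pd.DataFrame(ds.lifestyle,
                     columns=[f"ls{j:02d}" for j in range(ds.lifestyle.shape[1])])
    m.insert(0, "IID", ds.demographics["IID"])
    m.to_csv(workdir / "lifestyle.tsv", sep="\t", index=False)
    ds.traits.to_csv(workdir / "traits.tsv", sep="\t", index=False)
    np.savez_compressed(
        workdir / "truth.npz",
        **{f"lifestyle_{k}": v for k, v in ds.lifestyle_truth.components.items()},
        **{f"bv_{k}": v for k, v in ds.trait_truth.breeding_values.items()},
        **{f"latent_{k}": v for k, v in ds.trait_truth.latent.items()})
    _write_manifest(workdir, "simulate", config)


def _load_genotypes(config, workdir: Path):
    if config.get("genotype_format") == "plink":
        return read_plink(workdir / "genotypes")
    return read_dosage_tsv(workdir / "genotypes.tsv")


def stage_preprocess(config: dict, workdir) -> None:
    """QC variants, derive phenotypes and groupings, prune relatedness."""
    workdir = Path(workdir)
    g = _load_genotypes(config, workdir)
    g_qc, report = qc_variants(g, **config["qc"])
    report.to_csv(workdir / "variant_qc.tsv", sep="\t", index=False)
    grm = compute_grm(g_qc)
    keep_ids = prune_relatedness(grm, config["relatedness_threshold"])
    demo = pd.read_csv(workdir / "demographics.tsv", sep="\t")
    traits = pd.read_csv(workdir / "traits.tsv", sep="\t")
    pheno = derive_phenotypes(traits, demo,
                              rnd_seed=stage_seed(config, "rnd_groups")).data
    pheno = pheno[pheno["IID"].isin(keep_ids)].reset_index(drop=True)
    pheno.to_csv(workdir / "phenotypes.tsv", sep="\t", index=False)
    keep = np.isin(g_qc.ids, pheno["IID"].to_numpy())
    np.savez_compressed(workdir / "genotypes_qc.npz",
                        dosages=g_qc.dosages[keep], ids=g_qc.ids[keep],
                        variant_ids=g_qc.variant_ids)
    _write_manifest(workdir, "preprocess", config)


def _load_qc_genotypes(workdir: Path):
    from .datatypes import GenotypeMatrix

    z = np.load(workdir / "genotypes_qc.npz", allow_pickle=True)
    return GenotypeMatrix(dosages=z["dosages"], ids=z["ids"].astype(str),
                          variant_ids=z["variant_ids"].astype(str))


def stage_kernels(config: dict, workdir) -> None:
    """Compute the GRM (and its GCTA export) and the truncated-PC control."""
    workdir = Path(workdir)
    g = _load_qc_genotypes(workdir)
    grm = compute_grm(g)
    np.savez_compressed(workdir / "grm.npz", matrix=grm.matrix, ids=grm.ids)
    write_gcta_grm(grm, workdir / "grm", n_variants=g.n_variants)
    trunc = truncated_grm(grm, r=min(config["truncated_rank"], grm.n))
    np.savez_compressed(workdir / "grm_truncated.npz",
                        matrix=trunc.matrix, ids=trunc.ids)
    _write_manifest(workdir, "kernels", config)


def _load_kernel(workdir: Path, name: str, label: str) -> Kernel:
    z = np.load(workdir / name, allow_pickle=True)
    return Kernel(matrix=z["matrix"], ids=z["ids"].astype(str), label=label)


def _lifestyle_frame(workdir: Path, pheno: pd.DataFrame) -> np.ndarray:
    m = pd.read_csv(workdir / "lifestyle.tsv", sep="\t")
    m = m[m["IID"].isin(pheno["IID"])].reset_index(drop=True)
    return np.column_stack([standardize(m[c].to_numpy())
                            for c in m.columns if c != "IID"])


def stage_adjust(config: dict, workdir) -> None:
    """Fit the per-variable adjustment models and write M/L/E."""
    workdir = Path(workdir)
    pheno = pd.read_csv(workdir / "phenotypes.tsv", sep="\t")
    grm = _load_kernel(workdir, "grm.npz", "G")
    m_std = _lifestyle_frame(workdir, pheno)
    ls = adjust_lifestyle(m_std, pheno["cohort"].to_numpy(), grm,
                          _mcmc(config, "adjust"),
                          seed=stage_seed(config, "adjust"),
                          standardize_output=config["standardize_adjusted"])
    for name, mat in (("M", ls.M), ("L", ls.L), ("E", ls.E)):
        df = pd.DataFrame(mat, columns=[f"ls{j:02d}" for j in range(mat.shape[1])])
        df.insert(0, "IID", pheno["IID"])
        df.to_csv(workdir / f"lifestyle_{name}.tsv", sep="\t", index=False)
    ls.summaries.to_csv(workdir / "lifestyle_variance.tsv", sep="\t", index=False)
    rows = []
    for name, mat in (("MM", ls.M), ("LL", ls.L), ("EE", ls.E)):
        es = eigen_summary(lifestyle_kernel(mat, grm.ids, name))
        es.insert(0, "kernel", name)
        rows.append(es.head(mat.shape[1]))
    pd.concat(rows).to_csv(workdir / "kernel_eigen_summary.tsv", sep="\t",
                           index=False)
    _write_manifest(workdir, "adjust", config)


def _model_inputs(config, workdir: Path):
    pheno = pd.read_csv(workdir / "phenotypes.tsv", sep="\t")
    grm = _load_kernel(workdir, "grm.npz", "G")
    trunc = _load_kernel(workdir, "grm_truncated.npz", "P")
    kernels = {}
    for key in ("M", "L", "E"):
        path = workdir / f"lifestyle_{key}.tsv"
        if path.exists():
            mat = pd.read_csv(path, sep="\t").drop(columns="IID").to_numpy()
            kernels[key] = lifestyle_kernel(mat, grm.ids, f"{key}{key}")
    return pheno, grm, trunc, kernels


def _trait_response(pheno: pd.DataFrame, trait: str) -> np.ndarray:
    return standardize(pheno[trait].to_numpy(), mode="response")


def stage_decompose(config: dict, workdir) -> None:
    """Fit every requested model on the full data and tabulate variances."""
    workdir = Path(workdir)
    pheno, grm, trunc, kernels = _model_inputs(config, workdir)
    x = cohort_design(pheno["cohort"].to_numpy())
    tables = []
    for trait in config["traits"]:
        y = _trait_response(pheno, trait)
        for mid in config["models"]:
            spec = build_model_spec(mid, grm, kernels, trunc)
            fit = gibbs_lmm.fit(y, x, spec.terms, _mcmc(config, f"fit-{trait}-{mid}"))
            tab = variance_decomposition(fit, spec, x_design=x)
            tab.insert(0, "trait", trait)
            tables.append(tab)
    pd.concat(tables).to_csv(workdir / "variance_table.tsv", sep="\t",
                             index=False)
    _write_manifest(workdir, "decompose", config)


def stage_predict(config: dict, workdir) -> None:
    """Run the configured train/validation split for every model and trait."""
    workdir = Path(workdir)
    pheno, grm, trunc, kernels = _model_inputs(config, workdir)
    split = config["split"]
    if split == "Y-O":
        mask = yo_validation_mask(pheno["yo_group"].to_numpy())
    elif split == "RND":
        mask = rnd_validation_mask(pheno["rnd_group"].to_numpy())
    else:
        raise ValidationError(f"unknown split {split!r}")
    rows = []
    # the cohort-only model M02 is informative only for the RND design
    model_ids = config.get("predict_models", config["models"])
    if split == "Y-O":
        model_ids = [m for m in model_ids if m != "M02"]
    for trait in config["traits"]:
        y = _trait_response(pheno, trait)
        for mid in model_ids:
            spec = build_model_spec(mid, grm, kernels, trunc)
            res = run_split(spec, y, pheno["cohort"].to_numpy(), mask,
                            _mcmc(config, f"predict-{trait}-{mid}"),
                            split_name=split)
            rows.append({"trait": trait, "model": mid, "split": split,
                         "n_validation": int(mask.sum()), "r": res.r,
                         "beta0": res.beta0, "beta1": res.beta1})
    pd.DataFrame(rows).to_csv(workdir / "prediction_table.tsv", sep="\t",
                              index=False)
    _write_manifest(workdir, "predict", config)


def stage_gcor(config: dict, workdir) -> None:
    """Bivariate REML genetic correlation between Y and O per trait."""
    workdir = Path(workdir)
    pheno, grm, _, _ = _model_inputs(config, workdir)
    rows = []
    for trait in config["traits"]:
        y = _trait_response(pheno, trait)
        res = genetic_correlation(y, pheno["yo_group"].to_numpy(), grm,
                                  trait=trait)
        rows.append({"trait": trait, "rG": res.rg, "SE": res.se,
                     "ci_low": res.ci[0], "ci_high": res.ci[1],
                     "converged": res.converged, "boundary": res.boundary})
    pd.DataFrame(rows).to_csv(workdir / "genetic_correlation.tsv", sep="\t",
                              index=False)
    _write_manifest(workdir, "gcor", config)


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "kernels": stage_kernels,
    "adjust": stage_adjust,
    "decompose": stage_decompose,
    "predict": stage_predict,
    "gcor": stage_gcor,
}
STAGE_ORDER = ("simulate", "preprocess", "kernels", "adjust",
               "decompose", "predict", "gcor")


def run_all(config: dict, workdir) -> None:
    for name in STAGE_ORDER:
        STAGES[name](config, workdir)
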