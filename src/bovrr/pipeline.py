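"""End-to-end pipeline: simulate -> records -> grm -> fit -> effects ->
heterosis -> qtl, driven by a single YAML-able configuration.

Every stage writes its outputs under the run's output directory and a
manifest (JSON) records the seed, parameters, per-stage shapes and sha256
hashes of written files, so re-running with the same config and seed
reproduces identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hetmetrics, io, qtloverlap, records, relmat, rrgreml, simdata, varianteffects

logger = logging.getLogger(__name__)

ALL_STAGES = ["simulate", "records", "grm", "fit", "effects", "heterosis", "qtl"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "bovrr_run",
    "stages": ALL_STAGES,
    "inputs": {  # used when the simulate stage is disabled
        "genotypes_vcf": None,
        "genotypes_tsv": None,
        "pedigree_csv": None,
        "events_csv": None,
    },
    "simulate": {
        "n_breeds": 4,
        "n_variants": 2500,
        "n_chromosomes": 3,
        "chrom_length": 50_000_000,
        "fst": 0.15,
        "n_founders_per_breed": 24,
        "offspring_per_mating": 40,
        "n_generations": 2,
        "map_cm_per_mb": 1.0,
        "mode": "variant-effects",
        "causal_fraction": 0.1,
        "ratio_a8": 0.4,
        "ratio_d8": 0.1,
        "total_var_age8": 2500.0,
        "dominance_mean": 0.0,
        "directional_dominance": 0.7,
        "conception_heterosis": 0.8,
        "conception_base": 0.75,
    },
    "grm": {
        "min_call_rate": 0.95,
        "min_maf": 0.005,
        "window_bp": 50_000,
        "r_thresh": 0.98,
        "prune": True,
    },
    "fit": {
        "order": 1,
        "age_min": 2.0,
        "age_max": 8.0,
        "include_pe": False,
        # variance ratios stabilize well before the strict 1e-6 optimum;
        # pipeline runs use a pragmatic stop (reml_fit's own default is 1e-6)
        "tol": 1e-4,
        "max_iter": 60,
        "traits": ["CW", "WtW"],
        "projection_age": 8.0,
    },
    "effects": {"B": 5000, "alpha": 0.05},
    "heterosis": {
        "roh": {"min_length_bp": 1_000_000, "min_snp": 15},
        "hrr": {"min_length_bp": 100_000, "min_snp": 3},
    },
    "qtl": {"path": None, "dialect": "bed"},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def validate_config(cfg: dict) -> None:
    stages = cfg["stages"]
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "simulate" not in stages:
        inputs = cfg.get("inputs") or {}
        if "grm" in stages and not (
            inputs.get("genotypes_vcf") or inputs.get("genotypes_tsv")
        ):
            raise ValueError("grm stage enabled but no genotype input configured")
        if "records" in stages and not inputs.get("events_csv"):
            raise ValueError("records stage enabled but no events input configured")
    if "qtl" in stages and not cfg["qtl"].get("path"):
        raise ValueError("qtl stage enabled but no interval table configured")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def run_pipeline(cfg: dict) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    validate_config(cfg)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in cfg["stages"]]
    manifest: dict = {
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "outdir"},
        "stages": {},
        "files": {},
    }
    state: dict = {}

    for stage in stages:
        t0 = time.time()
        try:
            info = _STAGE_FUNCS[stage](cfg, state, outdir, seed)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, "failed", str(exc)) from exc
        info["seconds"] = round(time.time() - t0, 2)
        manifest["stages"][stage] = info
        logger.info("stage %s done in %.1fs", stage, info["seconds"])

    for f in sorted(outdir.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# -- stages ----------------------------------------------------------------


def _stage_simulate(cfg, state, outdir, seed):
    sc = cfg["simulate"]
    panel = simdata.simulate_breed_panel(
        n_breeds=sc["n_breeds"],
        n_variants=sc["n_variants"],
        n_chromosomes=sc["n_chromosomes"],
        chrom_length=sc["chrom_length"],
        fst=sc["fst"],
        seed=seed,
    )
    plan = simdata.default_plan(
        panel.breeds,
        offspring_per_mating=sc["offspring_per_mating"],
        n_generations=sc["n_generations"],
    )
    pedigree = simdata.simulate_pedigree(
        plan, n_founders_per_breed=sc["n_founders_per_breed"], seed=seed + 1
    )
    genotypes = simdata.drop_genotypes(
        pedigree, panel, map_cm_per_mb=sc["map_cm_per_mb"], seed=seed + 2
    )
    params = simdata.make_true_params(
        ratio_a8=sc["ratio_a8"],
        ratio_d8=sc["ratio_d8"],
        total_var_age8=sc["total_var_age8"],
        order=cfg["fit"]["order"],
        dominance_mean=sc["dominance_mean"],
        directional_dominance=sc["directional_dominance"],
        conception_heterosis=sc["conception_heterosis"],
        conception_base=sc["conception_base"],
    )
    events, truth = simdata.simulate_events(
        pedigree,
        genotypes,
        params,
        mode=sc["mode"],
        causal_fraction=sc["causal_fraction"],
        seed=seed + 3,
    )
    io.write_pedigree_csv(pedigree, outdir / "pedigree.csv")
    io.write_events_csv(events, outdir / "events.csv")
    io.write_genotypes_tsv(genotypes, outdir / "genotypes.tsv")
    io.write_params_yaml(params, outdir / "true_params.yaml")
    truth.to_csv(outdir / "true_values.csv", index=False)
    state.update(
        panel=panel, pedigree=pedigree, genotypes=genotypes, params=params,
        events=events, truth=truth,
    )
    return {
        "n_animals": genotypes.n_animals,
        "n_variants": genotypes.n_variants,
        "n_exposures": len(events),
    }


def _stage_records(cfg, state, outdir, seed):
    if "events" not in state:
        inputs = cfg["inputs"]
        state["events"] = io.read_events_csv(inputs["events_csv"])
        if inputs.get("pedigree_csv"):
            state["pedigree"] = io.read_pedigree_csv(inputs["pedigree_csv"])
    ped = state.get("pedigree")
    compositions = ped.composition if ped is not None else None
    seasons = (
        dict(zip(ped.table["animal_id"], ped.table["birth_season"]))
        if ped is not None
        else None
    )
    recs = records.build_records(state["events"], compositions, seasons)
    recs.to_csv(outdir / "records.csv", index=False)
    state["records"] = recs
    return {"n_records": len(recs), "traits": sorted(recs["trait"].unique().tolist())}


def _stage_grm(cfg, state, outdir, seed):
    if "genotypes" not in state:
        inputs = cfg["inputs"]
        if inputs.get("genotypes_vcf"):
            state["genotypes"] = io.read_vcf(inputs["genotypes_vcf"])
        else:
            state["genotypes"] = io.read_genotypes_tsv(inputs["genotypes_tsv"])
    gc = cfg["grm"]
    pair, pruned = relmat.build_relationships(
        state["genotypes"],
        min_call_rate=gc["min_call_rate"],
        min_maf=gc["min_maf"],
        window_bp=gc["window_bp"],
        r_thresh=gc["r_thresh"],
        prune=gc["prune"],
    )
    io.write_grm(pair.G, pair.animal_ids, outdir / "G")
    io.write_grm(pair.D, pair.animal_ids, outdir / "D")
    io.write_redundancy_map(pair.redundancy_map, outdir / "redundancy.csv")
    state["pair"] = pair
    state["pruned_genotypes"] = pruned
    return {
        "n_animals": len(pair.animal_ids),
        "n_variants": pruned.n_variants,
        "n_pruned": len(pair.redundancy_map),
    }


def _stage_fit(cfg, state, outdir, seed):
    fc = cfg["fit"]
    pair = state["pair"]
    fits: dict[str, rrgreml.RRFit] = {}
    projections: dict[str, pd.DataFrame] = {}
    results = {}
    for trait in fc["traits"]:
        spec = rrgreml.ModelSpec(
            trait=trait,
            order=fc["order"],
            age_min=fc["age_min"],
            age_max=fc["age_max"],
            include_pe=fc["include_pe"],
            tol=fc["tol"],
            max_iter=fc["max_iter"],
        )
        designs = rrgreml.build_design(state["records"], spec, pair.animal_ids)
        fit = rrgreml.reml_fit(designs, pair.G, pair.D, spec=spec)
        proj = rrgreml.project_to_age(
            fit.coef_a, fit.coef_d, spec, age=fc["projection_age"],
            animal_ids=pair.animal_ids,
        )
        proj.to_csv(outdir / f"projections_{trait}.csv", index=False)
        curve = rrgreml.heritability_curve(
            fit, np.arange(fc["age_min"], fc["age_max"] + 0.25, 0.5)
        )
        curve.to_csv(outdir / f"heritability_{trait}.csv", index=False)
        (outdir / f"fit_{trait}.json").write_text(
            json.dumps(
                {
                    "variance_components": fit.variance_components(),
                    "loglik": fit.loglik,
                    "converged": fit.converged,
                    "n_iter": fit.n_iter,
                },
                indent=2,
            )
        )
        fits[trait] = fit
        projections[trait] = proj
        h8 = rrgreml.heritability_curve(fit, [fc["age_max"]]).iloc[0]
        results[trait] = {
            "h2_a_age8": round(float(h8["h2_a"]), 4),
            "h2_d_age8": round(float(h8["h2_d"]), 4),
            "converged": fit.converged,
        }
    state["fits"] = fits
    state["projections"] = projections
    return results


def _stage_effects(cfg, state, outdir, seed):
    ec = cfg["effects"]
    pair = state["pair"]
    pruned = state["pruned_genotypes"]
    info = {}
    phenotyped = None
    for trait, fit in state["fits"].items():
        proj = state["projections"][trait]
        table = varianteffects.variant_effect_table(
            pruned.variants,
            pair.M,
            pair.H,
            pair.G,
            pair.D,
            pair.c_a,
            pair.c_d,
            proj["u_a"].to_numpy(),
            proj["u_d"].to_numpy(),
            B=ec["B"],
            alpha=ec["alpha"],
            seed=seed + 10,
            redundancy_map=pair.redundancy_map or None,
        )
        table.to_csv(outdir / f"variant_effects_{trait}.tsv", sep="\t", index=True,
                     index_label="variant_idx")
        state.setdefault("effect_tables", {})[trait] = table
        info[trait] = {
            "n_sig_additive": int(table["sig_a"].sum()),
            "n_sig_dominance": int(table["sig_d"].sum()),
        }
        phenotyped = proj
    return info


def _stage_heterosis(cfg, state, outdir, seed):
    hc = cfg["heterosis"]
    pair = state["pair"]
    pruned = state["pruned_genotypes"]
    Fg = relmat.genomic_inbreeding(pair.G)
    profile = hetmetrics.heterosis_profile(
        pruned, Fg, pedigree=state.get("pedigree"),
        roh_params=hc["roh"], hrr_params=hc["hrr"],
    )
    profile.to_csv(outdir / "heterosis_profile.csv", index=False)
    projections = state.get("projections", {})
    info = {"n_animals": len(profile)}
    if {"CW", "WtW"} <= set(projections):
        groups = hetmetrics.group_cows(projections["CW"], projections["WtW"])
        groups.to_csv(outdir / "merit_groups.csv", index=False)
        summary = hetmetrics.summarize_groups(profile, groups)
        summary.to_csv(outdir / "group_summary.csv", index=False)
        r2 = hetmetrics.regress_metrics(projections, profile)
        r2.to_csv(outdir / "r2_table.csv", index=False)
        state["groups"] = groups
        state["group_summary"] = summary
        info["groups"] = sorted(groups["quadrant"].unique().tolist())
    state["profile"] = profile
    return info


def _stage_qtl(cfg, state, outdir, seed):
    qc = cfg["qtl"]
    intervals = qtloverlap.load_qtl_table(qc["path"], dialect=qc["dialect"])
    significant = {}
    for trait, table in state.get("effect_tables", {}).items():
        significant[f"{trait} additive"] = table.loc[table["sig_a"], ["chrom", "pos"]]
        significant[f"{trait} dominance"] = table.loc[table["sig_d"], ["chrom", "pos"]]
    counts = qtloverlap.overlap_counts(significant, intervals)
    counts.to_csv(outdir / "qtl_overlap.csv", index=False)
    return {"n_intervals": len(intervals), "n_components": len(significant)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "records": _stage_records,
    "grm": _stage_grm,
    "fit": _stage_fit,
    "effects": _stage_effects,
    "heterosis": _stage_heterosis,
    "qtl": _stage_qtl,
}
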