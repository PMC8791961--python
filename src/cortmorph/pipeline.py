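"""End-to-end orchestration: simulate/load -> harmonise -> group stats ->
receptor associations -> PCA -> covariance networks, from one config.

A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` in a fixed, documented order (cohorts,
receptor maps, spins, bootstraps, permutations, community detection), so
any stage can be reproduced independently and the whole run is
deterministic: two runs from the same config and seed write byte-identical
machine-readable reports. Stage runtimes go to the log stream only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covnet, groupstats, harmonize, pcadim, receptormap, synthio
from .types import (
    Atlas,
    MorphometricTable,
    ValidationError,
    read_metadata,
    validate_metadata,
)

logger = logging.getLogger(__name__)

_SEED_CHILDREN = (
    "analysis_cohort",
    "network_cohort",
    "receptor_maps",
    "spins",
    "bootstrap",
    "permutations",
    "louvain",
    "truth",
)


def child_seeds(seed: int) -> dict:
    """Fan a global seed out to named per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_SEED_CHILDREN))
    return {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(_SEED_CHILDREN, children)
    }


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Either ``inputs`` points at existing CSV files (morphometrics,
    metadata, atlas, receptor maps) or ``synthetic`` describes the
    cohort to simulate. Counts are study defaults scaled for a desk run.
    """

    seed: int = 0
    out_dir: str = "results"
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    covariates: tuple = groupstats.DEFAULT_COVARIATES
    network_covariates: tuple = covnet.DEFAULT_COVARIATES
    harmonisation_covariates: tuple = harmonize.DEFAULT_COVARIATES
    interactions: tuple = ()
    fdr_q: float = 0.05
    densities: tuple = covnet.DENSITY_SWEEP
    n_spins: int = 1000
    n_boot: int = 1000
    n_perm: int = 200
    modularity_density: float = 0.13
    modularity_reps: int = 200
    louvain_restarts: int = 20
    run_permutation_tests: bool = True

    def __post_init__(self):
        if not (0 < self.fdr_q < 1):
            raise ValidationError("fdr_q must be in (0, 1)")
        for d in self.densities:
            if not 0 < d < 1:
                raise ValidationError("densities must be in (0, 1)")
        for name in ("n_spins", "n_boot", "modularity_reps"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if not self.synthetic and not self.inputs:
            self.synthetic = {}  # default synthetic run
        self.covariates = tuple(self.covariates)
        self.network_covariates = tuple(self.network_covariates)
        self.harmonisation_covariates = tuple(self.harmonisation_covariates)
        self.interactions = tuple(self.interactions)
        self.densities = tuple(float(d) for d in self.densities)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            out[name] = list(v) if isinstance(v, tuple) else v
        return out


_SYNTH_DEFAULTS = {
    "analysis_n_per_hemisphere": 74,   # 148-region analysis parcellation
    "network_n_per_hemisphere": 34,    # 68-region covariance parcellation
    "atlas_seed": 7,
    "n_per_group_per_site": None,      # None -> the 200-subject default plan
    "n_affected": 20,
    "effect_size": 0.3,
    "plant_hub": True,
    "receptors": {"D2D3": -0.4, "5HT1A": -0.4, "5HT2A": -0.4},
    "receptor_smoothness": 30.0,
}


def load_inputs(config: PipelineConfig) -> dict:
    """Build the validated in-memory bundle the pipeline runs on."""
    seeds = child_seeds(config.seed)
    if config.inputs:
        return _load_files(config)
    opts = dict(_SYNTH_DEFAULTS)
    unknown = set(config.synthetic) - set(opts)
    if unknown:
        raise ValidationError(f"unknown synthetic options: {sorted(unknown)}")
    opts.update(config.synthetic)

    atlas = synthio.generate_atlas(
        opts["analysis_n_per_hemisphere"], seed=opts["atlas_seed"]
    )
    net_atlas = synthio.generate_atlas(
        opts["network_n_per_hemisphere"], seed=opts["atlas_seed"] + 1
    )
    plan = opts["n_per_group_per_site"]
    if plan is None:
        plan = synthio.DEFAULT_COHORT_PLAN
    truth = synthio.default_truth(
        atlas,
        n_affected=opts["n_affected"],
        effect_size=opts["effect_size"],
        seed=seeds["truth"],
    )
    net_truth = synthio.default_truth(
        net_atlas,
        n_affected=max(4, opts["n_affected"] // 3),
        effect_size=opts["effect_size"],
        plant_hub=opts["plant_hub"],
        seed=seeds["truth"] + 1,
    )
    table, meta = synthio.generate_cohort(
        atlas, truth, plan, seed=seeds["analysis_cohort"]
    )
    net_table, net_meta = synthio.generate_cohort(
        net_atlas, net_truth, plan, seed=seeds["network_cohort"]
    )
    # receptor maps with planted correlation to the true difference map
    rmaps = {}
    rseed = seeds["receptor_maps"]
    for i, (label, rho) in enumerate(sorted(opts["receptors"].items())):
        rmaps[label] = synthio.generate_receptor_map(
            atlas,
            smoothness=opts["receptor_smoothness"],
            seed=rseed + i,
            target=(truth.delta, rho) if rho is not None else None,
            receptor_label=label,
        )
    return {
        "atlas": atlas,
        "net_atlas": net_atlas,
        "table": table,
        "meta": meta,
        "net_table": net_table,
        "net_meta": net_meta,
        "receptor_maps": rmaps,
        "truth": truth,
        "net_truth": net_truth,
        "seeds": seeds,
    }


def _load_files(config: PipelineConfig) -> dict:
    paths = config.inputs
    for key in ("morphometrics", "metadata", "atlas"):
        if key not in paths:
            raise ValidationError(f"inputs missing {key!r}")
    atlas = Atlas.from_csv(paths["atlas"])
    meta = read_metadata(paths["metadata"])
    table = MorphometricTable.from_csv(
        paths["morphometrics"], paths.get("measure_kind", "thickness")
    )
    unknown = [r for r in table.regions if r not in set(atlas.region_id)]
    if unknown:
        raise ValidationError(
            f"regions in morphometrics but not in atlas: {unknown[:10]}"
        )
    missing_subjects = set(table.subjects) - set(meta["subject_id"])
    if missing_subjects:
        raise ValidationError(
            f"subjects without metadata: {sorted(missing_subjects)[:10]}"
        )
    rmaps = {}
    for label, p in paths.get("receptor_maps", {}).items():
        rmaps[label] = receptormap.ReceptorMap.from_csv(p, receptor_label=label)
    net = paths.get("network_morphometrics")
    bundle = {
        "atlas": atlas,
        "net_atlas": Atlas.from_csv(paths["network_atlas"]) if net else atlas,
        "table": table,
        "meta": meta,
        "net_table": MorphometricTable.from_csv(net) if net else table,
        "net_meta": meta,
        "receptor_maps": rmaps,
        "truth": None,
        "net_truth": None,
        "seeds": child_seeds(config.seed),
    }
    return bundle


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artefacts + report.json to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_inputs(config)
    seeds = bundle["seeds"]
    # out_dir is a filesystem location, not an analysis parameter: leaving
    # it out keeps reports byte-identical wherever the run is written
    resolved = {k: v for k, v in config.resolved().items() if k != "out_dir"}
    report: dict = {
        "config": resolved,
        "seeds": seeds,
        "warnings": [],
        "stages": {},
    }

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # 1. harmonisation -----------------------------------------------------
    t0 = _stage("harmonise")
    adjusted, fit = harmonize.harmonize(
        bundle["table"], bundle["meta"], config.harmonisation_covariates
    )
    before = harmonize.site_effect_report(bundle["table"], bundle["meta"])
    after = harmonize.site_effect_report(adjusted, bundle["meta"])
    report["stages"]["harmonise"] = {
        "covariates": list(config.harmonisation_covariates),
        "mean_site_eta2_before": float(np.nanmean(before["eta2"])),
        "mean_site_eta2_after": float(np.nanmean(after["eta2"])),
        "converged": fit.converged,
    }
    fit.to_json(out / "harmonisation_fit.json")
    adjusted.to_csv(out / "morphometrics_harmonised.csv")
    logger.info("harmonise done in %.1fs", time.perf_counter() - t0)

    net_adjusted, _ = harmonize.harmonize(
        bundle["net_table"], bundle["net_meta"], config.harmonisation_covariates
    )

    # 2. screening + MANCOVA ----------------------------------------------
    t0 = _stage("groupstats")
    screen = groupstats.screen_regions_anova(
        adjusted, bundle["meta"], config.covariates, q=config.fdr_q
    )
    screen.to_csv(out / "region_screen.csv", index=False)
    flagged = list(screen.loc[screen["significant"], "region_id"])
    mancova_summary = None
    if flagged:
        n_max = max(
            2, len(bundle["meta"]) - len(config.covariates) - 8
        )
        entered = flagged[:n_max]
        try:
            mv = groupstats.fit_mancova(
                adjusted, bundle["meta"], entered,
                config.covariates, config.interactions,
            )
            mv.multivariate.to_csv(out / "mancova_multivariate.csv", index=False)
            mv.per_region.to_csv(out / "mancova_per_region.csv", index=False)
            grp = mv.multivariate.query("term == 'group'")
            mancova_summary = {
                "n_regions_entered": len(entered),
                "group_p": float(grp["p"].iloc[0]) if len(grp) else None,
                "n_pairwise_significant": int(
                    (mv.pairwise["p_bonferroni"] < 0.05).sum()
                ),
            }
        except ValidationError as err:
            report["warnings"].append(f"mancova: {err}")
    report["stages"]["groupstats"] = {
        "n_flagged": len(flagged),
        "flagged_regions": flagged,
        "mancova": mancova_summary,
    }
    logger.info("groupstats done in %.1fs", time.perf_counter() - t0)

    # 3. difference map -----------------------------------------------------
    diffmap = groupstats.compute_difference_map(adjusted, bundle["meta"])
    diffmap.to_csv(out / "difference_map.csv")

    # 4. receptor associations ---------------------------------------------
    t0 = _stage("receptormap")
    atlas = bundle["atlas"]
    spins = receptormap.generate_spin_permutations(
        atlas, config.n_spins, seed=seeds["spins"]
    )
    receptor_report = {}
    for label in sorted(bundle["receptor_maps"]):
        rmap = bundle["receptor_maps"][label]
        fits = receptormap.fit_receptor_subsets(
            diffmap.diff, rmap, flagged, atlas,
            n_boot=config.n_boot, seed=seeds["bootstrap"],
        )
        d, bp, _ = receptormap.align_receptor_map(rmap, diffmap.diff, atlas)
        full = pd.Series(bp, index=d.index)
        r_obs, p_spin = receptormap.spin_correlation_test(
            d.to_numpy(), full.to_numpy(), spins
        )
        receptor_report[label] = {
            "subsets": {k: v.as_dict() for k, v in fits.items()},
            "spin": {"r": r_obs, "p": p_spin, "n_spins": spins.n_spins},
        }
    report["stages"]["receptormap"] = receptor_report
    with open(out / "receptor_associations.json", "w") as fh:
        json.dump(_round_floats(receptor_report), fh, indent=1, sort_keys=True)
    logger.info("receptormap done in %.1fs", time.perf_counter() - t0)

    # 5. PCA ----------------------------------------------------------------
    t0 = _stage("pca")
    pca_report = None
    if len(flagged) >= 2:
        res = pcadim.run_pca(adjusted.values[flagged])
        sel = pcadim.select_components(res)
        res.loadings.to_csv(out / "pca_loadings.csv")
        res.contributions.to_csv(out / "pca_contributions.csv")
        pca_report = {
            "n_retained": sel["n_retained"],
            "eigenvalues": res.eigenvalues[: sel["n_retained"]].tolist(),
            "dimensions": sel["dimensions"],
        }
    else:
        report["warnings"].append("pca skipped: fewer than 2 flagged regions")
    report["stages"]["pca"] = pca_report
    logger.info("pca done in %.1fs", time.perf_counter() - t0)

    # 6. covariance networks ------------------------------------------------
    t0 = _stage("covnet")
    resid = covnet.residualize(
        net_adjusted, bundle["net_meta"], config.network_covariates
    )
    covs = {
        g: covnet.covariance_matrix(
            resid, bundle["net_meta"], g, config.network_covariates
        )
        for g in ("VH", "noVH")
    }
    edges = covnet.compare_edges(covs["VH"], covs["noVH"])
    edges.to_csv(out / "edge_stats.tsv", sep="\t", index=False)
    net_report = {
        "n_edges_tested": len(edges),
        "n_edges_fdr_significant": int((edges["p_fdr"] < 0.05).sum()),
    }
    for g, cov in covs.items():
        cov.r.to_csv(out / f"covariance_{g}.csv")
        metrics = covnet.metrics_across_densities(cov, config.densities)
        hubs = covnet.identify_hubs(metrics, group_label=g)
        part = covnet.detect_communities(
            covnet.threshold_graph(cov, config.modularity_density),
            seed=seeds["louvain"],
            restarts=config.louvain_restarts,
        )
        boot = covnet.bootstrap_modularity(
            resid, bundle["net_meta"], g,
            density=config.modularity_density,
            reps=config.modularity_reps,
            seed=seeds["bootstrap"],
            restarts=max(2, config.louvain_restarts // 4),
        )
        net_report[g] = {
            "hubs": list(hubs.hubs),
            "hub_threshold_densities": hubs.threshold,
            "modularity": part.modularity,
            "n_communities": int(part.labels.nunique()),
            "modularity_bootstrap": boot,
        }
        part.labels.to_frame().assign(region_id=part.labels.index).to_csv(
            out / f"communities_{g}.csv", index=False
        )
    if config.run_permutation_tests and config.n_perm >= 100:
        perm = covnet.permutation_test_metrics(
            resid, bundle["net_meta"],
            n_perm=config.n_perm,
            densities=config.densities,
            seed=seeds["permutations"],
        )
        perm.to_csv(out / "node_permutation_tests.csv", index=False)
        sig = perm.loc[perm["p_fdr"] < 0.05]
        net_report["permutation_tests"] = {
            "n_perm": config.n_perm,
            "n_significant": int(len(sig)),
            "significant_nodes": sorted(sig["region_id"].unique().tolist()),
        }
    report["stages"]["covnet"] = net_report
    logger.info("covnet done in %.1fs", time.perf_counter() - t0)

    report = _round_floats(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
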