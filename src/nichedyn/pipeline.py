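"""Config-driven end-to-end niche-dynamics analysis.

One :class:`AnalysisConfig` drives the whole workflow — occurrence
filtering, correlated-variable pruning, the pooled-background PCA, gridded
niche densities, overlap/similarity/S-U-E statistics, reciprocal maxent
SDMs with binary-range comparison, and occupancy profiles — on either
user-supplied rasters + occurrence CSVs or a self-contained synthetic
scenario. All randomness flows from one root seed through named substreams,
so any stage can be re-run in isolation and reproduce its numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from ._seeds import derive_seed
from .dynamics import compare_niches
from .geo import BackgroundRegion, OccurrenceSet, filter_occurrences, prune_correlated, sample_background
from .maxent import (
    compare_binary_ranges,
    evaluate,
    project_mean,
    threshold_at_percentile,
)
from .niche import build_niche_grid, fit_pca
from .profiles import compare_profiles, occupancy_profile
from .raster import ClimateStack, load_stack
from .synthetic import (
    ScenarioSpec,
    default_landscape_pair,
    default_species,
    make_scenario_pair,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run"]

log = logging.getLogger("nichedyn")


@dataclass
class AnalysisConfig:
    """Settings for one full analysis; defaults follow the classic protocol
    (10,000 background points, |r| <= 0.90 variable screening, R = 100 niche
    grid, 75% analogue envelope, beta = 1 maxent with a 75/25 split and the
    10th-percentile presence threshold)."""

    # synthetic-scenario block (used when no raster paths are given)
    scenario: str = "conserved"            # conserved | unfilled | expanded
    truncation_quantile: float = 0.5
    shift_breadths: float = 2.0            # expansion shift, in niche breadths, axis 1
    n_occurrences: int = 1000              # per region
    landscape_rows: int = 160
    landscape_cols: int = 160

    # user-data block: per-region raster paths and occurrence CSVs
    native_rasters: list[str] = field(default_factory=list)
    invaded_rasters: list[str] = field(default_factory=list)
    native_occurrences: str | None = None
    invaded_occurrences: str | None = None
    native_box: tuple[float, float, float, float] | None = None  # west,east,south,north
    invaded_box: tuple[float, float, float, float] | None = None
    min_year: int | None = None

    # analysis settings
    r_max: float = 0.90
    R: int = 100
    envelope: str = "75"
    beta: float = 1.0
    train_fraction: float = 0.75
    percentile: float = 10.0
    n_background: int = 10000
    n_reps_similarity: int = 99
    sdm_replicates: int = 100
    bin_width: float = 100.0
    profile_covariate: str | None = None   # default: first retained layer
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for key in ("native_box", "invaded_box"):
            v = getattr(cfg, key)
            if v is not None:
                setattr(cfg, key, tuple(float(x) for x in v))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        d = asdict(self)
        for key in ("native_box", "invaded_box"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class AnalysisReport:
    niche: dict
    sdm: dict
    profile: dict
    provenance: dict

    def as_dict(self) -> dict:
        return {
            "niche": self.niche,
            "sdm": self.sdm,
            "profile": self.profile,
            "provenance": self.provenance,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, default=float)


def _full_box(stack: ClimateStack) -> tuple[float, float, float, float]:
    west, south, east, north = stack.geometry.bounds
    return (west, east, south, north)


def _load_inputs(cfg: AnalysisConfig):
    """Resolve the two regions' stacks and raw occurrence sets."""
    if cfg.native_rasters or cfg.invaded_rasters:
        if not (cfg.native_rasters and cfg.invaded_rasters
                and cfg.native_occurrences and cfg.invaded_occurrences):
            raise ValueError(
                "user-data mode needs rasters and occurrence CSVs for both regions"
            )
        stack_nat = load_stack(cfg.native_rasters)
        stack_inv = load_stack(cfg.invaded_rasters)
        occ_nat = OccurrenceSet.from_csv(cfg.native_occurrences, region_id="native")
        occ_inv = OccurrenceSet.from_csv(cfg.invaded_occurrences, region_id="invaded")
        truth = None
    else:
        ln, li = default_landscape_pair(
            cfg.seed, n_rows=cfg.landscape_rows, n_cols=cfg.landscape_cols
        )
        sp = default_species(cfg.seed)
        breadth = sp.niche_breadth[0]
        if cfg.scenario == "conserved":
            scen = ScenarioSpec("conserved")
        elif cfg.scenario == "unfilled":
            scen = ScenarioSpec("unfilled", truncation_quantile=cfg.truncation_quantile)
        elif cfg.scenario == "expanded":
            shift = [0.0] * 4
            shift[0] = cfg.shift_breadths * breadth
            scen = ScenarioSpec("expanded", shift=tuple(shift))
        else:
            raise ValueError(f"unknown scenario {cfg.scenario!r}")
        pair = make_scenario_pair(ln, li, sp, scen, cfg.n_occurrences, cfg.n_occurrences)
        stack_nat, stack_inv = pair.stack_native, pair.stack_invaded
        occ_nat, occ_inv = pair.occ_native, pair.occ_invaded
        truth = {
            "scenario": cfg.scenario,
            "species_native_center": list(pair.species_native.niche_center),
            "species_invaded_center": list(pair.species_invaded.niche_center),
        }
    return stack_nat, stack_inv, occ_nat, occ_inv, truth


def run(cfg: AnalysisConfig, outdir: str | Path | None = None) -> AnalysisReport:
    """Execute the full workflow and return (and optionally write) the report."""
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage=load config=%s seed=%d", cfg.digest(), cfg.seed)
    stack_nat, stack_inv, occ_nat_raw, occ_inv_raw, truth = _load_inputs(cfg)

    # occurrence filtering (cell dedup, nodata, optional year cutoff)
    occ_nat, rep_nat = filter_occurrences(occ_nat_raw, stack_nat, min_year=cfg.min_year)
    occ_inv, rep_inv = filter_occurrences(occ_inv_raw, stack_inv, min_year=cfg.min_year)
    log.info("stage=filter native=%d->%d invaded=%d->%d",
             rep_nat.n_input, rep_nat.n_kept, rep_inv.n_input, rep_inv.n_kept)

    # backgrounds
    box_nat = cfg.native_box or _full_box(stack_nat)
    box_inv = cfg.invaded_box or _full_box(stack_inv)
    bg_nat = sample_background(
        box_nat, stack_nat, cfg.n_background, derive_seed(cfg.seed, "bg-native")
    )
    bg_inv = sample_background(
        box_inv, stack_inv, cfg.n_background, derive_seed(cfg.seed, "bg-invaded")
    )

    # correlated-variable screening on the native background, applied to both
    pruned_nat, prune_rep = prune_correlated(stack_nat, bg_nat, r_max=cfg.r_max)
    kept = pruned_nat.layer_names
    stack_nat, stack_inv = stack_nat.subset(kept), stack_inv.subset(kept)
    log.info("stage=prune kept=%s dropped=%s", kept, [d[1] for d in prune_rep.dropped])

    # common PCA space and niche grids
    pca = fit_pca(stack_nat, stack_inv, bg_nat, bg_inv)
    grid_nat = build_niche_grid(pca, stack_nat, bg_nat, occ_nat, R=cfg.R)
    grid_inv = build_niche_grid(pca, stack_inv, bg_inv, occ_inv, R=cfg.R)
    dyn = compare_niches(
        grid_nat, grid_inv,
        envelope=cfg.envelope,
        n_reps=cfg.n_reps_similarity,
        seed=derive_seed(cfg.seed, "similarity"),
    )
    log.info("stage=niche %s", dyn.summary())

    # reciprocal SDMs, replicate-averaged, projected onto the invaded region
    ev_nat = evaluate(
        stack_nat, bg_nat, occ_nat, beta=cfg.beta,
        train_fraction=cfg.train_fraction, n_replicates=cfg.sdm_replicates,
        seed=derive_seed(cfg.seed, "sdm-native"),
    )
    ev_inv = evaluate(
        stack_inv, bg_inv, occ_inv, beta=cfg.beta,
        train_fraction=cfg.train_fraction, n_replicates=cfg.sdm_replicates,
        seed=derive_seed(cfg.seed, "sdm-invaded"),
    )
    proj_nat = project_mean(ev_nat.models, stack_inv)
    proj_inv = project_mean(ev_inv.models, stack_inv)

    def _presence_scores(models, stack, occ):
        env = stack.env_at_points(occ.lon, occ.lat)
        return np.mean([m.suitability(env) for m in models], axis=0)

    thr_nat = threshold_at_percentile(
        _presence_scores(ev_nat.models, stack_nat, occ_nat), cfg.percentile
    )
    thr_inv = threshold_at_percentile(
        _presence_scores(ev_inv.models, stack_inv, occ_inv), cfg.percentile
    )
    ranges = compare_binary_ranges(proj_inv, proj_nat, thr_inv, thr_nat)
    log.info("stage=sdm auc_test(nat)=%.3f auc_test(inv)=%.3f incl(inv in nat)=%.3f",
             ev_nat.auc_test, ev_inv.auc_test, ranges.frac_1_in_2)

    # occupancy profiles along a covariate of the invaded region
    cov_name = cfg.profile_covariate or kept[0]
    covariate = stack_inv.layers[cov_name]
    prof_nat = occupancy_profile(proj_nat, covariate, bin_width=cfg.bin_width,
                                 source="native-trained")
    prof_inv = occupancy_profile(proj_inv, covariate, bin_width=cfg.bin_width,
                                 source="invaded-trained")
    ks, ks_p = compare_profiles(prof_nat, prof_inv)
    log.info("stage=profile wmean(nat)=%.1f wmean(inv)=%.1f ks=%.3f",
             prof_nat.weighted_mean, prof_inv.weighted_mean, ks)

    report = AnalysisReport(
        niche={
            **dyn.as_dict(),
            "pca_explained_axis1": float(pca.explained_variance_fraction[0]),
            "pca_explained_axis2": float(pca.explained_variance_fraction[1]),
        },
        sdm={
            "auc_train_native": ev_nat.auc_train,
            "auc_test_native": ev_nat.auc_test,
            "auc_train_invaded": ev_inv.auc_train,
            "auc_test_invaded": ev_inv.auc_test,
            "threshold_native": thr_nat,
            "threshold_invaded": thr_inv,
            "area_invaded_trained_km2": ranges.area_map1_km2,
            "area_native_trained_km2": ranges.area_map2_km2,
            "frac_invaded_range_in_native": ranges.frac_1_in_2,
            "frac_native_range_in_invaded": ranges.frac_2_in_1,
            "area_only_invaded_km2": ranges.area_only1_km2,
            "area_only_native_km2": ranges.area_only2_km2,
            "area_both_km2": ranges.area_both_km2,
        },
        profile={
            "covariate": cov_name,
            "weighted_mean_native_trained": prof_nat.weighted_mean,
            "weighted_mean_invaded_trained": prof_inv.weighted_mean,
            "ks_stat": ks,
            "ks_p_advisory": ks_p,
        },
        provenance={
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "version": __version__,
            "filter_native": asdict(rep_nat),
            "filter_invaded": asdict(rep_inv),
            "pruned_layers": [d[1] for d in prune_rep.dropped],
            "ground_truth": truth,
        },
    )
    if outdir is not None:
        report.write(outdir / "report.json")
        cfg.to_yaml(outdir / "config.yaml")
        prof_nat.to_frame().to_csv(outdir / "profile_native_trained.csv", index=False)
        prof_inv.to_frame().to_csv(outdir / "profile_invaded_trained.csv", index=False)
        with open(outdir / "pruning.json", "w") as fh:
            json.dump(
                {"dropped": prune_rep.dropped, "degenerate": prune_rep.degenerate,
                 "max_abs_r_after": prune_rep.max_abs_r_after},
                fh, indent=2, default=float,
            )
    return report
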