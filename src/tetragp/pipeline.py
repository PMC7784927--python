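"""Config-driven orchestration of the factorial resampling study.

Runs the four experiments — marker density, probe density x depth,
sequencing depth, and training-set size/composition x depth — over a fixed
set of test individuals per replicate, scoring every scenario by predictive
ability and MSE (plus accuracy against true genetic values in synthetic
mode).  Results are a tidy table, one row per scenario x replicate x trait;
failed cells are recorded and never abort the grid; completed cells are
skipped on re-run when an output directory is given.

Factor crossing mirrors the study design: marker-density and training-size
analyses run at the benchmark depth by default, the probe analysis may be
crossed with every depth scenario, and the training analyses with a subset
of depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import designs, depthsim, evalstats, gblup, genotypes, simpop
from .data import MarkerMap, ReadCountMatrix, child_seed

logger = logging.getLogger(__name__)

__all__ = [
    "ChainSettings",
    "StudyData",
    "ScenarioGrid",
    "DemoScale",
    "trait_presets",
    "simulate_study",
    "run_grid",
    "summarize_tukey",
    "run_demo",
]


@dataclass(frozen=True)
class ChainSettings:
    """Gibbs chain settings.  The desk-scale default is deliberately short;
    ``paper_chains()`` returns the study's full settings."""

    n_iter: int = 2000
    burn_in: int = 500
    thin: int = 5

    @staticmethod
    def paper_chains() -> "ChainSettings":
        return ChainSettings(n_iter=35_000, burn_in=5_000, thin=5)


@dataclass
class StudyData:
    """Inputs of one study: benchmark read counts, marker map, adjusted
    phenotypes per trait, and (synthetic mode) pedigree and truth."""

    rc: ReadCountMatrix
    marker_map: MarkerMap
    phenotypes: dict  # trait -> pd.Series of LSMeans indexed by individual
    benchmark_depth: float = 60.0
    pedigree: simpop.Pedigree | None = None
    truth: dict | None = None  # trait -> pd.Series of true genetic values

    @property
    def individual_ids(self) -> np.ndarray:
        return self.rc.individual_ids

    @property
    def traits(self) -> list:
        return list(self.phenotypes)


@dataclass(frozen=True)
class ScenarioGrid:
    """Factor levels and crossing rules of the factorial."""

    marker_sizes: tuple = designs.DEFAULT_MARKER_SIZES
    probe_counts: tuple = designs.DEFAULT_NPROBES
    depth_targets: tuple = depthsim.DEFAULT_DEPTH_TARGETS
    probe_depths: tuple | None = None  # None -> depth_targets + benchmark
    train_sizes: tuple = designs.DEFAULT_TRAIN_SIZES
    family_levels: tuple = designs.DEFAULT_FAMILY_LEVELS
    training_depths: tuple = (6.0, 12.0, 24.0, 60.0)
    min_depth: int = 2
    n_replicates: int = 5
    test_size: int = 200
    min_family_size: int = 10
    master_seed: int = 0
    experiments: tuple = ("markers", "probes", "depth", "training")


def trait_presets(n_markers: int) -> dict:
    """Three additive trait architectures of decreasing marker effect size,
    emulating traits under oligogenic to highly polygenic control."""
    return {
        "oligogenic": simpop.TraitArchitecture(
            n_qtl=min(50, n_markers), h2=0.6, year_effects=(0.0, 0.5)
        ),
        "polygenic": simpop.TraitArchitecture(
            n_qtl=min(500, n_markers), h2=0.5, year_effects=(0.0, 0.5)
        ),
        "highly_polygenic": simpop.TraitArchitecture(
            n_qtl=min(5000, n_markers), h2=0.35, year_effects=(0.0, 0.5)
        ),
    }


def simulate_study(
    n_founders: int = 40,
    n_families: int = 30,
    family_size: int = 12,
    n_chrom: int = 12,
    markers_per_chrom: int = 100,
    markers_per_probe: int = 18,
    mean_depth: float = 60.0,
    min_depth: int = 2,
    error_rate: float = 0.001,
    maf_range: tuple = (0.1, 0.5),
    ld_rho: float = 0.5,
    family_size_cv: float = 0.4,
    traits: dict | None = None,
    years: tuple = (2014, 2015),
    seed: int = 0,
) -> StudyData:
    """Simulate a complete synthetic study: map, founders, biparental
    families, phenotypes over two seasons (adjusted to LSMeans), and
    benchmark-depth read counts."""
    mm = simpop.simulate_marker_map(
        n_chrom=n_chrom,
        markers_per_chrom=markers_per_chrom,
        markers_per_probe=markers_per_probe,
        seed=child_seed(seed, 0),
    )
    founders = simpop.simulate_founders(
        n_founders, mm, maf_range=maf_range, ld_rho=ld_rho, seed=child_seed(seed, 1)
    )
    plan = simpop.random_cross_plan(
        founders.founder_ids, n_families, family_size,
        size_cv=family_size_cv, seed=child_seed(seed, 2),
    )
    ped, dosages, _ = simpop.simulate_crosses(founders, plan, mm, seed=child_seed(seed, 3))
    rc = simpop.simulate_read_counts(
        dosages,
        ped.individual_id,
        mm.marker_id,
        mean_depth=mean_depth,
        min_depth=min_depth,
        error_rate=error_rate,
        seed=child_seed(seed, 4),
    )
    if traits is None:
        traits = trait_presets(mm.n_markers)
    phenos, truth = {}, {}
    for t_idx, (name, arch) in enumerate(traits.items()):
        records, tv = simpop.simulate_phenotypes(
            dosages, ped.individual_id, mm.marker_id, arch,
            years=years, seed=child_seed(seed, 5, t_idx),
        )
        phenos[name] = genotypes.lsmeans(records)
        truth[name] = tv.as_series()
    return StudyData(
        rc=rc, marker_map=mm, phenotypes=phenos,
        benchmark_depth=mean_depth, pedigree=ped, truth=truth,
    )


_RESULT_COLUMNS = [
    "experiment", "scenario", "level", "depth", "composition", "replicate",
    "trait", "n_markers", "n_train", "predictive_ability", "mse",
    "accuracy", "pc1", "status",
]


def _evaluate_cell(
    data: StudyData,
    marker_ids,
    depth: float,
    train_ids,
    test_ids,
    trait: str,
    chains: ChainSettings,
    seed: int,
) -> dict:
    rc = data.rc.subset(markers=marker_ids) if marker_ids is not None else data.rc
    if depth is not None and depth != data.benchmark_depth:
        rc = depthsim.downsample(
            rc, depthsim.DepthScenario(depth, seed=child_seed(seed, 9))
        )
    m = genotypes.ratio_genotypes(rc)
    G = gblup.build_g(m)
    y = data.phenotypes[trait]
    fit = gblup.fit_gibbs(
        y, G, train_ids,
        n_iter=chains.n_iter, burn_in=chains.burn_in, thin=chains.thin,
        seed=child_seed(seed, 10),
    )
    pred = gblup.predict(fit, list(test_ids))
    obs = y.reindex(list(test_ids))
    out = {
        "n_markers": rc.n_markers,
        "n_train": len(train_ids),
        "predictive_ability": evalstats.predictive_ability(pred.to_numpy(), obs.to_numpy()),
        "mse": evalstats.mse(pred.to_numpy(), obs.to_numpy()),
        "pc1": float(evalstats.pc_variance_explained(G, 1)[0]),
        "accuracy": np.nan,
    }
    if data.truth is not None and trait in data.truth:
        g_true = data.truth[trait].reindex(list(test_ids)).to_numpy()
        out["accuracy"] = evalstats.predictive_ability(pred.to_numpy(), g_true)
    return out


def run_grid(
    data: StudyData,
    grid: ScenarioGrid,
    chains: ChainSettings = ChainSettings(),
    out_dir=None,
    resume: bool = True,
) -> pd.DataFrame:
    """Execute the requested experiments and return the tidy results table.

    Within a replicate index every scenario of every factor shares the same
    test set.  Infeasible or failing cells yield a row with status='failed'.
    If ``out_dir`` is given, results are written to results.tsv there and
    previously completed cells are skipped on re-run.
    """
    out_path = None
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        out_path = Path(out_dir) / "results.tsv"
    done: set = set()
    rows: list = []
    if out_path is not None and out_path.exists() and resume:
        prev = pd.read_csv(out_path, sep="\t").fillna({"composition": ""})
        rows = prev.to_dict("records")
        done = {
            (r["experiment"], r["scenario"], r["replicate"], r["trait"])
            for r in rows
        }
        logger.info("resuming: %d completed cells found", len(done))

    ids = list(data.individual_ids)
    test_sets = designs.make_test_sets(
        ids, size=grid.test_size, n_reps=grid.n_replicates, seed=grid.master_seed
    )

    def record(exp, scenario, level, depth, comp, rep, trait, seed, marker_ids, train_ids):
        key = (exp, scenario, rep, trait)
        if key in done:
            return
        row = dict.fromkeys(_RESULT_COLUMNS)
        row.update(
            experiment=exp, scenario=scenario, level=level, depth=depth,
            composition=comp, replicate=rep, trait=trait, status="ok",
        )
        try:
            row.update(
                _evaluate_cell(
                    data, marker_ids, depth, train_ids, test_sets[rep], trait,
                    chains, seed,
                )
            )
        except Exception as e:  # failed cells are flagged, never fatal
            logger.warning("cell %s failed: %s", key, e)
            row["status"] = "failed"
        rows.append(row)
        if out_path is not None:
            pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(
                out_path, sep="\t", index=False
            )

    if "markers" in grid.experiments:
        series = designs.sample_marker_series(
            data.marker_map, grid.marker_sizes, grid.n_replicates,
            seed=child_seed(grid.master_seed, 100),
        )
        for rep in range(grid.n_replicates):
            pool = np.setdiff1d(np.array(ids, dtype=object), test_sets[rep])
            for s_idx, size in enumerate(grid.marker_sizes):
                for trait in data.traits:
                    record(
                        "markers", f"markers={size}", size, data.benchmark_depth,
                        "", rep, trait,
                        child_seed(grid.master_seed, 101, s_idx, rep),
                        series[rep].markers(size), pool,
                    )

    if "probes" in grid.experiments:
        probe_depths = grid.probe_depths
        if probe_depths is None:
            probe_depths = tuple(grid.depth_targets) + (data.benchmark_depth,)
        pseries = designs.sample_probe_series(
            data.marker_map, grid.probe_counts, grid.n_replicates,
            seed=child_seed(grid.master_seed, 200),
        )
        for rep in range(grid.n_replicates):
            pool = np.setdiff1d(np.array(ids, dtype=object), test_sets[rep])
            for p_idx, nprobe in enumerate(grid.probe_counts):
                for d_idx, depth in enumerate(probe_depths):
                    for trait in data.traits:
                        record(
                            "probes", f"nprobe={nprobe},depth={depth:g}",
                            nprobe, depth, "", rep, trait,
                            child_seed(grid.master_seed, 201, p_idx, d_idx, rep),
                            pseries[rep].markers(nprobe), pool,
                        )

    if "depth" in grid.experiments:
        all_depths = tuple(grid.depth_targets) + (data.benchmark_depth,)
        for rep in range(grid.n_replicates):
            pool = np.setdiff1d(np.array(ids, dtype=object), test_sets[rep])
            for d_idx, depth in enumerate(all_depths):
                for trait in data.traits:
                    record(
                        "depth", f"depth={depth:g}", depth, depth, "", rep, trait,
                        child_seed(grid.master_seed, 301, d_idx, rep),
                        None, pool,
                    )

    if "training" in grid.experiments:
        for rep in range(grid.n_replicates):
            pool = np.setdiff1d(np.array(ids, dtype=object), test_sets[rep])
            feasible = tuple(s for s in grid.train_sizes if s <= len(pool))
            rand_series = (
                designs.training_series_random(
                    pool, feasible, seed=child_seed(grid.master_seed, 400, rep)
                )
                if feasible
                else {}
            )
            fam_series = None
            if data.pedigree is not None and grid.family_levels:
                fam_series = designs.training_series_by_family(
                    data.pedigree, pool, grid.family_levels,
                    min_family_size=grid.min_family_size,
                    seed=child_seed(grid.master_seed, 401, rep),
                )
            for d_idx, depth in enumerate(grid.training_depths):
                for s_idx, size in enumerate(grid.train_sizes):
                    for trait in data.traits:
                        record(
                            "training", f"random,n={size},depth={depth:g}",
                            size, depth, "random", rep, trait,
                            child_seed(grid.master_seed, 402, d_idx, s_idx, rep),
                            None, rand_series.get(size),
                        )
                if fam_series is not None:
                    for l_idx, level in enumerate(grid.family_levels):
                        for trait in data.traits:
                            record(
                                "training", f"by_family,k={level},depth={depth:g}",
                                level, depth, "by_family", rep, trait,
                                child_seed(grid.master_seed, 403, d_idx, l_idx, rep),
                                None, fam_series[level],
                            )

    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def summarize_tukey(
    results: pd.DataFrame,
    experiment: str,
    trait: str,
    metric: str = "predictive_ability",
    alpha: float = 0.05,
) -> evalstats.TukeyGrouping:
    """Tukey HSD compact letter display over the scenarios of one experiment
    for one trait, on replicate-level metric values."""
    sub = results[
        (results["experiment"] == experiment)
        & (results["trait"] == trait)
        & (results["status"] == "ok")
    ]
    if sub.empty:
        raise ValueError(f"no results for experiment {experiment!r}, trait {trait!r}")
    return evalstats.tukey_cld(
        pd.DataFrame({"level": sub["scenario"], "value": sub[metric]}), alpha=alpha
    )


@dataclass(frozen=True)
class DemoScale:
    """Problem sizes of the demonstration study.  The default is desk-scale;
    ``study()`` mirrors the real study's dimensions (1804 individuals from
    103+ crosses, ~10k mapped markers at 18 per probe)."""

    n_founders: int = 40
    n_families: int = 30
    family_size: int = 12
    n_chrom: int = 12
    markers_per_chrom: int = 100
    markers_per_probe: int = 18
    mean_depth: float = 60.0
    marker_sizes: tuple = (300, 600, 1200)
    probe_counts: tuple = (12, 24, 48)
    depth_targets: tuple = (6.0, 12.0)
    probe_depths: tuple = (6.0, 60.0)
    train_sizes: tuple = (60, 120, 240)
    family_levels: tuple = (1, 3, 6)
    training_depths: tuple = (6.0, 60.0)
    test_size: int = 60
    n_replicates: int = 3
    n_traits: int = 2
    min_family_size: int = 10

    @staticmethod
    def study() -> "DemoScale":
        return DemoScale(
            n_founders=146, n_families=117, family_size=16, n_chrom=12,
            markers_per_chrom=840, mean_depth=60.0,
            marker_sizes=(500, 1000, 2000, 3000, 5000, 10000),
            probe_counts=(50, 100, 500),
            depth_targets=(2.0, 6.0, 12.0, 24.0, 48.0),
            probe_depths=(2.0, 6.0, 12.0, 24.0, 48.0, 60.0),
            train_sizes=(120, 240, 480, 960, 1560),
            family_levels=(1, 3, 6, 9, 12, 15),
            training_depths=(6.0, 12.0, 24.0, 60.0),
            test_size=200, n_replicates=5, n_traits=3,
        )


def run_demo(
    seed: int = 0,
    out_dir=None,
    scale: DemoScale = DemoScale(),
    chains: ChainSettings = ChainSettings(),
) -> dict:
    """Simulate the preset population and run reduced versions of all four
    experiments; returns {'data', 'results', 'tukey', 'report'} and writes
    results.tsv / tukey tables / report.md when an output directory is given.
    """
    data = simulate_study(
        n_founders=scale.n_founders,
        n_families=scale.n_families,
        family_size=scale.family_size,
        n_chrom=scale.n_chrom,
        markers_per_chrom=scale.markers_per_chrom,
        markers_per_probe=scale.markers_per_probe,
        mean_depth=scale.mean_depth,
        seed=child_seed(seed, 1),
    )
    data.phenotypes = dict(list(data.phenotypes.items())[: scale.n_traits])
    grid = ScenarioGrid(
        marker_sizes=scale.marker_sizes,
        probe_counts=scale.probe_counts,
        depth_targets=scale.depth_targets,
        probe_depths=scale.probe_depths,
        train_sizes=scale.train_sizes,
        family_levels=scale.family_levels,
        training_depths=scale.training_depths,
        test_size=scale.test_size,
        min_family_size=scale.min_family_size,
        n_replicates=scale.n_replicates,
        master_seed=child_seed(seed, 2),
    )
    results = run_grid(data, grid, chains=chains, out_dir=out_dir)
    tukey = {}
    for exp in grid.experiments:
        for trait in data.traits:
            try:
                tukey[(exp, trait)] = summarize_tukey(results, exp, trait)
            except ValueError:
                continue
    report = _render_report(data, grid, results, tukey)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.md").write_text(report)
        for (exp, trait), tg in tukey.items():
            tg.table.to_csv(out / f"tukey_{exp}_{trait}.tsv", sep="\t", index=False)
    return {"data": data, "results": results, "tukey": tukey, "report": report}


_SECTION_TITLES = {
    "markers": "Marker density",
    "probes": "Probe density",
    "depth": "Sequencing depth",
    "training": "Training population size and composition",
}


def _render_report(data, grid, results: pd.DataFrame, tukey: dict) -> str:
    lines = [
        "# Synthetic genomic-prediction optimization report",
        "",
        f"Population: {len(data.individual_ids)} individuals, "
        f"{data.marker_map.n_markers} markers on "
        f"{len(data.marker_map.chromosomes)} chromosomes; "
        f"benchmark depth {data.benchmark_depth:g}X; traits: "
        + ", ".join(data.traits),
        "",
    ]
    n_failed = int((results["status"] == "failed").sum())
    if n_failed:
        lines += [f"**{n_failed} scenario cells failed and were skipped.**", ""]
    for exp in grid.experiments:
        lines += [f"## {_SECTION_TITLES.get(exp, exp)}", ""]
        sub = results[(results["experiment"] == exp) & (results["status"] == "ok")]
        if sub.empty:
            lines += ["(no successful cells)", ""]
            continue
        summary = (
            sub.groupby(["scenario", "trait"])["predictive_ability"]
            .agg(["mean", "std"])
            .round(3)
            .reset_index()
        )
        lines += [summary.to_string(index=False), ""]
        for trait in data.traits:
            tg = tukey.get((exp, trait))
            if tg is not None:
                lines += [
                    f"Tukey groups ({trait}):",
                    tg.table.round(3).to_string(index=False),
                    "",
                ]
    return "\n".join(lines)
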