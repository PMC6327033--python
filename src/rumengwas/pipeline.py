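"""End-to-end orchestration: simulate/load -> normalize -> filter -> IG ->
metaGWAS -> cluster support -> cross-population prediction -> random-contig null.

A run is driven by a :class:`core_io.PipelineConfig` (plus an optional
:class:`simulate.SimulationConfig` when inputs are synthetic) and produces a
:class:`RunManifest` recording the config snapshot, the per-stage feature
funnel (post-prevalence -> post-IG -> post-alpha counts, which must be
non-increasing), every derived seed, and the headline results.  All randomness
descends from a single root seed through named per-stage streams
(``SeedSequence(root).spawn``), so any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import association, cluster, core_io, infogain, prediction, simulate

logger = logging.getLogger("rumengwas")

#: order of the named per-stage random streams derived from the root seed
STAGE_SEEDS = ("simulate", "bootstrap", "lambda_cv", "null")


def derive_stage_seeds(root_seed: int) -> dict:
    """Named per-stage seeds spawned from the root seed (below 2**31)."""
    children = np.random.SeedSequence(root_seed).spawn(len(STAGE_SEEDS))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(STAGE_SEEDS, children)}


@dataclass
class RunManifest:
    """Everything needed to reproduce a run, plus the stage funnel and results."""

    config: dict
    seeds: dict
    n_samples: int = 0
    n_features_input: int = 0
    n_features_prevalence: int = 0
    n_features_ig: int = 0
    n_features_significant: int = 0
    results: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def validate_funnel(self) -> None:
        funnel = (self.n_features_input, self.n_features_prevalence,
                  self.n_features_ig, self.n_features_significant)
        if any(a < b for a, b in zip(funnel, funnel[1:])):
            raise core_io.DataError(f"feature funnel must be non-increasing, got {funnel}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass
class PipelineResult:
    manifest: RunManifest
    infogain_table: object
    association_table: object
    dendrogram: object
    accuracy_report: object
    model: object
    null: object


def run_pipeline(cfg: core_io.PipelineConfig,
                 sim_cfg: simulate.SimulationConfig | None = None,
                 boot_scales=cluster.DEFAULT_SCALES,
                 n_boot_per_scale: int | None = None,
                 null_subset_size: int | None = None,
                 out_dir: str | Path | None = None,
                 trait: str = "fe") -> PipelineResult:
    """Run the full analysis on synthetic cohorts and return all stage outputs.

    ``trait`` selects the phenotype the groups, metaGWAS and prediction use
    (``fe`` or ``dmi``).  When ``out_dir`` is given, every stage table plus the
    manifest is written there.
    """
    seeds = derive_stage_seeds(cfg.rng_seed)
    if sim_cfg is None:
        sim_cfg = simulate.SimulationConfig(rng_seed=seeds["simulate"])
    (ref_m, ref_p), (val_m, val_p), truth = simulate.simulate_cohorts(sim_cfg)

    manifest = RunManifest(
        config={**dataclasses.asdict(cfg), "trait": trait,
                "simulation": dataclasses.asdict(sim_cfg)},
        seeds=seeds,
        n_samples=ref_m.n_samples,
        n_features_input=ref_m.n_features,
    )

    # phenotype derivation and extreme-group assignment
    ref_p = core_io.derive_fe(ref_p)
    ref_p = core_io.derive_rfi(ref_p)
    val_p = core_io.derive_fe(val_p)
    ref_p = core_io.assign_groups(ref_p, trait, n_per_tail=len(ref_p) // 2)
    groups = core_io.group_labels(ref_p, ref_m.sample_ids)

    # paper order: quantify -> prevalence filter -> CPM
    filtered, dropped = core_io.prevalence_filter(ref_m, cfg.min_prevalence_count)
    manifest.n_features_prevalence = filtered.n_features
    cpm = core_io.cpm_normalize(filtered)

    ig_tab = infogain.information_gain_table(cpm, groups)
    ig_tab = infogain.select_top_percentile(ig_tab, cfg.ig_percentile)
    selected = infogain.selected_features(ig_tab)
    manifest.n_features_ig = len(selected)

    assoc = association.metagwas(cpm.restrict(selected), groups, alpha=cfg.alpha)
    sig = association.significant_features(assoc)
    manifest.n_features_significant = len(sig)
    manifest.validate_funnel()
    if not sig:
        raise core_io.DataError("no significant contigs at the configured alpha")

    # clustering with multiscale-bootstrap support
    b = n_boot_per_scale if n_boot_per_scale is not None else cfg.n_boot_per_scale
    dendro = cluster.multiscale_bootstrap(cluster.log2_cpm(cpm.restrict(sig)),
                                          scales=boot_scales,
                                          b_per_scale=b, seed=seeds["bootstrap"])
    report = cluster.cluster_accuracy(dendro, ref_p.data["group"], k=2)

    # cross-population prediction on the significant contigs
    val_filtered = core_io.AbundanceMatrix(
        val_m.data.loc[:, [f for f in filtered.feature_ids if f in val_m.data.columns]],
        unit="counts")
    val_cpm = core_io.cpm_normalize(val_filtered)
    y = ref_p.data.loc[cpm.sample_ids, trait].to_numpy(dtype=float)
    yval = val_p.data.loc[val_cpm.sample_ids, trait].to_numpy(dtype=float)
    # log2(CPM+1) predictors: like the clustering stage, the linear scale is
    # dominated by high-abundance contigs and fragile to the cross-population
    # baseline shift, which is multiplicative on CPM but additive on log-CPM
    Xtrain = cluster.log2_cpm(cpm.restrict(sig)).data
    Xval_log = cluster.log2_cpm(val_cpm).data
    lam = prediction.select_lambda(Xtrain, y, strategy=cfg.lambda_strategy,
                                   fixed_value=cfg.lambda_value, seed=seeds["lambda_cv"])
    model = prediction.fit_lasso(Xtrain, y, lam)
    r_obs, _ = prediction.predict_validation(model, Xval_log, yval)

    subset = null_subset_size if null_subset_size is not None else len(sig)
    null = prediction.random_contig_null(
        cluster.log2_cpm(cpm).data, y, Xval_log, yval,
        subset_size=subset, observed=r_obs,
        n_replicates=cfg.n_null_replicates, seed=seeds["null"],
        lambda_strategy=cfg.lambda_strategy, lambda_value=cfg.lambda_value)

    top2 = cluster.top_split_edges(dendro)
    manifest.results = {
        "trait": trait,
        "cluster_accuracy": report.accuracy,
        "top_cluster_au": [float(a) for a in top2["au"]] if "au" in top2.columns else [],
        "validation_pearson_r": r_obs,
        "lambda": lam,
        "n_active_coefficients": model.n_active,
        "null": null.summary(),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        core_io.write_abundance_tsv(cpm, out_dir / "reference_cpm.tsv")
        core_io.write_phenotypes_csv(ref_p, out_dir / "reference_phenotypes.csv")
        infogain.write_infogain_tsv(ig_tab, out_dir / "infogain.tsv")
        association.write_association_tsv(assoc, out_dir / "metagwas.tsv")
        cluster.write_edges_tsv(dendro, out_dir / "cluster_edges.tsv")
        (out_dir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        prediction.write_model_tsv(model, out_dir / "lasso_model.tsv")
        prediction.write_null_tsv(null, out_dir / "null_distribution.tsv")
        manifest.outputs = sorted(p.name for p in out_dir.iterdir())
        (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")

    return PipelineResult(manifest=manifest, infogain_table=ig_tab,
                          association_table=assoc, dendrogram=dendro,
                          accuracy_report=report, model=model, null=null)
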