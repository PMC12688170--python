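"""End-to-end workflow orchestration with one config and full provenance.

Stages (simulate/ingest → features → cluster → signatures → ntp → tme →
cimp → mutsig → survival) run in dependency order; every intermediate is
written in the package's text formats and the run ends with a
machine-readable JSON report that is reproducible byte-for-byte for a
fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    clinical_stats,
    consensus_subtyping,
    core_io,
    feature_selection,
    methylome_cimp,
    mutsig_fitting,
    ntp_classifier,
    subtype_signatures,
    synthetic_cohort,
    tme_scoring,
)
from .core_io import CohortError, GeneSetCollection

logger = logging.getLogger("leukotype")

DEFAULT_STAGES = (
    "features", "cluster", "signatures", "ntp", "tme", "cimp", "mutsig", "survival",
)


class PipelineConfig:
    """Resolved pipeline configuration (YAML block per stage)."""

    def __init__(self, raw: dict):
        self.raw = dict(raw)
        self.seed = int(raw.get("seed", 0))
        self.out_dir = Path(raw.get("out_dir", "leukotype_run"))
        self.stages = tuple(raw.get("stages", DEFAULT_STAGES))
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise CohortError(f"unknown stages: {sorted(unknown)}")
        self.simulate = raw.get("simulate")
        self.inputs = raw.get("inputs", {})
        if self.simulate is None and "expression" not in self.inputs:
            raise CohortError("config needs either a simulate block or inputs.expression")
        self.params = {
            "features": {"n_per_class": 1000, "min_rate": 0.03},
            "cluster": {"k_min": 2, "k_max": 5, "algorithms": list(
                consensus_subtyping.DEFAULT_ALGORITHMS), "gap_b": 20},
            "signatures": {"top_n": 50, "adj_p_max": 0.05},
            "ntp": {"n_null": 1000, "fdr_max": 0.05},
            "tme": {},
            "cimp": {"normal_beta_max": 0.9, "tumor_sd_min": 0.25},
            "mutsig": {"min_weight": 0.06},
            "survival": {"endpoint": "os"},
        }
        for stage, overrides in raw.get("params", {}).items():
            if stage not in self.params:
                raise CohortError(f"unknown parameter block: {stage}")
            self.params[stage].update(overrides)
        # fail fast on stage/input mismatches before any work happens
        if "cimp" in self.stages and self.simulate is None and \
                "beta" not in self.inputs:
            raise CohortError("cimp stage enabled but no β matrix configured")
        if "mutsig" in self.stages and self.simulate is None and \
                "mutations" not in self.inputs:
            raise CohortError("mutsig stage enabled but no mutation file configured")
        if "survival" in self.stages and self.simulate is None and \
                "clinical" not in self.inputs:
            raise CohortError("survival stage enabled but no clinical table configured")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def _sim_config(block: dict | None, seed: int) -> synthetic_cohort.SimConfig:
    block = dict(block or {})
    block.setdefault("seed", seed)
    field_names = {f.name for f in dataclasses.fields(synthetic_cohort.SimConfig)}
    unknown = set(block) - field_names
    if unknown:
        raise CohortError(f"unknown simulate parameters: {sorted(unknown)}")
    for tup in ("mixing_proportions", "cimp_positive_subtypes", "hazards",
                "beta_hyper", "beta_hypo", "beta_background", "beta_normal_high"):
        if tup in block and isinstance(block[tup], list):
            block[tup] = tuple(block[tup])
    return synthetic_cohort.SimConfig(**block)


def _load_cohort(config: PipelineConfig):
    """Simulate or ingest; returns (cohort, normals, annot, truth_or_none)."""
    if config.simulate is not None:
        sim = _sim_config(config.simulate, config.seed)
        cohort, truth = synthetic_cohort.simulate_cohort(sim)
        normals = synthetic_cohort.simulate_normals(
            sim.n_normal_methylation_samples, sim
        )
        annot = synthetic_cohort.probe_annotation(sim)
        return cohort, normals, annot, truth
    inputs = config.inputs
    expr = core_io.read_expression(
        inputs["expression"], gene_class_path=inputs.get("gene_class")
    )
    mutations = (
        core_io.read_mutations(inputs["mutations"])
        if "mutations" in inputs else None
    )
    methylation = normals = annot = None
    if "beta" in inputs:
        meth_all = core_io.read_beta_matrix(inputs["beta"], inputs["groups"])
        tumor = meth_all.tumor_samples()
        normal = meth_all.normal_samples()
        methylation = core_io.MethylationMatrix(
            meth_all.beta[tumor], meth_all.sample_group[tumor]
        )
        if normal:
            normals = core_io.MethylationMatrix(
                meth_all.beta[normal], meth_all.sample_group[normal]
            )
        annot = core_io.read_probe_annotation(inputs["probe_annotation"])
    clinical = (
        core_io.read_clinical(inputs["clinical"]) if "clinical" in inputs else None
    )
    cohort = core_io.assemble_cohort(expr, mutations, methylation, clinical)
    return cohort, normals, annot, None


def _subtype_groups(labels: np.ndarray, values: np.ndarray) -> dict[str, float]:
    return {
        str(c): float(np.median(values[labels == c])) for c in np.unique(labels)
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the run report (also written to
    ``out_dir/report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.raw, sort_keys=True))
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    stage = "load"
    try:
        t0 = time.monotonic()
        cohort, normals, annot, truth = _load_cohort(config)
        logger.info("stage load: %.1fs", time.monotonic() - t0)
        core_io.write_expression(cohort.expression, out / "expression.tsv")
        if truth is not None:
            pd.Series(
                truth, index=cohort.sample_ids, name="true_subtype"
            ).to_csv(out / "true_labels.tsv", sep="\t", index_label="sample_id")

        feature_matrix = None
        labels = None
        signature = None

        if "features" in config.stages:
            stage = "features"
            p = config.params["features"]
            expr_fs = feature_selection.select_top_mad(
                cohort.expression, n_per_class=p["n_per_class"]
            )
            mut_fs = None
            if cohort.mutations is not None and len(cohort.mutations.records):
                mut_fs = feature_selection.filter_mutation_prevalence(
                    cohort.mutations, cohort.sample_ids, min_rate=p["min_rate"]
                )
            feature_matrix = feature_selection.build_feature_matrix(
                cohort.expression, expr_fs, mut_fs
            )
            fs_frame = expr_fs.to_frame()
            if mut_fs is not None:
                fs_frame = pd.concat([fs_frame, mut_fs.to_frame()])
            fs_frame.to_csv(out / "features.tsv", sep="\t", index=False)
            report["features"] = {
                "n_expression": len(expr_fs.all_expression_genes()),
                "n_mutation": 0 if mut_fs is None else len(mut_fs.mutation_genes),
            }

        if "cluster" in config.stages:
            stage = "cluster"
            if feature_matrix is None:
                raise CohortError("cluster stage requires the features stage")
            p = config.params["cluster"]
            model = consensus_subtyping.fit_subtypes(
                feature_matrix,
                k_range=range(p["k_min"], p["k_max"] + 1),
                algorithms=tuple(p["algorithms"]),
                gap_B=p["gap_b"],
                seed=config.seed,
            )
            labels = model.labels
            pd.Series(labels, index=model.sample_ids, name="subtype").to_csv(
                out / "subtype_labels.tsv", sep="\t", index_label="sample_id"
            )
            pd.DataFrame(
                model.consensus.M, index=model.sample_ids, columns=model.sample_ids
            ).to_csv(out / "consensus_matrix.tsv", sep="\t", index_label="sample_id")
            curves = model.gap_curve.copy()
            curves["cpi"] = model.cpi_curve
            curves.to_csv(out / "k_selection.tsv", sep="\t", index_label="k")
            (out / "subtype_model.json").write_text(
                json.dumps(model.to_dict(), indent=2, sort_keys=True)
            )
            report["cluster"] = {
                "k": model.k,
                "silhouette_mean": model.silhouette_mean,
                "silhouette_per_cluster": model.silhouette_per_cluster,
            }
            if truth is not None:
                from sklearn.metrics import adjusted_rand_score
                report["cluster"]["ari_vs_truth"] = float(
                    adjusted_rand_score(truth, labels)
                )

        if "signatures" in config.stages:
            stage = "signatures"
            if labels is None:
                raise CohortError("signatures stage requires the cluster stage")
            p = config.params["signatures"]
            de_tables = {
                s: subtype_signatures.de_one_vs_rest(cohort.expression, labels, s)
                for s in np.unique(labels)
            }
            signature = subtype_signatures.derive_signature(
                de_tables, top_n=p["top_n"], adj_p_max=p["adj_p_max"]
            )
            signature.to_frame().to_csv(out / "signature.tsv", sep="\t", index=False)
            report["signatures"] = {
                "sizes": {int(s): len(signature.genes(s)) for s in signature.markers},
                "total_genes": len(signature.all_genes()),
            }

        if "ntp" in config.stages:
            stage = "ntp"
            if signature is None:
                raise CohortError("ntp stage requires the signatures stage")
            p = config.params["ntp"]
            templates = ntp_classifier.build_templates(signature)
            ntp_res = ntp_classifier.ntp_classify(
                cohort.expression, templates,
                n_null=p["n_null"], seed=config.seed, fdr_max=p["fdr_max"],
            )
            ntp_res.to_csv(out / "ntp_assignments.tsv", sep="\t")
            agreement = float(
                (ntp_res["subtype"].to_numpy() == labels).mean()
            )
            report["ntp"] = {
                "self_agreement": agreement,
                "n_confident": int(ntp_res["confident"].sum()),
            }

        if "tme" in config.stages:
            stage = "tme"
            markers = config.inputs.get("tme_markers")
            if markers is not None:
                marker_sets = core_io.read_gmt(markers)
            elif config.simulate is not None:
                marker_sets = GeneSetCollection({
                    name: ("synthetic markers", genes)
                    for name, genes in synthetic_cohort.TME_MARKER_GENES.items()
                })
            else:
                marker_sets = tme_scoring.default_population_markers()
            profile = tme_scoring.population_abundance(cohort.expression, marker_sets)
            measured = set(cohort.expression.gene_ids)
            orient = tme_scoring.default_orientation_sets()
            usable = {
                n: (d, g) for n, d, g in orient.items()
                if set(g) & measured
            }
            if usable:
                profile = pd.concat(
                    [profile, tme_scoring.orientation_profile(
                        cohort.expression, GeneSetCollection(usable))],
                    axis=1,
                )
            profile.to_csv(out / "tme_profile.tsv", sep="\t", index_label="sample_id")
            report["tme"] = {"columns": list(profile.columns)}
            if labels is not None:
                report["tme"]["median_by_subtype"] = {
                    col: _subtype_groups(labels, profile[col].to_numpy())
                    for col in profile.columns
                }

        if "cimp" in config.stages:
            stage = "cimp"
            if cohort.methylation is None or normals is None or annot is None:
                raise CohortError("cimp stage requires tumor+normal β and annotation")
            p = config.params["cimp"]
            combined = core_io.MethylationMatrix(
                pd.concat([cohort.methylation.beta, normals.beta], axis=1),
                pd.concat([cohort.methylation.sample_group, normals.sample_group]),
            )
            probes = methylome_cimp.select_cimp_probes(
                combined, annot,
                normal_beta_max=p["normal_beta_max"],
                tumor_sd_min=p["tumor_sd_min"],
            )
            cimp = methylome_cimp.call_cimp(combined, probes)
            cimp.epi_cluster.to_csv(
                out / "cimp_labels.tsv", sep="\t", index_label="sample_id"
            )
            plus = list(cimp.epi_cluster.index[cimp.epi_cluster == "CIMP+"])
            minus = list(cimp.epi_cluster.index[cimp.epi_cluster == "CIMP-"])
            report["cimp"] = {
                "n_selected_probes": len(probes),
                "n_cimp_pos": len(plus),
                "n_cimp_neg": len(minus),
            }
            if len(plus) >= 3 and len(minus) >= 3:
                dmps = methylome_cimp.call_dmps(
                    combined, plus, minus, annot=annot
                )
                dmps.to_csv(out / "dmps.tsv", sep="\t", index_label="probe_id")
                if len(dmps):
                    region = methylome_cimp.region_distribution(
                        dmps, annot, combined.beta.index
                    )
                    region.to_csv(out / "dmp_regions.tsv", sep="\t", index=False)
                report["cimp"]["n_dmps"] = int(len(dmps))

        if "mutsig" in config.stages:
            stage = "mutsig"
            if cohort.mutations is None:
                raise CohortError("mutsig stage requires mutation records")
            p = config.params["mutsig"]
            counts = mutsig_fitting.count_sbs96(cohort.mutations)
            catalog_path = config.inputs.get("sbs_catalog")
            catalog = (
                mutsig_fitting.load_catalog(catalog_path)
                if catalog_path else mutsig_fitting.toy_catalog()
            )
            exposures = mutsig_fitting.fit_cohort_exposures(
                counts, catalog, min_weight=p["min_weight"]
            )
            exposures.to_csv(out / "exposures.tsv", sep="\t", index_label="sample_id")
            report["mutsig"] = {
                "n_samples": int(len(exposures)),
                "mean_residual": float(exposures["residual"].mean()),
            }

        if "survival" in config.stages:
            stage = "survival"
            if cohort.clinical is None:
                raise CohortError("survival stage requires a clinical table")
            clin = cohort.clinical.table
            endpoint = config.params["survival"]["endpoint"]
            times = clin[f"{endpoint}_time"].to_numpy(float)
            events = clin[f"{endpoint}_event"].to_numpy(bool)
            report["survival"] = {}
            if labels is not None:
                chi2, p_lr = clinical_stats.logrank_test(times, events, labels)
                report["survival"]["logrank_by_subtype"] = {
                    "chi2": chi2, "p": p_lr
                }
                covs = pd.DataFrame(
                    {"age": clin["age"].to_numpy(float),
                     "wbc": clin["wbc"].to_numpy(float)},
                    index=clin.index,
                )
                for c in np.unique(labels)[1:]:
                    covs[f"subtype_{c}"] = (labels == c).astype(float)
                uni = clinical_stats.cox_univariate_table(times, events, covs)
                uni.to_csv(out / "cox_univariate.tsv", sep="\t", index_label="covariate")
                multi = clinical_stats.cox_fit(times, events, covs)
                multi.table.to_csv(
                    out / "cox_multivariate.tsv", sep="\t", index_label="covariate"
                )
                report["survival"]["cox_multivariate_hr"] = {
                    str(i): float(r["hr"]) for i, r in multi.table.iterrows()
                }
    except Exception as err:
        (out / "FAILED").write_text(f"stage {stage} failed: {err}\n")
        raise CohortError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def project_external(
    expr_path,
    signature_path,
    out_dir,
    n_null: int = 1000,
    seed: int = 0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Project an external expression cohort onto a saved signature (NTP),
    then summarize its TME by predicted subtype."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = core_io.read_expression(expr_path)
    if not expr.values.shape[1]:
        raise CohortError("empty expression file")
    sig_frame = pd.read_csv(signature_path, sep="\t")
    signature = subtype_signatures.SignatureSet.from_frame(sig_frame)
    templates = ntp_classifier.build_templates(signature)
    result = ntp_classifier.ntp_classify(
        expr, templates, n_null=n_null, seed=seed, fdr_max=fdr_max
    )
    result.to_csv(out / "ntp_assignments.tsv", sep="\t")
    measured = set(expr.gene_ids)
    markers = tme_scoring.default_population_markers()
    usable = {n: (d, g) for n, d, g in markers.items() if set(g) & measured}
    if usable:
        profile = tme_scoring.population_abundance(
            expr, GeneSetCollection(usable)
        )
        summary = profile.groupby(result["subtype"]).median()
        summary.to_csv(out / "tme_by_subtype.tsv", sep="\t", index_label="subtype")
    return result
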