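"""End-to-end pipeline orchestration and reporting.

``run_pipeline`` executes the full analysis chain on real or synthetic
inputs — depth filter → genus collapse → alpha/beta diversity → PERMANOVA →
ordination axis tests → symptom index → feature selection → covariate
associations → reference-cloud dysbiosis scoring → orthogonal validation →
differential abundance — and writes every stage output plus a JSON run
manifest (input digests, parameters, seed, versions, timing) to the output
directory.  Two runs with identical manifest inputs produce identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

import microdys
from microdys import diversity as div
from microdys import dysbiosis_cloud as cloud
from microdys import differential_power as diff
from microdys import symptom_classifier as sym
from microdys.tables_io import (
    check_tree_taxa,
    collapse_to_rank,
    filter_low_depth,
    read_count_table,
    read_metadata,
    read_tree,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "reference_group": "healthy",
    "min_reads": 1000,
    "rarefy_depth": 5000,
    "beta_metrics": ["braycurtis", "unifrac"],
    "cloud_level": "genus",
    "cloud_k": "all",
    "diff_ranks": ["genus"],
    "n_perm": 1000,
    "n_trees": 500,
    "boruta_max_iter": 50,
    "run_boruta": False,
    "seed": 0,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir) -> Path:
    """Execute the full pipeline; see module docstring for the stage chain.

    ``config`` must name ``counts``, ``metadata``, and optionally ``tree``
    paths plus any overrides of :data:`DEFAULT_CONFIG`.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": microdys.__version__,
        "parameters": {k: v for k, v in cfg.items() if k not in ("counts", "metadata", "tree")},
        "seed": cfg["seed"],
        "inputs": {},
        "outputs": [],
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    seeds = np.random.SeedSequence(cfg["seed"]).spawn(8)
    written: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t")
        written.append(name)

    def stage(name):
        t0 = time.time()

        def done():
            manifest["stages"][name] = round(time.time() - t0, 3)
            logger.info("stage %s done in %.2fs", name, time.time() - t0)

        return done

    try:
        name = "load"
        done = stage(name)
        for key in ("counts", "metadata"):
            if key not in cfg:
                raise ValueError(f"config must name {key!r}")
            manifest["inputs"][key] = {
                "path": str(cfg[key]),
                "sha256": _sha256(Path(cfg[key])),
            }
        table = read_count_table(cfg["counts"])
        metadata = read_metadata(cfg["metadata"])
        tree = None
        if cfg.get("tree"):
            manifest["inputs"]["tree"] = {
                "path": str(cfg["tree"]),
                "sha256": _sha256(Path(cfg["tree"])),
            }
            tree = read_tree(cfg["tree"])
            check_tree_taxa(tree, table.taxon_ids)
        elif "unifrac" in cfg["beta_metrics"]:
            raise ValueError(
                "UniFrac requested but no tree given: pass 'tree' in the config "
                "or drop 'unifrac' from beta_metrics"
            )
        done()

        name = "filter"
        done = stage(name)
        table = filter_low_depth(table, cfg["min_reads"])
        metadata = metadata.loc[table.sample_ids]
        labels = metadata["group"]
        done()

        name = "alpha_diversity"
        done = stage(name)
        genus = collapse_to_rank(table, cfg["cloud_level"]) if table.taxonomy is not None else table
        alpha = div.alpha_diversity_table(
            table, tree=tree, rarefy_depth=cfg["rarefy_depth"], seed=seeds[0]
        )
        emit(alpha, "alpha_diversity.tsv")
        done()

        name = "beta_diversity"
        done = stage(name)
        permanova_rows = []
        ords = {}
        for metric in cfg["beta_metrics"]:
            if metric == "braycurtis":
                dm = div.bray_curtis(table)
            elif metric == "unifrac":
                dm = div.unweighted_unifrac(table, tree)
            else:
                raise ValueError(f"unknown beta metric {metric!r}")
            emit(pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids), f"beta_{metric}.tsv")
            res = div.permanova(dm, labels.loc[list(dm.ids)], n_perm=999, seed=seeds[1])
            permanova_rows.append({"metric": metric, **res})
            ordn = div.pcoa(dm)
            ords[metric] = ordn
            emit(ordn.coordinates, f"pcoa_{metric}.tsv")
            axis_tests = div.axis_group_tests(
                ordn.coordinates.iloc[:, 0], labels.loc[ordn.coordinates.index]
            )
            emit(axis_tests, f"axis_tests_{metric}.tsv")
        emit(pd.DataFrame(permanova_rows).set_index("metric"), "permanova.tsv")
        done()

        name = "symptom_index"
        done = stage(name)
        norm = diff.normalize_counts(table)
        si_res = sym.fit_symptom_index(
            norm, labels, n_trees=cfg["n_trees"], seed=int(seeds[2].generate_state(1)[0] % 2**31)
        )
        emit(si_res.si.to_frame(), "si.tsv")
        (outdir / "auc.json").write_text(
            json.dumps(
                {
                    "auc": si_res.auc,
                    "ci_low": si_res.ci_low,
                    "ci_high": si_res.ci_high,
                    "p_value": si_res.auc_p,
                },
                indent=1,
            )
        )
        written.append("auc.json")
        done()

        if cfg["run_boruta"]:
            name = "boruta"
            done = stage(name)
            sel = sym.boruta_select(
                norm,
                labels,
                max_iter=cfg["boruta_max_iter"],
                seed=int(seeds[3].generate_state(1)[0] % 2**31),
                n_trees=min(cfg["n_trees"], 200),
            )
            emit(sel.status.to_frame("status"), "boruta.tsv")
            done()

        name = "associations"
        done = stage(name)
        assoc = sym.covariate_regression(si_res.si, metadata)
        emit(assoc["table"], "associations.tsv")
        (outdir / "combined_model.json").write_text(
            json.dumps(
                {"r2": assoc["combined_r2"], "covariates": assoc["combined_covariates"]}, indent=1
            )
        )
        written.append("combined_model.json")
        done()

        name = "cloud"
        done = stage(name)
        cres = cloud.cloud_analysis(
            table,
            metadata,
            reference_group=cfg["reference_group"],
            level=cfg["cloud_level"] if table.taxonomy is not None else None,
            k=cfg["cloud_k"],
        )
        emit(cres.samples, "cloud.tsv")
        (outdir / "cloud_threshold.json").write_text(
            json.dumps(
                {
                    "reference_mean": cres.reference_mean,
                    "reference_sd": cres.reference_sd,
                    "threshold": cres.threshold,
                    "k": cres.k_neighbors,
                },
                indent=1,
            )
        )
        written.append("cloud_threshold.json")
        done()

        name = "orthogonal_validation"
        done = stage(name)
        healthy_ids = metadata.index[labels == cfg["reference_group"]]
        oval = cloud.orthogonal_validation(
            si_res.si,
            healthy_ids,
            seed=int(seeds[4].generate_state(1)[0] % 2**31),
            n_trees=cfg["n_trees"],
            features=norm,
        )
        agreement = cloud.agreement_correlation(
            cres.samples["cloud_stat"],
            oval["probability_index"],
            labels_a=cres.samples["classification"],
            labels_b=oval["labels"],
        )
        emit(
            pd.DataFrame(
                {"logit_label": oval["labels"], "probability_index": oval["probability_index"]}
            ),
            "orthogonal_validation.tsv",
        )
        (outdir / "agreement.json").write_text(
            json.dumps(
                {
                    "pearson_r": agreement.pearson_r,
                    "p_value": agreement.p_value,
                    "label_concordance": agreement.label_concordance,
                    "shapiro_p_healthy_logit_si": oval["normality_p"],
                },
                indent=1,
            )
        )
        written.append("agreement.json")
        done()

        name = "differential_abundance"
        done = stage(name)
        da = diff.diff_abundance(
            table, metadata, ranks=cfg["diff_ranks"], n_perm=cfg["n_perm"], seed=seeds[5]
        )
        emit(da, "diff_abundance.tsv")
        done()
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(name, exc) from exc

    manifest["outputs"] = written
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return outdir


def render_report(outdir) -> dict:
    """Summarize pipeline outputs as machine-readable JSON + plain text.

    Missing stage outputs are flagged as gaps rather than failing.
    """
    outdir = Path(outdir)
    report: dict = {"gaps": []}

    def load(name):
        path = outdir / name
        if not path.exists():
            report["gaps"].append(name)
            return None
        return pd.read_csv(path, sep="\t", index_col=0)

    alpha = load("alpha_diversity.tsv")
    cloud_tab = load("cloud.tsv")
    da = load("diff_abundance.tsv")
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        report["seed"] = json.loads(manifest_path.read_text()).get("seed")

    lines = ["microdys pipeline report", "========================"]
    if alpha is not None:
        report["alpha_mean"] = alpha.mean(numeric_only=True).round(4).to_dict()
        lines.append(f"alpha diversity over {len(alpha)} samples (means): {report['alpha_mean']}")
    if cloud_tab is not None:
        counts = cloud_tab["classification"].value_counts().to_dict()
        report["classification_counts"] = counts
        lines.append(f"dysbiosis classification: {counts}")
    if da is not None:
        sig = da[(da["filter_status"] == "tested") & (da["q"] <= 0.05)]
        report["n_significant_taxa"] = int(len(sig))
        report["significant_taxa"] = sig["taxon"].tolist() if "taxon" in sig else []
        lines.append(f"{len(sig)} taxa significant at q <= 0.05")
    if report["gaps"]:
        lines.append(f"missing outputs: {report['gaps']}")
    text = "\n".join(lines) + "\n"
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (outdir / "report.txt").write_text(text)
    return report
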