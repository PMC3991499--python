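"""One-command orchestration: preprocess -> select -> enrich -> network.

A run is described by a plain dict (usually loaded from YAML) and writes
its outputs to a directory: ``selection.tsv``, ``rmsecv_components.tsv``,
``rmsecv_cutoff.tsv``, ``enrichment.tsv`` (when an annotation is given),
``network.sif``/``network.graphml``/``hubs.tsv`` (when interactions are
given), and a machine-readable ``run_summary.json`` recording every
stage's parameters and the selection funnel counts.  A single master
seed fans out to per-stage seeds through a documented derivation so each
stage is independently reproducible.

Config keys::

    seed: 17
    expression: X.tsv         # or: simulate: {n_samples: ..., ...}
    phenotype: cadi.tsv       # required with `expression`
    intersect: false          # allow sample-set mismatch at the join
    quantile_normalize: false
    log2: false               # log2-transform the matrix after loading
    annotation: go.tsv        # optional
    interactions: ppi.tsv     # optional
    hub_threshold: 10
    min_term_size: 1
    selection: {A_max: 10, folds: 4, alpha: 0.05, n_perm: 1000,
                n_subsets: 100, subset_fraction: 0.5, order: default}
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, enrichment, network, preprocess, synthetic_data
from .selection import SelectionParams, derive_seed, run_selection

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("load")
def _load_dataset(config: dict, seed: int) -> tuple[data_io.ExpressionDataset, dict]:
    info: dict = {}
    if "simulate" in config:
        sim_cfg = synthetic_data.SimulationConfig(
            **{**config["simulate"], "seed": derive_seed(seed, "simulate")})
        ds, truth = synthetic_data.simulate_dataset(sim_cfg)
        info["truth"] = truth
        info["n_samples_input"] = ds.n_samples
        info["n_samples_dropped"] = 0
        return ds, info
    if "expression" not in config or "phenotype" not in config:
        raise ValueError("config needs `expression` and `phenotype` paths "
                         "(or a `simulate` block)")
    ds = data_io.read_expression(config["expression"],
                                 transpose=config.get("transpose", False))
    pheno = data_io.read_phenotype(config["phenotype"])
    n_before = ds.n_samples
    ds = data_io.attach_phenotype(ds, pheno,
                                  intersect=config.get("intersect", False))
    info["n_samples_input"] = n_before
    info["n_samples_dropped"] = n_before - ds.n_samples
    return ds, info


@_stage("preprocess")
def _preprocess(ds: data_io.ExpressionDataset, config: dict) -> tuple[
        data_io.ExpressionDataset, dict]:
    info: dict = {}
    values = ds.values
    if config.get("log2", False):
        values = np.log2(values + 1.0)
    if config.get("quantile_normalize", False):
        values = preprocess.quantile_normalize(values)
    ds = data_io.ExpressionDataset(ds.gene_ids, ds.sample_ids, values,
                                   ds.phenotype)
    ds, removed = preprocess.drop_degenerate_genes(ds)
    info["n_degenerate_genes_dropped"] = len(removed)
    return ds, info


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the full analysis described by ``config``; returns the run
    summary (also written to ``run_summary.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    ds, load_info = _load_dataset(config, seed)
    ds, prep_info = _preprocess(ds, config)

    sel_cfg = dict(config.get("selection", {}))
    sel_cfg["seed"] = derive_seed(seed, "selection")
    params = SelectionParams(**sel_cfg)
    try:
        result = run_selection(ds, params)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'selection' failed: {exc}") from exc

    result.to_frame().to_csv(out / "selection.tsv", sep="\t", index=False)
    pd.DataFrame({
        "A": np.arange(1, len(result.rmsecv_components) + 1),
        "rmsecv": result.rmsecv_components,
    }).to_csv(out / "rmsecv_components.tsv", sep="\t", index=False)
    result.rmsecv_cutoff.to_csv(out / "rmsecv_cutoff.tsv", sep="\t",
                                index=False)
    selected = [g for g, s in zip(result.gene_ids, result.selected) if s]

    summary: dict = {
        "n_samples_input": load_info["n_samples_input"],
        "n_samples_dropped": load_info["n_samples_dropped"],
        "n_samples_used": ds.n_samples,
        **prep_info,
        **result.summary(),
        "selected_genes": selected,
        "seed": seed,
    }

    if "truth" in load_info:
        truth = load_info["truth"]
        truth.to_json(out / "truth.json")
        planted = truth.informative_gene_ids
        sel_set = set(selected)
        tp = len(sel_set & planted)
        summary["recovery"] = {
            "n_planted": len(planted),
            "true_positives": tp,
            "sensitivity": tp / len(planted) if planted else None,
            "false_selection_fraction":
                (len(sel_set) - tp) / len(sel_set) if sel_set else 0.0,
        }

    if config.get("annotation"):
        try:
            ann = data_io.read_annotation(config["annotation"])
            table = enrichment.enrich(
                selected, ann, ds.gene_ids,
                min_term_size=config.get("min_term_size", 1))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'enrichment' failed: {exc}") from exc
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary["top_enrichment"] = table.head(5).to_dict(orient="records")

    if config.get("interactions"):
        try:
            ints = data_io.read_interactions(config["interactions"])
            net = network.build_network(
                selected, ints,
                hub_threshold=config.get("hub_threshold", 10))
            network.export_network(net, out / "network.sif", "sif")
            network.export_network(net, out / "network.graphml", "graphml")
            hubs = network.find_hubs(net)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'network' failed: {exc}") from exc
        network.hubs_frame(net).to_csv(out / "hubs.tsv", sep="\t", index=False)
        summary["hubs"] = [{"gene": g, "degree": d} for g, d in hubs]
        summary["network_edges"] = net.n_edges

    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("pipeline finished: %d selected genes, outputs in %s",
                len(selected), out)
    return summary
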