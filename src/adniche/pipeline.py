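"""End-to-end orchestration: chemistry -> abundance -> niche -> screen -> networks.

A single :class:`PipelineConfig` drives the full analysis, either on
files (count table, metadata, ASV FASTA, reference MSA) or on a
simulated experiment.  One global seed is fanned out to every stochastic
stage through a NumPy seed sequence, so a fixed seed gives bit-identical
artifacts and report.  All intermediate tables are written as TSV, trees
as Newick, networks as GraphML, and the run summary as sorted-key JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (
    AsvTable,
    alpha_diversity_table,
    anosim,
    bray_curtis_matrix,
    rarefy,
    read_count_table,
    weight_to_absolute,
    write_count_table,
)
from .chemistry import speciate_metadata
from .errors import AdNicheError, MissingMetadataError
from .hmm import build_profile_hmm
from .network import build_network, components, composition_chisq
from .niche import PAPER_THRESHOLDS, niche_classification
from .phylo import nj_tree, pairwise_distances
from .screen import (
    align_hits_to_matches,
    msa_match_strings,
    read_fasta,
    screen_methanogens,
    write_fasta,
)
from .synthetic import SyntheticConfig, generate_experiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Keys mirror the module defaults."""

    seed: int = 0
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    counts_path: str | None = None
    metadata_path: str | None = None
    sequences_path: str | None = None
    reference_msa_path: str | None = None
    depth: int = 15000
    n_null: int = 999
    alpha: float = 0.05
    top_n: int = 1000
    thresholds: str | None = None  # None -> null-model quantiles; "paper" -> 0.24/0.88
    screen_n_null: int = 200
    screen_quantile: float = 0.99
    network_method: str = "mc"
    n_perm: int = 999
    min_samples: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise AdNicheError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["simulate", "rarefy", "anosim", "niche", "screen", "network"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis; returns the report dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "stage_seeds": seeds,
            "config_hash": config.config_hash(),
            "version": __version__,
        }
    }

    # ---- inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate:
            syn = SyntheticConfig(**{**config.synthetic, "seed": seeds["simulate"]})
            exp = generate_experiment(syn)
            metadata, table = exp.metadata, exp.table
            sequences, ref_msa = exp.sequences, exp.reference_msa
            exp.truth.taxa.to_csv(out / "ground_truth_taxa.tsv", sep="\t")
            exp.truth.samples.to_csv(out / "ground_truth_samples.tsv", sep="\t")
            write_fasta(sequences, out / "asv_sequences.fasta")
            write_fasta(ref_msa, out / "reference_msa.fasta")
        else:
            for key in ("counts_path", "metadata_path", "sequences_path", "reference_msa_path"):
                if getattr(config, key) is None:
                    raise MissingMetadataError(f"config key {key} required when simulate=false")
            table = read_count_table(config.counts_path)
            metadata = pd.read_csv(config.metadata_path, sep="\t")
            sequences = read_fasta(config.sequences_path)
            ref_msa = read_fasta(config.reference_msa_path)
        metadata = metadata.set_index("sample_id", drop=False)
    except AdNicheError as err:
        raise type(err)(f"stage {stage}: {err}") from err

    # ---- chemistry --------------------------------------------------
    stage = "chemistry"
    try:
        chem = speciate_metadata(metadata)
        chem.to_csv(out / "chemistry.tsv", sep="\t", index=False)
        report["chemistry"] = {
            "n_samples": int(len(chem)),
            "nh3_mean_low": float(chem.loc[chem["medium"] == "low", "nh3"].mean())
            if "medium" in chem
            else None,
            "nh3_mean_high": float(chem.loc[chem["medium"] == "high", "nh3"].mean())
            if "medium" in chem
            else None,
        }
    except AdNicheError as err:
        raise type(err)(f"stage {stage}: {err}") from err

    # ---- abundance --------------------------------------------------
    stage = "abundance"
    try:
        if "copies_per_ml" not in metadata.columns:
            raise MissingMetadataError("metadata lacks copies_per_ml column")
        rare = rarefy(table, depth=config.depth, seed=seeds["rarefy"])
        chem = chem.loc[[s for s in chem["sample_id"] if s in rare.samples]]
        copies = dict(zip(metadata["sample_id"], metadata["copies_per_ml"]))
        absolute = weight_to_absolute(rare, copies)
        write_count_table(rare, out / "rarefied_counts.tsv")
        absolute.data.to_csv(out / "absolute_abundance.tsv", sep="\t")
        alpha = alpha_diversity_table(absolute)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        bc = bray_curtis_matrix(absolute)
        bc.to_csv(out / "bray_curtis.tsv", sep="\t")
        report["alpha_diversity"] = {
            "richness_mean": float(alpha["richness"].mean()),
            "pielou_mean": float(alpha["pielou_evenness"].mean()),
        }
        anosim_res = {}
        meta_kept = chem.set_index("sample_id", drop=False).loc[absolute.samples]
        groups_all = meta_kept["community"].astype(str) + "/" + meta_kept["medium"].astype(str)
        res = anosim(bc, groups_all.tolist(), seed=seeds["anosim"])
        anosim_res["community_x_medium"] = {
            "R": res.r_statistic,
            "p": res.p_value,
            "n_permutations": res.n_permutations,
        }
        for comm in sorted(meta_kept["community"].unique()):
            sel = meta_kept.index[meta_kept["community"] == comm].tolist()
            sub_bc = bc.loc[sel, sel]
            res = anosim(
                sub_bc, meta_kept.loc[sel, "medium"].tolist(), seed=seeds["anosim"]
            )
            anosim_res[f"{comm}_medium"] = {"R": res.r_statistic, "p": res.p_value}
        report["anosim"] = anosim_res
    except AdNicheError as err:
        raise type(err)(f"stage {stage}: {err}") from err

    # ---- niche classification ---------------------------------------
    stage = "niche"
    try:
        fixed = PAPER_THRESHOLDS if config.thresholds == "paper" else None
        niche_tables: dict[str, pd.DataFrame] = {}
        niche_counts: dict[str, dict] = {}
        for comm in sorted(meta_kept["community"].unique()):
            sel = meta_kept.index[meta_kept["community"] == comm].tolist()
            sub = absolute.subset_samples(sel)
            nh3 = meta_kept.loc[sel, "nh3"].to_numpy()
            groups = (
                meta_kept.loc[sel, "medium"].astype(str)
                + "_d"
                + meta_kept.loc[sel, "day"].astype(str)
            ).tolist()
            df, null = niche_classification(
                sub,
                nh3,
                n_null=config.n_null,
                alpha=config.alpha,
                seed=seeds["niche"],
                fixed_thresholds=fixed,
                min_samples=config.min_samples,
                resource_groups=groups,
            )
            df.to_csv(out / f"niche_{comm}.tsv", sep="\t")
            niche_tables[comm] = df
            niche_counts[comm] = {
                **df["nh3_class"].value_counts().to_dict(),
                "thresholds": [null.lower_threshold, null.upper_threshold]
                if fixed is None
                else list(fixed),
            }
        report["niche"] = niche_counts
    except AdNicheError as err:
        raise type(err)(f"stage {stage}: {err}") from err

    # ---- methanogen screen ------------------------------------------
    stage = "screen"
    try:
        hmm = build_profile_hmm(ref_msa)
        screen = screen_methanogens(
            hmm,
            sequences,
            n_null=config.screen_n_null,
            quantile=config.screen_quantile,
            seed=seeds["screen"],
        )
        screen.to_tsv(out / "methanogen_calls.tsv")
        called = screen.called
        report["screen"] = {
            "n_asvs": int(len(sequences)),
            "n_called": int(len(called)),
            "threshold_bits": screen.threshold,
        }
        if len(called) >= 3:
            aligned = align_hits_to_matches(hmm, sequences, called)
            # spurious hits may align to only a handful of match states;
            # require half the model covered before placing on the tree
            aligned = {
                k: v for k, v in aligned.items()
                if 1.0 - v.count("-") / len(v) >= 0.5
            }
            aligned.update(msa_match_strings(ref_msa, hmm))
            try:
                dm = pairwise_distances(aligned)
                tree = nj_tree(dm)
                (out / "methanogen_tree.nwk").write_text(tree.newick + "\n")
            except AdNicheError as tree_err:
                logger.warning("screen: skipping NJ tree (%s)", tree_err)
    except AdNicheError as err:
        raise type(err)(f"stage {stage}: {err}") from err

    # ---- co-occurrence networks -------------------------------------
    stage = "network"
    try:
        nets = []
        net_report = {}
        for comm in sorted(meta_kept["community"].unique()):
            for medium in sorted(meta_kept["medium"].unique()):
                sel = meta_kept.index[
                    (meta_kept["community"] == comm) & (meta_kept["medium"] == medium)
                ].tolist()
                if len(sel) < 4:
                    continue
                label = f"{comm}_{medium}"
                sub = absolute.subset_samples(sel)
                g = build_network(
                    sub,
                    niche_tables[comm],
                    methanogens=set(called),
                    alpha=config.alpha,
                    top_n=config.top_n,
                    method=config.network_method,
                    n_perm=config.n_perm,
                    seed=seeds["network"],
                    condition=label,
                )
                nets.append(g)
                assignment, clusters = components(g)
                nodes = pd.DataFrame.from_dict(
                    {n: dict(g.nodes[n], cluster=assignment[n]) for n in g.nodes},
                    orient="index",
                ).rename_axis("taxon_id")
                nodes.to_csv(out / f"network_{label}_nodes.tsv", sep="\t")
                edges = nx.to_pandas_edgelist(g)
                edges.to_csv(out / f"network_{label}_edges.tsv", sep="\t", index=False)
                nx.write_graphml(g, out / f"network_{label}.graphml")
                total = max(g.number_of_nodes(), 1)
                type_counts = nodes["node_type"].value_counts().to_dict()
                net_report[label] = {
                    "n_nodes": g.number_of_nodes(),
                    "n_edges": g.number_of_edges(),
                    "n_clusters": int(clusters.shape[0]),
                    "node_type_counts": type_counts,
                    "percent_sensitive": 100.0
                    * sum(
                        v
                        for k, v in type_counts.items()
                        if k.startswith("sensitive")
                    )
                    / total,
                }
        report["networks"] = net_report
        if len(nets) >= 2:
            comp = composition_chisq(nets)
            report["network_composition_chisq"] = {
                "chi2": comp.chi2,
                "df": comp.df,
                "p": comp.p_value,
            }
    except AdNicheError as err:
        raise type(err)(f"stage {stage}: {err}") from err

    write_report(report, out / "report.json")
    return report


def write_report(report: dict, path) -> None:
    """Serialise the report as JSON with stable key order."""
    with open(path, "w") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
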