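"""End-to-end orchestration: detect -> filter -> classify -> stats.

Inputs follow the on-disk layout written by :mod:`intronpa.simulate` (the
same formats a real study would provide): per-species GFF3 + genome FASTA,
per-cluster aligned FASTA, per-cluster Newick trees, a cluster TSV, and
optional flags tables.  Every stage logs row counts; rejections are logged
per rule so the filter cascade is auditable.
"""

from __future__ import annotations

import glob
import hashlib
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import io_formats, groups as groups_mod, parsimony, stats as stats_mod
from .groups import FilterConfig, extract_introns, group_table
from .species import (GRASS_SPECIES, default_species_tree, grass_tree,
                      species_of_gene)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Single configuration for a full pipeline run."""

    dataset_dir: str
    out_dir: str
    min_cluster: int = 3
    max_cluster: int = 200
    max_te_fraction: float = 0.30
    min_flank_identity: float = 0.60
    flank_window: int = 20
    min_intron_length: int = 11
    min_spacing: int = 20
    junction_window: int = 3
    bootstrap: int = 1000
    bins: int = 10
    randomization_replicates: int = 0   # 0 = skip the randomization stage
    randomization_mode: str = "strict_unique"
    seed: int = 0

    def filter_config(self) -> FilterConfig:
        return FilterConfig(self.min_cluster, self.max_cluster,
                            self.max_te_fraction, self.junction_window,
                            self.flank_window, self.min_flank_identity,
                            self.min_intron_length, self.min_spacing)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise PipelineError("config", f"unknown keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute detect -> filter -> classify -> stats and write the artifact
    directory.  Returns the result tables."""
    d = config.dataset_dir
    os.makedirs(config.out_dir, exist_ok=True)
    counts: list[str] = []

    # -- detect ------------------------------------------------------------
    try:
        cluster_table = io_formats.parse_cluster_table(
            os.path.join(d, "clusters.tsv"))
        cds = io_formats.parse_fasta(os.path.join(d, "cds.fasta")) \
            if os.path.exists(os.path.join(d, "cds.fasta")) else None
        introns: dict[str, list] = {}
        models_by_gene = {}
        for gff in sorted(glob.glob(os.path.join(d, "genes", "*.gff3"))):
            species = os.path.splitext(os.path.basename(gff))[0]
            genome = io_formats.parse_fasta(
                os.path.join(d, "genomes", f"{species}.fasta"))
            models, _ = io_formats.parse_gene_models(gff, species)
            for m in models:
                models_by_gene[m.gene_id] = m
                introns[m.gene_id] = extract_introns(
                    m, genome.get(m.chromosome))
        counts.append(f"genes={len(models_by_gene)}")
    except (OSError, ValueError) as exc:
        raise PipelineError("detect", str(exc)) from exc

    te_flags, synteny_flags = _read_flags(d)

    # -- groups + filters ---------------------------------------------------
    all_groups, rejections = [], []
    aln_paths = sorted(glob.glob(os.path.join(d, "alignments", "*.fasta")))
    fc = config.filter_config()
    for path in aln_paths:
        cid = os.path.splitext(os.path.basename(path))[0]
        aln = io_formats.parse_alignment(path, cid, cds)
        gs = groups_mod.identify_intron_groups(
            aln, introns, fc.junction_window,
            ingroup_species=set(GRASS_SPECIES))
        kept, log = groups_mod.apply_group_filters(gs, aln, te_flags, fc)
        all_groups.extend(kept)
        rejections.append(log)
    rejection_log = (pd.concat(rejections, ignore_index=True) if rejections
                     else pd.DataFrame(columns=["cluster_id", "boundary",
                                                "rule"]))
    counts.append(f"groups_retained={len(all_groups)} "
                  f"groups_rejected={len(rejection_log)}")

    # -- classify -----------------------------------------------------------
    trees = io_formats.parse_gene_trees(os.path.join(d, "trees.tsv"),
                                        cluster_table)
    species_in_data = {species_of_gene(g) for g in cluster_table.cluster_of}
    sp_tree = (default_species_tree() if species_in_data -
               set(grass_tree().leaf_labels()) else grass_tree())
    class_rows, event_rows, classifications = [], [], []
    for g in sorted(all_groups, key=lambda g: (g.cluster_id, g.boundary)):
        if g.status == "conserved":
            cls = parsimony.GroupClassification("conserved", [])
            class_rows.append(_class_row(g, cls, None, 0))
            classifications.append(cls)
            continue
        tree = trees.get(g.cluster_id)
        if tree is None:
            raise PipelineError("classify",
                                f"no gene tree for cluster {g.cluster_id}")
        pattern = {gid: s for gid, s in g.states.items()
                   if s in ("present", "absent")}
        hists = parsimony.enumerate_min_histories(tree, pattern)
        cls = parsimony.classify_group(hists)
        classifications.append(cls)
        collapsed = None
        if cls.history is not None:
            species_of = {l: species_of_gene(l)
                          for l in (lf.taxon.label
                                    for lf in tree.leaf_node_iter())}
            collapsed = parsimony.collapse_paralog_events(cls, tree,
                                                          species_of)
            mapped, unmappable = parsimony.assign_events_to_species_branches(
                cls.history, species_of, sp_tree)
            for branch, kind in mapped:
                event_rows.append({"cluster_id": g.cluster_id,
                                   "boundary": g.boundary, "branch": branch,
                                   "kind": kind, "category": cls.category,
                                   "mappable": True})
            for ev in unmappable:
                event_rows.append({"cluster_id": g.cluster_id,
                                   "boundary": g.boundary,
                                   "branch": ",".join(ev.clade),
                                   "kind": ev.kind, "category": cls.category,
                                   "mappable": False})
        class_rows.append(_class_row(g, cls, collapsed, len(hists)))
    counts.append(f"classified={len(class_rows)} events={len(event_rows)}")

    results: dict[str, pd.DataFrame] = {
        "groups": group_table(all_groups),
        "rejections": rejection_log,
        "classifications": pd.DataFrame(
            class_rows, columns=["cluster_id", "boundary", "category",
                                 "n_events", "collapsed_events",
                                 "mixed_order", "n_histories", "affected"]),
        "events": pd.DataFrame(
            event_rows, columns=["cluster_id", "boundary", "branch", "kind",
                                 "category", "mappable"]),
    }

    # -- stats --------------------------------------------------------------
    results["summary"] = stats_mod.build_summary(classifications)
    mappable = results["events"][
        results["events"]["mappable"].astype(bool)]
    results["rates"] = stats_mod.compute_rates(mappable, sp_tree)
    merged = results["groups"]
    try:
        adj = stats_mod.adjacent_loss_test(merged)
        results["adjacency"] = pd.DataFrame([vars(adj)])
    except ValueError:
        results["adjacency"] = pd.DataFrame()
    pa_pos, all_pos = _positions(all_groups, introns, models_by_gene)
    if pa_pos and all_pos:
        results["positions"] = stats_mod.gene_position_distribution(
            pa_pos, all_pos, bins=config.bins, bootstrap=config.bootstrap,
            seed=config.stage_seed("positions"))
    if config.randomization_replicates > 0:
        rnd = stats_mod.randomization_test(
            n_groups=8782, tips_per_group=5,
            n_absences=257, replicates=config.randomization_replicates,
            seed=config.stage_seed("randomization"),
            resolution_mode=config.randomization_mode, observed=37)
        results["randomization"] = pd.DataFrame([{
            "replicates": rnd.replicates, "mean": rnd.mean, "max": rnd.max,
            "observed": rnd.observed, "p": rnd.p_value,
            "p_string": rnd.p_string}])

    io_formats.write_tables(results, config.out_dir)
    summary_attrs = results["summary"].attrs
    prov = {"config": asdict(config), "seed": config.seed,
            "config_sha256": hashlib.sha256(
                yaml.safe_dump(asdict(config), sort_keys=True).encode()
            ).hexdigest(),
            "stage_counts": counts,
            "loss_gain_ratio": summary_attrs.get("loss_gain_ratio")}
    with open(os.path.join(config.out_dir, "provenance.yaml"), "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)
    with open(os.path.join(config.out_dir, "report.md"), "w") as fh:
        fh.write(generate_report(config.out_dir))
    return results


def _class_row(g, cls, collapsed, n_hist):
    return {"cluster_id": g.cluster_id, "boundary": g.boundary,
            "category": cls.category, "n_events": cls.n_events,
            "collapsed_events": collapsed, "mixed_order": cls.mixed_order,
            "n_histories": n_hist, "affected": ",".join(cls.affected)}


def _read_flags(d: str):
    te, syn = {}, {}
    path = os.path.join(d, "flags.tsv")
    if os.path.exists(path):
        df = pd.read_csv(path, sep="\t")
        for r in df.itertuples():
            if hasattr(r, "te_protein"):
                te[r.gene_id] = bool(r.te_protein)
            if hasattr(r, "synteny"):
                syn[r.gene_id] = bool(r.synteny)
    return (te or None), syn


def _positions(groups, introns, models):
    pa, ref = [], []
    pa_keys = {(g.cluster_id, g.boundary) for g in groups
               if g.status == "PA"}
    for g in groups:
        for gid, site in g.sites.items():
            model = models.get(gid)
            if model is None or model.cds_length == 0:
                continue
            rel = site.cds_breakpoint / model.cds_length
            if 0 < rel < 1:
                ref.append(rel)
                if (g.cluster_id, g.boundary) in pa_keys:
                    pa.append(rel)
    return pa, ref


def generate_report(artifact_dir: str) -> str:
    """Human-readable summary of an artifact directory."""
    def load(name: str) -> pd.DataFrame | None:
        path = os.path.join(artifact_dir, f"{name}.tsv")
        if not os.path.exists(path):
            return None
        try:
            return pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            return pd.DataFrame()

    summary = load("summary")
    if summary is None:
        raise PipelineError("report", "missing table summary.tsv")
    lines = ["# Intron turnover run report", "", "## Category counts", ""]
    total_loss = total_gain = 0
    for r in summary.itertuples():
        ev = "" if pd.isna(r.events) else f", events {int(r.events)}"
        lines.append(f"- {r.category}: {int(r.groups)} groups{ev}, "
                     f"{int(r.affected_genes)} affected genes")
    events = load("events")
    if events is not None and len(events):
        total_loss = int((events.kind == "loss").sum())
        total_gain = int((events.kind == "gain").sum())
    ratio = (f"{total_loss / total_gain:.1f}:1" if total_gain
             else "undefined (no gains)")
    lines += ["", f"Loss events: {total_loss}; gain events: {total_gain}; "
              f"loss:gain ratio {ratio}", ""]
    rates = load("rates")
    if rates is not None and len(rates):
        lines += ["## Per-branch frequencies (all events)", ""]
        for r in rates[rates.category == "all"].itertuples():
            lines.append(f"- {r.branch}: {int(r.count)} events / "
                         f"{r.branch_length_my:g} MY = "
                         f"{r.frequency_per_my:.3g}/MY")
        lines.append("")
    rnd = load("randomization")
    if rnd is not None and len(rnd):
        r = rnd.iloc[0]
        p = r.p_string if isinstance(r.p_string, str) else f"{r.p:g}"
        lines += ["## Recurrent-loss randomization", "",
                  f"- mean {r['mean']:.2f}, max {int(r['max'])} over "
                  f"{int(r.replicates)} replicates; observed "
                  f"{int(r.observed)}; empirical p {p}", ""]
    return "\n".join(lines) + "\n"
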