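"""End-to-end driver: simulate -> infer -> clones -> metrics -> phylo -> concord.

All stage outputs are written as documented plain-text formats into the
run directory, plus a machine-readable ``summary.json``. All randomness
flows from the single config seed through named per-stage substreams, so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clones as clones_mod
from . import concord as concord_mod
from . import infer as infer_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import phylo as phylo_mod
from . import simulate as sim_mod
from .config import PipelineConfig
from .genome import make_bins

__all__ = ["run_pipeline", "stage_seed", "truth_to_tree"]

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def truth_to_tree(truth: sim_mod.ClonalTruth, bins) -> phylo_mod.CopyNumberTree:
    """View a simulated ClonalTruth as a CopyNumberTree for writing."""
    nodes = {phylo_mod.ROOT: sim_mod.diploid_profile(bins)}
    edges = []
    total = 0
    for cid in truth.clone_ids:
        nodes[cid] = truth.clone_profiles[cid]
        evs = truth.edge_events[cid]
        count = len(evs)
        edges.append((truth.parent[cid], cid, evs, count))
        total += count
    return phylo_mod.CopyNumberTree(nodes=nodes, edges=edges, total_events=total, bins=bins)


def _profile_to_segments(cn: np.ndarray, bins) -> pd.DataFrame:
    """Merge adjacent equal-total bins of a profile into segments."""
    rows = []
    totals = cn.sum(axis=1)
    for chrom, sl in bins.chrom_slices():
        start_i = sl.start
        for i in range(sl.start + 1, sl.stop + 1):
            if i == sl.stop or totals[i] != totals[start_i]:
                rows.append({
                    "chrom": chrom,
                    "start": int(bins.bin_start[start_i]),
                    "end": int(bins.bin_end[i - 1]),
                    "total_cn": int(totals[start_i]),
                })
                start_i = i
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write all outputs under ``config.outdir`` and
    return the summary dictionary (also stored as summary.json)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_lengths = config.genome.resolve()
    bins = make_bins(chrom_lengths, config.genome.bin_size)
    summary: dict = {"n_bins": bins.n_bins, "genome_bp": bins.total_bp}

    # -- simulate ------------------------------------------------------
    sim = config.simulate
    truth = sim_mod.simulate_clonal_truth(
        bins,
        n_clones=sim.n_clones,
        n_truncal_events=sim.n_truncal_events,
        n_private_events=sim.n_private_events,
        p_wgd=sim.p_wgd,
        deletion_bias=sim.deletion_bias,
        seed=stage_seed(config.seed, "truth"),
        clone_proportions=sim.clone_proportions,
        normal_fraction=sim.normal_fraction,
        topology=sim.topology,
        min_event_bins=sim.min_event_bins,
    )
    obs = sim_mod.simulate_cells(
        truth, bins,
        n_cells=sim.n_cells,
        mean_coverage=sim.mean_coverage,
        snp_density=sim.snp_density,
        noise_cell_fraction=sim.noise_cell_fraction,
        seed=stage_seed(config.seed, "cells"),
    )
    truthdir = outdir / "truth"
    truthdir.mkdir(exist_ok=True)
    io_mod.write_clone_profiles(truthdir / "clone_profiles.tsv", bins, [
        clones_mod.CloneProfile(cid, truth.clone_profiles[cid], 0)
        for cid in truth.clone_ids
    ])
    io_mod.write_cell_table(truthdir / "cells.tsv",
                            {c.cell_id: c.true_clone for c in obs},
                            column="true_clone")
    io_mod.write_tree(truthdir / "tree", truth_to_tree(truth, bins), bins)
    io_mod.write_observations(outdir / "observations.tsv", bins, obs)
    summary["truth"] = {
        "clone_proportions": {k: round(v, 6) for k, v in truth.clone_proportions.items()},
        "wgd_edges": sorted(truth.wgd_edges),
        "n_resampled_events": truth.n_resampled_events,
    }

    # -- infer ---------------------------------------------------------
    normals = [c for c in obs if c.true_clone == sim_mod.NORMAL]
    reference_pool = normals if normals else obs  # matched-normal analog
    reference = infer_mod.pseudobulk_reference(reference_pool)
    signals = infer_mod.compute_signals(obs, reference)
    profiles = infer_mod.call_cells(
        signals, config.infer.ploidy_grid, bins=bins, max_cn=config.infer.max_cn
    )
    io_mod.write_calls(outdir / "calls.tsv", bins, profiles)
    summary["infer"] = {
        "n_cells_called": len(profiles),
        "reference": "matched_normal" if normals else "pseudobulk",
        "mean_ploidy": round(float(np.mean([p.ploidy for p in profiles])), 4),
    }

    # -- clones --------------------------------------------------------
    cloneset = clones_mod.identify_clones(
        profiles, bins,
        error_rate=config.clones.error_rate,
        min_clone_size=config.clones.min_clone_size,
    )
    io_mod.write_cell_table(outdir / "clone_assignments.tsv", cloneset.labels)
    io_mod.write_clone_profiles(outdir / "clone_profiles.tsv", bins, cloneset.clones)
    audit = clones_mod.noisy_cell_audit(cloneset, profiles, bins)
    audit.to_csv(outdir / "noisy_cell_audit.tsv", sep="\t", index=False,
                 float_format="%.6f")
    summary["clones"] = {
        "n_clones": len(cloneset.clones),
        "n_noisy": len(cloneset.noisy_cells),
        "clone_sizes": {c.clone_id: c.n_cells for c in cloneset.clones},
    }

    # -- metrics -------------------------------------------------------
    for cp in cloneset.clones:
        cp.wgd = metrics_mod.detect_wgd(cp, bins, config.metrics.wgd_threshold)
    modal = metrics_mod.modal_profile(profiles, bins)
    wgd_of_cell = {}
    for p in profiles:
        lab = cloneset.labels[p.cell_id]
        if lab == clones_mod.NOISY:
            wgd_of_cell[p.cell_id] = metrics_mod.detect_wgd(p, bins,
                                                            config.metrics.wgd_threshold)
        else:
            wgd_of_cell[p.cell_id] = cloneset.clone(lab).wgd
    cell_metrics = [
        metrics_mod.compute_cell_metrics(p, bins, modal, wgd_of_cell[p.cell_id])
        for p in profiles
    ]
    io_mod.write_metrics(outdir / "cell_metrics.tsv", cell_metrics)
    locus = tuple(config.metrics.locus)
    locus_rows = []
    if locus[0] in chrom_lengths and locus[2] <= chrom_lengths[locus[0]]:
        for cp in cloneset.clones:
            st = metrics_mod.locus_status(cp, bins, locus, wgd=cp.wgd)
            locus_rows.append({"clone_id": cp.clone_id, "status": st.status,
                               "cnA": st.cn_at_locus[0], "cnB": st.cn_at_locus[1]})
    pd.DataFrame(locus_rows, columns=["clone_id", "status", "cnA", "cnB"]).to_csv(
        outdir / "locus_report.tsv", sep="\t", index=False)
    per_clone = {}
    for cp in cloneset.clones:
        members = [m for m in cell_metrics
                   if cloneset.labels[m.cell_id] == cp.clone_id]
        if members:
            per_clone[cp.clone_id] = {
                "wgd": bool(cp.wgd),
                "consensus_frac_aberrant": round(
                    metrics_mod.aberrant_fraction(cp.cn, bins, cp.wgd), 4),
                "mean_ploidy": round(float(np.mean([m.ploidy for m in members])), 4),
                "mean_frac_aberrant": round(float(np.mean([m.frac_aberrant for m in members])), 4),
                "mean_frac_deleted": round(float(np.mean([m.frac_deleted for m in members])), 4),
                "mean_frac_amplified": round(float(np.mean([m.frac_amplified for m in members])), 4),
                "mean_frac_subclonal": round(float(np.mean([m.frac_subclonal for m in members])), 4),
            }
    summary["metrics"] = per_clone

    # -- phylo ---------------------------------------------------------
    tumor_clones = [(cp.clone_id, cp.cn) for cp in cloneset.clones]
    tree = phylo_mod.reconstruct_tree(
        tumor_clones, bins,
        allow_wgd=config.phylo.allow_wgd,
        method=config.phylo.method,
    )
    io_mod.write_tree(outdir / "tree", tree, bins)
    root_children = tree.children(tree.root)
    truncal_counts = {c: n for p, c, _, n in tree.edges if p == tree.root}
    summary["phylo"] = {
        "total_events": tree.total_events,
        "n_nodes": len(tree.nodes),
        "root_edge_events": {c: truncal_counts.get(c, 0) for c in root_children},
    }

    # -- concord -------------------------------------------------------
    conc_rows = []
    if len(cloneset.clones) >= 2:
        vectors = {}
        for cp in cloneset.clones:
            seg = concord_mod.SegmentTable(
                cp.clone_id, _profile_to_segments(cp.cn, bins),
                source="single_cell_consensus",
            )
            io_mod.write_segments(outdir / f"segments_{cp.clone_id}.tsv", seg.segments)
            _, vec = concord_mod.binned_median_cn(
                seg, chrom_lengths, bin_size=config.concord.bin_size)
            vectors[cp.clone_id] = vec
        corr = concord_mod.correlation_matrix(vectors)
        corr.to_csv(outdir / "correlation_matrix.tsv", sep="\t", float_format="%.6f")
        groups, _, newick = concord_mod.cluster_samples(
            corr, config.concord.cluster_threshold)
        (outdir / "dendrogram.nwk").write_text(newick + "\n")
        for i, ca in enumerate(cloneset.clones):
            for cb in cloneset.clones[i + 1:]:
                res = concord_mod.window_concordance(
                    ca, cb, bins, wgd_a=ca.wgd, wgd_b=cb.wgd,
                    names=(ca.clone_id, cb.clone_id), mode=config.concord.mode)
                r = float(corr.loc[ca.clone_id, cb.clone_id])
                conc_rows.append({
                    "sample_a": ca.clone_id, "sample_b": cb.clone_id,
                    "prop_identical": (round(res.prop_identical, 6)
                                       if res.defined else None),
                    "n_windows": res.n_windows_considered,
                    "pearson_r": None if np.isnan(r) else round(r, 6),
                })
        pd.DataFrame(conc_rows).to_csv(outdir / "window_concordance.tsv",
                                       sep="\t", index=False)
        summary["concord"] = {
            "pairs": conc_rows,
            "groups": groups,
        }
        _write_heatmap(corr, outdir / "correlation_heatmap.png")
    else:
        summary["concord"] = {"pairs": [], "groups": {}}

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    logger.info("pipeline complete: %s", outdir)
    return summary


def _write_heatmap(corr: pd.DataFrame, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover - plotting is best-effort
        logger.warning("matplotlib unavailable; skipping heatmap")
        return
    fig, ax = plt.subplots(figsize=(4 + 0.3 * len(corr), 3 + 0.3 * len(corr)))
    im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90)
    ax.set_yticks(range(len(corr)), corr.index)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
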