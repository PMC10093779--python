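"""Readers and writers for the pipeline's plain-text formats.

Everything on disk is TSV (BED-compatible 0-based half-open coordinates;
1-based GFF-style input accepted via a flag) or Newick. The per-cell call
dialect mirrors the columns of common allele-specific single-cell callers:
``chrom  start  end  cell_id  cn  total_cn`` with ``cn`` as "cnA|cnB".
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .clones import CloneProfile
from .events import EventRecord
from .genome import GenomeBins
from .infer import CellProfile
from .phylo import CopyNumberTree
from .simulate import CellObservation

__all__ = [
    "write_calls",
    "read_calls",
    "write_clone_profiles",
    "read_clone_profiles",
    "write_cell_table",
    "read_cell_table",
    "write_observations",
    "read_observations",
    "write_segments",
    "read_segments",
    "write_tree",
    "read_tree",
    "write_metrics",
]


class ParseError(ValueError):
    pass


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _check_coords(df: pd.DataFrame, path, one_based: bool) -> pd.DataFrame:
    df = df.copy()
    if one_based:
        df["start"] = df["start"] - 1
    bad = (df["start"] < 0) | (df["end"] <= df["start"])
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 1-based
        raise ParseError(f"{path}: invalid coordinates at line {line}")
    return df


def _profile_frame(bins: GenomeBins, cn: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": bins.chrom_labels,
        "start": bins.bin_start,
        "end": bins.bin_end,
        "cn": [f"{a}|{b}" for a, b in cn.tolist()],
        "total_cn": cn.sum(axis=1),
    })


def _split_cn(series: pd.Series, path) -> np.ndarray:
    try:
        parts = series.str.split("|", expand=True).astype(int)
    except (ValueError, AttributeError) as exc:
        raise ParseError(f"{path}: malformed cn column ({exc})") from exc
    cn = parts.values
    if (cn < 0).any():
        line = int(np.argwhere((cn < 0).any(axis=1))[0][0]) + 2
        raise ParseError(f"{path}: negative copy number at line {line}")
    return cn


# -- per-cell calls ----------------------------------------------------

def write_calls(path, bins: GenomeBins, profiles: list[CellProfile]) -> None:
    frames = []
    for p in profiles:
        f = _profile_frame(bins, p.cn)
        f.insert(3, "cell_id", p.cell_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_calls(path, one_based: bool = False) -> tuple[GenomeBins, list[CellProfile]]:
    """Read a calls TSV; the bin grid is reconstructed from the rows."""
    df = _read_tsv(path, ["chrom", "start", "end", "cell_id", "cn"])
    df = _check_coords(df, path, one_based)
    first = df[df["cell_id"] == df["cell_id"].iloc[0]]
    bins = GenomeBins.from_intervals(
        first["chrom"].values, first["start"].values, first["end"].values
    )
    profiles = []
    lengths = bins.lengths.astype(float)
    for cell_id, grp in df.groupby("cell_id", sort=True):
        if len(grp) != bins.n_bins:
            raise ParseError(f"{path}: cell {cell_id} has {len(grp)} rows, "
                             f"expected {bins.n_bins}")
        cn = _split_cn(grp["cn"], path)
        ploidy = float((lengths * cn.sum(axis=1)).sum() / lengths.sum())
        profiles.append(CellProfile(str(cell_id), cn, ploidy, scale=float("nan")))
    return bins, profiles


# -- clone profiles ----------------------------------------------------

def write_clone_profiles(path, bins: GenomeBins, clones: list[CloneProfile]) -> None:
    frames = []
    for cp in clones:
        f = _profile_frame(bins, cp.cn)
        f.insert(3, "clone_id", cp.clone_id)
        f.insert(4, "n_cells", cp.n_cells)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_clone_profiles(path, one_based: bool = False) -> tuple[GenomeBins, list[CloneProfile]]:
    df = _read_tsv(path, ["chrom", "start", "end", "clone_id", "cn"])
    df = _check_coords(df, path, one_based)
    first = df[df["clone_id"] == df["clone_id"].iloc[0]]
    bins = GenomeBins.from_intervals(
        first["chrom"].values, first["start"].values, first["end"].values
    )
    clones = []
    for clone_id, grp in df.groupby("clone_id", sort=True):
        cn = _split_cn(grp["cn"], path)
        n_cells = int(grp["n_cells"].iloc[0]) if "n_cells" in grp.columns else 0
        clones.append(CloneProfile(str(clone_id), cn, n_cells))
    return bins, clones


# -- cell tables and observations -------------------------------------

def write_cell_table(path, labels: dict[str, str], column: str = "clone_id") -> None:
    pd.DataFrame(
        {"cell_id": list(labels), column: list(labels.values())}
    ).sort_values("cell_id").to_csv(path, sep="\t", index=False)


def read_cell_table(path, column: str = "clone_id") -> dict[str, str]:
    df = _read_tsv(path, ["cell_id", column])
    return dict(zip(df["cell_id"].astype(str), df[column].astype(str)))


def write_observations(path, bins: GenomeBins, obs: list[CellObservation]) -> None:
    frames = []
    for cell in obs:
        frames.append(pd.DataFrame({
            "cell_id": cell.cell_id,
            "chrom": bins.chrom_labels,
            "start": bins.bin_start,
            "end": bins.bin_end,
            "read_count": cell.read_count,
            "b_count": cell.b_count,
            "snp_total": cell.snp_total,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_observations(
    path, truth_labels: dict[str, str] | None = None, one_based: bool = False
) -> tuple[GenomeBins, list[CellObservation]]:
    df = _read_tsv(path, ["cell_id", "chrom", "start", "end",
                          "read_count", "b_count", "snp_total"])
    df = _check_coords(df, path, one_based)
    first = df[df["cell_id"] == df["cell_id"].iloc[0]]
    bins = GenomeBins.from_intervals(
        first["chrom"].values, first["start"].values, first["end"].values
    )
    obs = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        obs.append(CellObservation(
            cell_id=str(cell_id),
            read_count=grp["read_count"].values.astype(np.int64),
            b_count=grp["b_count"].values.astype(np.int64),
            snp_total=grp["snp_total"].values.astype(np.int64),
            true_clone=(truth_labels or {}).get(str(cell_id), "unknown"),
        ))
    return bins, obs


# -- segment tables ----------------------------------------------------

def write_segments(path, segments: pd.DataFrame) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_segments(path, one_based: bool = False) -> pd.DataFrame:
    df = _read_tsv(path, ["chrom", "start", "end"])
    return _check_coords(df, path, one_based)


# -- trees -------------------------------------------------------------

def _tree_to_dendropy(tree: CopyNumberTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    node_of = {tree.root: dtree.seed_node}
    dtree.seed_node.label = tree.root
    counts = {c: n for _, c, _, n in tree.edges}

    def add(parent_name):
        for child in sorted(tree.children(parent_name)):
            node = node_of[parent_name].new_child(edge_length=counts[child])
            node.label = child
            node_of[child] = node
            add(child)

    add(tree.root)
    for leaf in dtree.leaf_node_iter():
        leaf.taxon = taxa.new_taxon(leaf.label)
    return dtree


def write_tree(prefix, tree: CopyNumberTree, bins: GenomeBins) -> dict[str, Path]:
    """Write Newick + edge-events sidecar TSV + DOT next to ``prefix``."""
    prefix = Path(prefix)
    paths = {
        "newick": prefix.with_suffix(".nwk"),
        "events": prefix.parent / (prefix.name + "_events.tsv"),
        "dot": prefix.with_suffix(".dot"),
    }
    dtree = _tree_to_dendropy(tree)
    paths["newick"].write_text(
        dtree.as_string(schema="newick", suppress_rooting=True,
                        suppress_internal_node_labels=False)
    )
    rows = []
    for parent, child, events, _ in tree.edges:
        for ev in events:
            rows.append({
                "parent": parent, "child": child, "kind": ev.kind,
                "haplotype": ev.haplotype, "chrom": ev.chrom,
                "start_bin": ev.start_bin, "end_bin": ev.end_bin,
                "delta": ev.delta,
            })
    pd.DataFrame(rows, columns=["parent", "child", "kind", "haplotype",
                                "chrom", "start_bin", "end_bin", "delta"]
                 ).to_csv(paths["events"], sep="\t", index=False)

    buf = _io.StringIO()
    buf.write("digraph copy_number_tree {\n")
    for parent, child, events, count in tree.edges:
        label = ", ".join(sorted({e.kind for e in events})) or "none"
        buf.write(f'  "{parent}" -> "{child}" [label="{count}: {label}"];\n')
    buf.write("}\n")
    paths["dot"].write_text(buf.getvalue())
    return paths


def read_tree(newick_path, events_path, bins: GenomeBins) -> CopyNumberTree:
    """Rebuild a CopyNumberTree from Newick + edge-events sidecar.

    Node profiles are recovered by replaying the events from the diploid
    root, so a written tree round-trips exactly.
    """
    from .events import apply_events, diploid_profile

    dtree = dendropy.Tree.get(path=str(newick_path), schema="newick",
                              suppress_internal_node_taxa=False)
    ev_df = pd.read_csv(events_path, sep="\t")
    events_by_edge: dict[tuple[str, str], list[EventRecord]] = {}
    for row in ev_df.itertuples(index=False):
        events_by_edge.setdefault((row.parent, row.child), []).append(EventRecord(
            kind=row.kind, haplotype=row.haplotype, chrom=row.chrom,
            start_bin=int(row.start_bin), end_bin=int(row.end_bin),
            delta=int(row.delta),
        ))

    def name_of(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    root_name = name_of(dtree.seed_node)
    nodes = {root_name: diploid_profile(bins)}
    edges = []
    total = 0

    def walk(node):
        nonlocal total
        pname = name_of(node)
        for child in node.child_nodes():
            cname = name_of(child)
            evs = events_by_edge.get((pname, cname), [])
            nodes[cname] = apply_events(nodes[pname], evs, check=False)
            count = len(evs)
            edges.append((pname, cname, evs, count))
            total += count
            walk(child)

    walk(dtree.seed_node)
    return CopyNumberTree(nodes=nodes, edges=edges, total_events=total,
                          bins=bins, root=root_name)


# -- metrics -----------------------------------------------------------

def write_metrics(path, metrics) -> None:
    rows = [{
        "cell_id": m.cell_id, "ploidy": m.ploidy,
        "frac_aberrant": m.frac_aberrant, "frac_deleted": m.frac_deleted,
        "frac_amplified": m.frac_amplified, "frac_subclonal": m.frac_subclonal,
        "wgd": m.wgd,
    } for m in metrics]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
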