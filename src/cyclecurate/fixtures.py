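"""Deterministic small datasets used by the test suite and demos.

Everything is generated programmatically from a seed: two toy graphs with
known MCL behaviour (two disjoint triangles; two 4-cliques joined by a unit
bridge), a 60-gene synchronized time course, and a 6-cell-type promoter
atlas.  A JSON manifest records the expected shapes.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from cyclecurate.network import WeightedGraph
from cyclecurate.synthetic import (
    AtlasConfig,
    CellType,
    TimecourseConfig,
    simulate_atlas,
    simulate_timecourse,
)

__all__ = ["two_triangles", "barbell", "generate_fixtures"]


def two_triangles() -> WeightedGraph:
    """Two disjoint unit-weight triangles: a1-a2-a3 and b1-b2-b3."""
    g = nx.Graph()
    for trio in (("a1", "a2", "a3"), ("b1", "b2", "b3")):
        for i in range(3):
            g.add_edge(trio[i], trio[(i + 1) % 3], weight=1.0)
    return WeightedGraph(g, threshold=0.0)


def barbell() -> WeightedGraph:
    """Two unit-weight 4-cliques joined by a single unit bridge (8 nodes)."""
    g = nx.Graph()
    left = [f"l{i}" for i in range(1, 5)]
    right = [f"r{i}" for i in range(1, 5)]
    for clique in (left, right):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(clique[i], clique[j], weight=1.0)
    g.add_edge("l1", "r1", weight=1.0)
    return WeightedGraph(g, threshold=0.0)


def fixture_timecourse_config(seed: int = 1) -> TimecourseConfig:
    """60-gene time course: 14 G0, 14 G1, 15 S, 15 G2M, 2 flat."""
    return TimecourseConfig(
        genes_per_module={"G0": 14, "G1": 14, "S": 15, "G2M": 15, "flat": 2},
        seed=seed,
    )


def fixture_atlas_config(seed: int = 1) -> AtlasConfig:
    """6-cell-type atlas spanning the proliferation range."""
    return AtlasConfig(
        cell_types=[
            CellType("embryonic_stem", 0.95, "embryonic"),
            CellType("epithelial", 0.80, "epithelial"),
            CellType("fibroblast", 0.70, "mesenchymal"),
            CellType("t_cell", 0.40, "immune"),
            CellType("hepatocyte", 0.15, "liver"),
            CellType("monocyte", 0.05, "immune"),
        ],
        cycle_genes=30,
        other_genes=40,
        seed=seed,
    )


def generate_fixtures(seed: int = 1, outdir: str | Path = "fixtures") -> dict:
    """Write the packaged fixtures under ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tri = two_triangles()
    tri.to_edgelist_tsv(outdir / "two_triangles.tsv")
    bar = barbell()
    bar.to_edgelist_tsv(outdir / "barbell.tsv")

    tc = simulate_timecourse(fixture_timecourse_config(seed))
    tc.write(outdir / "timecourse")
    atlas = simulate_atlas(fixture_atlas_config(seed))
    atlas.write(outdir / "atlas")

    manifest = {
        "seed": seed,
        "two_triangles": {"n_nodes": tri.n_nodes, "n_edges": tri.n_edges},
        "barbell": {"n_nodes": bar.n_nodes, "n_edges": bar.n_edges},
        "timecourse": {
            "n_genes": tc.matrix.n_features,
            "n_samples": tc.matrix.n_samples,
        },
        "atlas": {
            "n_promoters": atlas.tpm.n_features,
            "n_samples": atlas.tpm.n_samples,
            "n_alt_genes": len(atlas.alt_genes),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
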