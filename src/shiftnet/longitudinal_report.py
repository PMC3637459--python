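"""Longitudinal stratified reporting: metric series, QAP panel summaries, sociograms.

Metrics are stratified by week and day/night shift (never interpolated across
missing shift-points), QAP correlation panels are condensed to boxplot order
statistics per relation pair and shift, and per-shift networks are exported
as GraphML/DOT sociograms in which node size encodes in-degree centrality and
edge width encodes reported communication frequency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .network_metrics import ShiftMetrics
from .qap import QapResult
from .survey_io import RELATIONS, ShiftNetworkSet

# Affine node-size map: size = NODE_SIZE_MIN + NODE_SIZE_SLOPE * in_degree.
# In-degree is normalized to [0, 1], so sizes span [8, 48] drawing units.
NODE_SIZE_MIN = 8.0
NODE_SIZE_SLOPE = 40.0

# Edge width = EDGE_WIDTH_MIN + EDGE_WIDTH_SLOPE * frequency (frequency 1..10).
EDGE_WIDTH_MIN = 0.5
EDGE_WIDTH_SLOPE = 0.35

#: Quartile convention used for all boxplot statistics.
QUARTILE_METHOD = "linear"  # inclusive linear interpolation (R type 7)


@dataclass
class MetricsSeries:
    """Stratified metric table plus night-minus-day density contrasts."""

    table: pd.DataFrame  # one row per (week, shift, relation)
    contrasts: pd.DataFrame  # one row per (week, relation) where both shifts present


@dataclass(frozen=True)
class BoxplotSummary:
    """Order statistics of one QAP panel group (relation pair x shift)."""

    pair: tuple[str, str]
    shift: str
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    count: int
    n_significant: int
    alpha: float

    def __post_init__(self) -> None:
        if not (
            self.minimum - 1e-12
            <= self.q1
            <= self.median
            <= self.q3
            <= self.maximum + 1e-12
        ):
            raise ConfigurationError("boxplot order statistics out of order")


@dataclass(frozen=True)
class SociogramSpec:
    """Declarative sociogram: nodes with size attributes, edges with widths."""

    shift_id: str
    relation: str
    nodes: tuple[Mapping[str, object], ...]
    edges: tuple[Mapping[str, object], ...]
    layout_seed: int


def metrics_to_frame(metrics: Iterable[ShiftMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append(
            {
                "week": m.week,
                "shift": m.shift,
                "relation": m.relation,
                "shift_id": m.shift_id,
                "density_pct": m.density_pct,
                "centralization_pct": m.centralization_pct,
                "in_degree_centralization_pct": m.in_degree_centralization_pct,
                "top_in_degree_roles": "|".join(m.top_in_degree_roles),
                "n_stars": len(m.stars),
                "n_isolates": len(m.isolates),
                "excluded_dyads": m.excluded_dyads,
            }
        )
    return pd.DataFrame(rows)


def build_series(metrics: Iterable[ShiftMetrics]) -> MetricsSeries:
    """Stratify metrics by (week, shift, relation) and derive shift contrasts.

    Missing shift-points stay absent from the table — nothing is interpolated.
    Duplicate (week, shift, relation) records are an error.
    """
    frame = metrics_to_frame(metrics)
    if frame.empty:
        raise ConfigurationError("no metric records supplied")
    keys = ["week", "shift", "relation"]
    dup = frame.duplicated(subset=keys)
    if dup.any():
        first = frame.loc[dup.idxmax(), keys].tolist()
        raise ConfigurationError(f"duplicate metric record for {tuple(first)}")
    frame = frame.sort_values(keys).reset_index(drop=True)
    wide = frame.pivot_table(
        index=["week", "relation"],
        columns="shift",
        values="density_pct",
        aggfunc="first",
    )
    contrasts = []
    for (week, relation), row in wide.iterrows():
        if "day" in row.index and "night" in row.index:
            day, night = row.get("day"), row.get("night")
            if pd.notna(day) and pd.notna(night):
                contrasts.append(
                    {
                        "week": week,
                        "relation": relation,
                        "night_minus_day_density": night - day,
                    }
                )
    return MetricsSeries(table=frame, contrasts=pd.DataFrame(contrasts))


def summarize_qap_panel(
    panel: Sequence[QapResult], alpha: float = 0.05
) -> list[BoxplotSummary]:
    """Boxplot statistics of observed QAP correlations per (pair x shift).

    Quartiles use inclusive linear interpolation (the even-count median is
    the midpoint of the two central values); the significant count applies
    the two-sided p-value at ``alpha``. Groups are ordered by relation pair
    then night before day.
    """
    if not panel:
        raise ConfigurationError("empty QAP panel")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    groups: dict[tuple[tuple[str, str], str], list[QapResult]] = {}
    for res in panel:
        shift = res.shift or "all"
        groups.setdefault((res.relation_pair, shift), []).append(res)
    out = []
    shift_order = {"night": 0, "day": 1, "all": 2}
    for (pair, shift) in sorted(
        groups, key=lambda k: (k[0], shift_order.get(k[1], 3))
    ):
        rs = np.array([r.r_obs for r in groups[(pair, shift)]])
        q1, med, q3 = np.percentile(rs, [25, 50, 75], method=QUARTILE_METHOD)
        out.append(
            BoxplotSummary(
                pair=pair,
                shift=shift,
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                minimum=float(rs.min()),
                maximum=float(rs.max()),
                count=len(rs),
                n_significant=int(
                    sum(r.p_two_sided < alpha for r in groups[(pair, shift)])
                ),
                alpha=alpha,
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[BoxplotSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": "~".join(s.pair),
                "shift": s.shift,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "min": s.minimum,
                "max": s.maximum,
                "count": s.count,
                "n_significant": s.n_significant,
                "alpha": s.alpha,
                "quartile_method": QUARTILE_METHOD,
            }
            for s in summaries
        ]
    )


# ---------------------------------------------------------------------------
# sociograms
# ---------------------------------------------------------------------------


def build_sociogram(
    network: ShiftNetworkSet,
    relation: str,
    metrics: ShiftMetrics,
    layout_seed: int = 0,
) -> SociogramSpec:
    """Assemble the sociogram spec: sized nodes, weighted directed edges.

    Node size is an affine, strictly increasing map of in-degree centrality;
    edge width an affine, strictly increasing map of reported frequency.
    Isolates are flagged and given a separate layout group so renderers can
    place them apart from the connected component.
    """
    if relation not in RELATIONS:
        raise ConfigurationError(f"unknown relation {relation!r}")
    if metrics.shift_id != network.roster.shift_id or metrics.relation != relation:
        raise ConfigurationError("metrics do not correspond to this network/relation")
    idx = network.roster.index()
    isolates = set(metrics.isolates)
    nodes = []
    for pid, role in network.roster.members:
        in_deg = metrics.in_degree.get(pid, math.nan)
        size_basis = 0.0 if math.isnan(in_deg) else in_deg
        nodes.append(
            {
                "id": pid,
                "role": role,
                "in_degree": 0.0 if math.isnan(in_deg) else float(in_deg),
                "size": NODE_SIZE_MIN + NODE_SIZE_SLOPE * size_basis,
                "isolate": pid in isolates,
                "layout_group": "isolates" if pid in isolates else "core",
            }
        )
    w = network.matrices[relation]
    edges = []
    for source, i in idx.items():
        for target, j in idx.items():
            if i == j:
                continue
            value = w[i, j]
            if np.isfinite(value) and value >= 1:
                edges.append(
                    {
                        "source": source,
                        "target": target,
                        "weight": int(value),
                        "width": EDGE_WIDTH_MIN + EDGE_WIDTH_SLOPE * float(value),
                    }
                )
    return SociogramSpec(
        shift_id=network.roster.shift_id,
        relation=relation,
        nodes=tuple(nodes),
        edges=tuple(edges),
        layout_seed=layout_seed,
    )


def sociogram_graph(spec: SociogramSpec) -> nx.DiGraph:
    """Materialize the spec as a networkx directed graph with attributes."""
    g = nx.DiGraph(shift_id=spec.shift_id, relation=spec.relation,
                   layout_seed=spec.layout_seed)
    for node in spec.nodes:
        g.add_node(
            node["id"],
            role=node["role"],
            in_degree=float(node["in_degree"]),
            size=float(node["size"]),
            isolate=bool(node["isolate"]),
            layout_group=node["layout_group"],
        )
    for edge in spec.edges:
        g.add_edge(
            edge["source"], edge["target"],
            weight=int(edge["weight"]), width=float(edge["width"]),
        )
    return g


def _write_dot(spec: SociogramSpec, path: Path) -> None:
    # Hand-rolled writer: the DOT grammar needed here is a flat attribute list.
    lines = [f'digraph "{spec.shift_id}_{spec.relation}" {{']
    for node in spec.nodes:
        attrs = (
            f'role="{node["role"]}", in_degree={node["in_degree"]:.4f}, '
            f'width={node["size"] / 10.0:.3f}, '
            f'group="{node["layout_group"]}"'
        )
        lines.append(f'  "{node["id"]}" [{attrs}];')
    for edge in spec.edges:
        lines.append(
            f'  "{edge["source"]}" -> "{edge["target"]}" '
            f'[weight={edge["weight"]}, penwidth={edge["width"]:.3f}];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_sociogram(
    network: ShiftNetworkSet,
    relation: str,
    metrics: ShiftMetrics,
    outdir: str | Path,
    layout_seed: int = 0,
) -> SociogramSpec:
    """Write GraphML and DOT sociogram files; returns the spec written.

    The canonical artifacts are these attribute-complete text graphs; PNG
    rendering (:func:`render_sociogram`) is an optional thin layer on top.
    """
    spec = build_sociogram(network, relation, metrics, layout_seed=layout_seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{spec.shift_id}_{relation}"
    nx.write_graphml(sociogram_graph(spec), outdir / f"{stem}.graphml")
    _write_dot(spec, outdir / f"{stem}.dot")
    return spec


def sociogram_layout(spec: SociogramSpec) -> dict[str, tuple[float, float]]:
    """Deterministic positions: spring layout for the core, isolates in a side column."""
    g = sociogram_graph(spec)
    core = [n["id"] for n in spec.nodes if not n["isolate"]]
    isolates = [n["id"] for n in spec.nodes if n["isolate"]]
    pos: dict[str, tuple[float, float]] = {}
    if core:
        sub = g.subgraph(core)
        pos.update(
            {
                k: (float(x), float(y))
                for k, (x, y) in nx.spring_layout(sub, seed=spec.layout_seed).items()
            }
        )
    for rank, pid in enumerate(isolates):
        pos[pid] = (-1.6, 1.4 - 0.35 * rank)  # apart from the connected component
    return pos


def render_sociogram(spec: SociogramSpec, path: str | Path) -> Path:
    """Render the sociogram to an image file via matplotlib (optional layer)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = sociogram_graph(spec)
    pos = sociogram_layout(spec)
    fig, ax = plt.subplots(figsize=(8, 6))
    sizes = [g.nodes[n]["size"] * 12 for n in g.nodes]
    widths = [g.edges[e]["width"] for e in g.edges]
    nx.draw_networkx_nodes(g, pos, node_size=sizes, node_color="#7fa8d9", ax=ax)
    nx.draw_networkx_edges(g, pos, width=widths, alpha=0.5, arrowsize=8, ax=ax)
    nx.draw_networkx_labels(g, pos, font_size=7, ax=ax)
    ax.set_title(f"{spec.shift_id} — {spec.relation}")
    ax.axis("off")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def write_report(
    series: MetricsSeries,
    summaries: Iterable[BoxplotSummary],
    outdir: str | Path,
    manifest_extra: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write the metric series, contrasts, QAP summaries and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": outdir / "metrics_series.csv",
        "contrasts": outdir / "density_contrasts.csv",
        "qap_summary": outdir / "qap_summary.csv",
        "manifest": outdir / "report_manifest.json",
    }
    series.table.to_csv(paths["metrics"], index=False)
    series.contrasts.to_csv(paths["contrasts"], index=False)
    summaries_to_frame(summaries).to_csv(paths["qap_summary"], index=False)
    manifest = {
        "conventions": {
            "quartiles": QUARTILE_METHOD,
            "node_size": f"{NODE_SIZE_MIN} + {NODE_SIZE_SLOPE} * in_degree",
            "edge_width": f"{EDGE_WIDTH_MIN} + {EDGE_WIDTH_SLOPE} * frequency",
        },
        "n_metric_rows": int(len(series.table)),
        **(dict(manifest_extra) if manifest_extra else {}),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return paths
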