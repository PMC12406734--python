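"""Per-system interaction networks and reference-vs-variant edge comparison.

Each system (reference plus variants) gets a residue interaction network
whose edges carry max-aggregated H-bond strengths and salt-bridge
occupancies.  The union of candidate keys across all systems is evaluated
in every system, so an interaction absent from one system appears there
with strength 0.  Differential edges are then filtered and classified:

* an H-bond edge is reported iff its strength variation across systems
  (max minus min, in absolute percentage points) is >= 40 points;
* a salt-bridge edge is reported iff its occupancy exceeds 40 % of
  simulation time (strict) in at least one system;
* per variant, an edge is classified lost / gained / retained / absent by
  comparing reference and variant strengths against the same 40 % level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .fluctuation import TrimPolicy
from .interactions import (
    HBOND,
    SALTBRIDGE,
    InteractionCriteria,
    PairStatistic,
    hbond_statistics,
    residue_tag,
    salt_bridge_occupancy,
    salt_bridge_pairs,
    saltbridge_statistics,
)
from .structure_io import Ensemble

_STRICT_EPS = 1e-12


@dataclass
class InteractionNetwork:
    """One system's residues and interaction edges (both kinds)."""

    system_label: str
    nodes: list[tuple[str, int, str]]
    edges: list[PairStatistic]

    def __post_init__(self) -> None:
        node_keys = {(c, n) for c, n, _ in self.nodes}
        for e in self.edges:
            for c, n, _ in e.endpoints:
                if (c, n) not in node_keys:
                    raise ValueError(
                        f"edge {e.key} endpoint {(c, n)} missing from nodes"
                    )


@dataclass
class DifferentialEdge:
    """One interaction compared across the reference and variant systems."""

    key: str
    kind: str
    endpoints: tuple[tuple[str, int, str], tuple[str, int, str]]
    strength_by_system: dict[str, float]
    variation: float
    classification: dict[str, str]  # variant label -> lost/gained/retained/absent


def build_networks(
    ensemble: Ensemble,
    criteria: InteractionCriteria = InteractionCriteria(),
    trim: TrimPolicy = TrimPolicy(0.10),
) -> dict[str, InteractionNetwork]:
    """Interaction statistics per system over the union of candidate keys.

    H-bond edges are atom-level (donor atom, acceptor atom) keys; salt
    bridges are residue-level.  A key that is a candidate in any system is
    evaluated in all of them (occupancy recomputed where the pair exists
    topologically, zero strength where it does not).
    """
    per_system: dict[str, dict[tuple, PairStatistic]] = {}
    n_reps: dict[str, int] = {}
    for label, reps in ensemble.systems.items():
        n_reps[label] = len(reps)
        stats: dict[tuple, PairStatistic] = {}
        for s in hbond_statistics(reps, criteria, trim):
            stats[(HBOND, s.match_key)] = s
        for s in saltbridge_statistics(reps, criteria, trim):
            stats[(SALTBRIDGE, s.match_key)] = s
        per_system[label] = stats

    union_keys = sorted(
        {k for stats in per_system.values() for k in stats},
        key=lambda k: (k[0], k[1]),
    )
    networks: dict[str, InteractionNetwork] = {}
    for label, reps in ensemble.systems.items():
        stats = per_system[label]
        sb_pairs = {p.key: p for p in salt_bridge_pairs(reps[0].system)}
        edges: list[PairStatistic] = []
        for kind, mkey in union_keys:
            stat = stats.get((kind, mkey))
            if stat is None and kind == SALTBRIDGE and mkey in sb_pairs:
                # candidate elsewhere only: evaluate occupancy here anyway
                stat = salt_bridge_occupancy(reps, sb_pairs[mkey], criteria, trim)
            if stat is None:
                donor = next(
                    s for other in per_system.values()
                    for (k2, m2), s in other.items()
                    if k2 == kind and m2 == mkey
                )
                stat = PairStatistic(
                    key=donor.key,
                    kind=kind,
                    per_replicate_strength=(0.0,) * n_reps[label],
                    endpoints=donor.endpoints,
                    match_key=mkey,
                )
            edges.append(stat)
        networks[label] = InteractionNetwork(
            system_label=label,
            nodes=reps[0].system.residues,
            edges=edges,
        )
    return networks


def _above(value: float, threshold: float) -> bool:
    return value > threshold + _STRICT_EPS


def differential_edges(
    networks: dict[str, InteractionNetwork],
    reference_label: str,
    criteria: InteractionCriteria = InteractionCriteria(),
    hb_variation_mode: str = "spread",
) -> list[DifferentialEdge]:
    """Filter and classify edges across systems relative to the reference.

    ``hb_variation_mode='spread'`` (default) measures variation as the
    max-minus-min strength across all systems; ``'vs_reference'`` uses the
    largest absolute difference between any variant and the reference.
    """
    if reference_label not in networks:
        raise KeyError(f"reference label {reference_label!r} not among networks")
    if hb_variation_mode not in ("spread", "vs_reference"):
        raise ValueError(f"unknown hb_variation_mode {hb_variation_mode!r}")
    labels = list(networks)
    variants = [l for l in labels if l != reference_label]
    by_key: dict[tuple, dict[str, PairStatistic]] = {}
    for label in labels:
        for e in networks[label].edges:
            by_key.setdefault((e.kind, e.match_key), {})[label] = e

    out: list[DifferentialEdge] = []
    for (kind, mkey), stats in sorted(by_key.items()):
        strengths = {
            label: (stats[label].aggregated_strength if label in stats else 0.0)
            for label in labels
        }
        values = list(strengths.values())
        if hb_variation_mode == "spread" or kind == SALTBRIDGE:
            variation = max(values) - min(values)
        else:
            ref = strengths[reference_label]
            variation = max(abs(strengths[v] - ref) for v in variants)
        if kind == HBOND:
            reported = variation >= criteria.hb_variation_min - _STRICT_EPS
        else:
            reported = any(_above(v, criteria.sb_report_min) for v in values)
        if not reported:
            continue
        level = criteria.sb_report_min
        ref_above = _above(strengths[reference_label], level)
        classification = {}
        for v in variants:
            var_above = _above(strengths[v], level)
            if ref_above and var_above:
                classification[v] = "retained"
            elif ref_above and not var_above:
                classification[v] = "lost"
            elif var_above:
                classification[v] = "gained"
            else:
                classification[v] = "absent"
        exemplar = next(iter(stats.values()))
        out.append(
            DifferentialEdge(
                key=exemplar.key,
                kind=kind,
                endpoints=exemplar.endpoints,
                strength_by_system=strengths,
                variation=float(variation),
                classification=classification,
            )
        )
    out.sort(key=_edge_order)
    return out


def _edge_order(e: DifferentialEdge):
    (c1, n1, _), (c2, n2, _) = e.endpoints
    return (e.kind, min(n1, n2), max(n1, n2), c1, c2, e.key)


def differential_table(edges: list[DifferentialEdge]) -> pd.DataFrame:
    """diffnet.tsv contents: one row per reported differential edge."""
    rows = []
    for e in sorted(edges, key=_edge_order):
        row = {"key": e.key, "kind": e.kind, "variation": round(e.variation, 6)}
        for label, s in e.strength_by_system.items():
            row[f"strength_{label}"] = round(s, 6)
        for v, c in e.classification.items():
            row[f"class_{v}"] = c
        rows.append(row)
    columns = None
    if rows:
        columns = list(rows[0])
    elif edges == []:
        columns = ["key", "kind", "variation"]
    return pd.DataFrame(rows, columns=columns)


def export_network(
    edges: list[DifferentialEdge],
    tsv_path: str | Path | None = None,
    graphml_path: str | Path | None = None,
) -> None:
    """Write the differential edge table and/or a GraphML interchange file.

    Ordering is deterministic (kind, then residue numbers ascending); an
    empty edge list writes a header-only table / empty graph.
    """
    edges = sorted(edges, key=_edge_order)
    if tsv_path is not None:
        differential_table(edges).to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        g = nx.MultiGraph()
        for e in edges:
            nodes = []
            for chain, num, name in e.endpoints:
                node = f"{chain}:{num}:{name}"
                g.add_node(node, chain=chain, residue_number=num, residue_name=name)
                nodes.append(node)
            attrs = {
                "kind": e.kind,
                "variation": round(e.variation, 6),
            }
            for label, s in e.strength_by_system.items():
                attrs[f"strength_{label}"] = round(s, 6)
            for v, c in e.classification.items():
                attrs[f"class_{v}"] = c
            g.add_edge(nodes[0], nodes[1], key=f"{e.kind}:{e.key}", **attrs)
        nx.write_graphml(g, graphml_path)
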