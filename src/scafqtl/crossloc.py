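"""Cross-location QTL regions.

A QTL region groups representative QTL-markers from the per-location
MultiQTL models of one trait that are correlated at |r| >= 0.3 across
locations.  Regions are connected components of the graph whose nodes are
representative markers and whose edges join markers from different locations
with |r| above threshold; components spanning at least two locations are
reported.  Component (single-linkage) grouping can chain markers whose
direct correlation falls below threshold; such regions are flagged.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .ld import DEFAULT_R_COLLINEAR
from .types import MarkerPanel, MultiQTLModel, QTLRegion, split_marker_id


def match_regions(
    models: list[MultiQTLModel],
    panel: MarkerPanel | pd.DataFrame,
    r_collinear: float = DEFAULT_R_COLLINEAR,
) -> list[QTLRegion]:
    """Cross-location QTL regions for one trait.

    ``models`` are the per-location MultiQTL models of a single trait (>= 2
    locations required).  The same marker id appearing in several locations
    is trivially connected.  Output is deterministic and invariant to the
    order in which the models are supplied: regions are sorted by location
    count (descending) then smallest member marker id, and numbered
    ``QTL_<trait>1, QTL_<trait>2, ...``.
    """
    traits = {m.trait for m in models}
    if len(traits) != 1:
        raise ValueError(f"models span several traits: {sorted(traits)}")
    trait = traits.pop()
    locations = {m.location for m in models}
    if len(locations) < 2:
        raise ValueError("need MultiQTL models from at least two locations")
    scores = panel.scores if isinstance(panel, MarkerPanel) else panel

    marker_locs: dict[str, set[str]] = {}
    for m in sorted(models, key=lambda m: m.location):
        for rep in m.representatives:
            marker_locs.setdefault(rep, set()).add(m.location)

    graph = nx.Graph()
    graph.add_nodes_from(marker_locs)
    ids = sorted(marker_locs)
    if ids:
        sub = scores[ids].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(np.atleast_2d(np.corrcoef(sub, rowvar=False)))
        for i, j in itertools.combinations(range(len(ids)), 2):
            a, b = ids[i], ids[j]
            # an edge needs a cross-location pair: forbidden only when both
            # markers come from the same single location
            cross = not (len(marker_locs[a]) == 1 and marker_locs[a] == marker_locs[b])
            if cross and corr[i, j] >= r_collinear:
                graph.add_edge(a, b, r=float(corr[i, j]))

    regions: list[QTLRegion] = []
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        locs: set[str] = set()
        for mid in comp:
            locs |= marker_locs[mid]
        if len(locs) < 2:
            continue
        by_loc: dict[str, list[str]] = {}
        for mid in comp:
            for loc in sorted(marker_locs[mid]):
                by_loc.setdefault(loc, []).append(mid)
        for loc in by_loc:
            by_loc[loc] = sorted(by_loc[loc])
        # chaining check: any cross-location pair inside the component whose
        # direct correlation is below threshold was joined only transitively
        chained = False
        for a, b in itertools.combinations(comp, 2):
            cross = not (len(marker_locs[a]) == 1 and marker_locs[a] == marker_locs[b])
            if cross and not graph.has_edge(a, b):
                chained = True
                break
        scaffolds = sorted({split_marker_id(mid)[0] for mid in comp})
        regions.append(
            QTLRegion(
                region_id="",
                trait=trait,
                markers_by_location={loc: by_loc[loc] for loc in sorted(by_loc)},
                n_locations=len(locs),
                scaffolds=scaffolds,
                chained=chained,
            )
        )
    regions.sort(key=lambda r: (-r.n_locations, r.markers[0]))
    for i, region in enumerate(regions, start=1):
        region.region_id = f"QTL_{trait}{i}"
    return regions


def regions_table(regions: list[QTLRegion], locations: list[str]) -> pd.DataFrame:
    """Tabular view: one row per region, one column of ;-joined markers per
    location (the layout used to report regions across test sites)."""
    rows = []
    for r in regions:
        row = {"region_id": r.region_id, "trait": r.trait, "n_locations": r.n_locations,
               "chained": r.chained}
        for loc in locations:
            row[loc] = ";".join(r.markers_by_location.get(loc, [])) or "-"
        rows.append(row)
    return pd.DataFrame(rows, columns=["region_id", "trait", "n_locations", "chained", *locations])


def cross_trait_overlap(regions_by_trait: dict[str, list[QTLRegion]]) -> pd.DataFrame:
    """Regions of different traits sharing representative markers or scaffolds.

    Returns one row per (trait pair, region pair) with the shared marker ids
    and shared scaffolds; empty when all regions are disjoint.
    """
    rows = []
    traits = sorted(regions_by_trait)
    for ta, tb in itertools.combinations(traits, 2):
        for ra in regions_by_trait[ta]:
            markers_a = set(ra.markers)
            scaff_a = set(ra.scaffolds)
            for rb in regions_by_trait[tb]:
                shared_m = sorted(markers_a & set(rb.markers))
                shared_s = sorted(scaff_a & set(rb.scaffolds))
                if shared_m or shared_s:
                    rows.append(
                        {
                            "trait_a": ta,
                            "trait_b": tb,
                            "region_a": ra.region_id,
                            "region_b": rb.region_id,
                            "shared_markers": ";".join(shared_m),
                            "shared_scaffolds": ";".join(shared_s),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["trait_a", "trait_b", "region_a", "region_b", "shared_markers", "shared_scaffolds"],
    )
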