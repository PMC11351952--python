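"""Metabolite-level profiling: VIP selection, region integration, heatmaps.

Bins whose mean VIP exceeds 1.5 in at least one pairwise comparison mark the
metabolites driving group separation.  Named chemical-shift regions are then
integrated on the normalized bin matrix (a bin belongs to a region when its
midpoint falls inside one of the region's intervals) and expressed as a
percentage of the control-group mean, yielding the tables behind the usual
heatmap and boxplot figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohortsim import MetaboliteSpec
from .preproc import BinMatrix

__all__ = [
    "MetaboliteRegion",
    "MetabolitePanel",
    "regions_from_specs",
    "select_bins",
    "integrate_regions",
    "normalize_to_control",
    "heatmap_table",
]


@dataclass(frozen=True)
class MetaboliteRegion:
    """A named metabolite as a set of non-overlapping ppm intervals."""

    name: str
    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ValueError(f"{self.name}: overlapping intervals {ivs}")
        for a, b in ivs:
            if b <= a:
                raise ValueError(f"{self.name}: empty interval ({a}, {b})")


@dataclass
class MetabolitePanel:
    """Per-sample metabolite levels, optionally as percent of control mean."""

    levels: pd.DataFrame  # index sample_id, columns metabolite names
    groups: pd.Series  # sample_id -> group label
    state: str = "level"  # "level" | "percent"
    control_group: str | None = None


def regions_from_specs(
    specs: tuple[MetaboliteSpec, ...] | list[MetaboliteSpec],
    pad_linewidths: float = 1.0,
) -> list[MetaboliteRegion]:
    """Region table derived from simulator metabolite definitions.

    Each multiplet contributes its line span padded by ``pad_linewidths``
    linewidths; this is the same rule the simulator's ground truth uses, so
    recovery tests close the loop.  For real data, hand-edit or replace.
    """
    return [
        MetaboliteRegion(s.name, tuple(s.intervals(pad_linewidths))) for s in specs
    ]


def select_bins(vips: dict[str, np.ndarray], threshold: float = 1.5) -> np.ndarray:
    """Bins with mean VIP above threshold in at least one comparison.

    ``vips`` maps comparison label → per-bin mean VIP vector (all the same
    length); returns the sorted union of selected bin indices.
    """
    if not vips:
        raise ValueError("no VIP aggregates given")
    lengths = {v.shape[0] for v in map(np.asarray, vips.values())}
    if len(lengths) != 1:
        raise ValueError(f"VIP vectors disagree in length: {sorted(lengths)}")
    hits: set[int] = set()
    for v in vips.values():
        hits.update(np.nonzero(np.asarray(v) > threshold)[0].tolist())
    return np.array(sorted(hits), dtype=int)


def integrate_regions(
    m: BinMatrix,
    regions: list[MetaboliteRegion],
    design: pd.DataFrame,
) -> MetabolitePanel:
    """Sum normalized bin integrals over each region's bins, per sample."""
    if m.state != "normalized":
        raise ValueError(f"integrate_regions requires state='normalized', got {m.state!r}")
    mids = m.bin_midpoints
    cols = {}
    for r in regions:
        mask = np.zeros(mids.size, dtype=bool)
        for a, b in r.intervals:
            mask |= (mids >= a) & (mids < b)
        if not mask.any():
            raise ValueError(f"region {r.name!r} covers no bins")
        cols[r.name] = m.values[:, mask].sum(axis=1)
    levels = pd.DataFrame(cols, index=pd.Index(m.sample_ids, name="sample_id"))
    groups = design.set_index("sample_id")["group"].reindex(levels.index)
    if groups.isna().any():
        missing = levels.index[groups.isna()].tolist()
        raise ValueError(f"design has no group for samples {missing}")
    return MetabolitePanel(levels=levels, groups=groups, state="level")


def normalize_to_control(panel: MetabolitePanel, control_group: str = "WT/CD") -> MetabolitePanel:
    """Express levels as percent of the control group's mean level."""
    if panel.state != "level":
        raise ValueError("panel already normalized")
    ctrl = panel.levels[panel.groups == control_group]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} not present")
    mean = ctrl.mean(axis=0)
    if (mean == 0).any():
        bad = mean.index[mean == 0].tolist()
        raise ValueError(f"control mean is zero for {bad}")
    return MetabolitePanel(
        levels=100.0 * panel.levels / mean,
        groups=panel.groups,
        state="percent",
        control_group=control_group,
    )


def heatmap_table(
    panel: MetabolitePanel,
    group_order: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Group × metabolite table of mean percent-of-control levels."""
    if panel.state != "percent":
        raise ValueError("heatmap_table requires a percent-normalized panel")
    tab = panel.levels.groupby(panel.groups).mean()
    if group_order is not None:
        tab = tab.loc[list(group_order)]
    tab.index.name = "group"
    return tab
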