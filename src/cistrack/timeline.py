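"""Global maturation timeline from pairwise peak-to-peak delays.

Each two-colour experiment measures the mean delay between the intensity
peaks of one marker pair on single cisternae. Placing all markers on one
time axis from such pairwise offsets is a classic graph synchronization
problem: with t_i the unknown peak time of marker i and Delta_ij the
measured early->late delay, minimize

    sum_ij w_ij (t_j - t_i - Delta_ij)^2,   t_anchor = 0,

a weighted least-squares fit on the pairwise-offset graph. Consistent
inputs are reproduced exactly; inconsistent cycles (delays measured in
different experiments never close perfectly) are reconciled, with per-edge
residuals quantifying the tension. The default weights n/sd^2 trust each
edge according to its sample size and spread, with the SD floored at one
frame interval so near-zero printed SDs cannot dominate.

The module ships a transcription of the published pairwise delay table
(``load_reference_delays``); the second, late-Golgi appearance of Ypt1 is
kept as a separate marker ``Ypt1.2`` so the two visits are not conflated.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PairwiseDelay",
    "Timeline",
    "assemble_timeline",
    "order_markers",
    "load_reference_delays",
    "canonical_label",
    "plot_timeline",
]

_TAG_TOKENS = {
    "gfp",
    "egfp",
    "yegfp",
    "2xgfp",
    "2xegfp",
    "mcherry",
    "2xmcherry",
    "irfp",
    "tagrfp",
    "mrfp",
}


def canonical_label(label: str) -> str:
    """Strip fluorophore-tag tokens from a construct label.

    'EGFP-Emp46' -> 'Emp46', 'Grh1-2xmCherry' -> 'Grh1', so the same
    protein measured with different tags is merged under one marker name.
    """
    parts = [p for p in re.split(r"[-_ ]", label.strip()) if p]
    kept = [p for p in parts if p.lower() not in _TAG_TOKENS]
    return "-".join(kept) if kept else label.strip()


@dataclass(frozen=True)
class PairwiseDelay:
    """Mean peak-to-peak delay (s) from ``early`` to ``late`` marker."""

    early: str
    late: str
    mean_s: float
    sd_s: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.early == self.late:
            raise ValueError(f"self-delay for marker {self.early!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_s < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class Timeline:
    """Inferred common-axis peak times, anchor at 0, with edge residuals."""

    anchor: str
    times: dict[str, float]
    edges: pd.DataFrame  # early, late, mean_s, weight, fitted_s, residual_s
    weighted_rms_residual_s: float
    unplaced: list[str]


def _weights(delays: list[PairwiseDelay], weighting: str, sd_floor: float) -> np.ndarray:
    if weighting == "equal":
        return np.ones(len(delays))
    if weighting == "inverse_variance":
        return np.array([d.n / max(d.sd_s, sd_floor) ** 2 for d in delays])
    raise ValueError("weighting must be 'equal' or 'inverse_variance'")


def assemble_timeline(
    delays: list[PairwiseDelay],
    anchor: str,
    weighting: str = "inverse_variance",
    sd_floor: float = 5.0,
) -> Timeline:
    """Weighted least-squares placement of all markers on one time axis.

    Only the connected component containing ``anchor`` is placed; markers
    outside it are listed as unplaced. The anchor's time is exactly 0.
    """
    if not delays:
        raise ValueError("no delays given")
    graph = nx.Graph()
    for d in delays:
        graph.add_edge(d.early, d.late)
    if anchor not in graph:
        raise ValueError(f"anchor {anchor!r} appears in no delay")
    component = nx.node_connected_component(graph, anchor)
    placed = sorted(component)
    unplaced = sorted(set(graph.nodes) - component)
    in_comp = [d for d in delays if d.early in component]
    idx = {m: i for i, m in enumerate(placed)}

    w = _weights(in_comp, weighting, sd_floor)
    a_mat = np.zeros((len(in_comp), len(placed)))
    rhs = np.empty(len(in_comp))
    for r, d in enumerate(in_comp):
        a_mat[r, idx[d.late]] += 1.0
        a_mat[r, idx[d.early]] -= 1.0
        rhs[r] = d.mean_s
    free = [i for i, m in enumerate(placed) if m != anchor]
    sw = np.sqrt(w)
    sol, *_ = np.linalg.lstsq(a_mat[:, free] * sw[:, None], rhs * sw, rcond=None)
    times = {anchor: 0.0}
    for i, col in enumerate(free):
        times[placed[col]] = float(sol[i])

    fitted = np.array([times[d.late] - times[d.early] for d in in_comp])
    residual = fitted - rhs
    edges = pd.DataFrame(
        {
            "early": [d.early for d in in_comp],
            "late": [d.late for d in in_comp],
            "mean_s": rhs,
            "weight": w,
            "fitted_s": fitted,
            "residual_s": residual,
        }
    )
    rms = float(np.sqrt(np.sum(w * residual**2) / np.sum(w)))
    return Timeline(
        anchor=anchor,
        times=times,
        edges=edges,
        weighted_rms_residual_s=rms,
        unplaced=unplaced,
    )


def order_markers(timeline: Timeline) -> list[str]:
    """Marker labels sorted by inferred peak time (ties alphabetical).

    Exact ties are resolved alphabetically and reported with a warning.
    """
    items = sorted(timeline.times.items(), key=lambda kv: (kv[1], kv[0]))
    by_time: dict[float, list[str]] = {}
    for label, t in items:
        by_time.setdefault(t, []).append(label)
    for t, labels in by_time.items():
        if len(labels) > 1:
            warnings.warn(
                f"tied peak time {t:g} s for markers {labels}; ordered alphabetically",
                stacklevel=2,
            )
    return [label for label, _ in items]


def load_reference_delays(
    path: str | Path | None = None, merge_tag_variants: bool = True
) -> list[PairwiseDelay]:
    """Load a pairwise-delay table (default: the bundled published table).

    With ``merge_tag_variants`` the canonical marker columns are used (the
    same protein under different fluorophore tags becomes one marker);
    otherwise the raw construct labels are kept distinct.
    """
    if path is None:
        with resources.files("cistrack.data").joinpath("peak_delays.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    if merge_tag_variants and {"early", "late"} <= set(table.columns):
        early_col, late_col = "early", "late"
    elif {"early_label", "late_label"} <= set(table.columns):
        early_col, late_col = "early_label", "late_label"
    else:
        early_col, late_col = "early", "late"
    out = []
    for _, row in table.iterrows():
        early, late = str(row[early_col]), str(row[late_col])
        if merge_tag_variants and early_col == "early_label":
            early, late = canonical_label(early), canonical_label(late)
        out.append(
            PairwiseDelay(
                early=early,
                late=late,
                mean_s=float(row["mean_s"]),
                sd_s=float(row.get("sd_s", 0.0)),
                n=int(row.get("n", 1)),
            )
        )
    return out


def plot_timeline(timeline: Timeline, path: str | Path) -> None:
    """Simple horizontal timeline figure (one marker per row)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = order_markers(timeline)
    times = [timeline.times[m] for m in order]
    fig, ax = plt.subplots(figsize=(7, 0.3 * len(order) + 1.5))
    for i, (m, t) in enumerate(zip(order, times)):
        ax.plot([min(times), t], [i, i], color="0.8", lw=1)
        ax.plot(t, i, "o", color="tab:blue")
        ax.annotate(f" {t:+.1f} s", (t, i), fontsize=8, va="center")
    ax.set_yticks(range(len(order)), order)
    ax.invert_yaxis()
    ax.set_xlabel(f"peak time relative to {timeline.anchor} (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
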