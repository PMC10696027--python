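"""Threshold sweep against Erdos-Renyi null ensembles and critical-point detection.

Sweeping the similarity cut-off from the floor to 1 traces the network
through a percolation-like transition: betweenness rises to a peak where the
giant component assembles and then collapses as edges densify. The peak
(equivalently the giant-component onset) marks the critical threshold, used
as the "optimal" cut-off for downstream community and classification work.
Each threshold's CSN is paired with an ensemble of uniform G(N, E) graphs at
the same edge count, so deviations from the null (notably elevated
assortativity from similarity transitivity) are density-controlled.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from csncrit.mcs import SimilarityStore
from csncrit.network import (
    ThresholdNetwork,
    assortativity,
    build_network,
    centrality_profile,
    giant_component_fraction,
    sample_er,
)

METRICS = (
    "mean_degree",
    "mean_betweenness",
    "mean_eigenvector",
    "giant_fraction",
    "assortativity",
)

CRITERIA = ("betweenness_peak", "assortativity_peak", "giant_onset")


def default_grid(floor: float = 0.30, stop: float = 1.00, step: float = 0.01) -> np.ndarray:
    """Threshold grid from the similarity floor to 1 (inclusive)."""
    n = int(round((stop - floor) / step)) + 1
    return np.round(np.linspace(floor, stop, n), 10)


def scale_unit(series: Sequence[float]) -> np.ndarray:
    """Min-max rescale a curve into [0, 1]; a constant curve maps to zeros.

    NaNs (undefined points, e.g. assortativity of an edgeless graph) are
    ignored for the min/max and preserved in place.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot scale an empty series")
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        return x.copy()
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        out = np.where(np.isfinite(x), 0.0, np.nan)
        return out
    return (x - lo) / (hi - lo)


def _summaries(net: ThresholdNetwork) -> dict[str, float]:
    prof = centrality_profile(net)
    r = assortativity(net)
    return {
        "E": float(net.e),
        "p": net.p,
        "mean_degree": prof.mean_degree,
        "mean_betweenness": prof.mean_betweenness,
        "mean_eigenvector": prof.mean_eigenvector,
        "giant_fraction": giant_component_fraction(net),
        "assortativity": np.nan if r is None else r,
    }


@dataclass
class SweepResult:
    """Per-threshold CSN and ER-ensemble diagnostics.

    ``csn[metric]`` and ``er_mean[metric]`` / ``er_sd[metric]`` are arrays
    aligned with ``thresholds``; ``scaled_csn`` / ``scaled_er`` carry the
    min-max rescaled curves used for cross-metric comparison. Undefined
    values (assortativity on edgeless/regular graphs) are NaN.
    """

    thresholds: np.ndarray
    n_nodes: int
    n_er: int
    csn: dict[str, np.ndarray]
    er_mean: dict[str, np.ndarray]
    er_sd: dict[str, np.ndarray]
    scaled_csn: dict[str, np.ndarray] = field(default_factory=dict)
    scaled_er: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def p(self) -> np.ndarray:
        return self.csn["p"]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["threshold", "p", "model", "metric", "value", "sd"])
            for k, t in enumerate(self.thresholds):
                for metric in ("E",) + METRICS:
                    writer.writerow(
                        [t, self.csn["p"][k], "csn", metric, self.csn[metric][k], ""]
                    )
                    writer.writerow(
                        [t, self.csn["p"][k], "er", metric,
                         self.er_mean[metric][k], self.er_sd[metric][k]]
                    )


def threshold_sweep(
    store: SimilarityStore,
    grid: Sequence[float] | None = None,
    n_er: int = 20,
    seed: int = 0,
) -> SweepResult:
    """Sweep the similarity cut-off, pairing each CSN with a G(N, E) ensemble.

    For every threshold ``t`` in ``grid`` the CSN summaries are computed and
    ``n_er`` uniform random graphs with the identical edge count are
    summarised as ensemble mean and standard deviation. Deterministic for a
    fixed ``seed``: one sub-seed is fanned out per (threshold, replicate).
    """
    if grid is None:
        grid = default_grid(floor=store.floor)
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if n_er < 1:
        raise ValueError("need at least one ER replicate")
    if grid[0] < store.floor:
        raise ValueError(f"grid starts below the store floor {store.floor}")

    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(grid.size)

    csn = {m: np.empty(grid.size) for m in ("E", "p") + METRICS}
    er_mean = {m: np.empty(grid.size) for m in ("E", "p") + METRICS}
    er_sd = {m: np.empty(grid.size) for m in ("E", "p") + METRICS}

    for k, t in enumerate(grid):
        net = build_network(store, float(t))
        s = _summaries(net)
        for m, v in s.items():
            csn[m][k] = v
        rep_seeds = sub[k].spawn(n_er)
        reps = {m: [] for m in ("E", "p") + METRICS}
        for r in range(n_er):
            er = sample_er(net.n_nodes, net.e, seed=np.random.default_rng(rep_seeds[r]))
            es = _summaries(er)
            for m, v in es.items():
                reps[m].append(v)
        for m in reps:
            vals = np.asarray(reps[m], dtype=float)
            defined = vals[np.isfinite(vals)]
            er_mean[m][k] = defined.mean() if defined.size else np.nan
            er_sd[m][k] = defined.std(ddof=1) if defined.size > 1 else np.nan

    result = SweepResult(
        thresholds=grid,
        n_nodes=store.n_molecules,
        n_er=n_er,
        csn=csn,
        er_mean=er_mean,
        er_sd=er_sd,
    )
    for m in METRICS:
        result.scaled_csn[m] = scale_unit(csn[m])
        result.scaled_er[m] = scale_unit(er_mean[m])
    return result


@dataclass
class CriticalPoint:
    """The detected critical threshold and its connection probability."""

    t_crit: float
    p_crit: float
    criterion: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"t_crit": self.t_crit, "p_crit": self.p_crit, "criterion": self.criterion},
                indent=2,
            )
        )


class NoTransitionError(ValueError):
    """The sweep curve is flat; no critical point can be located."""


def detect_critical_point(
    sweep: SweepResult,
    criterion: str = "betweenness_peak",
    onset_fraction: float = 0.05,
) -> CriticalPoint:
    """Locate the critical threshold on the sweep grid.

    ``betweenness_peak`` and ``assortativity_peak`` take the argmax of the
    corresponding CSN curve; ``giant_onset`` takes the largest threshold at
    which the giant-component fraction still exceeds ``onset_fraction``.
    Ties break toward larger thresholds (sparser, higher-similarity graphs).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
    if sweep.thresholds.size < 3:
        raise ValueError("critical-point detection needs at least 3 grid points")

    if criterion == "giant_onset":
        mask = sweep.csn["giant_fraction"] > onset_fraction
        if not mask.any():
            raise NoTransitionError("giant-component fraction never exceeds the onset")
        k = int(np.max(np.nonzero(mask)[0]))
    else:
        metric = "mean_betweenness" if criterion == "betweenness_peak" else "assortativity"
        curve = sweep.csn[metric]
        finite = curve[np.isfinite(curve)]
        if finite.size == 0 or np.all(finite == finite[0]):
            raise NoTransitionError(f"{metric} curve is flat or undefined everywhere")
        best = np.nanmax(curve)
        k = int(np.max(np.nonzero(curve == best)[0]))  # tie -> larger t
    return CriticalPoint(
        t_crit=float(sweep.thresholds[k]),
        p_crit=float(sweep.csn["p"][k]),
        criterion=criterion,
    )
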