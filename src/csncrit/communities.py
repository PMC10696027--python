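"""Community detection at criticality and the descriptor screen.

Louvain modularity maximisation partitions the critical-threshold network
into structurally coherent communities ("archetypes"). Each community is
then profiled with molecular descriptors: near-constant descriptors are
filtered out, the remaining ones are compared across the top communities
with pairwise Mood's median tests under Bonferroni correction, and medians
with interquartile ranges summarise the significant ones.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from csncrit.network import ThresholdNetwork

logger = logging.getLogger(__name__)


@dataclass
class CommunityPartition:
    """A node partition with modularity and connectivity summaries."""

    assignment: dict[int, int]
    sizes: list[int]
    modularity: float
    fraction_connected: float

    def members(self, community: int) -> list[int]:
        return [n for n, c in self.assignment.items() if c == community]

    def top_communities(self, k: int) -> list[list[int]]:
        """Member lists of the k most populous communities, largest first."""
        groups: dict[int, list[int]] = {}
        for n, c in self.assignment.items():
            groups.setdefault(c, []).append(n)
        ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
        return ordered[:k]

    def to_files(self, csv_path: str | Path, json_path: str | Path) -> None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["node_id", "community"])
            for n in sorted(self.assignment):
                writer.writerow([n, self.assignment[n]])
        Path(json_path).write_text(
            json.dumps(
                {
                    "sizes": self.sizes,
                    "modularity": self.modularity,
                    "fraction_connected": self.fraction_connected,
                },
                indent=2,
            )
        )


def louvain_partition(net: ThresholdNetwork, seed: int = 0) -> CommunityPartition:
    """Louvain modularity maximisation at resolution 1 on the unweighted graph.

    Isolated nodes end up as singleton communities. The reported modularity
    is that of the returned partition; ``fraction_connected`` is the share
    of nodes with degree >= 1.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        communities = [{n} for n in g.nodes()]
        q = 0.0
    else:
        communities = nx.community.louvain_communities(g, resolution=1.0, seed=seed)
        q = nx.community.modularity(g, communities)
    assignment: dict[int, int] = {}
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    for cid, comm in enumerate(ordered):
        for n in comm:
            assignment[n] = cid
    degrees = dict(g.degree())
    return CommunityPartition(
        assignment=assignment,
        sizes=[len(c) for c in ordered],
        modularity=float(q),
        fraction_connected=sum(1 for d in degrees.values() if d >= 1) / g.number_of_nodes(),
    )


def modularity_direct(net: ThresholdNetwork, assignment: dict[int, int]) -> float:
    """Modularity from its definition, Q = sum_c [e_c/E - (d_c/2E)^2].

    Independent of the networkx routine; used as a cross-check.
    """
    g = net.graph
    e_total = g.number_of_edges()
    if e_total == 0:
        return 0.0
    within: dict[int, int] = {}
    deg_sum: dict[int, float] = {}
    for u, v in g.edges():
        if assignment[u] == assignment[v]:
            within[assignment[u]] = within.get(assignment[u], 0) + 1
    for n, d in g.degree():
        c = assignment[n]
        deg_sum[c] = deg_sum.get(c, 0.0) + d
    q = 0.0
    for c in set(assignment.values()):
        q += within.get(c, 0) / e_total - (deg_sum.get(c, 0.0) / (2 * e_total)) ** 2
    return q


def compute_descriptors(smiles: Sequence[str]) -> pd.DataFrame:
    """2D molecular descriptors for a list of SMILES (RDKit descriptor set).

    Returns a rectangular numeric table with one row per molecule; columns
    that fail to compute for some molecule are filled with NaN there.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        rows.append(Descriptors.CalcMolDescriptors(mol))
    table = pd.DataFrame(rows, dtype=float)
    table.attrs["provenance"] = "RDKit 2D descriptor set"
    return table


def descriptor_filter(
    table: pd.DataFrame, min_variability: float = 0.10
) -> pd.DataFrame:
    """Drop near-constant descriptors.

    A descriptor's variability is the fraction of molecules NOT sharing its
    modal value; columns with variability below ``min_variability`` (default
    10%) carry essentially no between-molecule information and are removed.
    """
    if table.shape[1] == 0:
        raise ValueError("empty descriptor table")
    keep = []
    dropped = []
    n = len(table)
    for col in table.columns:
        counts = table[col].value_counts(dropna=False)
        variability = (n - counts.iloc[0]) / n if n else 0.0
        # strict "<" with a tolerance so exact-boundary columns are kept
        if variability < min_variability - 1e-12:
            dropped.append(col)
        else:
            keep.append(col)
    if dropped:
        logger.info("descriptor filter dropped %d columns: %s", len(dropped), dropped[:20])
    if not keep:
        logger.warning("descriptor filter removed every column")
    return table[keep]


def moods_median_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Mood's median test across k groups.

    Pools all values, takes the grand median, and tabulates per group the
    counts above vs not-above (values equal to the grand median count as
    not-above). The statistic is the 2xk contingency chi-square with k-1
    degrees of freedom, no continuity correction.
    """
    if len(groups) < 2:
        raise ValueError("Mood's test needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    grand = np.median(pooled)
    above = np.array([np.sum(a > grand) for a in arrays], dtype=float)
    below = np.array([a.size - ab for a, ab in zip(arrays, above)], dtype=float)
    table = np.vstack([above, below])
    col_tot = table.sum(axis=0)
    row_tot = table.sum(axis=1)
    expected = np.outer(row_tot, col_tot) / table.sum()
    if np.any(expected == 0.0):
        raise ValueError("degenerate contingency table: zero expected count")
    chi2 = float(((table - expected) ** 2 / expected).sum())
    dof = len(groups) - 1
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, p


@dataclass
class ScreenResult:
    """Per-descriptor pairwise Mood p-values, significance flags and profiles."""

    pvalues: pd.DataFrame          # columns p12, p13, p23 (for top_k=3)
    significant: pd.Series         # bool per descriptor
    profiles: pd.DataFrame         # median_c*/iqr_c* per community
    alpha: float
    bonferroni_m: int
    community_sizes: list[int]
    failed: list[str] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.pvalues, self.significant.rename("significant"),
                         self.profiles], axis=1)
        out.index.name = "descriptor"
        out.to_csv(path)


def community_descriptor_screen(
    table: pd.DataFrame,
    part: CommunityPartition,
    top_k: int = 3,
    alpha: float = 0.01,
    min_members: int = 5,
) -> ScreenResult:
    """Screen descriptors for separation among the top-k communities.

    For each descriptor, all pairwise Mood's median tests among the ``top_k``
    most populous communities are run; the Bonferroni family is
    (number of descriptors) x (number of pairs), and a descriptor is flagged
    significant only when every pairwise test survives at ``alpha``. Medians
    and IQRs per community are reported regardless of the flag. Descriptors
    whose contingency table degenerates are recorded in ``failed``.
    """
    groups = part.top_communities(top_k)
    if len(groups) < top_k:
        raise ValueError(f"partition has only {len(groups)} communities, need {top_k}")
    for g in groups:
        if len(g) < min_members:
            raise ValueError(
                f"a top-{top_k} community has {len(g)} members (< {min_members})"
            )
    pairs = [(i, j) for i in range(top_k) for j in range(i + 1, top_k)]
    m = table.shape[1] * len(pairs)
    threshold = alpha / m

    pcols = {f"p{i + 1}{j + 1}": [] for i, j in pairs}
    prof_cols: dict[str, list[float]] = {}
    for c in range(top_k):
        prof_cols[f"median_c{c + 1}"] = []
        prof_cols[f"iqr_c{c + 1}"] = []
    sig = []
    failed = []

    for col in table.columns:
        samples = [table[col].iloc[g].dropna().to_numpy() for g in groups]
        ps = []
        ok = True
        for (i, j) in pairs:
            try:
                _, p = moods_median_test([samples[i], samples[j]])
            except ValueError:
                ok = False
                p = np.nan
            pcols[f"p{i + 1}{j + 1}"].append(p)
            ps.append(p)
        if not ok:
            failed.append(col)
            sig.append(False)
        else:
            sig.append(all(p < threshold for p in ps))
        for c in range(top_k):
            vals = samples[c]
            if vals.size:
                prof_cols[f"median_c{c + 1}"].append(float(np.median(vals)))
                q75, q25 = np.percentile(vals, [75, 25])
                prof_cols[f"iqr_c{c + 1}"].append(float(q75 - q25))
            else:
                prof_cols[f"median_c{c + 1}"].append(np.nan)
                prof_cols[f"iqr_c{c + 1}"].append(np.nan)

    return ScreenResult(
        pvalues=pd.DataFrame(pcols, index=table.columns),
        significant=pd.Series(sig, index=table.columns),
        profiles=pd.DataFrame(prof_cols, index=table.columns),
        alpha=alpha,
        bonferroni_m=m,
        community_sizes=[len(g) for g in groups],
        failed=failed,
    )
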