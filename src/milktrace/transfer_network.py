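"""Inter-compartment transfer networks from genus relative abundances.

Within each farm the strength of a putative microbial transfer between two
compartments is the Pearson correlation of genus relative abundances between
the two compartments' samples (genera absent from both are excluded).
Benjamini-Hochberg FDR control is applied over the whole farm x pair family;
significant edges form one signed weighted network per farm. Farm networks are
merged into a consensus network by abundance-proportional weight averaging,
with edge significance assessed by a farm-level bootstrap. A signed weighted
topological overlap (wTO) transform of the per-farm networks is available as
an optional stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import (
    COMPARTMENT_PAIRS,
    COMPARTMENTS,
    RelAbundanceTable,
    SampleMetadata,
    canonical_pair,
)

#: minimum genus columns for a defined correlation
MIN_GENERA = 3


@dataclass
class FarmEdgeEstimate:
    """One compartment-pair correlation within one farm."""

    farm: str
    pair: tuple[str, str]
    r: float | None
    p: float | None
    n_genera: int
    q: float | None = None
    significant: bool = False

    @property
    def defined(self) -> bool:
        return self.r is not None


@dataclass
class FarmNetwork:
    """Signed weighted 4-node network for one farm.

    ``weights`` holds one entry per *tested* pair: the correlation where
    significant, 0.0 where tested non-significant, NaN where the correlation
    was undefined (degenerate vectors). Untested pairs (a compartment missing
    from the farm) are absent from the mapping.
    """

    farm: str
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    present: frozenset[str] = frozenset(COMPARTMENTS)

    def weight(self, a: str, b: str) -> float:
        return self.weights.get(canonical_pair(a, b), float("nan"))

    def adjacency(self) -> pd.DataFrame:
        mat = pd.DataFrame(0.0, index=list(COMPARTMENTS), columns=list(COMPARTMENTS))
        for (a, b), w in self.weights.items():
            mat.loc[a, b] = mat.loc[b, a] = 0.0 if math.isnan(w) else w
        return mat


@dataclass
class ConsensusEdge:
    """Consensus weight for one compartment pair across farms."""

    pair: tuple[str, str]
    consensus_weight: float
    p_value: float
    n_farms: int  # farms contributing a non-zero weight
    farm_weights: dict[str, float]
    significant: bool = False


# ---------------------------------------------------------------------------
# per-farm estimation


def pair_correlation(
    relab_a: np.ndarray | pd.Series,
    relab_b: np.ndarray | pd.Series,
    transform: str | None = None,
) -> tuple[float | None, float | None, int]:
    """Pearson correlation of two genus-aligned proportion vectors.

    Genera absent (zero) in both compartments are excluded before the
    correlation; the two-sided p-value comes from the t reference distribution
    with ``n_genera - 2`` degrees of freedom. Returns ``(None, None, n)`` when
    fewer than 3 genera remain or a vector is constant. ``transform="log10"``
    applies log10(x + 1e-6) to the retained proportions before correlating.
    """
    a = np.asarray(relab_a, dtype=float)
    b = np.asarray(relab_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genus vectors must be aligned")
    keep = (a > 0) | (b > 0)
    a, b = a[keep], b[keep]
    n = int(keep.sum())
    if transform == "log10":
        a, b = np.log10(a + 1e-6), np.log10(b + 1e-6)
    elif transform is not None:
        raise ValueError(f"unknown abundance transform {transform!r}")
    if n < MIN_GENERA or np.ptp(a) == 0 or np.ptp(b) == 0:
        return None, None, n
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue), n


def farm_pair_estimates(
    relab: RelAbundanceTable,
    metadata: SampleMetadata,
    transform: str | None = None,
) -> list[FarmEdgeEstimate]:
    """All per-farm compartment-pair estimates from a merged abundance table.

    Samples of one (farm, compartment) are averaged into a single composition
    before correlating (the study design has one sample per compartment per
    farm, in which case this is the identity).
    """
    meta = metadata.for_samples(relab.samples)
    estimates: list[FarmEdgeEstimate] = []
    for farm in sorted(meta["farm"].unique()):
        farm_samples = meta.index[meta["farm"] == farm]
        comps: dict[str, np.ndarray] = {}
        for comp in COMPARTMENTS:
            rows = [
                s
                for s in farm_samples
                if meta.loc[s, "compartment"] == comp
            ]
            if rows:
                comps[comp] = relab.values.loc[rows].mean(axis=0).to_numpy()
        for pair in COMPARTMENT_PAIRS:
            a, b = pair
            if a not in comps or b not in comps:
                continue
            r, p, n = pair_correlation(comps[a], comps[b], transform=transform)
            estimates.append(FarmEdgeEstimate(farm=farm, pair=pair, r=r, p=p, n_genera=n))
    return estimates


def fdr_adjust(
    estimates: Sequence[FarmEdgeEstimate], alpha: float = 0.001, use_raw_p: bool = False
) -> list[FarmEdgeEstimate]:
    """Benjamini-Hochberg adjustment over the whole farm x pair family.

    An edge is significant when its BH-adjusted q (or raw p, with
    ``use_raw_p``) is strictly below ``alpha``.
    """
    defined = [e for e in estimates if e.p is not None]
    if not defined:
        raise ValueError("no defined p-values to adjust")
    pvals = np.array([e.p for e in defined])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for e, q in zip(defined, qvals):
        e.q = float(q)
        e.significant = (e.p if use_raw_p else e.q) < alpha
    return list(estimates)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (thin statsmodels wrapper)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def build_farm_network(estimates: Sequence[FarmEdgeEstimate]) -> FarmNetwork:
    """Assemble one farm's signed network from its (FDR-adjusted) estimates."""
    if not estimates:
        raise ValueError("no estimates for this farm")
    farms = {e.farm for e in estimates}
    if len(farms) != 1:
        raise ValueError(f"estimates span several farms: {sorted(farms)}")
    weights: dict[tuple[str, str], float] = {}
    present: set[str] = set()
    for e in estimates:
        present.update(e.pair)
        if not e.defined:
            weights[e.pair] = float("nan")
        else:
            weights[e.pair] = e.r if e.significant else 0.0
    return FarmNetwork(farm=next(iter(farms)), weights=weights, present=frozenset(present))


# ---------------------------------------------------------------------------
# wTO transform


def wto_transform(net: FarmNetwork) -> FarmNetwork:
    """Signed weighted topological overlap of a farm network.

    omega_ij = (a_ij + sum_u a_iu a_uj) / (min(k_i, k_j) + 1 - |a_ij|) with
    node strength k_i = sum_u |a_iu|; the shared-neighbour sum runs over the
    nodes u distinct from i and j.
    """
    adj = net.adjacency()
    nodes = [c for c in COMPARTMENTS if c in net.present]
    a = adj.loc[nodes, nodes].to_numpy()
    k = np.abs(a).sum(axis=1)
    out: dict[tuple[str, str], float] = {}
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            shared = sum(
                a[i, u] * a[u, j] for u in range(len(nodes)) if u not in (i, j)
            )
            denom = min(k[i], k[j]) + 1.0 - abs(a[i, j])
            out[canonical_pair(nodes[i], nodes[j])] = (a[i, j] + shared) / denom
    return FarmNetwork(farm=net.farm, weights=out, present=net.present)


# ---------------------------------------------------------------------------
# consensus


def _consensus_weight(weights: np.ndarray) -> float:
    """Abundance-proportional average: CN = sum_f alpha_f w_f with
    alpha_f = |w_f| / sum_g |w_g|; 0 when every weight is 0."""
    w = weights[~np.isnan(weights)]
    denom = np.abs(w).sum()
    if w.size == 0 or denom == 0:
        return 0.0
    return float((np.abs(w) / denom) @ w)


def consensus(
    nets: Sequence[FarmNetwork],
    n_boot: int = 2000,
    seed: int | None = 0,
    alpha: float = 0.001,
) -> list[ConsensusEdge]:
    """Merge farm networks into a consensus network.

    Nodes absent in any farm network are removed first. For each conserved
    pair the consensus weight is the abundance-proportional average of the
    per-farm weights (undefined farm edges are excluded from the weighting,
    not zero-filled). The p-value comes from a farm-level bootstrap: farms are
    resampled with replacement ``n_boot`` times and the two-sided p-value is
    ``2 * min(P(CN* <= 0), P(CN* >= 0))``, floored at ``1/(n_boot + 1)``.
    """
    if len(nets) < 2:
        raise ValueError("consensus needs at least 2 farm networks")
    conserved = frozenset.intersection(*(n.present for n in nets))
    pairs = [p for p in COMPARTMENT_PAIRS if p[0] in conserved and p[1] in conserved]
    rng = np.random.default_rng(seed)
    farms = [n.farm for n in nets]
    mat = np.array(
        [[n.weights.get(p, float("nan")) for p in pairs] for n in nets]
    )  # farms x pairs
    boot_idx = rng.integers(0, len(nets), size=(n_boot, len(nets)))

    edges: list[ConsensusEdge] = []
    for j, pair in enumerate(pairs):
        col = mat[:, j]
        cn = _consensus_weight(col)
        boot = np.array([_consensus_weight(col[idx]) for idx in boot_idx])
        p = 2.0 * min(np.mean(boot <= 0), np.mean(boot >= 0))
        p = min(1.0, max(p, 1.0 / (n_boot + 1)))
        n_support = int(np.sum(~np.isnan(col) & (col != 0)))
        edges.append(
            ConsensusEdge(
                pair=pair,
                consensus_weight=cn,
                p_value=float(p),
                n_farms=n_support,
                farm_weights={f: w for f, w in zip(farms, col)},
                significant=float(p) < alpha,
            )
        )
    return edges


def significant_links(
    edges: Sequence[ConsensusEdge], alpha: float = 0.001
) -> list[ConsensusEdge]:
    """Consensus edges with bootstrap p strictly below ``alpha``."""
    return [e for e in edges if e.p_value < alpha]


# ---------------------------------------------------------------------------
# tabular views


def edges_frame(estimates: Sequence[FarmEdgeEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "farm": e.farm,
                "compartment_a": e.pair[0],
                "compartment_b": e.pair[1],
                "r": np.nan if e.r is None else e.r,
                "p": np.nan if e.p is None else e.p,
                "q": np.nan if e.q is None else e.q,
                "n_genera": e.n_genera,
                "significant": e.significant,
            }
            for e in estimates
        ],
        columns=[
            "farm",
            "compartment_a",
            "compartment_b",
            "r",
            "p",
            "q",
            "n_genera",
            "significant",
        ],
    )


def consensus_frame(edges: Sequence[ConsensusEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compartment_a": e.pair[0],
                "compartment_b": e.pair[1],
                "consensus_weight": e.consensus_weight,
                "p_value": e.p_value,
                "n_farms": e.n_farms,
                "significant": e.significant,
            }
            for e in edges
        ],
        columns=[
            "compartment_a",
            "compartment_b",
            "consensus_weight",
            "p_value",
            "n_farms",
            "significant",
        ],
    )
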