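"""Community fingerprints, Hill-number diversity and multiplicative partitioning.

T-RFLP electropherograms are reduced to relative-abundance vectors (one OTU
per terminal-fragment size), and flume-level (gamma) diversity is
partitioned multiplicatively into within-microhabitat alpha and
among-microhabitat beta components using Hill numbers of order q, following
the effective-number framework of Jost.  Beta diversity — the effective
number of distinct communities — is the response variable linked to flow
heterogeneity downstream.

Conventions
-----------
* Hill number of order q: ``(sum p_i^q)^(1/(1-q))``, with the q -> 1 limit
  ``exp(H)`` where H is Shannon entropy (natural log).  q=0 is richness,
  q=2 the inverse Simpson concentration.
* Partitioning uses equally weighted communities (balanced microhabitat
  design): gamma from the pooled mean vector, alpha from the generalized
  mean of within-community sums, beta = gamma / alpha, so gamma = alpha*beta
  holds exactly for every q.
* Zero abundances never enter entropy sums (0*ln 0 := 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _sp_braycurtis

__all__ = [
    "TrflpProfile",
    "OtuTable",
    "DiversityPartition",
    "profile_to_abundances",
    "hill_number",
    "partition_diversity",
    "evenness",
    "bray_curtis",
    "mean_pairwise_bc",
    "filter_core_taxa",
]

Microhabitat = Literal["upstream", "crest", "downstream", "trough"]
MICROHABITATS: tuple[str, ...] = ("upstream", "crest", "downstream", "trough")


@dataclass(frozen=True)
class TrflpProfile:
    """Peak table from one electropherogram: fragment sizes (bp) and heights."""

    fragment_sizes: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "fragment_sizes", np.asarray(self.fragment_sizes, dtype=float))
        object.__setattr__(self, "heights", np.asarray(self.heights, dtype=float))
        if self.fragment_sizes.shape != self.heights.shape:
            raise ValueError("fragment_sizes and heights must align")
        if np.any(self.heights < 0):
            raise ValueError("peak heights must be non-negative")


@dataclass
class OtuTable:
    """Relative OTU abundances for samples indexed by (flume, microhabitat, date).

    ``data`` is a DataFrame with a (flume, microhabitat, date) MultiIndex and
    one column per OTU; every row sums to 1.
    """

    data: pd.DataFrame

    def __post_init__(self):
        arr = self.data.to_numpy(dtype=float)
        if np.any(arr < 0):
            raise ValueError("abundances must be non-negative")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each sample row must sum to 1")

    @property
    def abundances(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col=[0, 1, 2])
        return cls(df)


@dataclass(frozen=True)
class DiversityPartition:
    """Multiplicative alpha/beta/gamma partition at Hill order q."""

    q: float
    gamma: float  # effective species, flume level
    alpha: float  # effective species per community
    beta: float  # effective number of distinct communities
    richness_gamma: int
    evenness_gamma: float  # Hill evenness D1/S
    pielou_gamma: float


def profile_to_abundances(
    profile: TrflpProfile,
    min_bp: float = 30.0,
    max_bp: float = 900.0,
    rel_height_threshold: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Filter a peak table and normalize to relative abundances.

    Fragments outside [min_bp, max_bp] are excluded (primer and sizing
    artifacts); peaks at or below ``rel_height_threshold`` of the maximum
    retained height are treated as background noise.  Returns
    ``(fragment_sizes, relative_abundances)`` for the retained peaks.
    """
    if profile.heights.size == 0:
        raise ValueError("profile has no peaks")
    keep = (profile.fragment_sizes >= min_bp) & (profile.fragment_sizes <= max_bp)
    sizes, heights = profile.fragment_sizes[keep], profile.heights[keep]
    if heights.size:
        keep2 = heights > rel_height_threshold * heights.max()
        sizes, heights = sizes[keep2], heights[keep2]
    total = heights.sum()
    if total <= 0:
        raise ValueError("all peaks filtered out; empty sample")
    return sizes, heights / total


def hill_number(p: np.ndarray, q: float) -> float:
    """Diversity of order q as an effective number of equally abundant species."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("abundances must be non-negative")
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("empty abundance vector")
    if q < 0:
        raise ValueError("q must be non-negative")
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def _pooled(tables: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return weights @ tables


def partition_diversity(
    tables: Sequence[np.ndarray] | np.ndarray,
    q: float,
    weights: np.ndarray | None = None,
) -> DiversityPartition:
    """Partition gamma diversity into alpha and beta at Hill order q.

    ``tables`` holds N relative-abundance vectors over a common OTU set
    (rows).  With equal weights (default):

    * gamma = Hill number of the pooled (mean) vector,
    * alpha (q != 1) = ``[(1/N) sum_j sum_i p_ij^q]^(1/(1-q))``,
      alpha (q = 1) = exp(mean Shannon entropy),
    * beta = gamma / alpha, the effective number of communities.

    The weighted variant follows the same generalized-mean construction and
    is exact for equal weights at any q; unequal weights are only supported
    at q = 0 and q = 1 (where the decomposition remains multiplicative).
    """
    P = np.atleast_2d(np.asarray(tables, dtype=float))
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 communities to partition")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each community vector must sum to 1")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        equalw = np.allclose(w, 1.0 / n)
        if not equalw and not (q in (0, 1)):
            raise ValueError("unequal weights supported only for q in {0, 1}")
    pooled = _pooled(P, w)
    gamma = hill_number(pooled, q)
    if abs(q - 1.0) < 1e-12:
        ents = np.array([-np.sum(row[row > 0] * np.log(row[row > 0])) for row in P])
        alpha = float(np.exp(w @ ents))
    elif q == 0:
        alpha = float(w @ (P > 0).sum(axis=1))
    else:
        alpha = float((w @ (P**q).sum(axis=1)) ** (1.0 / (1.0 - q)))
    beta = gamma / alpha
    s_gamma = int(np.count_nonzero(pooled))
    d1 = hill_number(pooled, 1.0)
    ev = d1 / s_gamma
    pielou = float(np.log(d1) / np.log(s_gamma)) if s_gamma >= 2 else float("nan")
    return DiversityPartition(q=q, gamma=gamma, alpha=alpha, beta=beta,
                              richness_gamma=s_gamma, evenness_gamma=ev, pielou_gamma=pielou)


def evenness(p: np.ndarray) -> tuple[float, float]:
    """Hill evenness (D1/S) and Pielou's Shannon evenness ln(D1)/ln(S)."""
    p = np.asarray(p, dtype=float)
    s = int(np.count_nonzero(p))
    if s < 2:
        raise ValueError("evenness undefined for fewer than 2 taxa")
    d1 = hill_number(p, 1.0)
    return d1 / s, float(np.log(d1) / np.log(s))


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity, sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("vectors must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_sp_braycurtis(x, y))


def mean_pairwise_bc(tables: Sequence[np.ndarray] | np.ndarray) -> float:
    """Mean Bray-Curtis dissimilarity over all unordered sample pairs."""
    P = np.atleast_2d(np.asarray(tables, dtype=float))
    if P.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    vals = [bray_curtis(P[i], P[j]) for i, j in combinations(range(P.shape[0]), 2)]
    return float(np.mean(vals))


def filter_core_taxa(table: OtuTable, scope: str = "all_flumes") -> OtuTable:
    """Reduce to taxa present in every unit of the chosen scope, renormalized.

    ``scope='all_flumes'`` keeps OTUs detected in at least one sample of
    every flume; ``'all_microhabitats'`` requires detection in every
    microhabitat.  Restricting to such core taxa turns the diversity
    analysis into a conservative evenness-only comparison among widespread
    taxa, robust to fingerprinting detection limits.
    """
    level = {"all_flumes": "flume", "all_microhabitats": "microhabitat"}.get(scope)
    if level is None:
        raise ValueError(f"unknown scope: {scope!r}")
    present = (table.data > 0).groupby(level=level).any()
    core = present.all(axis=0)
    if not core.any():
        raise ValueError("no core taxa under the requested scope")
    reduced = table.data.loc[:, core[core].index]
    sums = reduced.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("a sample lost all its taxa during core filtering")
    return OtuTable(reduced.div(sums, axis=0))
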