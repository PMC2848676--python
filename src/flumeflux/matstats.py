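"""Distance-matrix statistics: Mantel tests, path analysis, UPGMA, Bonferroni.

The flume-level analysis works on "metavariables": small symmetric
dissimilarity matrices among the six flumes, each built from a subset of
variables (flow heterogeneity, beta diversity, resource-use descriptors,
mass transfer ...).  Association between metavariables is tested with
Mantel and partial Mantel permutation tests; with only six objects the full
set of 6! = 720 simultaneous row/column permutations is enumerated, so the
null distribution is exact and the minimum attainable one-tailed P is
1/720.  Causal hypotheses among metavariables are expressed as a directed
acyclic graph; path coefficients are computed from the Mantel correlation
structure by per-node least squares, and their significance by joint
randomization of all involved matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _all_perms

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _upgma_linkage
from scipy.spatial.distance import pdist, squareform

from .regstats import zscore

__all__ = [
    "DistanceMatrix",
    "PathModel",
    "metavariable_distance",
    "mantel",
    "partial_mantel",
    "path_coefficients",
    "path_significance",
    "upgma",
    "bonferroni",
    "mantel_table",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("dissimilarities must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index), df.to_numpy())


@dataclass
class PathModel:
    """A DAG over metavariable labels with fitted path coefficients.

    ``dag`` maps each endogenous node to its parent labels.  After fitting,
    ``coefficients`` maps (parent, child) edges to standardized path
    coefficients and ``error_variance_pct`` maps each endogenous node to the
    unexplained variance in percent.
    """

    dag: dict[str, tuple[str, ...]]
    coefficients: dict[tuple[str, str], float] = field(default_factory=dict)
    error_variance_pct: dict[str, float] = field(default_factory=dict)
    p_values: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        self.dag = {k: tuple(v) for k, v in self.dag.items()}
        # cycle check by Kahn's algorithm
        nodes = set(self.dag)
        for parents in self.dag.values():
            nodes.update(parents)
        indeg = {u: 0 for u in nodes}
        for child, parents in self.dag.items():
            indeg[child] += len(parents)
        queue = [u for u in nodes if indeg[u] == 0]
        seen = 0
        children_of: dict[str, list[str]] = {u: [] for u in nodes}
        for child, parents in self.dag.items():
            for p in parents:
                children_of[p].append(child)
        while queue:
            u = queue.pop()
            seen += 1
            for v in children_of[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    queue.append(v)
        if seen != len(nodes):
            raise ValueError("path model graph contains a cycle")

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, parents in self.dag.items() for p in parents]

    def to_edge_list(self) -> pd.DataFrame:
        rows = [(p, c, self.coefficients.get((p, c), np.nan),
                 self.p_values.get((p, c), np.nan))
                for p, c in self.edges()]
        return pd.DataFrame(rows, columns=["parent", "child", "coefficient", "p_value"])

    def to_dot(self) -> str:
        lines = ["digraph paths {"]
        for node, ev in self.error_variance_pct.items():
            lines.append(f'  "{node}" [label="{node}\\n{ev:.0f}%"];')
        for (p, c) in self.edges():
            beta = self.coefficients.get((p, c))
            lab = f"{beta:.2f}" if beta is not None else ""
            pv = self.p_values.get((p, c))
            style = "solid" if pv is None or pv < 0.05 else "dashed"
            lines.append(f'  "{p}" -> "{c}" [label="{lab}", style={style}];')
        lines.append("}")
        return "\n".join(lines)


def metavariable_distance(values: pd.DataFrame, metric: str = "euclidean_z") -> DistanceMatrix:
    """Dissimilarity among flumes from a per-flume value table.

    ``euclidean_z`` z-standardizes each variable (column) across flumes and
    takes Euclidean distances — the convention for mixed-unit metavariables.
    ``bray_curtis`` is for compositional tables (non-negative rows).
    """
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    X = values.to_numpy(dtype=float)
    if metric == "euclidean_z":
        Z = np.column_stack([zscore(X[:, j]) for j in range(X.shape[1])])
        d = pdist(Z, metric="euclidean")
    elif metric == "euclidean":
        d = pdist(X, metric="euclidean")
    elif metric == "bray_curtis":
        if np.any(X < 0):
            raise ValueError("bray_curtis requires non-negative values")
        d = pdist(X, metric="braycurtis")
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return DistanceMatrix(tuple(values.index), squareform(d, checks=False))


def _triu(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    return m[iu]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant distance triangle; Mantel r undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _check_labels(*mats: DistanceMatrix) -> None:
    for m in mats[1:]:
        if m.labels != mats[0].labels:
            raise ValueError("distance matrices must share labels in order")


def _perm_stream(n: int, mode: str, n_perm: int, rng: np.random.Generator):
    """Yield index permutations for the null; identity is always included."""
    if mode == "full_enumeration":
        if n > 8:
            raise ValueError("full enumeration only supported for n <= 8")
        for p in _all_perms(range(n)):
            yield np.asarray(p)
    elif mode == "sampled":
        yield np.arange(n)
        for _ in range(n_perm):
            yield rng.permutation(n)
    else:
        raise ValueError(f"unknown mode: {mode!r}")


def mantel(A: DistanceMatrix, B: DistanceMatrix, mode: str = "full_enumeration",
           n_perm: int = 9999, seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation P.

    r is the Pearson correlation of the upper triangles.  The null permutes
    B's objects (simultaneous rows and columns); with ``full_enumeration``
    all n! permutations form the exact null.  P is one-tailed (greater): the
    proportion of permutations, identity included, with r_perm >= r_obs.
    """
    _check_labels(A, B)
    if A.n < 3:
        raise ValueError("need at least 3 objects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = _triu(A.values)
    r_obs = _pearson(a, _triu(B.values))
    count = total = 0
    for p in _perm_stream(A.n, mode, n_perm, rng):
        r_p = _pearson(a, _triu(B.values[np.ix_(p, p)]))
        count += r_p >= r_obs - 1e-12
        total += 1
    return r_obs, count / total


def _partial_r(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    r_ab, r_ac, r_bc = _pearson(a, b), _pearson(a, c), _pearson(b, c)
    if abs(r_ac) >= 1.0 - 1e-12 or abs(r_bc) >= 1.0 - 1e-12:
        raise ValueError("control matrix collinear with an input; partial r undefined")
    return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))


def partial_mantel(A: DistanceMatrix, B: DistanceMatrix, C: DistanceMatrix,
                   mode: str = "full_enumeration", n_perm: int = 9999,
                   seed: int | np.random.Generator = 0,
                   permute: str = "residuals") -> tuple[float, float]:
    """Partial Mantel correlation of A and B controlling for C.

    ``r_AB.C = (r_AB - r_AC r_BC) / sqrt((1-r_AC²)(1-r_BC²))``.  The null
    permutes the residuals of A's triangle regressed on C's (arranged back
    as a matrix and permuted object-wise, Legendre's recommendation);
    ``permute='raw'`` permutes A itself.  One-tailed (greater), identity
    included.
    """
    _check_labels(A, B, C)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b, c = _triu(A.values), _triu(B.values), _triu(C.values)
    r_obs = _partial_r(a, b, c)
    if permute == "residuals":
        slope, intercept = np.polyfit(c, a, 1)
        resid = a - (intercept + slope * c)
        base = squareform(resid, checks=False)  # residuals as a symmetric matrix
    elif permute == "raw":
        base = A.values
    else:
        raise ValueError(f"unknown permute: {permute!r}")
    count = total = 0
    for p in _perm_stream(A.n, mode, n_perm, rng):
        perm_tri = _triu(base[np.ix_(p, p)])
        r_p = _partial_r(perm_tri, b, c)
        count += r_p >= r_obs - 1e-12
        total += 1
    return float(r_obs), count / total


def _mantel_corr_matrix(triangles: dict[str, np.ndarray]) -> pd.DataFrame:
    labels = list(triangles)
    M = np.corrcoef(np.vstack([triangles[k] for k in labels]))
    return pd.DataFrame(M, index=labels, columns=labels)


def _fit_paths(corr: pd.DataFrame, dag: dict[str, tuple[str, ...]]):
    coeffs: dict[tuple[str, str], float] = {}
    errvar: dict[str, float] = {}
    for child, parents in dag.items():
        R_xx = corr.loc[list(parents), list(parents)].to_numpy()
        R_xy = corr.loc[list(parents), child].to_numpy()
        if abs(np.linalg.det(R_xx)) < 1e-12:
            raise ValueError(f"singular parent correlation block for {child!r}")
        beta = np.linalg.solve(R_xx, R_xy)
        for p_lab, b in zip(parents, beta):
            coeffs[(p_lab, child)] = float(b)
        errvar[child] = float((1.0 - R_xy @ beta) * 100.0)
    return coeffs, errvar


def path_coefficients(mantel_corr: pd.DataFrame, dag: dict[str, tuple[str, ...]]) -> PathModel:
    """Path coefficients for a DAG from a Mantel correlation matrix.

    For each endogenous node y with parents X the standardized coefficients
    are ``beta = R_XX^-1 R_Xy`` and the error variance is
    ``(1 - R_yX beta) * 100`` percent.
    """
    model = PathModel(dag=dag)
    for node in set(model.dag) | {p for ps in model.dag.values() for p in ps}:
        if node not in mantel_corr.index:
            raise ValueError(f"node {node!r} missing from the correlation matrix")
    coeffs, errvar = _fit_paths(mantel_corr, model.dag)
    model.coefficients = coeffs
    model.error_variance_pct = errvar
    return model


def path_significance(matrices: dict[str, DistanceMatrix],
                      dag: dict[str, tuple[str, ...]],
                      n_perm: int = 100_000,
                      seed: int | np.random.Generator = 0) -> PathModel:
    """Fit a path model and attach per-edge permutation P values.

    Every involved distance matrix is permuted independently
    (object-wise), the Mantel correlation matrix and path coefficients are
    recomputed, and each edge's P is the proportion of randomizations
    (observed configuration included) with |beta_perm| >= |beta_obs|.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(matrices)
    _check_labels(*matrices.values())
    n = matrices[labels[0]].n
    tris = {k: _triu(m.values) for k, m in matrices.items()}
    corr = _mantel_corr_matrix(tris)
    model = path_coefficients(corr, dag)
    exceed = {e: 1 for e in model.edges()}  # identity configuration counts
    valid = 1
    for _ in range(n_perm):
        perm_tris = {}
        for k in labels:
            p = rng.permutation(n)
            perm_tris[k] = _triu(matrices[k].values[np.ix_(p, p)])
        try:
            coeffs, _ = _fit_paths(_mantel_corr_matrix(perm_tris), model.dag)
        except ValueError:
            continue
        valid += 1
        for e in model.edges():
            if abs(coeffs[e]) >= abs(model.coefficients[e]) - 1e-12:
                exceed[e] += 1
    model.p_values = {e: exceed[e] / valid for e in model.edges()}
    return model


def upgma(D: DistanceMatrix):
    """Average-linkage (UPGMA) agglomerative clustering.

    Returns a scipy linkage matrix; merge heights are non-decreasing
    (average linkage is reducible).  Use ``scipy.cluster.hierarchy.dendrogram``
    with ``labels=D.labels`` to draw it.
    """
    if D.n < 2:
        raise ValueError("need at least 2 objects")
    return _upgma_linkage(D.condensed())


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted P values: min(1, p*m); m defaults to len(p_values)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    m = m if m is not None else p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, p * m)


def mantel_table(matrices: dict[str, DistanceMatrix], control: str,
                 mode: str = "full_enumeration", n_perm: int = 9999,
                 seed: int = 0, bonferroni_m: int | None = None) -> pd.DataFrame:
    """Square table: upper triangle Mantel (r, P), lower partial controlling one matrix.

    Mirrors the conventional presentation of pairwise Mantel statistics
    among metavariables, with partial statistics (controlling for the
    ``control`` metavariable, typically flow heterogeneity) below the
    diagonal.  Returns a tidy frame with columns row, col, kind, r, p,
    p_bonferroni.
    """
    labels = [k for k in matrices]
    rows = []
    rng = np.random.default_rng(seed)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i >= j:
                continue
            r, p = mantel(matrices[a], matrices[b], mode=mode, n_perm=n_perm, seed=rng)
            rows.append((a, b, "mantel", r, p))
            if a != control and b != control:
                rp, pp = partial_mantel(matrices[a], matrices[b], matrices[control],
                                        mode=mode, n_perm=n_perm, seed=rng)
                rows.append((b, a, "partial_mantel", rp, pp))
    df = pd.DataFrame(rows, columns=["row", "col", "kind", "r", "p"])
    m = bonferroni_m if bonferroni_m is not None else len(df)
    df["p_bonferroni"] = bonferroni(df["p"].to_numpy(), m)
    return df
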