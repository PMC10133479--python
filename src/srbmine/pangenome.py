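"""Pangenome partitioning: persistent / shell / cloud gene families.

A binary gene-family × genome presence/absence matrix ``x`` is modelled
by a multivariate Bernoulli mixture

    P(x_f) = sum_k pi_k * prod_g theta_{k,g}^{x_fg} (1 - theta_{k,g})^{1-x_fg},

with component count K (default 3).  Parameters are estimated by EM: the
E-step computes responsibilities in log space, the M-step updates the
mixing weights and per-genome Bernoulli parameters from responsibility-
weighted counts, and iteration stops when the relative log-likelihood
change falls below ``tol``.  Initialization is by presence-frequency
quantiles — families sorted by row mean are split into K bins and each
component's theta starts at its bin's column means — with seed-controlled
jitter; theta is clamped to [eps, 1-eps] (eps = 1e-4) throughout.

After convergence, labels are smoothed over the family contiguity graph
(two families linked when their genes are genomic neighbors) by a Potts
Markov random field: iterated conditional modes (ICM) reassigns each
family, in input order, to the component maximizing

    log pi_k + log P_k(x_f) + beta * #{neighbors currently labelled k}

until no label changes or ``n_sweeps`` is reached.  Components ranked by
mean presence probability become persistent (highest), cloud (lowest),
and shell (everything between; shell_1..shell_j when K > 3).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "EPS",
    "MixtureModel",
    "PartitionResult",
    "load_matrix",
    "load_contiguity",
    "fit_bmm",
    "log_likelihood",
    "smooth_mrf",
    "assign_partitions",
    "map_query_genes",
]

EPS = 1e-4  # theta clamp; prevents log(0) and degenerate components


@dataclass
class MixtureModel:
    """Fitted Bernoulli mixture: weights pi (K,), theta (K, G)."""

    pi: np.ndarray
    theta: np.ndarray
    genomes: list[str]
    beta: float = 2.5
    seed: int | None = None
    n_iter: int = 0
    converged: bool = False
    ll_trace: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.pi)

    def component_order(self) -> np.ndarray:
        """Component indices sorted by mean presence probability, descending."""
        return np.argsort(-self.theta.mean(axis=1), kind="stable")

    def partition_names(self) -> list[str]:
        """Per-component partition name after ranking by mean theta."""
        order = self.component_order()
        names = [""] * self.K
        if self.K == 1:
            names[order[0]] = "persistent"
            return names
        names[order[0]] = "persistent"
        names[order[-1]] = "cloud"
        mids = order[1:-1]
        for j, k in enumerate(mids, start=1):
            names[k] = "shell" if len(mids) == 1 else f"shell_{j}"
        means = self.theta.mean(axis=1)
        ranked = means[order]
        if np.any(np.abs(np.diff(ranked)) < 1e-9):
            warnings.warn(
                "tied component mean presence probabilities; "
                "tie broken by component index",
                stacklevel=2,
            )
        return names

    def to_json(self, path) -> None:
        payload = {
            "K": self.K,
            "pi": self.pi.tolist(),
            "theta": self.theta.tolist(),
            "genomes": self.genomes,
            "beta": self.beta,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "MixtureModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            pi=np.array(d["pi"]),
            theta=np.array(d["theta"]),
            genomes=d["genomes"],
            beta=d["beta"],
            seed=d["seed"],
            n_iter=d["n_iter"],
            converged=d["converged"],
        )


def load_matrix(path_or_df) -> pd.DataFrame:
    """Validate a presence/absence matrix (families × genomes, 0/1).

    Rejects non-binary entries, duplicate family or genome identifiers,
    and families observed in zero genomes (they carry no information and
    break maximum likelihood).
    """
    df = (
        pd.read_csv(path_or_df, index_col=0)
        if not isinstance(path_or_df, pd.DataFrame)
        else path_or_df.copy()
    )
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate family or genome identifiers")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence/absence matrix entries must be 0 or 1")
    empty = df.index[values.sum(axis=1) == 0]
    if len(empty):
        raise ValueError(
            f"families present in zero genomes: {list(empty[:5])}"
            + ("..." if len(empty) > 5 else "")
        )
    return df.astype(np.int8)


def load_contiguity(path, families) -> nx.Graph:
    """Load a family contiguity edge TSV; endpoints must exist in the matrix."""
    fam = set(families)
    graph = nx.Graph()
    graph.add_nodes_from(families)
    df = pd.read_csv(path, sep="\t")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        a, b = row[0], row[1]
        if a not in fam or b not in fam:
            raise ValueError(f"line {i}: contiguity edge endpoint not in matrix")
        graph.add_edge(a, b)
    return graph


def _log_bernoulli(X: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-family, per-component log P_k(x_f); shapes (F,G),(K,G) -> (F,K)."""
    return X @ np.log(theta).T + (1 - X) @ np.log1p(-theta).T


def _init_theta(
    X: np.ndarray, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile initialization: K bins of families sorted by row mean."""
    order = np.argsort(X.mean(axis=1), kind="stable")
    bins = np.array_split(order, K)
    theta = np.vstack([X[b].mean(axis=0) for b in bins])
    theta = theta + rng.uniform(-0.01, 0.01, size=theta.shape)
    pi = np.array([len(b) for b in bins], dtype=float)
    return np.clip(theta, EPS, 1 - EPS), pi / pi.sum()


def fit_bmm(
    matrix: pd.DataFrame,
    K: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    beta: float = 2.5,
) -> tuple[MixtureModel, pd.DataFrame]:
    """Fit the Bernoulli mixture by EM.

    Returns the model and a families × components responsibility
    DataFrame.  The log-likelihood is asserted non-decreasing at every
    iteration (1e-9 relative slack for floating point).
    """
    matrix = load_matrix(matrix)
    F, G = matrix.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > F:
        raise ValueError(f"K={K} exceeds the number of families ({F})")
    X = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    theta, pi = _init_theta(X, K, rng)

    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        # E-step in log space
        log_joint = np.log(pi)[None, :] + _log_bernoulli(X, theta)
        norm = logsumexp(log_joint, axis=1)
        resp = np.exp(log_joint - norm[:, None])
        ll = float(norm.sum())
        if ll < prev_ll - 1e-9 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll} -> {ll} (iter {it})"
            )
        # M-step
        nk = resp.sum(axis=0)
        pi = nk / F
        theta = np.clip((resp.T @ X) / np.maximum(nk[:, None], 1e-300), EPS, 1 - EPS)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    model = MixtureModel(
        pi=pi, theta=theta, genomes=list(matrix.columns), beta=beta,
        seed=seed, n_iter=it, converged=converged,
    )
    model.ll_trace.append(ll)
    # final responsibilities under the returned parameters
    log_joint = np.log(pi)[None, :] + _log_bernoulli(X, theta)
    resp = np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])
    resp_df = pd.DataFrame(resp, index=matrix.index, columns=range(K))
    return model, resp_df


def log_likelihood(matrix: pd.DataFrame, model: MixtureModel) -> float:
    """Total mixture log-likelihood of the matrix under a model."""
    matrix = load_matrix(matrix)
    if matrix.shape[1] != model.theta.shape[1]:
        raise ValueError(
            f"matrix has {matrix.shape[1]} genomes, model expects "
            f"{model.theta.shape[1]}"
        )
    X = matrix.to_numpy(dtype=float)
    log_joint = np.log(model.pi)[None, :] + _log_bernoulli(X, model.theta)
    return float(logsumexp(log_joint, axis=1).sum())


def smooth_mrf(
    responsibilities: pd.DataFrame,
    graph: nx.Graph | None,
    beta: float = 2.5,
    n_sweeps: int = 10,
) -> pd.Series:
    """ICM label smoothing over the contiguity graph.

    Starts from the per-family argmax of responsibilities and sweeps
    families in input order, reassigning each to the component maximizing
    ``log r_fk + beta * #{neighbors currently assigned k}`` (log
    responsibilities equal log pi_k + log-likelihood up to a per-family
    constant, which cannot change the argmax).  Stops when a sweep changes
    nothing or after ``n_sweeps``.  With beta = 0 or an edgeless graph the
    result is exactly the responsibility argmax.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    families = list(responsibilities.index)
    logr = np.log(np.maximum(responsibilities.to_numpy(dtype=float), 1e-300))
    K = logr.shape[1]
    argmax0 = logr.argmax(axis=1)
    if graph is None or graph.number_of_edges() == 0 or beta == 0:
        return pd.Series(argmax0, index=responsibilities.index)
    idx = {f: i for i, f in enumerate(families)}
    nbrs = [
        [idx[n] for n in graph[f] if n in idx] if f in graph else []
        for f in families
    ]

    def sweep(labels: np.ndarray) -> np.ndarray:
        for _ in range(n_sweeps):
            changed = False
            for i in range(len(families)):
                score = logr[i].copy()
                for j in nbrs[i]:
                    score[labels[j]] += beta
                new = int(score.argmax())
                if new != labels[i]:
                    labels[i] = new
                    changed = True
            if not changed:
                break
        return labels

    def energy(labels: np.ndarray) -> float:
        e = float(logr[np.arange(len(labels)), labels].sum())
        e += beta * sum(
            1 for a, b in graph.edges if a in idx and b in idx
            and labels[idx[a]] == labels[idx[b]]
        )
        return e

    # deterministic restarts guard against ICM's local optima at large beta:
    # the argmax start plus one uniform start per component
    starts = [argmax0.copy()] + [np.full(len(families), k) for k in range(K)]
    best = None
    best_e = -np.inf
    for start in starts:
        labels = sweep(start)
        e = energy(labels)
        if e > best_e + 1e-12:
            best_e = e
            best = labels
    return pd.Series(best, index=responsibilities.index)


@dataclass
class PartitionResult:
    """Per-family partition labels with responsibilities and frequencies."""

    table: pd.DataFrame  # columns: partition, component, mean_presence, resp_*
    model: MixtureModel

    def counts(self) -> dict[str, int]:
        return self.table["partition"].value_counts().to_dict()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="family")


def assign_partitions(
    model: MixtureModel,
    responsibilities: pd.DataFrame,
    matrix: pd.DataFrame,
    assignments: pd.Series | None = None,
) -> PartitionResult:
    """Name each family's partition from its (smoothed) component label.

    ``assignments`` defaults to the responsibility argmax; pass the output
    of :func:`smooth_mrf` for MRF-smoothed labels.
    """
    if assignments is None:
        assignments = pd.Series(
            responsibilities.to_numpy().argmax(axis=1), index=responsibilities.index
        )
    names = model.partition_names()
    matrix = load_matrix(matrix)
    table = pd.DataFrame(index=responsibilities.index)
    table["component"] = assignments
    table["partition"] = [names[k] for k in assignments]
    table["mean_presence"] = matrix.loc[table.index].mean(axis=1)
    for k in range(model.K):
        table[f"resp_{names[k]}"] = responsibilities[k]
    return PartitionResult(table=table, model=model)


def map_query_genes(
    queries: pd.DataFrame, result: PartitionResult
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join query genes onto their family's partition.

    ``queries`` must carry ``gene`` and ``family`` columns; quality
    columns (pident, e-value, bit score) pass through untouched.  Returns
    ``(matched, unmatched)`` tables; unmatched queries name families
    absent from the partition result.
    """
    required = {"gene", "family"}
    missing = required - set(queries.columns)
    if missing:
        raise ValueError(f"query table missing columns: {sorted(missing)}")
    known = queries["family"].isin(result.table.index)
    matched = queries[known].copy()
    matched["partition"] = (
        result.table["partition"].reindex(matched["family"]).to_numpy()
    )
    return matched, queries[~known].copy()
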