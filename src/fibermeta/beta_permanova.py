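"""Rarefaction-averaged Bray-Curtis dissimilarity and sequential PERMANOVA.

The variance partition follows the distance-based linear model of
McArdle & Anderson: Gower-center the squared dissimilarities, fit model
terms sequentially (Type-I sums of squares), and assess each term's
pseudo-F against free permutations of sample labels.  The default model
fits subject before the pre/post intervention factor, mirroring a two-term
``adonis2(dist ~ subject_id + fiber, by="term")`` analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .alpha_diversity import rarefy
from .data_model import CountTable, SampleMetadata, StudyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PermanovaTerm",
    "PermanovaResult",
    "bray_curtis",
    "averaged_sqrt_bray",
    "sequential_permanova",
    "permanova",
]


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x-y| / sum(x+y).

    Accepts a :class:`CountTable` or any samples x features DataFrame /
    array of non-negative abundances.
    """
    if isinstance(table, CountTable):
        data = table.data.astype(float)
    elif isinstance(table, pd.DataFrame):
        data = table.astype(float)
    else:
        data = pd.DataFrame(np.asarray(table, dtype=float))
    if data.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    row_sums = data.sum(axis=1)
    zero = row_sums[row_sums <= 0]
    if len(zero):
        raise ValueError(
            f"zero-sum sample(s) have undefined Bray-Curtis: {list(zero.index)}"
        )
    condensed = pdist(data.to_numpy(), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in data.index])


def averaged_sqrt_bray(
    study: StudyDataset,
    depth: int | None = None,
    iterations: int = 1000,
    seed: int | None = None,
) -> DistanceMatrix:
    """Mean Bray-Curtis matrix over rarefied, square-root transformed tables.

    Per iteration: rarefy to ``depth`` -> element-wise sqrt -> Bray-Curtis;
    the output is the element-wise mean across iterations.  The square-root
    transform damps the influence of the most abundant taxa.
    """
    table = study.table
    if depth is None:
        depth = int(table.sample_totals.min())
    acc = None
    ids = None
    n = 0
    for rarefied in rarefy(table, depth=depth, iterations=iterations, seed=seed):
        dm = bray_curtis(np.sqrt(rarefied.data))
        if acc is None:
            acc = np.zeros_like(dm.data)
            ids = list(rarefied.sample_ids)
        acc += dm.data
        n += 1
    return DistanceMatrix(acc / n, ids=ids)


@dataclass(frozen=True)
class PermanovaTerm:
    name: str
    df: int
    sum_of_squares: float
    r_squared: float
    pseudo_f: float
    p_value: float | None


@dataclass(frozen=True)
class PermanovaResult:
    """Sequential-SS variance partition of a dissimilarity matrix."""

    terms: tuple[PermanovaTerm, ...]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int

    def term(self, name: str) -> PermanovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t.name, t.df, t.sum_of_squares, t.r_squared, t.pseudo_f, t.p_value)
            for t in self.terms
        ]
        rows.append(
            (
                "residual",
                self.residual_df,
                self.residual_ss,
                self.residual_ss / self.total_ss,
                np.nan,
                np.nan,
            )
        )
        return pd.DataFrame(
            rows,
            columns=["term", "df", "sum_of_squares", "r_squared", "pseudo_f", "p_value"],
        )

    def to_dict(self) -> dict:
        return {
            "terms": [
                {
                    "term": t.name,
                    "df": t.df,
                    "sum_of_squares": t.sum_of_squares,
                    "r_squared": t.r_squared,
                    "pseudo_f": t.pseudo_f,
                    "p_value": t.p_value,
                }
                for t in self.terms
            ],
            "residual_df": self.residual_df,
            "residual_ss": self.residual_ss,
            "total_ss": self.total_ss,
            "n_permutations": self.n_permutations,
        }


def _dummy_matrix(labels: list) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = list(dict.fromkeys(labels))
    cols = [
        np.asarray([1.0 if lab == lev else 0.0 for lab in labels])
        for lev in levels[1:]
    ]
    if not cols:
        return np.empty((len(labels), 0))
    return np.column_stack(cols)


def _projection(x: np.ndarray) -> np.ndarray:
    """Orthogonal projection matrix onto the column space of x."""
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    q = q[:, :rank]
    return q @ q.T


def sequential_permanova(
    dist: DistanceMatrix,
    factors: dict[str, list],
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Distance-based ANOVA with sequential (Type-I) sums of squares.

    ``factors`` maps term name -> per-sample categorical labels, ordered as
    in ``dist.ids``; terms are fitted in dict order.  ``SS_total =
    (1/n) sum_{i<j} d_ij^2``; term SS are the sequential trace increments
    ``tr(H_k G) - tr(H_{k-1} G)`` on the Gower-centered matrix ``G``;
    pseudo-F divides each term's mean square by the residual mean square;
    p-values come from free permutation of sample labels,
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.
    """
    n = len(dist.ids)
    names = list(factors)
    if not names:
        raise ValueError("need at least one factor")
    for name, labels in factors.items():
        if len(labels) != n:
            raise ValueError(f"factor {name!r} has {len(labels)} labels for {n} samples")

    d2 = dist.data.astype(float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    total_ss = float(np.trace(g))

    design = [np.ones((n, 1))]
    projections = []
    dfs = []
    prev_rank = 1
    for name in names:
        design.append(_dummy_matrix(list(factors[name])))
        h = _projection(np.hstack(design))
        rank = int(round(np.trace(h)))
        projections.append(h)
        dfs.append(rank - prev_rank)
        prev_rank = rank
    df_resid = n - prev_rank
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    def partition(gm: np.ndarray) -> tuple[np.ndarray, float]:
        traces = np.array([(h * gm).sum() for h in projections])  # tr(H G), H symmetric
        ss = np.diff(np.concatenate([[0.0], traces]))
        ss_resid = float(np.trace(gm)) - traces[-1]
        return ss, ss_resid

    ss_terms, ss_resid = partition(g)
    ms_resid = ss_resid / df_resid
    f_terms = (ss_terms / np.asarray(dfs)) / ms_resid

    p_values: list[float | None] = [None] * len(names)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        ge = np.zeros(len(names), dtype=int)
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            ssp, srp = partition(gp)
            fp = (ssp / np.asarray(dfs)) / (srp / df_resid)
            ge += fp >= f_terms
        p_values = list((1 + ge) / (1 + n_permutations))

    terms = tuple(
        PermanovaTerm(
            name=name,
            df=dfs[k],
            sum_of_squares=float(ss_terms[k]),
            r_squared=float(ss_terms[k] / total_ss),
            pseudo_f=float(f_terms[k]),
            p_value=p_values[k],
        )
        for k, name in enumerate(names)
    )
    return PermanovaResult(
        terms=terms,
        residual_df=df_resid,
        residual_ss=float(ss_resid),
        total_ss=total_ss,
        n_permutations=n_permutations,
    )


def permanova(
    dist: DistanceMatrix,
    metadata: list[SampleMetadata],
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Two-term sequential PERMANOVA: subject first, then pre/post phase.

    A significant subject term means individuals carry distinct
    communities; a significant fiber (phase) term means the intervention
    shifted composition consistently across individuals.
    """
    by_id = {m.sample_id: m for m in metadata}
    missing = [i for i in dist.ids if i not in by_id]
    if missing:
        raise ValueError(f"metadata lacks samples present in distances: {missing}")
    meta = [by_id[i] for i in dist.ids]
    subjects = [m.subject_id for m in meta]
    phases = [m.phase.value for m in meta]
    if len(set(subjects)) < 2:
        raise ValueError("need >= 2 subjects")
    if len(set(phases)) < 2:
        raise ValueError("need both pre and post samples")
    subj_phases: dict[str, set] = {}
    for s, p in zip(subjects, phases):
        subj_phases.setdefault(s, set()).add(p)
    if all(len(v) == 1 for v in subj_phases.values()):
        logger.warning(
            "every subject is observed in a single phase: the fiber term "
            "is confounded with subjects"
        )
    return sequential_permanova(
        dist,
        {"subject": subjects, "fiber": phases},
        n_permutations=n_permutations,
        seed=seed,
    )
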