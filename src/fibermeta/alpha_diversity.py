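"""Alpha diversity under iterated rarefaction and paired pre/post testing.

Rarefaction subsamples each sample's reads without replacement to a common
depth (multivariate hypergeometric draw), repeated for a number of
iterations; diversity indices are computed per iteration and averaged.
Pre/post change per subject is tested with a paired t-test on the earliest
pre and latest post sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CountTable, Phase, StudyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaResult",
    "rarefy",
    "default_rarefaction_depth",
    "shannon",
    "simpson",
    "alpha_change",
]


@dataclass(frozen=True)
class AlphaResult:
    """Paired pre/post alpha-diversity comparison for one intervention."""

    study_id: str
    metric: str
    depth: int
    n_subjects: int
    per_subject_pre: dict[str, float]
    per_subject_post: dict[str, float]
    t_statistic: float
    df: int
    p_value: float
    mean_difference: float
    percent_change: float

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "metric": self.metric,
            "depth": self.depth,
            "n_subjects": self.n_subjects,
            "per_subject_pre": self.per_subject_pre,
            "per_subject_post": self.per_subject_post,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "mean_difference": self.mean_difference,
            "percent_change": self.percent_change,
        }


def default_rarefaction_depth(table: CountTable) -> int:
    """The largest depth retaining every sample: the minimum sample total."""
    return int(table.sample_totals.min())


def _retained_samples(table: CountTable, depth: int) -> CountTable:
    totals = table.sample_totals
    keep = totals[totals >= depth].index.tolist()
    if not keep:
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    if len(keep) < table.n_samples:
        dropped = sorted(set(table.sample_ids) - set(keep))
        logger.warning(
            "dropping %d samples below depth %d: %s", len(dropped), depth, dropped
        )
    return table.select_samples(keep)


def rarefy(
    table: CountTable, depth: int, iterations: int = 1000, seed: int | None = None
) -> Iterator[CountTable]:
    """Yield ``iterations`` rarefied tables at exactly ``depth`` reads/sample.

    Samples whose total is below ``depth`` are dropped once, with a warning;
    within each iteration every retained sample is subsampled without
    replacement. Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    retained = _retained_samples(table, depth)
    rng = np.random.default_rng(seed)
    counts = retained.counts
    for _ in range(iterations):
        out = np.empty_like(counts)
        for i, row in enumerate(counts):
            out[i] = rng.multivariate_hypergeometric(row, depth)
        yield CountTable(
            pd.DataFrame(out, index=retained.sample_ids, columns=retained.otu_ids)
        )


def shannon(abundances) -> float:
    """Shannon entropy H = -sum p ln p, in nats."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon index of an all-zero vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(abundances) -> float:
    """Gini-Simpson index D = 1 - sum p^2."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot compute Simpson index of an all-zero vector")
    p = x / total
    return float(1.0 - (p * p).sum())


_METRICS = {"shannon": shannon, "simpson": simpson}


def _paired_samples(study: StudyDataset) -> dict[str, tuple[str, str]]:
    """Earliest pre and latest post sample id per subject with both phases."""
    pairs: dict[str, tuple[str, str]] = {}
    for subject in study.subjects:
        pre = study.samples_for(subject, Phase.PRE)
        post = study.samples_for(subject, Phase.POST)
        if not pre or not post:
            logger.warning(
                "%s: subject %s lacks a %s sample; excluded from paired analysis",
                study.study_id,
                subject,
                "pre" if not pre else "post",
            )
            continue
        earliest_pre = min(pre, key=lambda m: m.timepoint_day)
        latest_post = max(post, key=lambda m: m.timepoint_day)
        pairs[subject] = (earliest_pre.sample_id, latest_post.sample_id)
    return pairs


def alpha_change(
    study: StudyDataset,
    metric: str = "shannon",
    depth: int | None = None,
    iterations: int = 1000,
    seed: int | None = None,
) -> AlphaResult:
    """Paired pre/post alpha-diversity test for one intervention.

    Per subject the earliest pre and latest post samples are compared; the
    index is the mean over rarefaction iterations; a two-sided paired t-test
    is applied to the per-subject differences.  ``percent_change`` is the
    post-minus-pre change of the subject-mean index, as a percentage of the
    pre-intervention mean; ``mean_difference`` is the raw difference.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    index_fn = _METRICS[metric]
    pairs = _paired_samples(study)
    if len(pairs) < 3:
        raise ValueError(
            f"{study.study_id}: need >= 3 subjects with both phases, got {len(pairs)}"
        )
    wanted = sorted({sid for pair in pairs.values() for sid in pair})
    sub_table = study.table.select_samples(wanted)
    if depth is None:
        depth = default_rarefaction_depth(sub_table)

    sums = pd.Series(0.0, index=wanted)
    n_iter = 0
    for rarefied in rarefy(sub_table, depth=depth, iterations=iterations, seed=seed):
        vals = rarefied.data.apply(lambda row: index_fn(row.to_numpy()), axis=1)
        sums = sums.add(vals, fill_value=np.nan)
        n_iter += 1
    mean_index = sums / n_iter
    # paired analysis requires both samples of a pair to have survived rarefaction
    usable = {
        subj: pair
        for subj, pair in pairs.items()
        if pair[0] in mean_index.index and pair[1] in mean_index.index
        and np.isfinite(mean_index[pair[0]]) and np.isfinite(mean_index[pair[1]])
    }
    if len(usable) < 3:
        raise ValueError(
            f"{study.study_id}: fewer than 3 paired subjects survive depth {depth}"
        )
    subjects = sorted(usable)
    pre_vals = np.array([mean_index[usable[s][0]] for s in subjects])
    post_vals = np.array([mean_index[usable[s][1]] for s in subjects])
    diffs = post_vals - pre_vals
    n = len(diffs)
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        if np.allclose(diffs.mean(), 0.0):
            t_stat, p_value = 0.0, 1.0
        else:
            logger.warning(
                "%s: degenerate zero variance of paired differences", study.study_id
            )
            t_stat = np.inf * np.sign(diffs.mean())
            p_value = 0.0
    else:
        t_stat = diffs.mean() / (sd / np.sqrt(n))
        p_value = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
    mean_pre, mean_post = pre_vals.mean(), post_vals.mean()
    if mean_pre == 0.0:
        logger.warning("%s: pre-intervention mean index is 0", study.study_id)
        pct = float("nan")
    else:
        pct = float(100.0 * (mean_post - mean_pre) / mean_pre)
    return AlphaResult(
        study_id=study.study_id,
        metric=metric,
        depth=depth,
        n_subjects=n,
        per_subject_pre={s: float(mean_index[usable[s][0]]) for s in subjects},
        per_subject_post={s: float(mean_index[usable[s][1]]) for s in subjects},
        t_statistic=float(t_stat),
        df=n - 1,
        p_value=float(p_value),
        mean_difference=float(mean_post - mean_pre),
        percent_change=pct,
    )
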