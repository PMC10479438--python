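"""Per-study differential abundance and cross-study consensus responders.

The estimator is deliberately simple and fully specified: median-of-ratios
size factors normalize library depth, the effect is the plug-in log2 ratio
of post- to pre-intervention mean normalized abundance (pseudocount 0.5),
and significance comes from a subject-paired sign-flip permutation test
with Benjamini-Hochberg control across OTUs.  Per-study effects are then
averaged over the studies in which an OTU survives filtering; only
"widespread" OTUs seen in at least ``min_studies`` studies are classified.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import CountTable, Phase, StudyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "LOG2FC_LARGE_EFFECT",
    "OtuResponse",
    "ConsensusResponse",
    "filter_low_abundance",
    "filter_prevalence",
    "size_factors",
    "study_log2fc",
    "cross_study_consensus",
]

#: |log2 fold change| beyond which an effect is called "large"
#: (a 1.5-fold change: |log2 1.5| = 0.585, conventionally quoted as 0.58).
LOG2FC_LARGE_EFFECT = 0.58

#: pseudocount added to phase-mean normalized abundances before the log ratio
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class OtuResponse:
    """One OTU's response to the intervention within one study."""

    otu_id: str
    study_id: str
    log2_fold_change: float
    p_value: float
    p_adjusted: float
    significant: bool
    large_effect: bool


@dataclass(frozen=True)
class ConsensusResponse:
    """Cross-study averaged response of a widespread OTU."""

    otu_id: str
    mean_log2_fold_change: float
    n_studies_present: int
    direction: str  # "positive" | "negative"
    top_responder: bool
    ambiguous: bool = False


def filter_low_abundance(
    table: CountTable, min_total: int = 10, min_samples: int = 3
) -> CountTable:
    """Drop OTUs with total count < ``min_total`` or seen in < ``min_samples``
    samples; likely sequencing errors or chimeras rather than real taxa."""
    totals = table.data.sum(axis=0)
    occupancy = (table.data > 0).sum(axis=0)
    keep = table.data.columns[(totals >= min_total) & (occupancy >= min_samples)]
    if len(keep) == 0:
        raise ValueError("low-abundance filter removed every OTU")
    return table.select_otus(list(keep))


def filter_prevalence(table: CountTable, min_prevalence: float = 0.5) -> CountTable:
    """Keep OTUs present (count > 0) in at least ``min_prevalence`` of samples.

    A tie at exactly the threshold (e.g. 3 of 6 samples at 0.5) is kept.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    occupancy = (table.data > 0).sum(axis=0)
    keep = table.data.columns[occupancy >= min_prevalence * table.n_samples]
    if len(keep) == 0:
        raise ValueError("prevalence filter removed every OTU")
    return table.select_otus(list(keep))


def size_factors(table: CountTable, allow_fallback: bool = True) -> pd.Series:
    """Median-of-ratios per-sample scaling factors.

    The reference profile is the geometric mean of each OTU across samples,
    computed over OTUs positive in every sample; a sample's factor is the
    median ratio of its counts to the reference.  If no OTU is positive in
    every sample, a +1 pseudocount on the whole table is used instead
    (``allow_fallback``), otherwise an error is raised.
    """
    data = table.data.to_numpy().astype(float)
    all_positive = (data > 0).all(axis=0)
    if not all_positive.any():
        if not allow_fallback:
            raise ValueError(
                "no OTU is present in every sample; cannot form the "
                "geometric-mean reference"
            )
        logger.warning(
            "no OTU present in every sample; using +1 pseudocount fallback "
            "for size factors"
        )
        data = data + 1.0
        all_positive = np.ones(data.shape[1], dtype=bool)
    ref = np.exp(np.log(data[:, all_positive]).mean(axis=0))
    factors = np.median(data[:, all_positive] / ref, axis=1)
    return pd.Series(factors, index=table.sample_ids, name="size_factor")


def _phase_samples(study: StudyDataset) -> tuple[dict, dict]:
    pre: dict[str, list[str]] = {}
    post: dict[str, list[str]] = {}
    for m in study.metadata:
        target = pre if m.phase == Phase.PRE else post
        target.setdefault(m.subject_id, []).append(m.sample_id)
    return pre, post


def study_log2fc(
    study: StudyDataset,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> list[OtuResponse]:
    """Per-OTU log2 fold change (post vs pre) with sign-flip significance.

    Normalized counts are counts divided by the sample's size factor.  The
    effect is ``log2((mean_post + c) / (mean_pre + c))`` over all samples of
    each phase, with pseudocount ``c = 0.5``.  The permutation test uses the
    per-subject difference of phase-mean normalized abundance: the observed
    statistic is its mean over subjects, and the null randomly negates each
    subject's difference vector (two-sided).  With fewer than 5 paired
    subjects all ``2^n`` sign patterns are enumerated exactly and
    ``p = #{|T| >= |T_obs|} / 2^n``.
    """
    table = study.table
    factors = size_factors(table)
    norm = table.data.astype(float).div(factors, axis=0)

    pre_map, post_map = _phase_samples(study)
    paired_subjects = sorted(set(pre_map) & set(post_map))
    if len(paired_subjects) < 2:
        raise ValueError(f"{study.study_id}: need >= 2 subjects with both phases")

    pre_ids = [s for subj in paired_subjects for s in pre_map[subj]]
    post_ids = [s for subj in paired_subjects for s in post_map[subj]]
    mean_pre = norm.loc[pre_ids].mean(axis=0)
    mean_post = norm.loc[post_ids].mean(axis=0)
    log2fc = np.log2((mean_post + PSEUDOCOUNT) / (mean_pre + PSEUDOCOUNT))

    # subjects x OTUs matrix of within-subject phase-mean differences
    deltas = np.vstack(
        [
            norm.loc[post_map[subj]].mean(axis=0).to_numpy()
            - norm.loc[pre_map[subj]].mean(axis=0).to_numpy()
            for subj in paired_subjects
        ]
    )
    n_subj = deltas.shape[0]
    t_obs = np.abs(deltas.mean(axis=0))

    if n_subj < 5:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_subj)))
        t_null = np.abs(signs @ deltas) / n_subj  # patterns x OTUs
        p_values = (t_null >= t_obs[None, :] - 1e-12).mean(axis=0)
    else:
        rng = np.random.default_rng(seed)
        ge = np.zeros(deltas.shape[1])
        for _ in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=n_subj)
            t_perm = np.abs(signs @ deltas) / n_subj
            ge += t_perm >= t_obs - 1e-12
        p_values = (1.0 + ge) / (1.0 + n_permutations)

    p_adj = multipletests(p_values, method="fdr_bh")[1]
    out = []
    for k, otu in enumerate(table.otu_ids):
        fc = float(log2fc.iloc[k])
        out.append(
            OtuResponse(
                otu_id=otu,
                study_id=study.study_id,
                log2_fold_change=fc,
                p_value=float(p_values[k]),
                p_adjusted=float(p_adj[k]),
                significant=bool(p_adj[k] < 0.05),
                large_effect=bool(abs(fc) > LOG2FC_LARGE_EFFECT),
            )
        )
    return out


def cross_study_consensus(
    results: dict[str, list[OtuResponse]] | list[list[OtuResponse]],
    min_studies: int = 3,
) -> list[ConsensusResponse]:
    """Average per-study log2 fold changes for widespread OTUs.

    An OTU is retained only if it survived filtering in at least
    ``min_studies`` studies; its consensus effect is the unweighted mean of
    the per-study log2 fold changes.  ``direction`` is positive iff the mean
    is strictly > 0 (an exact zero is classified negative and flagged
    ambiguous); ``top_responder`` marks |mean| > 1.
    """
    if isinstance(results, dict):
        per_study = list(results.values())
    else:
        per_study = list(results)
    if len(per_study) < min_studies:
        raise ValueError(
            f"need results from >= {min_studies} studies, got {len(per_study)}"
        )
    fcs: dict[str, list[float]] = {}
    for study_results in per_study:
        for r in study_results:
            fcs.setdefault(r.otu_id, []).append(r.log2_fold_change)
    out = []
    for otu in sorted(fcs):
        values = fcs[otu]
        if len(values) < min_studies:
            continue
        mean_fc = float(np.mean(values))
        out.append(
            ConsensusResponse(
                otu_id=otu,
                mean_log2_fold_change=mean_fc,
                n_studies_present=len(values),
                direction="positive" if mean_fc > 0 else "negative",
                top_responder=bool(abs(mean_fc) > 1.0),
                ambiguous=bool(mean_fc == 0.0),
            )
        )
    return out


def consensus_frame(consensus: list[ConsensusResponse]) -> pd.DataFrame:
    """Tabular view of a consensus list (for TSV export)."""
    return pd.DataFrame(
        {
            "otu_id": [c.otu_id for c in consensus],
            "mean_log2fc": [c.mean_log2_fold_change for c in consensus],
            "n_studies": [c.n_studies_present for c in consensus],
            "direction": [c.direction for c in consensus],
            "top_responder": [c.top_responder for c in consensus],
        }
    )
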