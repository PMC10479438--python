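"""Shared fixtures: tiny hand-built studies and trees."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from fibermeta.data_model import (
    CountTable,
    Phase,
    SampleMetadata,
    StudyDataset,
)


def make_study(
    study_id: str,
    pre_rows: dict[str, list[int]],
    post_rows: dict[str, list[int]],
    otu_ids: list[str] | None = None,
) -> StudyDataset:
    """Build a StudyDataset with one pre and one post sample per subject.

    ``pre_rows``/``post_rows`` map subject id -> count vector.
    """
    assert set(pre_rows) == set(post_rows)
    n_otus = len(next(iter(pre_rows.values())))
    otu_ids = otu_ids or [f"o{k+1}" for k in range(n_otus)]
    rows, ids, meta = [], [], []
    for subject in pre_rows:
        for phase, source, day in (
            (Phase.PRE, pre_rows, 0),
            (Phase.POST, post_rows, 14),
        ):
            sample_id = f"{subject}_{phase.value}"
            rows.append(source[subject])
            ids.append(sample_id)
            meta.append(
                SampleMetadata(
                    sample_id=sample_id,
                    subject_id=subject,
                    study_id=study_id,
                    timepoint_day=day,
                    phase=phase,
                )
            )
    table = CountTable(pd.DataFrame(rows, index=ids, columns=otu_ids))
    return StudyDataset(study_id=study_id, table=table, metadata=tuple(meta))


@pytest.fixture
def balanced_quartet() -> TreeNode:
    """((A:1,B:1):1,(C:1,D:1):1); — the 4-tip worked-example tree."""
    return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])


@pytest.fixture
def balanced_octet() -> TreeNode:
    """Perfectly balanced 8-tip tree, every branch length 0.05."""
    newick = (
        "(((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05):0.05,"
        "((E:0.05,F:0.05):0.05,(G:0.05,H:0.05):0.05):0.05);"
    )
    return TreeNode.read([newick])
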