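"""Corpus-level summaries and the end-to-end pipeline driver.

Aggregates per-intervention results (alpha-diversity outcomes, PERMANOVA
variance fractions, consenTRAIT depths) into the summary statistics a
multi-study synthesis reports: registry totals, per-column means over all
rows and over significant-only rows, and significance counts.  Bundled
fixture tables for the published 12-study / 21-intervention fiber corpus
are provided so these summaries can be recomputed without any raw data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alpha_diversity, beta_permanova, differential_abundance
from . import synthetic_data, trait_phylogenetics
from .data_model import StudyRegistryRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RegistrySummary",
    "MetaSummary",
    "load_study_registry",
    "load_intervention_summary",
    "load_trait_depth_summary",
    "summarize_registry",
    "summarize_meta",
    "run_pipeline",
]

#: display rounding used in reports: percentages to 1 decimal, tau_D to 3
ROUND_PCT = 1
ROUND_TAU = 3


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("fibermeta.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_study_registry() -> list[StudyRegistryRecord]:
    """The bundled per-study registry (12 studies)."""
    df = _fixture("study_registry.tsv")
    return [
        StudyRegistryRecord(
            study_id=row.study_id,
            fiber_type=row.fiber_type,
            fiber_grams=float(row.fiber_grams),
            duration_days=int(row.duration_days),
            n_timepoints=int(row.n_timepoints),
            n_subjects=int(row.n_subjects),
            n_samples=int(row.n_samples),
        )
        for row in df.itertuples()
    ]


def load_intervention_summary() -> pd.DataFrame:
    """The bundled per-intervention outcome table (21 interventions)."""
    return _fixture("intervention_summary.tsv")


def load_trait_depth_summary() -> pd.DataFrame:
    """The bundled per-study consenTRAIT depth table (8 V4 studies)."""
    return _fixture("trait_depth_summary.tsv")


@dataclass(frozen=True)
class RegistrySummary:
    n_studies: int
    n_interventions: int | None
    total_subjects: int
    total_samples: int
    duration_median_days: float
    duration_sd_days: float
    duration_min_days: int
    duration_max_days: int
    sd_degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_registry(
    records: list[StudyRegistryRecord], n_interventions: int | None = None
) -> RegistrySummary:
    """Totals and duration statistics over registry records.

    The duration median uses the midpoint of the central pair for even n;
    the SD uses the sample (n-1) denominator.  For a single record the SD
    is reported as 0 with ``sd_degenerate`` set.
    """
    if not records:
        raise ValueError("empty registry")
    durations = np.array([r.duration_days for r in records], dtype=float)
    degenerate = len(records) == 1
    return RegistrySummary(
        n_studies=len(records),
        n_interventions=n_interventions,
        total_subjects=int(sum(r.n_subjects for r in records)),
        total_samples=int(sum(r.n_samples for r in records)),
        duration_median_days=float(np.median(durations)),
        duration_sd_days=0.0 if degenerate else float(np.std(durations, ddof=1)),
        duration_min_days=int(durations.min()),
        duration_max_days=int(durations.max()),
        sd_degenerate=degenerate,
    )


@dataclass(frozen=True)
class MetaSummary:
    """Column means and counts over per-intervention result rows.

    ``*_mean_significant`` fields average only rows flagged significant for
    that column; counts refer to the same flags.  tau fields are None when
    no trait-depth rows are supplied.
    """

    n_interventions: int
    subject_r2_mean_all: float
    subject_r2_mean_significant: float | None
    n_subject_significant: int
    fiber_r2_mean_all: float
    fiber_r2_mean_significant: float | None
    n_fiber_significant: int
    n_alpha_decreased: int
    n_alpha_significant: int
    n_trait_rows: int | None = None
    tau_pos_mean_all: float | None = None
    tau_pos_mean_significant: float | None = None
    n_tau_pos_significant: int | None = None
    tau_neg_mean_all: float | None = None
    tau_neg_mean_significant: float | None = None
    n_tau_neg_significant: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _flag(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.lower().isin(["true", "1", "yes"])


def _sig_mean(values: pd.Series, flags: pd.Series) -> float | None:
    sel = values[flags]
    return float(sel.mean()) if len(sel) else None


def summarize_meta(
    rows: pd.DataFrame, trait_rows: pd.DataFrame | None = None
) -> MetaSummary:
    """Footer statistics over a per-intervention results table.

    ``rows`` needs columns ``subject_r2_pct``, ``subject_significant``,
    ``fiber_r2_pct``, ``fiber_significant``, ``alpha_direction`` and
    ``alpha_significant``; ``trait_rows`` (optional) needs ``tau_pos`` /
    ``tau_neg`` with their significance flags.
    """
    if rows.empty:
        raise ValueError("no intervention rows")
    subject_sig = _flag(rows["subject_significant"])
    fiber_sig = _flag(rows["fiber_significant"])
    alpha_sig = _flag(rows["alpha_significant"])
    decreased = rows["alpha_direction"].astype(str).str.lower().eq("down")

    kwargs: dict = {}
    if trait_rows is not None and len(trait_rows):
        pos_sig = _flag(trait_rows["tau_pos_significant"])
        neg_sig = _flag(trait_rows["tau_neg_significant"])
        kwargs = dict(
            n_trait_rows=len(trait_rows),
            tau_pos_mean_all=float(trait_rows["tau_pos"].mean()),
            tau_pos_mean_significant=_sig_mean(trait_rows["tau_pos"], pos_sig),
            n_tau_pos_significant=int(pos_sig.sum()),
            tau_neg_mean_all=float(trait_rows["tau_neg"].mean()),
            tau_neg_mean_significant=_sig_mean(trait_rows["tau_neg"], neg_sig),
            n_tau_neg_significant=int(neg_sig.sum()),
        )
    return MetaSummary(
        n_interventions=len(rows),
        subject_r2_mean_all=float(rows["subject_r2_pct"].mean()),
        subject_r2_mean_significant=_sig_mean(rows["subject_r2_pct"], subject_sig),
        n_subject_significant=int(subject_sig.sum()),
        fiber_r2_mean_all=float(rows["fiber_r2_pct"].mean()),
        fiber_r2_mean_significant=_sig_mean(rows["fiber_r2_pct"], fiber_sig),
        n_fiber_significant=int(fiber_sig.sum()),
        n_alpha_decreased=int(decreased.sum()),
        n_alpha_significant=int(alpha_sig.sum()),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "preset": "paperlike",
    "seed": 0,
    "rarefaction": {"iterations": 100, "depth": None},
    "permanova": {"permutations": 999},
    "diffabund": {
        "min_total": 10,
        "min_samples": 3,
        "prevalence": 0.5,
        "min_studies": 3,
        "permutations": 1000,
    },
    "consentrait": {"cutoff": 0.9, "permutations": 1000},
    "simulation": {},
}


def _merge_config(config: dict) -> dict:
    merged = json.loads(json.dumps(_DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _validate_config(cfg: dict) -> None:
    for section in ("permanova", "diffabund", "consentrait"):
        if cfg[section]["permutations"] < 1:
            raise ValueError(f"{section}.permutations must be >= 1")
    if cfg["rarefaction"]["iterations"] < 1:
        raise ValueError("rarefaction.iterations must be >= 1")


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Simulate -> alpha -> beta -> diffabund -> consenTRAIT -> summary.

    ``config`` is a declarative document (dict, or path to a YAML file)
    with keys ``preset``/``simulation``, ``seed``, ``rarefaction``,
    ``permanova``, ``diffabund`` and ``consentrait``; results are written
    under ``outdir`` as JSON, one file per stage plus ``summary.json`` and
    a run log.  Re-running with an identical config reproduces identical
    JSON payloads.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge_config(config)
    _validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    params = synthetic_data.paperlike_params(seed=seed, **cfg.get("simulation", {}))
    tree, traits_pos, traits_neg, studies = synthetic_data.simulate_everything(params)

    log_lines = [f"pipeline seed={seed} preset={cfg['preset']}"]
    alpha_rows, beta_rows, per_study_responses = [], [], {}
    rare_iters = cfg["rarefaction"]["iterations"]
    rare_depth = cfg["rarefaction"]["depth"]
    stage = "init"
    study_id = None
    try:
        for k, study in enumerate(studies):
            study_id = study.study_id
            stage = "alpha"
            for metric in ("shannon", "simpson"):
                res = alpha_diversity.alpha_change(
                    study,
                    metric=metric,
                    depth=rare_depth,
                    iterations=rare_iters,
                    seed=seed * 1000 + k,
                )
                alpha_rows.append(res.to_dict())
            stage = "beta"
            dm = beta_permanova.averaged_sqrt_bray(
                study, depth=rare_depth, iterations=rare_iters, seed=seed * 1000 + k
            )
            perm = beta_permanova.permanova(
                dm,
                list(study.metadata),
                n_permutations=cfg["permanova"]["permutations"],
                seed=seed * 1000 + k,
            )
            beta_rows.append({"study_id": study.study_id, **perm.to_dict()})
            stage = "diffabund"
            da_cfg = cfg["diffabund"]
            filtered = differential_abundance.filter_prevalence(
                differential_abundance.filter_low_abundance(
                    study.table, da_cfg["min_total"], da_cfg["min_samples"]
                ),
                da_cfg["prevalence"],
            )
            sub_study = type(study)(
                study_id=study.study_id, table=filtered, metadata=study.metadata
            )
            per_study_responses[study.study_id] = differential_abundance.study_log2fc(
                sub_study,
                n_permutations=da_cfg["permutations"],
                seed=seed * 1000 + k,
            )
        stage = "consensus"
        study_id = None
        consensus = differential_abundance.cross_study_consensus(
            per_study_responses, min_studies=cfg["diffabund"]["min_studies"]
        )
        stage = "consentrait"
        tau_results = {}
        for direction in ("positive", "negative"):
            trait = {t.name: 0 for t in tree.tips()}
            for c in consensus:
                if c.direction == direction:
                    trait[c.otu_id] = 1
            if sum(trait.values()) == 0:
                logger.warning("no %s consensus responders; skipping tau_D", direction)
                tau_results[direction] = None
                continue
            res = trait_phylogenetics.consentrait_test(
                tree,
                trait,
                cutoff=cfg["consentrait"]["cutoff"],
                n_permutations=cfg["consentrait"]["permutations"],
                seed=seed + (1 if direction == "positive" else 2),
            )
            tau_results[direction] = res.to_dict()
    except Exception as exc:
        where = f"stage={stage}" + (f" study={study_id}" if study_id else "")
        raise RuntimeError(f"pipeline failed at {where}: {exc}") from exc

    stage_payloads = {
        "alpha.json": alpha_rows,
        "beta.json": beta_rows,
        "diffabund.json": {
            sid: [r.__dict__ for r in responses]
            for sid, responses in per_study_responses.items()
        },
        "consensus.json": [c.__dict__ for c in consensus],
        "consentrait.json": tau_results,
    }

    # per-intervention summary rows from the computed stages
    rows = []
    for k, study in enumerate(studies):
        a_sh = alpha_rows[2 * k]
        a_si = alpha_rows[2 * k + 1]
        beta = beta_rows[k]
        subj = next(t for t in beta["terms"] if t["term"] == "subject")
        fib = next(t for t in beta["terms"] if t["term"] == "fiber")
        direction = "down" if min(a_sh["percent_change"], a_si["percent_change"]) < 0 else "up"
        rows.append(
            {
                "intervention_id": study.study_id,
                "alpha_direction": direction,
                "alpha_significant": bool(
                    (a_sh["p_value"] < 0.05) or (a_si["p_value"] < 0.05)
                ),
                "subject_r2_pct": 100.0 * subj["r_squared"],
                "subject_significant": bool(subj["p_value"] < 0.05),
                "fiber_r2_pct": 100.0 * fib["r_squared"],
                "fiber_significant": bool(fib["p_value"] < 0.05),
            }
        )
    summary = summarize_meta(pd.DataFrame(rows))
    payload = {
        "config": cfg,
        "interventions": rows,
        "meta_summary": summary.to_dict(),
        "tau": tau_results,
    }
    for name, data in stage_payloads.items():
        with open(outdir / name, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    log_lines.append(f"processed {len(studies)} studies")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return payload
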