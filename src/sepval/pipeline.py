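"""One-command pipeline: inputs -> classification -> linkage -> agreement ->
mortality -> report bundle.

In ``synthetic`` mode the generator produces (and writes) all input tables;
in ``files`` mode they are read from the configured paths.  Every run writes
a JSON manifest (seed, config hash, row counts, exclusion counts, output
files) sufficient to reproduce it byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import DEFAULT_PAIRS, evaluate_pairs, prevalence
from .config import RunConfig, config_hash
from .icd9 import CodeTaxonomy
from .io import (
    read_claims,
    read_events,
    read_participants,
    write_claims,
    write_coverage,
    write_events,
    write_participants,
)
from .linkage import CLASSIFIER_FLAGS, build_analysis_set, primary_infection_subgroup
from .mortality import build_followup, mortality_report, survival_dataset
from .synth import GeneratorConfig, config_to_dict, generate

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    analysis: pd.DataFrame
    excluded: pd.DataFrame
    prevalence: pd.DataFrame
    agreement: pd.DataFrame
    agreement_subgroup: pd.DataFrame
    agreement_recent: pd.DataFrame
    mortality: pd.DataFrame
    survival: pd.DataFrame
    manifest: dict
    ground_truth: Optional[pd.DataFrame] = None


def _prevalence_table(analysis: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for flag in CLASSIFIER_FLAGS:
        if len(analysis):
            p = prevalence(analysis[flag].to_numpy())
        else:
            p = float("nan")
        rows.append(
            {
                "classifier": flag,
                "n_positive": int(analysis[flag].sum()) if len(analysis) else 0,
                "n": len(analysis),
                "prevalence": p,
                "prevalence_pct": 100.0 * p if p == p else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _agreement_or_empty(df: pd.DataFrame, B: int, seed: int, alpha: float, method: str) -> pd.DataFrame:
    if df.empty:
        warnings.warn("agreement requested on an empty analysis set; emitting empty table")
        return pd.DataFrame(
            columns=["index", "standard", "statistic", "estimate", "ci_low", "ci_high",
                     "a", "b", "c", "d", "n", "B", "seed"]
        )
    return evaluate_pairs(df, DEFAULT_PAIRS, B=B, seed=seed, alpha=alpha, method=method)


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    mode: str = "synthetic",
    seed: int | None = None,
    write_plots: bool = False,
) -> PipelineResult:
    """Execute the full pipeline and write the report bundle to *outdir*."""
    if mode not in ("synthetic", "files"):
        raise ValueError(f"unknown mode {mode!r}")
    if seed is not None:
        config.seed = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    taxonomy = CodeTaxonomy.from_dict(config.taxonomy)
    ground_truth = None

    if mode == "synthetic":
        gen_overrides = dict(config.generator)
        gen_overrides.setdefault("seed", config.seed)
        if "window" in gen_overrides:
            gen_overrides["window"] = tuple(
                v if isinstance(v, dt.date) else dt.date.fromisoformat(str(v))
                for v in gen_overrides["window"]
            )
        else:
            gen_overrides["window"] = config.window
        gen_config = GeneratorConfig(**gen_overrides)
        cohort = generate(gen_config)
        events, claims, participants = cohort.events, cohort.claims, cohort.participants
        ground_truth = cohort.ground_truth
        write_events(events, outdir / "events.csv")
        write_claims(claims, outdir / "claims.csv")
        write_participants(participants.values(), outdir / "participants.csv")
        write_coverage(participants.values(), outdir / "coverage.csv")
        ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        with open(outdir / "generator_config.json", "w") as fh:
            json.dump(config_to_dict(gen_config), fh, indent=2, default=str)
    else:
        required = ("events", "claims", "participants", "coverage")
        missing = [k for k in required if k not in config.inputs]
        if missing:
            raise ValueError(f"files mode requires input path(s): {', '.join(missing)}")
        events = read_events(config.inputs["events"])
        claims = read_claims(config.inputs["claims"])
        participants = read_participants(config.inputs["participants"], config.inputs["coverage"])

    # --- classify, build episodes, link ----------------------------------
    analysis, excluded, diag = build_analysis_set(
        events, claims, participants, taxonomy, window=config.window, sofa_table=config.sofa_table
    )
    if analysis.empty:
        warnings.warn("analysis set is empty after exclusions")

    # --- agreement --------------------------------------------------------
    seed_seq = np.random.SeedSequence(config.seed)
    boot_seeds = [int(s) for s in seed_seq.generate_state(3) % (2**31)]
    B, alpha, method = config.bootstrap_reps, config.bootstrap_alpha, config.bootstrap_method
    agreement = _agreement_or_empty(analysis, B, boot_seeds[0], alpha, method)

    subgroup = primary_infection_subgroup(analysis)
    agreement_subgroup = _agreement_or_empty(subgroup, B, boot_seeds[1], alpha, method)

    rw = config.recent_window
    recent = analysis[
        (analysis["admission_date"] >= rw[0]) & (analysis["admission_date"] <= rw[1])
    ].reset_index(drop=True)
    agreement_recent = _agreement_or_empty(recent, B, boot_seeds[2], alpha, method)

    # --- mortality --------------------------------------------------------
    if analysis.empty:
        followup = pd.DataFrame(
            columns=["event_id", "participant_id", "start", "end", "died", "stop_cause",
                     "person_days", "person_years", *CLASSIFIER_FLAGS]
        )
        mortality = pd.DataFrame(
            columns=["group", "label", "events", "deaths", "person_years", "rate_per_100py"]
        )
        survival = pd.DataFrame()
    else:
        followup = build_followup(
            analysis, participants, config.horizon_days, config.same_day_person_days
        )
        mortality = mortality_report(followup)
        survival = survival_dataset(followup, analysis)

    prev_table = _prevalence_table(analysis)

    # --- write bundle -----------------------------------------------------
    tables = {
        "analysis.csv": analysis,
        "excluded.csv": excluded,
        "prevalence.csv": prev_table,
        "agreement.csv": agreement,
        "agreement_subgroup.csv": agreement_subgroup,
        "agreement_recent.csv": agreement_recent,
        "mortality_rates.csv": mortality,
        "survival.csv": survival,
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, index=False)

    if write_plots and not analysis.empty:
        from .agreement import cross_tabulate, spine_plot
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 3, figsize=(12, 8))
        for ax, (index_col, standard_col) in zip(axes.ravel(), DEFAULT_PAIRS):
            t = cross_tabulate(analysis[index_col].to_numpy(), analysis[standard_col].to_numpy())
            spine_plot(t, index_col, standard_col, ax=ax)
            ax.set_title(f"{index_col} vs {standard_col}", fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "spine_plots.png", dpi=120)
        plt.close(fig)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "mode": mode,
        "config_hash": config_hash(config),
        "bootstrap": {"B": B, "alpha": alpha, "method": method, "seeds": boot_seeds},
        "row_counts": {
            "events": len(events),
            "claims": len(claims),
            "participants": len(participants),
            "analysis_set": len(analysis),
            "subgroup": len(subgroup),
            "recent_window": len(recent),
        },
        "exclusions": diag.n_excluded,
        "linkage": {"n_matched": diag.n_matched, "n_multi_match": diag.n_multi_match},
        "outputs": sorted(tables),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        analysis=analysis,
        excluded=excluded,
        prevalence=prev_table,
        agreement=agreement,
        agreement_subgroup=agreement_subgroup,
        agreement_recent=agreement_recent,
        mortality=mortality,
        survival=survival,
        manifest=manifest,
        ground_truth=ground_truth,
    )
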