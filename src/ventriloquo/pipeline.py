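"""End-to-end analysis pipeline: cohort → effects → three-step fits → report.

``run_analysis`` accepts either a tidy trial table (path or DataFrame) or a
simulation configuration, computes per-participant effect summaries and the
three-step model fits, aggregates a group-level BIC comparison table
(group mean ± SEM per family with within-group rankings) and the group
statistics, and optionally writes everything as delimiter-separated text,
JSON and figures.  Deterministic given the config and seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import cohort_metadata, cohort_to_frame, simulate_cohort
from .design import Apparatus, DEFAULT_APPARATUS, TrialSequence, validate_sequence
from .effects import GroupTestReport, group_tests, summarize_cohort
from .fitting import FAMILIES, FitConfig, fit_participant
from .io import read_trial_table, write_trial_table

__all__ = ["AnalysisReport", "run_analysis", "load_cohort_frame", "apparatus_from_config"]


def apparatus_from_config(cfg: dict | None) -> Apparatus:
    cfg = cfg or {}
    return Apparatus(
        speaker_azimuths=tuple(cfg.get("speaker_azimuths", (-15.0, -5.0, 5.0, 15.0))),
        button_count=int(cfg.get("button_count", 12)),
        button_spacing=float(cfg.get("button_spacing_deg", 10.0 / 3.0)),
    )


@dataclass
class AnalysisReport:
    """All pipeline outputs for one cohort."""

    effects: pd.DataFrame
    fits: pd.DataFrame
    best_models: pd.DataFrame
    group_bic: pd.DataFrame
    tests: GroupTestReport | None
    excluded: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.effects.to_csv(out / "effects.tsv", sep="\t", index=False)
        if not self.fits.empty:
            self.fits.to_csv(out / "fits.tsv", sep="\t", index=False)
            self.best_models.to_csv(out / "best_models.tsv", sep="\t", index=False)
            self.group_bic.to_csv(out / "group_bic.tsv", sep="\t", index=False)
        if self.tests is not None:
            self.tests.welch.to_csv(out / "welch.tsv", sep="\t", index=False)
            self.tests.games_howell.to_csv(out / "games_howell.tsv", sep="\t", index=False)
            self.tests.one_sample.to_csv(out / "one_sample_t.tsv", sep="\t", index=False)
            self.tests.spearman.to_csv(out / "spearman.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(self.metadata, indent=2))

    def summary(self) -> str:
        parts = [
            f"Participants analysed: {self.effects.shape[0]} "
            f"({len(self.excluded)} excluded)",
            "\nGroup-mean effects (degrees):",
            self.effects.groupby("group")[
                [c for c in self.effects.columns if c not in ("participant", "group")]
            ].mean().round(2).to_string(),
        ]
        if not self.group_bic.empty:
            parts += ["\nGroup-mean BIC (rank within group):",
                      self.group_bic.round(2).to_string(index=False)]
        return "\n".join(parts)


def load_cohort_frame(source) -> pd.DataFrame:
    """Coerce a path, DataFrame, or list of participant datasets to one tidy frame."""
    if isinstance(source, (str, Path)):
        return read_trial_table(source)
    if isinstance(source, pd.DataFrame):
        return source
    return cohort_to_frame(list(source))


def _group_bic_table(fits: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for group, gdata in fits.groupby("group"):
        agg = gdata.groupby("family")["bic"].agg(["mean", "sem", "count"])
        agg["rank"] = agg["mean"].rank(method="min").astype(int)
        for family, r in agg.iterrows():
            rows.append(
                {
                    "group": group,
                    "family": family,
                    "bic_mean": r["mean"],
                    "bic_sem": r["sem"],
                    "n": int(r["count"]),
                    "rank": int(r["rank"]),
                }
            )
    return pd.DataFrame(rows)


def _validate_participant(pdata: pd.DataFrame, apparatus: Apparatus) -> list[str]:
    problems = []
    for block in (1, 2):
        bdata = pdata[pdata["block"] == block]
        if bdata.empty:
            problems.append(f"block {block} missing")
            continue
        seq = TrialSequence.from_frame(bdata, block=block)
        report = validate_sequence(seq, apparatus)
        problems += [f"block {block}: {v}" for v in report.violations]
    return problems


def run_analysis(
    cohort_source=None,
    *,
    simulate: dict | None = None,
    fit_config: FitConfig | None = None,
    families=FAMILIES,
    do_fit: bool = True,
    apparatus: Apparatus = DEFAULT_APPARATUS,
    seed: int = 0,
    out_dir=None,
) -> AnalysisReport:
    """Run the full analysis.

    Exactly one of ``cohort_source`` (path / tidy frame / dataset list) or
    ``simulate`` (kwargs for :func:`ventriloquo.cohort.simulate_cohort`) must
    be given.  ``do_fit=False`` skips the (slow) model-fitting stages and
    reports effects only.
    """
    metadata: dict = {"seed": seed, "version": __version__}
    if (cohort_source is None) == (simulate is None):
        raise ValueError("provide exactly one of cohort_source or simulate")
    if simulate is not None:
        sim_kwargs = dict(simulate)
        sim_kwargs.setdefault("seed", seed)
        datasets = simulate_cohort(apparatus=apparatus, **sim_kwargs)
        frame = cohort_to_frame(datasets)
        metadata["simulated"] = {
            "n_participants": len(datasets),
            "seed": sim_kwargs["seed"],
        }
        metadata["ground_truth"] = cohort_metadata(datasets).to_dict("records")
    else:
        frame = load_cohort_frame(cohort_source)

    excluded, effect_frames, fit_rows, best_rows = [], [], [], []
    for participant, pdata in frame.groupby("participant", sort=False):
        problems = _validate_participant(pdata, apparatus)
        if problems:
            excluded.append({"participant": participant, "problems": problems})
            continue
        effect_frames.append(pdata)
    if not effect_frames:
        raise ValueError("no participant passed sequence validation")
    valid = pd.concat(effect_frames, ignore_index=True)
    effects = summarize_cohort(
        [g for _, g in valid.groupby("participant", sort=False)], apparatus
    )

    fits = pd.DataFrame()
    best = pd.DataFrame()
    if do_fit:
        fit_config = fit_config or FitConfig()
        for participant, pdata in valid.groupby("participant", sort=False):
            group = pdata["group"].iloc[0]
            report = fit_participant(
                pdata[pdata["block"] == 1],
                pdata[pdata["block"] == 2],
                participant=str(participant),
                families=families,
                apparatus=apparatus,
                config=fit_config,
            )
            tbl = report.bic_table()
            tbl.insert(1, "group", group)
            fit_rows.append(tbl)
            b2 = report.block2_fit
            best_rows.append(
                {
                    "participant": participant,
                    "group": group,
                    "best_family": report.best_family,
                    **{f"b1_{k}": v for k, v in report.block1_fits[report.best_family].params.items()},
                    **{f"b2_{k}": v for k, v in b2.params.items()},
                    "b1_bic": report.block1_fits[report.best_family].bic,
                    "b2_bic": b2.bic,
                }
            )
        fits = pd.concat(fit_rows, ignore_index=True)
        best = pd.DataFrame(best_rows)
        metadata["fit_config"] = {
            "n_sim": fit_config.n_sim,
            "grid_points_per_param": fit_config.grid_points_per_param,
            "seed": fit_config.seed,
            "families": list(families),
        }

    tests = None
    if effects["group"].nunique() >= 2 and (effects.groupby("group").size() >= 2).sum() >= 2:
        tests = group_tests(effects)

    report = AnalysisReport(
        effects=effects,
        fits=fits,
        best_models=best,
        group_bic=_group_bic_table(fits) if not fits.empty else pd.DataFrame(),
        tests=tests,
        excluded=excluded,
        metadata=metadata,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
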