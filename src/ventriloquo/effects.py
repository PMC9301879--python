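"""Trial-level ventriloquism statistics and group-level tests.

All effects are computed on signed localization errors obtained by
baseline-coding: button responses (1..12) are averaged over the 10 unimodal
Block 1 trials per modality and stimulus location, and this per-cell
baseline is subtracted from every response of both blocks.  Positive errors
indicate rightward bias; all effects are expressed in degrees (one response
unit = the button spacing).

* **VE** (ventriloquism effect): mean AV-trial error after rightward
  discrepancies (V right of A) minus mean error after leftward
  discrepancies, Block 1.  Positive values mean attraction of the response
  toward the V location.
* **VAEi** (immediate aftereffect): the same right-minus-left contrast on
  unimodal Block 1 trials, conditioned on the discrepancy of the nearest
  preceding AV trial (interjacent unimodal trials are skipped;
  zero-discrepancy predecessors are excluded from the contrast).
* **VAEc** (cumulative aftereffect): mean signed error over the unimodal
  trials of Block 2, whose AV trials carry a constant +10° discrepancy.
* **SD_A / SD_V**: precision, the SD of the unimodal Block 1 errors.

Group-level comparisons use Welch's heteroscedastic ANOVA with Games-Howell
post-hoc tests; one-sample directional t-tests against zero are
Holm-corrected per effect type; associations between effects are Spearman
rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import Apparatus, DEFAULT_APPARATUS

__all__ = [
    "localization_errors",
    "ventriloquism_effect",
    "immediate_aftereffect",
    "cumulative_aftereffect",
    "unimodal_precision",
    "effect_summary",
    "summarize_cohort",
    "group_tests",
    "GroupTestReport",
    "EFFECT_COLUMNS",
]

EFFECT_COLUMNS = ("VE_A", "VE_V", "VAEi_A", "VAEi_V", "VAEc_A", "VAEc_V")


def _tidy(data) -> pd.DataFrame:
    if hasattr(data, "to_frame") and not isinstance(data, pd.DataFrame):
        data = data.to_frame()
    frame = data.copy()
    if "participant" not in frame.columns:
        frame["participant"] = "p0"
    if "group" not in frame.columns:
        frame["group"] = "NA"
    return frame


def localization_errors(
    data, apparatus: Apparatus = DEFAULT_APPARATUS
) -> pd.DataFrame:
    """Baseline-coded signed localization errors, one row per response.

    ``data`` is a tidy trial table (or an object with ``to_frame()``):
    columns participant, group, block, trial_index, modality, s_A, s_V,
    resp_A, resp_V.  The returned table has one row per *response* with the
    response modality, its stimulus azimuth, the error in response units and
    degrees, and (for unimodal Block 1 rows) the discrepancy of the nearest
    preceding AV trial.
    """
    frame = _tidy(data)
    out_rows = []
    for participant, pdata in frame.groupby("participant", sort=False):
        pdata = pdata.sort_values(["block", "trial_index"])
        group = pdata["group"].iloc[0]

        base = {}
        b1 = pdata[pdata["block"] == 1]
        for mod, (s_col, r_col) in (("A", ("s_A", "resp_A")), ("V", ("s_V", "resp_V"))):
            uni = b1[b1["modality"] == mod]
            for loc, cell in uni.groupby(s_col):
                base[(mod, float(loc))] = float(cell[r_col].mean())
        for loc in (np.asarray(apparatus.speaker_azimuths, float)):
            for mod in ("A", "V"):
                if (mod, float(loc)) not in base:
                    raise ValueError(
                        f"participant {participant}: no Block 1 unimodal {mod} "
                        f"trials at {loc:+g}° to establish a baseline"
                    )

        for block, bdata in pdata.groupby("block"):
            last_disc = np.nan
            for _, row in bdata.iterrows():
                mods = ("A", "V") if row["modality"] == "AV" else (row["modality"],)
                disc = (
                    row["s_V"] - row["s_A"] if row["modality"] == "AV" else np.nan
                )
                for mod in mods:
                    s = row["s_A"] if mod == "A" else row["s_V"]
                    resp = row["resp_A"] if mod == "A" else row["resp_V"]
                    err_units = float(resp) - base[(mod, float(s))]
                    out_rows.append(
                        {
                            "participant": participant,
                            "group": group,
                            "block": int(block),
                            "trial_index": int(row["trial_index"]),
                            "modality": row["modality"],
                            "response_modality": mod,
                            "s": float(s),
                            "resp": int(resp),
                            "error_units": err_units,
                            "error_deg": err_units * apparatus.button_spacing,
                            "discrepancy": disc,
                            "preceding_disc": (
                                last_disc if row["modality"] != "AV" else np.nan
                            ),
                        }
                    )
                if row["modality"] == "AV":
                    last_disc = disc
    return pd.DataFrame(out_rows)


def _rl_contrast(sub: pd.DataFrame, disc_col: str) -> float:
    right = sub[sub[disc_col] > 0]["error_deg"]
    left = sub[sub[disc_col] < 0]["error_deg"]
    if right.empty or left.empty:
        return np.nan
    return float(right.mean() - left.mean())


def ventriloquism_effect(errors: pd.DataFrame) -> tuple[float, float]:
    """(VE_A, VE_V): right-minus-left AV error contrast, Block 1, degrees."""
    av = errors[(errors["block"] == 1) & (errors["modality"] == "AV")]
    return (
        _rl_contrast(av[av["response_modality"] == "A"], "discrepancy"),
        _rl_contrast(av[av["response_modality"] == "V"], "discrepancy"),
    )


def immediate_aftereffect(errors: pd.DataFrame) -> tuple[float, float]:
    """(VAEi_A, VAEi_V): right-minus-left contrast on the preceding AV discrepancy."""
    uni = errors[
        (errors["block"] == 1)
        & (errors["modality"] != "AV")
        & errors["preceding_disc"].notna()
    ]
    return (
        _rl_contrast(uni[uni["response_modality"] == "A"], "preceding_disc"),
        _rl_contrast(uni[uni["response_modality"] == "V"], "preceding_disc"),
    )


def cumulative_aftereffect(errors: pd.DataFrame) -> tuple[float, float]:
    """(VAEc_A, VAEc_V): mean unimodal Block 2 error (Block 1 baselines), degrees."""
    uni = errors[(errors["block"] == 2) & (errors["modality"] != "AV")]
    out = []
    for mod in ("A", "V"):
        vals = uni[uni["response_modality"] == mod]["error_deg"]
        out.append(float(vals.mean()) if not vals.empty else np.nan)
    return tuple(out)


def unimodal_precision(errors: pd.DataFrame) -> tuple[float, float]:
    """(SD_A, SD_V): SD of unimodal Block 1 errors per modality, degrees."""
    uni = errors[(errors["block"] == 1) & (errors["modality"] != "AV")]
    out = []
    for mod in ("A", "V"):
        vals = uni[uni["response_modality"] == mod]["error_deg"]
        out.append(float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return tuple(out)


def effect_summary(data, apparatus: Apparatus = DEFAULT_APPARATUS) -> dict:
    """Per-participant effect summary (degrees): VE, VAEi, VAEc, precision."""
    errors = localization_errors(data, apparatus)
    participants = errors["participant"].unique()
    if len(participants) != 1:
        raise ValueError("effect_summary expects a single participant")
    ve = ventriloquism_effect(errors)
    vaei = immediate_aftereffect(errors)
    vaec = cumulative_aftereffect(errors)
    sd = unimodal_precision(errors)
    return {
        "participant": participants[0],
        "group": errors["group"].iloc[0],
        "VE_A": ve[0], "VE_V": ve[1],
        "VAEi_A": vaei[0], "VAEi_V": vaei[1],
        "VAEc_A": vaec[0], "VAEc_V": vaec[1],
        "SD_A": sd[0], "SD_V": sd[1],
    }


def summarize_cohort(datasets, apparatus: Apparatus = DEFAULT_APPARATUS) -> pd.DataFrame:
    """Effect summaries for a list of participant datasets (or tidy frames)."""
    return pd.DataFrame([effect_summary(d, apparatus) for d in datasets])


@dataclass
class GroupTestReport:
    """Group-level statistics over per-participant effect summaries."""

    welch: pd.DataFrame
    games_howell: pd.DataFrame
    one_sample: pd.DataFrame
    spearman: pd.DataFrame
    excluded_groups: list

    def summary(self) -> str:
        parts = ["Welch ANOVA per effect:", self.welch.to_string(index=False)]
        parts += ["\nOne-sample t-tests (Holm per effect type):",
                  self.one_sample.to_string(index=False)]
        return "\n".join(parts)


def _spearman_block(summaries: pd.DataFrame, label: str) -> list[dict]:
    pairs = [("VE", "VAEi"), ("VE", "VAEc"), ("VAEi", "VAEc")]
    rows = []
    for mod in ("A", "V"):
        for a, b in pairs:
            x = summaries[f"{a}_{mod}"]
            y = summaries[f"{b}_{mod}"]
            mask = x.notna() & y.notna()
            if mask.sum() < 3:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x[mask], y[mask])
            rows.append(
                {"scope": label, "modality": mod, "pair": f"{a}-{b}",
                 "rho": float(rho), "p": float(p)}
            )
    return rows


def group_tests(
    summaries: pd.DataFrame,
    effects: tuple[str, ...] = EFFECT_COLUMNS,
    alternative: str = "greater",
) -> GroupTestReport:
    """Welch ANOVA, Games-Howell, Holm-corrected one-sample t, Spearman.

    One-sample tests are one-tailed (default: effect larger than zero) and
    Holm-corrected within each effect type (e.g. the six VE tests across
    modalities and groups form one family).  Groups with fewer than two
    members are excluded with a warning entry.
    """
    counts = summaries.groupby("group").size()
    excluded = list(counts[counts < 2].index)
    data = summaries[~summaries["group"].isin(excluded)].copy()
    if data["group"].nunique() < 2:
        raise ValueError("need at least two groups of size >= 2")

    welch_rows, gh_rows, t_rows = [], [], []
    for eff in effects:
        sub = data[["group", eff]].dropna().rename(columns={eff: "value"})
        aov = pg.welch_anova(data=sub, dv="value", between="group")
        welch_rows.append(
            {
                "effect": eff,
                "F": float(aov["F"].iloc[0]),
                "df1": float(aov["ddof1"].iloc[0]),
                "df2": float(aov["ddof2"].iloc[0]),
                "p": float(aov["p_unc"].iloc[0]),
            }
        )
        gh = pg.pairwise_gameshowell(data=sub, dv="value", between="group")
        for _, row in gh.iterrows():
            gh_rows.append(
                {
                    "effect": eff,
                    "A": row["A"],
                    "B": row["B"],
                    "diff": float(row["diff"]),
                    "T": float(row["T"]),
                    "df": float(row["df"]),
                    "p": float(row["pval"]),
                }
            )
        for grp, cell in sub.groupby("group"):
            t, p = stats.ttest_1samp(
                cell["value"], popmean=0.0, alternative=alternative
            )
            t_rows.append(
                {
                    "effect": eff,
                    "effect_type": eff.split("_")[0],
                    "group": grp,
                    "n": len(cell),
                    "mean": float(cell["value"].mean()),
                    "t": float(t),
                    "p": float(p),
                }
            )

    one_sample = pd.DataFrame(t_rows)
    one_sample["p_holm"] = np.nan
    for _, idx in one_sample.groupby("effect_type").groups.items():
        reject, p_adj, _, _ = multipletests(
            one_sample.loc[idx, "p"], method="holm"
        )
        one_sample.loc[idx, "p_holm"] = p_adj
        one_sample.loc[idx, "significant"] = reject

    spearman_rows = _spearman_block(data, "overall")
    for grp, gdata in data.groupby("group"):
        spearman_rows += _spearman_block(gdata, str(grp))

    return GroupTestReport(
        welch=pd.DataFrame(welch_rows),
        games_howell=pd.DataFrame(gh_rows),
        one_sample=one_sample,
        spearman=pd.DataFrame(spearman_rows),
        excluded_groups=excluded,
    )
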