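"""End-to-end analysis pipeline.

Assembles the full study flow -- synthesise (or ingest) a cohort,
compute spectral summaries, classify groups, apply inclusion rules,
and run every group comparison -- and writes the result tables:

* ``table1_demographics.csv``  -- demographic / clinical comparisons
  (ANOVA for continuous rows, chi-square for categorical rows)
* ``table2_psg.csv``           -- sleep-architecture metrics with ANOVA
  and Bonferroni post-hoc pairs
* ``table3_total_sleep.csv``   -- per-band group means, ANOVA and
  covariate-adjusted ANCOVA over total sleep (Bonferroni x5)
* ``table4_nrem_rem.csv``      -- the same over NREM and REM sleep
  (Bonferroni x10)
* ``matched_reanalysis.csv``   -- NI-vs-HI comparison repeated on the
  1:5 propensity-matched subset
* ``run_log.txt``              -- config, seeds, versions, exclusion
  cascade

The pipeline is a pure function of (inputs, config, seed): identical
runs produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .edf_io import read_edf, read_hypnogram
from .grouping import (EXCLUDED, GROUPS, QUESTION_COLUMNS, apply_inclusion,
                       classify_groups, psg_metrics)
from .hypnogram import N1, N2, N3, REM
from .spectral import (BAND_NAMES, DEFAULT_MIN_FREQ, NREM, REM_STATE, STATES,
                       TOTAL, default_bands, participant_summary)
from .stats import (ancova_group_comparison, bonferroni, format_p,
                    one_way_anova, pearson_chi_square, propensity_match)
from .synthetic import (SyntheticConfig, generate_feature_cohort,
                        generate_hypnograms_batch)

#: covariates entering every ANCOVA (untransformed; binning is used only
#: inside the propensity model)
ANCOVA_COVARIATES = ("age", "sex_female", "ahi", "current_smoking",
                     "alcohol_per_day", "tca", "non_tca", "benzodiazepine")

CONTINUOUS_TABLE1 = ("age", "bmi", "alcohol_per_day", "ess")
CATEGORICAL_TABLE1 = ("sex_female", "current_smoking", "tca", "non_tca",
                      "benzodiazepine")
SYMPTOM_ROWS = (("sleep_initiation", "q1_initiation"),
                ("sleep_maintenance", "q2_maintenance"),
                ("early_awakening", "q3_early_awakening"),
                ("sleeping_pills", "q4_sleeping_pills"))


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    mode: str = "synthesize"                # "synthesize" | "ingest"
    output_dir: str = "results/pipeline"
    seed: int = 0
    min_freq: float = DEFAULT_MIN_FREQ
    total_correction_factor: float = 5.0    # five bands, total sleep
    nrem_rem_correction_factor: float = 10.0  # five bands x two states
    match_ratio: int = 5
    match_seed: Optional[int] = None        # defaults to seed
    psg_epochs: int = 960                   # simulated night length, 8 h
    write_participants: bool = True         # dump the analysed cohort CSV
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # ingest-mode paths
    edf_dir: Optional[str] = None
    hypnogram_dir: Optional[str] = None
    participant_csv: Optional[str] = None

    def validate(self) -> None:
        if self.mode not in ("synthesize", "ingest"):
            raise ValueError(f"mode must be synthesize|ingest, got {self.mode!r}")
        if self.total_correction_factor < 1 or self.nrem_rem_correction_factor < 1:
            raise ValueError("correction factors must be >= 1")
        if self.mode == "ingest":
            for name in ("edf_dir", "hypnogram_dir", "participant_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"ingest mode requires existing path for {name}: {p}")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage (and participant)."""


def _mean_sd(values: pd.Series) -> str:
    return f"{values.mean():.1f} ± {values.std(ddof=1):.1f}"


def _n_pct(flags: pd.Series) -> str:
    n = int(flags.sum())
    return f"{n} ({100.0 * n / len(flags):.1f}%)"


def _present(levels) -> Tuple[str, ...]:
    return tuple(g for g in GROUPS if g in set(levels))


def build_table1(df: pd.DataFrame) -> pd.DataFrame:
    """Demographic/clinical group comparison table."""
    groups = _present(df["group"])
    by = {g: df[df["group"] == g] for g in groups}
    rows: List[dict] = []

    def add_row(variable, cells, result):
        row = {"variable": variable}
        for g in groups:
            row[g] = cells[g]
        row["test"] = result.test
        row["statistic"] = round(result.statistic, 2)
        row["df"] = "/".join(f"{d:g}" for d in result.df)
        row["p"] = format_p(result.p_raw)
        rows.append(row)

    for var in CONTINUOUS_TABLE1:
        if var not in df.columns:
            continue
        res = one_way_anova(df[var], df["group"])
        add_row(var, {g: _mean_sd(by[g][var]) for g in groups}, res)
    for var in CATEGORICAL_TABLE1:
        if var not in df.columns:
            continue
        table = [[int(by[g][var].sum()), int((1 - by[g][var]).sum())]
                 for g in groups]
        try:
            res = pearson_chi_square(table)
        except ValueError:
            continue                      # zero-margin category in a tiny cohort
        add_row(var, {g: _n_pct(by[g][var]) for g in groups}, res)
    for label, col in SYMPTOM_ROWS:
        if col not in df.columns:
            continue
        present = df[col] == 5
        table = [[int(present[df["group"] == g].sum()),
                  int((~present[df["group"] == g]).sum())] for g in groups]
        try:
            res = pearson_chi_square(table)
        except ValueError:
            continue                      # a symptom absent everywhere
        add_row(label, {g: _n_pct(present[df["group"] == g]) for g in groups}, res)
    return pd.DataFrame(rows)


def simulate_psg_table(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Per-participant sleep-architecture metrics from simulated hypnograms."""
    hyps = generate_hypnograms_batch(
        config.synthetic.hypnogram_model, len(df), config.psg_epochs,
        seed=config.seed + 1)
    rows = []
    for (_, part), hyp in zip(df.iterrows(), hyps):
        m = psg_metrics(hyp)
        rows.append({
            "participant_id": part["participant_id"],
            "group": part["group"],
            "time_in_bed_min": m.time_in_bed_min,
            "total_sleep_time_min": m.total_sleep_time_min,
            "sleep_efficiency_pct": m.sleep_efficiency_pct,
            "waso_min": m.waso_min,
            "rem_latency_min": m.rem_latency_min,
            "pct_n1": m.stage_pct[N1], "pct_n2": m.stage_pct[N2],
            "pct_n3": m.stage_pct[N3], "pct_rem": m.stage_pct[REM],
        })
    return pd.DataFrame(rows)


def build_table2(psg: pd.DataFrame) -> pd.DataFrame:
    """ANOVA + Bonferroni post-hoc comparison of PSG metrics."""
    groups = _present(psg["group"])
    metrics = [c for c in psg.columns if c not in ("participant_id", "group")]
    rows = []
    for metric in metrics:
        sub = psg[["group", metric]].dropna()
        res = ancova_group_comparison(sub[metric], sub["group"])
        cells = {g: _mean_sd(sub[sub["group"] == g][metric]) for g in groups}
        rows.append({
            "variable": metric, **cells,
            "anova_F": round(res.f_statistic, 2),
            "anova_p": format_p(res.p_raw),
            "significant_pairs": "; ".join(
                f"{a} vs {b}" for a, b in res.significant_pairs) or "None",
        })
    return pd.DataFrame(rows)


def build_spectral_table(df: pd.DataFrame, states: Sequence[str],
                         correction_factor: float) -> pd.DataFrame:
    """Band-power group comparisons for the given sleep states.

    Per state and band: group mean +/- SD of the log10 power, raw-data
    ANOVA, covariate-adjusted ANCOVA, both Bonferroni-corrected by
    ``correction_factor``, and the post-hoc significant pairs.
    """
    groups = _present(df["group"])
    rows = []
    for state in states:
        for band in BAND_NAMES:
            col = f"{state}_{band}"
            covs = [c for c in ANCOVA_COVARIATES if c in df.columns]
            sub = df[["group", col, *covs]].dropna()
            covs = [c for c in covs if sub[c].nunique() > 1]
            anova = one_way_anova(sub[col], sub["group"])
            anova.with_correction(correction_factor)
            # adjust for covariates only when the design leaves residual df
            if len(sub) <= len(groups) + len(covs) + 2:
                covs = []
            ancova = ancova_group_comparison(
                sub[col], sub["group"], sub[list(covs)],
                correction_factor=correction_factor)
            row = {"state": state, "band": band}
            for g in groups:
                vals = sub[sub["group"] == g][col]
                row[g] = f"{vals.mean():.3f} ± {vals.std(ddof=1):.3f}"
            row.update({
                "anova_F": round(anova.statistic, 2),
                "anova_p": format_p(anova.p_raw),
                "anova_p_corr": format_p(anova.p_corrected),
                "ancova_F": round(ancova.f_statistic, 2),
                "ancova_p": format_p(ancova.p_raw),
                "ancova_p_corr": format_p(ancova.p_corrected),
                "ancova_significant": ancova.p_corrected is not None
                                      and ancova.p_corrected < 0.05,
                "posthoc_significant_pairs": "; ".join(
                    f"{a} vs {b}" for a, b in ancova.significant_pairs) or "None",
            })
            rows.append(row)
    return pd.DataFrame(rows)


def matched_reanalysis(df: pd.DataFrame, treated_label: str = "HI",
                       control_label: str = "NI", ratio: int = 5,
                       seed: int = 0) -> Tuple[pd.DataFrame, "object"]:
    """Repeat the band comparisons on the propensity-matched subset."""
    match = propensity_match(df, treated_label, control_label,
                             ratio=ratio, seed=seed)
    subset = df[df["participant_id"].isin(match.matched_ids())]
    rows = []
    for state in STATES:
        for band in BAND_NAMES:
            col = f"{state}_{band}"
            if col not in subset.columns:
                continue
            sub = subset[["group", col, *ANCOVA_COVARIATES]].dropna()
            # constant covariates in the matched subset carry no information
            covs = [c for c in ANCOVA_COVARIATES if sub[c].nunique() > 1]
            res = ancova_group_comparison(sub[col], sub["group"], sub[covs])
            diff = (res.adjusted_means[treated_label]
                    - res.adjusted_means[control_label])
            rows.append({
                "state": state, "band": band,
                "n_treated": int((sub["group"] == treated_label).sum()),
                "n_control": int((sub["group"] == control_label).sum()),
                "adjusted_diff": round(diff, 4),
                "ancova_F": round(res.f_statistic, 2),
                "ancova_p": format_p(res.p_raw),
                "significant": res.p_raw < 0.05,
            })
    return pd.DataFrame(rows), match


def ingest_cohort(config: RunConfig) -> pd.DataFrame:
    """Read a participant table and compute spectral summaries from files.

    Expects ``<edf_dir>/<participant_id>.edf`` and
    ``<hypnogram_dir>/<participant_id>.csv`` for every row of the
    participant CSV.
    """
    df = pd.read_csv(config.participant_csv)
    bands = default_bands()
    summaries = []
    for pid in df["participant_id"]:
        try:
            rec = read_edf(Path(config.edf_dir) / f"{pid}.edf")
            hyp = read_hypnogram(Path(config.hypnogram_dir) / f"{pid}.csv")
            summ = participant_summary(rec, hyp, bands, min_freq=config.min_freq)
        except Exception as exc:
            raise PipelineStageError(
                f"spectral stage failed for participant {pid}: {exc}") from exc
        row = {"participant_id": pid}
        for state in STATES:
            for band in BAND_NAMES:
                row[f"{state}_{band}"] = summ.log_power[state][band]
        summaries.append(row)
    return df.merge(pd.DataFrame(summaries), on="participant_id")


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full analysis and write the output bundle.

    Returns the output tables keyed by name, plus the kept cohort and
    the exclusion cascade.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = io.StringIO()
    from . import __version__ as pkg_version
    log.write(f"sleepqeeg {pkg_version} pipeline run\n")
    for mod in ("numpy", "scipy", "pandas", "statsmodels", "sklearn"):
        log.write(f"  {mod} {__import__(mod).__version__}\n")
    log.write(f"mode: {config.mode}\nseed: {config.seed}\n")
    log.write(f"config: {dataclasses.asdict(config)}\n")

    if config.mode == "synthesize":
        cohort = generate_feature_cohort(
            dataclasses.replace(config.synthetic, seed=config.seed))
        participants = cohort.participants
    else:
        participants = ingest_cohort(config)

    participants = participants.copy()
    participants["group"] = classify_groups(participants)
    kept, cascade = apply_inclusion(participants)
    log.write("exclusion cascade:\n")
    log.write(cascade.to_string(index=False) + "\n")
    log.write(f"analysed participants: {len(kept)}\n")
    for g in GROUPS:
        log.write(f"  {g}: {int((kept['group'] == g).sum())}\n")

    tables: Dict[str, pd.DataFrame] = {}
    tables["table1_demographics"] = build_table1(kept)
    if config.mode == "synthesize":
        psg = simulate_psg_table(kept, config)
        tables["table2_psg"] = build_table2(psg)
    tables["table3_total_sleep"] = build_spectral_table(
        kept, [TOTAL], config.total_correction_factor)
    tables["table4_nrem_rem"] = build_spectral_table(
        kept, [NREM, REM_STATE], config.nrem_rem_correction_factor)

    match_seed = config.match_seed if config.match_seed is not None else config.seed
    matched_table, match = matched_reanalysis(
        kept, ratio=config.match_ratio, seed=match_seed)
    tables["matched_reanalysis"] = matched_table
    log.write(f"propensity matching: {len(match.matches)} treated, "
              f"{match.n_matched_controls} matched controls "
              f"(ratio 1:{config.match_ratio}, seed {match_seed})\n")

    if config.write_participants:
        kept.to_csv(out / "participants.csv", index=False, float_format="%.6g")
    for name, table in tables.items():
        table.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
    (out / "run_log.txt").write_text(log.getvalue())

    return {**tables, "participants": kept, "cascade": cascade, "match": match}
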