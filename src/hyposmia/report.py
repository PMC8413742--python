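"""End-to-end report surfaces: descriptive, prevalence, agreement and model tables,
plus the grouped-bar prevalence figure contrasting PD cases with simulated controls.

Every writer embeds the seed and a config hash as a comment header so that a
re-run with the same configuration reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .agreement import pairwise_agreement
from .classify import classify_cohort
from .cohort import Cohort, compare_cohorts, summarize_cohort
from .conversion import ConversionTable, convert_scores
from .normative import (
    NormativeModel,
    PDGeneratorConfig,
    PPMI_CONFIG,
    derive_centile_cutoffs,
    generate_pd_cohort,
    prevalence_to_frame,
    sample_reference,
    simulate_counterfactual,
)
from .regress import fit_binary_model, fit_linear_model, fit_ordered_model

DEFAULT_CONFIG = {
    "seed": 20210630,
    "replicates": 2000,
    "reference_n": 100000,
    "method4_cutoff": 27,
    "generators": {
        "tracking": {},      # PDGeneratorConfig defaults
        "ppmi": "ppmi",      # named preset
    },
    "normative": {},          # NormativeModel defaults
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, config: dict) -> None:
    """CSV with a reproducibility header (# seed=..., config=...)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# seed={config.get('seed')} config={config_hash(config)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")


def build_generator_config(block, seed: int) -> PDGeneratorConfig:
    if block == "ppmi":
        return PPMI_CONFIG.__class__(**{**PPMI_CONFIG.__dict__, "seed": seed + 1})
    return PDGeneratorConfig(**{**block, "seed": block.get("seed", seed)})


def descriptive_table(cohorts: dict[str, Cohort]) -> pd.DataFrame:
    """Table of per-cohort descriptors with between-cohort comparison p-values."""
    rows = []
    names = list(cohorts)
    summaries = {k: summarize_cohort(c) for k, c in cohorts.items()}
    variables = [
        ("n", None),
        ("male", "gender"),
        ("age_at_test", "age_at_test"),
        ("disease_duration", "disease_duration"),
        ("score_ss", "score_ss"),
    ]
    for var, testvar in variables:
        row = {"variable": var}
        for k in names:
            s = summaries[k]
            if var == "n":
                row[k] = s["n"]
            elif var == "male":
                row[k] = f"{s['male']['count']} ({s['male']['percent']:.1f}%)"
            elif var in s:
                row[k] = f"{s[var]['mean']:.1f} ({s[var]['sd']:.1f})"
            else:
                row[k] = ""
        if testvar and len(names) == 2:
            try:
                _, p = compare_cohorts(cohorts[names[0]], cohorts[names[1]], testvar)
                row["p"] = p
            except KeyError:
                row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def prevalence_table(cohort: Cohort, matrix: pd.DataFrame,
                     counterfactual: pd.DataFrame) -> pd.DataFrame:
    """PD vs simulated-control prevalence per method and gender, with the
    absolute difference (percentage points)."""
    gender = cohort.df["gender"]
    rows = []
    method_cols = {
        "method1": matrix["method1"],
        "method2_any": matrix["method2_binary"],
        "method3": matrix["method3"],
        "method4": matrix["method4"],
    }
    for method, calls in method_cols.items():
        for stratum in ("male", "female"):
            mask = (gender == stratum).to_numpy()
            pd_prev = 100.0 * calls.to_numpy()[mask].mean() if mask.any() else np.nan
            cf = counterfactual[
                (counterfactual["method"] == method)
                & (counterfactual["stratum"] == stratum)
            ]
            if cf.empty:
                continue
            cf = cf.iloc[0]
            rows.append(
                {
                    "method": method,
                    "stratum": stratum,
                    "pd_percent": pd_prev,
                    "control_percent": cf["point"],
                    "control_ci_low": cf["ci_low"],
                    "control_ci_high": cf["ci_high"],
                    "difference": pd_prev - cf["point"],
                }
            )
    return pd.DataFrame(rows)


def models_table(cohort: Cohort, matrix: pd.DataFrame) -> pd.DataFrame:
    """All six outcome models in one long table (term-level estimates)."""
    rows = []
    lin = fit_linear_model(cohort)
    for _, t in lin.terms.iterrows():
        rows.append({"model": "linear", **t})
    for method in (1, 2, 3, 4):
        res = fit_binary_model(cohort, matrix, method)
        for _, t in res.terms.iterrows():
            rows.append({"model": f"logistic_method{method}", **t})
    ordres = fit_ordered_model(cohort, matrix)
    for _, t in ordres.terms.iterrows():
        rows.append({"model": "ordered_logistic", **t})
    rows.append(
        {
            "model": "ordered_logistic",
            "term": "brant_test",
            "estimate": ordres.diagnostics["brant_chi2"],
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": ordres.diagnostics["brant_p"],
        }
    )
    return pd.DataFrame(rows)


def prevalence_figure(table2: pd.DataFrame, path) -> None:
    """Grouped horizontal bars: PD vs simulated controls per method/gender,
    percentages annotated at the end of the bars."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 5), sharey=True)
    for ax, stratum in zip(axes, ("male", "female")):
        sub = table2[table2["stratum"] == stratum]
        ypos = np.arange(len(sub))
        ax.barh(ypos + 0.2, sub["pd_percent"], height=0.35, label="PD cases",
                color="#c23b22")
        ax.barh(ypos - 0.2, sub["control_percent"], height=0.35,
                label="simulated controls", color="#4878a8")
        for y, v in zip(ypos + 0.2, sub["pd_percent"]):
            ax.text(v + 1, y, f"{v:.1f}", va="center", fontsize=8)
        for y, v in zip(ypos - 0.2, sub["control_percent"]):
            ax.text(v + 1, y, f"{v:.1f}", va="center", fontsize=8)
        ax.set_yticks(ypos)
        ax.set_yticklabels(sub["method"])
        ax.set_xlabel("% hyposmic")
        ax.set_title(stratum)
        ax.set_xlim(0, 110)
    axes[0].legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_report(config: dict, out_dir) -> dict:
    """Full pipeline on synthetic data: generate, convert, classify, agree,
    regress, counterfactual; writes one CSV per result table plus the figure.
    Returns the in-memory tables keyed by name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", DEFAULT_CONFIG["seed"]))
    replicates = int(config.get("replicates", 2000))
    conversion = ConversionTable.default()
    model = NormativeModel(**config.get("normative", {}))

    gen_blocks = config.get("generators", DEFAULT_CONFIG["generators"])
    cohorts: dict[str, Cohort] = {}
    for name, block in gen_blocks.items():
        cfg = build_generator_config(block, seed)
        cohorts[name] = convert_scores(generate_pd_cohort(cfg, conversion), conversion)

    ref = sample_reference(
        n=int(config.get("reference_n", 100000)), model=model, seed=seed + 7
    )
    cutoffs = derive_centile_cutoffs(ref)

    primary_name = next(iter(cohorts))
    primary = cohorts[primary_name]
    matrix = classify_cohort(primary, cutoffs, conversion,
                             method4_cutoff=int(config.get("method4_cutoff", 27)))
    counterfactual = prevalence_to_frame(
        simulate_counterfactual(primary, model, cutoffs,
                                replicates=replicates, seed=seed + 13)
    )

    tables = {
        "table1_descriptives": descriptive_table(cohorts),
        "table2_prevalence": prevalence_table(primary, matrix, counterfactual),
        "table3_agreement": pairwise_agreement(matrix),
        "table4_models": models_table(primary, matrix),
        "counterfactual_full": counterfactual,
        "cutoffs": cutoffs.df,
    }
    for name, df in tables.items():
        write_csv(df, out / f"{name}.csv", config)
    prevalence_figure(tables["table2_prevalence"], out / "figure2_prevalence.png")
    return tables
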