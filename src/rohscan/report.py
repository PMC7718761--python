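"""TSV report writers.

Percentages are rounded to one decimal place and F_ROH to two, matching
the conventional presentation of such tables.
"""

from __future__ import annotations

import pandas as pd

from .stats import CLASS_LABELS


def write_diversity_table(div: pd.DataFrame, path) -> None:
    out = div.copy()
    for c in ("ho_mean", "ho_sd", "he_mean", "he_sd"):
        out[c] = out[c].round(3)
    for c in ("pn_mean", "pn_sd"):
        out[c] = out[c].round(2)
    for c in ("fis_mean", "fis_max", "fis_min"):
        out[c] = out[c].round(4)
    out.to_csv(path, sep="\t", index=False)


def write_length_class_table(lc: pd.DataFrame, path) -> None:
    out = lc.copy()
    for lab in CLASS_LABELS:
        out[f"pct_{lab}"] = out[f"pct_{lab}"].round(1)
    for c in ("mean_n", "total_length_mb", "max_mb", "min_mb"):
        out[c] = out[c].round(2)
    out.to_csv(path, sep="\t", index=False)


def write_froh_table(froh_summary: pd.DataFrame, path) -> None:
    out = froh_summary.copy()
    for lab in CLASS_LABELS:
        out[f"froh_{lab}"] = out[f"froh_{lab}"].round(3)
    out["froh_total"] = out["froh_total"].round(2)
    out["froh_sd"] = out["froh_sd"].round(2)
    out.to_csv(path, sep="\t", index=False)


def write_per_individual_table(per_ind: pd.DataFrame, froh: pd.DataFrame,
                               diversity_fis: dict[str, pd.DataFrame], path) -> None:
    fis = (
        pd.concat(diversity_fis.values(), ignore_index=True)
        if diversity_fis else pd.DataFrame(columns=["individual", "fis"])
    )
    out = per_ind.merge(froh[["individual", "froh_total"]], on="individual")
    out = out.merge(fis, on="individual", how="left")
    out["total_length_mb"] = (out["total_length_bp"] / 1e6).round(2)
    out["froh_total"] = out["froh_total"].round(4)
    out["fis"] = out["fis"].round(4)
    out.drop(columns="total_length_bp").to_csv(path, sep="\t", index=False)
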