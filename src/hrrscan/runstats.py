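"""Descriptive statistics of detected runs.

Breed-level parameters follow the usual ROH/HRR nomenclature:

* ``N_HRR`` — mean number of runs per individual,
* ``L_HRR`` — mean run length in Mbp (mean over individuals of each
  individual's mean; zero-run individuals excluded from L only),
* ``S_HRR`` — mean per-individual genome covered by runs, in Mbp,
* ``D_HRR`` — mean per-individual covered fraction of the autosomal
  genome span covered by the array.

Geographic-group aggregates (AN/AL/AS/AD) are unweighted means over
breed values, and cross-method agreement is the Pearson correlation of
breed means between the CR and SW detectors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

MBP = 1.0e6

PARAMS = ["N_HRR", "L_HRR", "S_HRR", "D_HRR"]


def genome_length_from_map(snpmap: pd.DataFrame) -> int:
    """Array-covered autosomal span: sum over chromosomes of (last - first bp)."""
    spans = snpmap.groupby("chrom", sort=False)["pos_bp"].agg(["min", "max"])
    return int((spans["max"] - spans["min"]).sum())


def summarize_individual(runs: pd.DataFrame,
                         samples: pd.DataFrame | None = None,
                         method: str | None = None) -> pd.DataFrame:
    """Per-individual (n_runs, mean_length_mbp, total_length_mbp).

    With a sample table, individuals without any run are retained with
    (0, NaN, 0) so they still weigh into breed means.
    """
    r = runs if method is None else runs[runs["method"] == method]
    grouped = r.groupby("sample")["length_bp"].agg(["count", "mean", "sum"])
    if samples is not None:
        grouped = grouped.reindex(samples["sample_id"])
    out = pd.DataFrame({
        "sample": grouped.index,
        "n_runs": grouped["count"].fillna(0).astype(int).values,
        "mean_length_mbp": (grouped["mean"] / MBP).values,
        "total_length_mbp": (grouped["sum"].fillna(0) / MBP).values,
    }).reset_index(drop=True)
    if samples is not None:
        out["breed"] = out["sample"].map(
            dict(zip(samples["sample_id"], samples["breed"]))
        )
    elif len(r):
        out["breed"] = out["sample"].map(
            dict(zip(r["sample"], r["breed"]))
        )
    else:
        out["breed"] = pd.Series(dtype=object)
    return out


def summarize_breed(runs: pd.DataFrame, samples: pd.DataFrame,
                    genome_bp: float, method: str | None = None) -> pd.DataFrame:
    """Breed-level mean and sd of the four run parameters."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    ind = summarize_individual(runs, samples, method=method)
    rows = []
    for breed, sub in ind.groupby("breed", sort=False):
        if sub["n_runs"].sum() == 0:
            warnings.warn(f"breed {breed!r} has no runs; all-zero summary row")
        d_vals = sub["total_length_mbp"] * MBP / genome_bp
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows.append({
                "breed": breed,
                "method": method if method is not None else "",
                "n_ind": len(sub),
                "N_HRR": sub["n_runs"].mean(),
                "N_sd": sub["n_runs"].std(ddof=1),
                "L_HRR": np.nanmean(sub["mean_length_mbp"]),
                "L_sd": np.nanstd(sub["mean_length_mbp"], ddof=1),
                "S_HRR": sub["total_length_mbp"].mean(),
                "S_sd": sub["total_length_mbp"].std(ddof=1),
                "D_HRR": d_vals.mean(),
                "D_sd": d_vals.std(ddof=1),
            })
    return pd.DataFrame(rows)


def aggregate_group(breed_summary: pd.DataFrame,
                    samples: pd.DataFrame) -> pd.DataFrame:
    """Unweighted group means/sds of the breed parameters (AN/AL/AS/AD)."""
    group_of = samples.drop_duplicates("breed").set_index("breed")["geo_group"]
    t = breed_summary.copy()
    t["geo_group"] = t["breed"].map(group_of)
    if t["geo_group"].isna().any():
        missing = t.loc[t["geo_group"].isna(), "breed"].tolist()
        raise ValueError(f"breeds without geographic group: {missing}")
    rows = []
    for grp, sub in t.groupby("geo_group", sort=False):
        row = {"geo_group": grp, "n_breeds": len(sub)}
        for par, out in zip(PARAMS, ["AN_HRR", "AL_HRR", "AS_HRR", "AD_HRR"]):
            row[out] = sub[par].mean()
            row[out + "_sd"] = sub[par].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def method_correlation(b_cr: pd.DataFrame, b_sw: pd.DataFrame) -> pd.Series:
    """Pearson r between CR and SW breed means, one value per parameter."""
    merged = b_cr.merge(b_sw, on="breed", suffixes=("_cr", "_sw"))
    if len(merged) < 3:
        raise ValueError("method correlation needs at least 3 shared breeds")
    out = {}
    for par in PARAMS:
        x = merged[f"{par}_cr"].to_numpy(dtype=float)
        y = merged[f"{par}_sw"].to_numpy(dtype=float)
        if np.nanstd(x) == 0 or np.nanstd(y) == 0:
            warnings.warn(f"zero variance for {par}; correlation undefined")
            out[par] = np.nan
        else:
            ok = ~np.isnan(x) & ~np.isnan(y)
            out[par] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return pd.Series(out, name="pearson_r")
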