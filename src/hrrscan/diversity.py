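"""Per-breed genetic diversity indices.

Observed/expected heterozygosity (H_O, H_E), the molecular inbreeding
coefficient (F_IS, method-of-moments excess homozygosity against the
within-breed Hardy-Weinberg expectation) and minor-allele frequencies,
plus unweighted averages over geographic groups.

All allele frequencies are estimated within breed; H_E uses the plain
2pq estimator while the finite-sample factor 2n/(2n-1) enters only the
expected-homozygosity term of F, mirroring the conventions of the
standard SNP-toolkit flags (``--hardy`` / ``--het`` / ``--freq``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


def _breed_indices(g: GenotypeMatrix, samples: pd.DataFrame) -> dict[str, np.ndarray]:
    breed_of = dict(zip(samples["sample_id"], samples["breed"]))
    order: dict[str, list[int]] = {}
    for i, sid in enumerate(g.samples):
        order.setdefault(breed_of[sid], []).append(i)
    return {b: np.array(ix) for b, ix in order.items()}


def breed_allele_freqs(g: GenotypeMatrix, samples: pd.DataFrame,
                       snp_ids=None) -> pd.DataFrame:
    """Allele1 frequency per SNP (rows) and breed (columns).

    p = (2 n_hom1 + n_het) / (2 n_called); NaN where a breed has no
    calls at a SNP.  Minor-allele frequency is ``min(p, 1-p)``.
    """
    cols = {}
    for breed, idx in _breed_indices(g, samples).items():
        sub = g.codes[idx]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        dos2 = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = 1.0 - dos2 / (2.0 * n_called)
        p[n_called == 0] = np.nan
        cols[breed] = p
    out = pd.DataFrame(cols)
    if snp_ids is not None:
        out.index = pd.Index(snp_ids, name="snp_id")
    return out


def observed_expected_het(g: GenotypeMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Breed-level H_O and H_E (unweighted means over informative SNPs)."""
    rows = []
    for breed, idx in _breed_indices(g, samples).items():
        sub = g.codes[idx]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        n_het = (sub == 1).sum(axis=0)
        dos2 = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            h_obs = n_het / n_called
            p = 1.0 - dos2 / (2.0 * n_called)
        h_exp = 2.0 * p * (1.0 - p)
        ok = n_called > 0
        rows.append({
            "breed": breed,
            "n_ind": len(idx),
            "H_O": float(np.nanmean(np.where(ok, h_obs, np.nan))),
            "H_E": float(np.nanmean(np.where(ok, h_exp, np.nan))),
        })
    return pd.DataFrame(rows)


def inbreeding(g: GenotypeMatrix, samples: pd.DataFrame, pooled: bool = False):
    """Method-of-moments F per individual and mean F_IS per breed.

    For each individual over its L called SNPs,
    ``F = (O_hom - E_hom) / (L - E_hom)`` with
    ``E_hom = sum_snp [1 - 2 p (1-p) * 2n/(2n-1)]`` where p is the
    allele frequency and n the number of called individuals at the SNP
    in the individual's breed (or the whole dataset when ``pooled``).
    Individuals with ``L - E_hom <= 0`` get NaN and are excluded from
    the breed mean.
    """
    breed_of = dict(zip(samples["sample_id"], samples["breed"]))
    groups = (
        {"__all__": np.arange(g.n_ind)} if pooled else _breed_indices(g, samples)
    )

    f_vals = np.full(g.n_ind, np.nan)
    for _, idx in groups.items():
        sub = g.codes[idx]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        dos2 = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = 1.0 - dos2 / (2.0 * n)
            e_term = 1.0 - 2.0 * p * (1.0 - p) * (2.0 * n / (2.0 * n - 1.0))
        for local_i, row_i in enumerate(idx):
            mask = called[local_i]
            L = int(mask.sum())
            if L == 0:
                continue
            o_hom = int(((sub[local_i] == 0) | (sub[local_i] == 2))[mask].sum())
            e_hom = float(np.nansum(np.where(mask, e_term, 0.0)))
            denom = L - e_hom
            if denom <= 0:
                continue
            f_vals[row_i] = (o_hom - e_hom) / denom

    per_ind = pd.DataFrame({
        "sample_id": g.samples,
        "breed": [breed_of[s] for s in g.samples],
        "F": f_vals,
    })
    per_breed = per_ind.groupby("breed", sort=False)["F"].mean().rename("F_IS")
    return per_ind, per_breed


def diversity_table(g: GenotypeMatrix, samples: pd.DataFrame,
                    pooled_f: bool = False) -> pd.DataFrame:
    """Combined per-breed table: n_ind, H_O, H_E, F_IS, MAF."""
    het = observed_expected_het(g, samples)
    _, fis = inbreeding(g, samples, pooled=pooled_f)
    freqs = breed_allele_freqs(g, samples)
    maf = freqs.apply(lambda p: np.nanmean(np.minimum(p, 1.0 - p)))
    out = het.merge(fis, left_on="breed", right_index=True)
    out["MAF"] = out["breed"].map(maf)
    return out[["breed", "n_ind", "H_O", "H_E", "F_IS", "MAF"]]


def group_averages(table: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Unweighted means of breed-level indices per geographic group."""
    group_of = (
        samples.drop_duplicates("breed").set_index("breed")["geo_group"]
    )
    t = table.copy()
    t["geo_group"] = t["breed"].map(group_of)
    if t["geo_group"].isna().any():
        missing = t.loc[t["geo_group"].isna(), "breed"].tolist()
        raise ValueError(f"breeds without geographic group: {missing}")
    num_cols = [c for c in t.columns if c not in ("breed", "geo_group", "n_ind")]
    agg = t.groupby("geo_group", sort=False)[num_cols].mean().reset_index()
    agg.insert(1, "n_breeds", t.groupby("geo_group", sort=False)["breed"].count().values)
    return agg


def write_diversity_tsv(table: pd.DataFrame, path) -> None:
    cols = ["breed", "n_ind", "H_O", "H_E", "F_IS", "MAF"]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")
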