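"""PLINK-text genotype handling: reading, merging, QC and breed subsampling.

Genotypes are held as small integer codes per individual and SNP:

* ``0`` — homozygous for ``allele1``
* ``1`` — heterozygous
* ``2`` — homozygous for ``allele2``
* ``-1`` — missing call

Heterozygosity analyses depend only on whether the two allele calls
differ, so the allele1/allele2 orientation never affects run detection;
it matters only when merging datasets whose files store the alleles in
opposite order, which :func:`merge_datasets` harmonizes explicitly.

Coordinates are 1-based inclusive base pairs throughout the package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

MAP_COLUMNS = ["chrom", "snp_id", "cm", "pos_bp"]
SNPMAP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele1", "allele2"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of genotype codes.

    ``codes`` is an ``int8`` array of shape ``(len(samples), n_snp)``
    using the module-level coding with :data:`MISSING` for no-calls.
    """

    samples: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.samples):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples"
            )
        bad = ~np.isin(self.codes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes outside {-1, 0, 1, 2}")

    @property
    def n_ind(self) -> int:
        return len(self.samples)

    @property
    def n_snp(self) -> int:
        return self.codes.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.codes != MISSING

    def het(self) -> np.ndarray:
        """Boolean mask of heterozygous calls."""
        return self.codes == 1

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix([self.samples[i] for i in idx], self.codes[idx])

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.codes[:, np.asarray(idx)])


@dataclass
class QcParams:
    """Quality-control thresholds (PLINK-flag conventions).

    ``min_maf`` keeps SNPs with minor-allele frequency >= the value
    (``--maf``); ``max_snp_missing`` drops SNPs with a missing fraction
    above it (``--geno``); ``max_ind_missing`` drops individuals with a
    missing fraction above it (``--mind``).
    """

    min_maf: float = 0.05
    max_snp_missing: float = 0.05
    max_ind_missing: float = 0.20
    autosomes_only: bool = True
    max_autosome: int | None = 29

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_snp_missing", "max_ind_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def make_sample_table(
    sample_ids: list[str],
    breed_codes: list[str],
    geo_groups: list[str] | None = None,
) -> pd.DataFrame:
    """Build a sample table (sample_id, breed, geo_group).

    When no geographic grouping is known the group defaults to the breed
    code, so group-level aggregation degrades to breed-level values.
    """
    if geo_groups is None:
        geo_groups = list(breed_codes)
    return pd.DataFrame(
        {"sample_id": sample_ids, "breed": breed_codes, "geo_group": geo_groups}
    )


def attach_groups(samples: pd.DataFrame, breed_to_group: dict[str, str]) -> pd.DataFrame:
    out = samples.copy()
    out["geo_group"] = out["breed"].map(breed_to_group).fillna(out["breed"])
    return out


def _is_autosome(chrom: str, max_autosome: int | None) -> bool:
    c = str(chrom)
    if not c.isdigit():
        return False
    v = int(c)
    if v < 1:
        return False
    return max_autosome is None or v <= max_autosome


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    c = chrom.astype(str)
    num = pd.to_numeric(c, errors="coerce")
    # non-numeric labels (X, Y, MT, 0) sort after numeric chromosomes
    return num.fillna(np.inf)


def sort_map(snpmap: pd.DataFrame) -> pd.DataFrame:
    key = _chrom_sort_key(snpmap["chrom"])
    order = np.lexsort((snpmap["pos_bp"].to_numpy(), key.to_numpy()))
    return snpmap.iloc[order].reset_index(drop=True)


def validate_map(snpmap: pd.DataFrame) -> None:
    """Check strictly increasing positions within chromosomes and unique ids."""
    if snpmap["snp_id"].duplicated().any():
        dup = snpmap.loc[snpmap["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id {dup!r} in map")
    for chrom, sub in snpmap.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chromosome {chrom}")


# ---------------------------------------------------------------------------
# PED/MAP text I/O
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path):
    """Read a PLINK PED/MAP text pair.

    Returns ``(GenotypeMatrix, SnpMap DataFrame, SampleTable DataFrame)``.
    The PED family-id column is taken as the breed code.  Per SNP,
    ``allele1`` is the first allele observed in file order; when both
    alleles of a SNP first appear in the same genotype field they are
    assigned in lexicographic order.  A ``0 0`` field is a missing call.
    """
    snpmap = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=MAP_COLUMNS,
        dtype={"chrom": str, "snp_id": str},
    )
    if snpmap["pos_bp"].isna().any():
        raise ValueError(f"MAP file {map_path}: rows without 4 columns")
    snpmap["pos_bp"] = snpmap["pos_bp"].astype(np.int64)
    n_snp = len(snpmap)

    sample_ids: list[str] = []
    breeds: list[str] = []
    rows: list[np.ndarray] = []
    allele1: list[str | None] = [None] * n_snp
    allele2: list[str | None] = [None] * n_snp

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_snp:
                raise ValueError(
                    f"PED line {lineno}: expected {6 + 2 * n_snp} fields "
                    f"({n_snp} SNPs), got {len(tok)}"
                )
            breeds.append(tok[0])
            sample_ids.append(tok[1])
            row = np.full(n_snp, MISSING, dtype=np.int8)
            alleles = tok[6:]
            for j in range(n_snp):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    continue
                if allele1[j] is None:
                    if a == b:
                        allele1[j] = a
                    else:
                        allele1[j], allele2[j] = sorted((a, b))
                for x in (a, b):
                    if x != allele1[j] and allele2[j] is None:
                        allele2[j] = x
                code = 0
                for x in (a, b):
                    if x == allele2[j]:
                        code += 1
                    elif x != allele1[j]:
                        raise ValueError(
                            f"PED line {lineno}: SNP {snpmap['snp_id'][j]!r} has a "
                            f"third allele {x!r}"
                        )
                row[j] = code
            rows.append(row)

    codes = (
        np.vstack(rows) if rows else np.empty((0, n_snp), dtype=np.int8)
    )
    out_map = pd.DataFrame(
        {
            "snp_id": snpmap["snp_id"],
            "chrom": snpmap["chrom"],
            "pos_bp": snpmap["pos_bp"],
            "allele1": [a if a is not None else "0" for a in allele1],
            "allele2": [a if a is not None else "0" for a in allele2],
        }
    )
    g = GenotypeMatrix(sample_ids, codes)
    samples = make_sample_table(sample_ids, breeds)
    return g, out_map, samples


def write_ped_map(g: GenotypeMatrix, snpmap: pd.DataFrame, samples: pd.DataFrame,
                  ped_path, map_path) -> None:
    """Write a PLINK PED/MAP text pair (family id = breed code)."""
    with open(map_path, "w") as fh:
        for rec in snpmap.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.snp_id}\t0\t{rec.pos_bp}\n")

    breed_of = dict(zip(samples["sample_id"], samples["breed"]))
    a1 = snpmap["allele1"].to_numpy()
    a2 = snpmap["allele2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.samples):
            fields = [breed_of.get(sid, sid), sid, "0", "0", "0", "-9"]
            row = g.codes[i]
            for j in range(g.n_snp):
                c = row[j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [a1[j], a1[j]]
                elif c == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_datasets(parts):
    """Merge >=2 ``(GenotypeMatrix, SnpMap, SampleTable)`` triples.

    Keeps the intersection of snp_ids, harmonizing parts whose allele1/
    allele2 orientation is swapped (codes 0 <-> 2).  SNPs whose allele
    sets cannot be reconciled are dropped (counted in the report printed
    to the returned map's ``attrs['n_dropped_alleles']``).  Samples are
    concatenated; duplicate sample ids raise.  SNP order in the result
    is deterministic by (chromosome, position).
    """
    if len(parts) < 2:
        raise ValueError("merge_datasets needs at least two parts")

    ref_g, ref_map, ref_s = parts[0]
    common = set(ref_map["snp_id"])
    for _, m, _ in parts[1:]:
        common &= set(m["snp_id"])
    if not common:
        raise ValueError("no common markers between datasets")

    ref_map = ref_map[ref_map["snp_id"].isin(common)].reset_index(drop=True)
    ref_idx = {sid: k for k, sid in enumerate(ref_map["snp_id"])}
    n_common = len(ref_map)

    all_samples = [ref_s]
    mats = [ref_g.codes[:, [ref_idx[s] for s in ref_map["snp_id"]]]]
    sample_ids = list(ref_g.samples)
    dropped: set[str] = set()

    ref_a1 = list(ref_map["allele1"])
    ref_a2 = list(ref_map["allele2"])

    for g, m, s in parts[1:]:
        m_idx = {sid: k for k, sid in enumerate(m["snp_id"])}
        cols = np.array([m_idx[sid] for sid in ref_map["snp_id"]])
        sub = g.codes[:, cols].copy()
        a1 = m["allele1"].to_numpy()[cols]
        a2 = m["allele2"].to_numpy()[cols]
        for j in range(n_common):
            known_ref = {x for x in (ref_a1[j], ref_a2[j]) if x != "0"}
            known_part = {x for x in (a1[j], a2[j]) if x != "0"}
            if len(known_ref | known_part) > 2:
                dropped.add(ref_map["snp_id"].iloc[j])
                continue
            if not known_part:
                continue  # part has no calls here; nothing to orient
            if not known_ref:
                # adopt the part's orientation for the merged map
                ref_a1[j], ref_a2[j] = a1[j], a2[j]
                flip = False
            elif a1[j] == ref_a1[j] or a2[j] == ref_a2[j]:
                flip = False
            elif a1[j] == ref_a2[j] or a2[j] == ref_a1[j]:
                flip = True
            else:
                # single known allele on each side and they differ
                flip = True
                if ref_a2[j] == "0":
                    ref_a2[j] = a1[j] if a1[j] != "0" else a2[j]
            if flip:
                col = sub[:, j]
                m_called = col >= 0
                sub[m_called, j] = 2 - col[m_called]
            elif ref_a2[j] == "0" and a2[j] != "0":
                ref_a2[j] = a2[j]
        for sid in g.samples:
            if sid in sample_ids:
                raise ValueError(f"duplicate sample_id {sid!r} across datasets")
        sample_ids.extend(g.samples)
        mats.append(sub)
        all_samples.append(s)
    ref_map = ref_map.assign(allele1=ref_a1, allele2=ref_a2)

    codes = np.vstack(mats)
    keep = ~ref_map["snp_id"].isin(dropped)
    out_map = ref_map[keep].reset_index(drop=True)
    codes = codes[:, keep.to_numpy()]
    if out_map.empty:
        raise ValueError("no common markers after allele harmonization")

    out_map = sort_map(out_map)
    order = {sid: k for k, sid in enumerate(ref_map.loc[keep, "snp_id"])}
    codes = codes[:, [order[sid] for sid in out_map["snp_id"]]]

    samples = pd.concat(all_samples, ignore_index=True)
    out_map.attrs["n_dropped_alleles"] = len(dropped)
    return GenotypeMatrix(sample_ids, codes), out_map, samples


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def allele1_freq(codes: np.ndarray) -> np.ndarray:
    """Frequency of allele1 per SNP (NaN where no calls)."""
    called = codes != MISSING
    n_called = called.sum(axis=0)
    # dosage of allele2 per call: code itself
    dos2 = np.where(called, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p2 = dos2 / (2.0 * n_called)
    p1 = 1.0 - p2
    p1[n_called == 0] = np.nan
    return p1


def apply_qc(g: GenotypeMatrix, snpmap: pd.DataFrame, q: QcParams):
    """Filter SNPs and individuals; returns ``(g, map, report)``.

    Filter order is fixed: (1) non-autosomal / unmapped SNPs, (2)
    high-missing individuals, (3) high-missing SNPs, (4) low-MAF SNPs
    (MAF computed on the individuals remaining after step 2).
    """
    report: dict[str, object] = {
        "n_snp_in": g.n_snp,
        "n_ind_in": g.n_ind,
    }

    if q.autosomes_only:
        keep_snp = np.array(
            [_is_autosome(c, q.max_autosome) and p > 0
             for c, p in zip(snpmap["chrom"], snpmap["pos_bp"])]
        )
    else:
        keep_snp = np.ones(g.n_snp, dtype=bool)
    report["removed_nonautosomal"] = int((~keep_snp).sum())
    codes = g.codes[:, keep_snp]
    snpmap = snpmap[keep_snp].reset_index(drop=True)

    if codes.shape[1] == 0:
        raise ValueError("QC removed all SNPs (autosome filter)")

    miss_ind = (codes == MISSING).mean(axis=1)
    keep_ind = miss_ind <= q.max_ind_missing
    report["removed_individuals"] = int((~keep_ind).sum())
    report["removed_individual_ids"] = [
        s for s, k in zip(g.samples, keep_ind) if not k
    ]
    samples = [s for s, k in zip(g.samples, keep_ind) if k]
    codes = codes[keep_ind]
    if codes.shape[0] == 0:
        raise ValueError("QC removed all individuals")

    miss_snp = (codes == MISSING).mean(axis=0)
    keep1 = miss_snp <= q.max_snp_missing
    report["removed_snp_missing"] = int((~keep1).sum())
    codes = codes[:, keep1]
    snpmap = snpmap[keep1].reset_index(drop=True)

    p1 = allele1_freq(codes)
    maf = np.minimum(p1, 1.0 - p1)
    with np.errstate(invalid="ignore"):
        keep2 = maf >= q.min_maf
    keep2 &= ~np.isnan(maf)
    report["removed_snp_maf"] = int((~keep2).sum())
    codes = codes[:, keep2]
    snpmap = snpmap[keep2].reset_index(drop=True)
    if codes.shape[1] == 0:
        raise ValueError("QC removed all SNPs")

    report["n_snp_out"] = codes.shape[1]
    report["n_ind_out"] = codes.shape[0]
    return GenotypeMatrix(samples, codes), snpmap, report


def qc_report_to_tsv(report: dict, path) -> None:
    keys = [
        "n_snp_in", "n_ind_in", "removed_nonautosomal", "removed_individuals",
        "removed_snp_missing", "removed_snp_maf", "n_snp_out", "n_ind_out",
    ]
    with open(path, "w") as fh:
        fh.write("step\tcount\n")
        for k in keys:
            fh.write(f"{k}\t{report[k]}\n")


# ---------------------------------------------------------------------------
# Breed subsampling
# ---------------------------------------------------------------------------

def subsample_breeds(g: GenotypeMatrix, samples: pd.DataFrame, max_n: int,
                     seed: int):
    """Reduce every breed to at most ``max_n`` individuals.

    Breeds at or below the cap are untouched; larger ones are reduced by
    uniform sampling without replacement driven by ``seed``.  The
    original within-breed sample order is preserved.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    rng = np.random.default_rng(seed)
    keep = np.zeros(g.n_ind, dtype=bool)
    breed_of = dict(zip(samples["sample_id"], samples["breed"]))
    breeds = pd.Series([breed_of[s] for s in g.samples])
    for _, idx in breeds.groupby(breeds, sort=False).groups.items():
        idx = np.asarray(list(idx))
        if len(idx) <= max_n:
            keep[idx] = True
        else:
            chosen = rng.choice(idx, size=max_n, replace=False)
            keep[np.sort(chosen)] = True
    kept_ids = [s for s, k in zip(g.samples, keep) if k]
    out_samples = samples[samples["sample_id"].isin(kept_ids)].reset_index(drop=True)
    return g.take_samples(np.flatnonzero(keep)), out_samples
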