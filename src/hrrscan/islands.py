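"""HRR island calling and cross-breed merging.

Within a breed, each SNP's *incidence* is the fraction of individuals
whose runs cover it.  Incidences are standardized to z-scores over all
SNPs of the breed/method, converted to upper-tail normal p-values, and
the top 0.1% of SNPs (ties at the threshold included) are selected.
Only SNPs selected by both detection methods are kept; maximal map-
consecutive stretches of such SNPs become candidate regions, filtered
by a minimum of 4 member SNPs and a within-breed frequency of at least
20%, and nearby surviving regions are merged into islands.  Islands
from different breeds that overlap on a chromosome merge transitively
into shared islands coded ``CHI{chrom}-{A,B,...}``.
"""

from __future__ import annotations

import string
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

ISLAND_COLUMNS = ["breed", "chrom", "start_bp", "end_bp", "n_snp", "freq", "snp_ids"]


def snp_incidence(runs: pd.DataFrame, samples: pd.DataFrame,
                  snpmap: pd.DataFrame, method: str) -> pd.DataFrame:
    """Per-breed per-SNP run coverage with z-scores and p-values.

    A SNP is covered for an individual when any of that individual's
    runs (of the given method) spans its position; incidence divides by
    the full breed size, including individuals without runs.
    """
    snpmap = snpmap.reset_index(drop=True)
    r = runs[runs["method"] == method]
    breeds = samples["breed"].unique()
    breed_size = samples.groupby("breed", sort=False)["sample_id"].count()

    pos_by_chrom = {
        c: (sub.index.to_numpy(), sub["pos_bp"].to_numpy())
        for c, sub in snpmap.groupby("chrom", sort=False)
    }
    M = len(snpmap)
    frames = []
    for breed in breeds:
        counts = np.zeros(M)
        sub = r[r["breed"] == breed]
        for sample, ind_runs in sub.groupby("sample", sort=False):
            covered = np.zeros(M, dtype=bool)
            for rec in ind_runs.itertuples(index=False):
                idx, pos = pos_by_chrom.get(rec.chrom, (None, None))
                if idx is None:
                    continue
                lo = np.searchsorted(pos, rec.start_bp, side="left")
                hi = np.searchsorted(pos, rec.end_bp, side="right")
                covered[idx[lo:hi]] = True
            counts += covered
        inc = counts / breed_size[breed]
        sd = inc.std()  # population sd; selection is rank-based anyway
        if sd > 0:
            z = (inc - inc.mean()) / sd
            p = sps.norm.sf(z)
        else:
            z = np.full(M, np.nan)
            p = np.full(M, np.nan)
        frames.append(pd.DataFrame({
            "breed": breed,
            "method": method,
            "snp_id": snpmap["snp_id"].to_numpy(),
            "chrom": snpmap["chrom"].to_numpy(),
            "pos_bp": snpmap["pos_bp"].to_numpy(),
            "incidence": inc,
            "z": z,
            "p": p,
        }))
    return pd.concat(frames, ignore_index=True)


def select_top_snps(incidence: pd.DataFrame,
                    top_frac: float = 0.001) -> dict[str, set[str]]:
    """Top ``top_frac`` of SNPs per breed by p-value, ties included.

    The threshold is the k-th smallest empirical p-value with
    ``k = ceil(top_frac * n_snp)``; every SNP with p <= threshold is
    selected, so tie groups can push the selection beyond k.  Breeds
    with constant incidence (sd = 0) yield an empty selection.
    """
    out: dict[str, set[str]] = {}
    for breed, sub in incidence.groupby("breed", sort=False):
        p = sub["p"].to_numpy()
        if np.isnan(p).all():
            warnings.warn(f"breed {breed!r}: constant incidence, no SNPs selected")
            out[breed] = set()
            continue
        k = max(1, int(np.ceil(top_frac * len(p))))
        thr = np.sort(p)[k - 1]
        out[breed] = set(sub.loc[sub["p"] <= thr, "snp_id"])
    return out


def intersect_methods(sel_cr: dict[str, set[str]],
                      sel_sw: dict[str, set[str]]) -> dict[str, set[str]]:
    """Per-breed intersection of the CR- and SW-selected SNP sets."""
    breeds = set(sel_cr) | set(sel_sw)
    return {b: sel_cr.get(b, set()) & sel_sw.get(b, set()) for b in breeds}


def call_islands(selected: dict[str, set[str]], incidence_cr: pd.DataFrame,
                 snpmap: pd.DataFrame, min_snp: int = 4, min_freq: float = 0.20,
                 merge_gap_bp: int = 1_000_000,
                 runs: pd.DataFrame | None = None):
    """Call within-breed islands from the selected SNP sets.

    Candidate regions are maximal stretches of selected SNPs that are
    consecutive on the post-QC map (same chromosome, no unselected SNP
    between).  Region frequency is the mean CR incidence of member
    SNPs.  Regions passing the ``min_snp``/``min_freq`` filters and
    separated by less than ``merge_gap_bp`` merge into final islands.

    Returns ``(island table, diagnostics)`` where diagnostics maps each
    breed to the number of individual-level runs containing at least
    one selected SNP (when ``runs`` is given).
    """
    snp_order = {sid: j for j, sid in enumerate(snpmap["snp_id"])}
    chrom_arr = snpmap["chrom"].to_numpy()
    pos_arr = snpmap["pos_bp"].to_numpy()
    snp_arr = snpmap["snp_id"].to_numpy()

    inc_of: dict[str, dict[str, float]] = {}
    for breed, sub in incidence_cr.groupby("breed", sort=False):
        inc_of[breed] = dict(zip(sub["snp_id"], sub["incidence"]))

    records = []
    diagnostics: dict[str, int] = {}
    for breed, sel in selected.items():
        if not sel:
            continue
        idx = np.sort([snp_order[s] for s in sel])
        # maximal consecutive stretches on the map within one chromosome
        stretches = []
        s = 0
        for k in range(1, len(idx) + 1):
            if (k == len(idx) or idx[k] != idx[k - 1] + 1
                    or chrom_arr[idx[k]] != chrom_arr[idx[k - 1]]):
                stretches.append(idx[s:k])
                s = k
        inc = inc_of.get(breed, {})
        kept = []
        for st in stretches:
            freq = float(np.mean([inc.get(snp_arr[j], 0.0) for j in st]))
            if len(st) >= min_snp and freq >= min_freq:
                kept.append(st)
        # merge retained regions separated by < merge_gap_bp on one chromosome
        merged: list[list[np.ndarray]] = []
        for st in kept:
            if (merged and chrom_arr[st[0]] == chrom_arr[merged[-1][-1][-1]]
                    and pos_arr[st[0]] - pos_arr[merged[-1][-1][-1]] < merge_gap_bp):
                merged[-1].append(st)
            else:
                merged.append([st])
        for group in merged:
            members = np.concatenate(group)
            freq = float(np.mean([inc.get(snp_arr[j], 0.0) for j in members]))
            records.append({
                "breed": breed,
                "chrom": chrom_arr[members[0]],
                "start_bp": int(pos_arr[members[0]]),
                "end_bp": int(pos_arr[members[-1]]),
                "n_snp": int(len(members)),
                "freq": freq,
                "snp_ids": [snp_arr[j] for j in members],
            })
        if runs is not None:
            sel_pos = [(chrom_arr[snp_order[s]], pos_arr[snp_order[s]]) for s in sel]
            n_hit = 0
            for rec in runs[runs["breed"] == breed].itertuples(index=False):
                if any(c == rec.chrom and rec.start_bp <= p <= rec.end_bp
                       for c, p in sel_pos):
                    n_hit += 1
            diagnostics[breed] = n_hit

    islands = pd.DataFrame(records, columns=ISLAND_COLUMNS)
    return islands, diagnostics


def merge_across_breeds(islands: pd.DataFrame):
    """Merge overlapping breed islands into shared islands + tallies.

    Islands on one chromosome overlapping by >= 1 bp merge transitively
    (union span, union of breeds).  Codes are ``CHI{chrom}-{letter}``
    with letters assigned per chromosome in descending breed-count
    order, ties broken by start position.  Tallies report, per
    chromosome, the summed breed-island count and the number of
    distinct shared islands.
    """
    shared_rows = []
    tally_rows = []
    for chrom, sub in islands.groupby("chrom", sort=False):
        sub = sub.sort_values("start_bp")
        clusters = []
        for rec in sub.itertuples(index=False):
            if clusters and rec.start_bp <= clusters[-1]["end_bp"]:
                c = clusters[-1]
                c["end_bp"] = max(c["end_bp"], rec.end_bp)
                c["breeds"].append(rec.breed)
                c["start_bp"] = min(c["start_bp"], rec.start_bp)
            else:
                clusters.append({
                    "chrom": chrom, "start_bp": rec.start_bp,
                    "end_bp": rec.end_bp, "breeds": [rec.breed],
                })
        clusters.sort(key=lambda c: (-len(c["breeds"]), c["start_bp"]))
        for letter, c in zip(_letters(), clusters):
            shared_rows.append({
                "code": f"CHI{chrom}-{letter}",
                "chrom": chrom,
                "start_bp": c["start_bp"],
                "end_bp": c["end_bp"],
                "n_breeds": len(c["breeds"]),
                "breeds": sorted(set(c["breeds"])),
            })
        tally_rows.append({
            "chrom": chrom,
            "total_islands": len(sub),
            "unique_islands": len(clusters),
        })
    shared = pd.DataFrame(
        shared_rows,
        columns=["code", "chrom", "start_bp", "end_bp", "n_breeds", "breeds"],
    )
    tallies = pd.DataFrame(
        tally_rows, columns=["chrom", "total_islands", "unique_islands"]
    )
    return shared, tallies


def _letters():
    for ch in string.ascii_uppercase:
        yield ch
    for a in string.ascii_uppercase:      # AA, AB, ... just in case
        for b in string.ascii_uppercase:
            yield a + b


def export_islands_bed(islands: pd.DataFrame, path,
                       name_col: str | None = None) -> None:
    """BED export (0-based half-open): start_bp-1, end_bp.

    Score column is ``round(1000 * freq)`` when a frequency column is
    present, else 0.
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\n")
        for i, rec in enumerate(islands.itertuples(index=False)):
            d = rec._asdict()
            if name_col is not None and name_col in d:
                name = d[name_col]
            elif "code" in d:
                name = d["code"]
            else:
                name = f"{d.get('breed', 'island')}_{i}"
            score = int(round(1000 * d["freq"])) if "freq" in d else 0
            fh.write(f"{d['chrom']}\t{d['start_bp'] - 1}\t{d['end_bp']}\t{name}\t{score}\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            tok = line.split()
            rows.append({
                "chrom": tok[0],
                "start_bp": int(tok[1]) + 1,
                "end_bp": int(tok[2]),
                "name": tok[3] if len(tok) > 3 else "",
                "score": int(tok[4]) if len(tok) > 4 else 0,
            })
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name", "score"])
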