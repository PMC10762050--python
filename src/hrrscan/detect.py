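"""Run detection: Consecutive Runs (CR) and Sliding Window (SW) scanners.

Both scanners find heterozygosity-rich regions (HRR) — stretches of
consecutive heterozygous genotypes in one diploid individual — or, with
``zygosity_mode="homozygous"``, classic runs of homozygosity (ROH).

CR scans genotypes in map order and extends a run while the genotype
matches the target zygosity, terminating it at a missing call beyond
``max_miss``, an opposite genotype beyond ``max_opp``, or an inter-SNP
gap above ``max_gap_bp``.  SW scores every SNP by the fraction of
fixed-size windows containing it that satisfy the zygosity criteria and
keeps SNPs whose score strictly exceeds ``snp_in_run_threshold``.

Run length is ``end_bp - start_bp`` (first to last SNP of the run),
which is what the 250 kb minimum-length filter applies to.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, validate_map

RUN_COLUMNS = ["sample", "breed", "method", "chrom",
               "start_bp", "end_bp", "n_snp", "length_bp"]


@dataclass
class DetectionParams:
    """Detection parameterization; defaults are the study settings:

    at least 10 SNPs per run, no missing or opposite genotypes, a 1 Mb
    maximum gap between consecutive SNPs, a 250 kb minimum run length
    and — for SW — 10-SNP windows, a minimum density of one SNP per
    100 kb and an in-run score threshold of 0.05.
    """

    min_snp: int = 10
    max_miss: int = 0
    max_opp: int = 0
    max_gap_bp: int = 1_000_000
    min_length_bp: int = 250_000
    window_size: int = 10
    max_opp_window: int = 0
    max_miss_window: int = 0
    min_density: float = 1.0 / 100_000
    snp_in_run_threshold: float = 0.05
    zygosity_mode: str = "heterozygous"
    split_at_gaps: bool = True   # SW: split candidate runs at large gaps (vs discard)

    def __post_init__(self) -> None:
        if self.zygosity_mode not in ("heterozygous", "homozygous"):
            raise ValueError(f"bad zygosity_mode {self.zygosity_mode!r}")
        for name in ("min_snp", "max_miss", "max_opp", "window_size",
                     "max_opp_window", "max_miss_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_gap_bp <= 0 or self.min_length_bp <= 0:
            raise ValueError("lengths must be positive")
        if not 0.0 < self.snp_in_run_threshold < 1.0:
            raise ValueError("snp_in_run_threshold must be in (0, 1)")


def _zygosity_masks(row: np.ndarray, mode: str):
    missing = row == MISSING
    if mode == "heterozygous":
        match = row == 1
    else:
        match = (row == 0) | (row == 2)
    opposite = ~match & ~missing
    return match, opposite, missing


def _scan_consecutive(row, pos, p: DetectionParams):
    """Greedy left-to-right scan of one individual's chromosome.

    Yields (start_idx, end_idx) pairs trimmed to matching genotypes;
    absorbed missing/opposite calls inside a run count toward n_snp via
    the index span.  Filters (min_snp, min_length_bp) applied here.
    """
    match, opposite, missing = _zygosity_masks(row, p.zygosity_mode)
    segs = []
    start = last = -1
    n_miss = n_opp = 0

    def flush():
        nonlocal start, last, n_miss, n_opp
        if start >= 0:
            segs.append((start, last))
        start = last = -1
        n_miss = n_opp = 0

    M = len(row)
    for j in range(M):
        if start >= 0 and pos[j] - pos[j - 1] > p.max_gap_bp:
            flush()
        if match[j]:
            if start < 0:
                start = j
            last = j
        elif missing[j]:
            if start >= 0:
                if n_miss < p.max_miss:
                    n_miss += 1
                else:
                    flush()
        else:  # opposite genotype
            if start >= 0:
                if n_opp < p.max_opp:
                    n_opp += 1
                else:
                    flush()
    flush()

    out = []
    for s, e in segs:
        n_snp = e - s + 1
        length = int(pos[e] - pos[s])
        if n_snp >= p.min_snp and length >= p.min_length_bp:
            out.append((s, e, n_snp, length))
    return out


def _scan_sliding(row, pos, p: DetectionParams):
    """Window-score scan of one individual's chromosome.

    Windows are every fully contained block of ``window_size``
    consecutive SNPs.  A window complies when it holds at most
    ``max_opp_window`` opposite and ``max_miss_window`` missing calls.
    A SNP is in-run when its compliant-window fraction strictly exceeds
    the threshold; maximal in-run stretches are split at large gaps and
    filtered by min_snp, min_length_bp and SNP density.
    """
    M = len(row)
    w = p.window_size
    if M < w:
        return []
    _, opposite, missing = _zygosity_masks(row, p.zygosity_mode)
    opp = np.concatenate([[0], np.cumsum(opposite)])
    mis = np.concatenate([[0], np.cumsum(missing)])
    n_win = M - w + 1
    starts = np.arange(n_win)
    compliant = ((opp[starts + w] - opp[starts] <= p.max_opp_window) &
                 (mis[starts + w] - mis[starts] <= p.max_miss_window))
    comp_cum = np.concatenate([[0], np.cumsum(compliant)])

    j = np.arange(M)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    n_containing = hi - lo + 1
    n_compliant = comp_cum[hi + 1] - comp_cum[lo]
    in_run = (n_compliant / n_containing) > p.snp_in_run_threshold

    # maximal in-run stretches, then gap handling per stretch
    stretches = []
    s = -1
    for k in range(M):
        if in_run[k] and s < 0:
            s = k
        elif not in_run[k] and s >= 0:
            stretches.append((s, k - 1))
            s = -1
    if s >= 0:
        stretches.append((s, M - 1))

    segs = []
    for s0, e0 in stretches:
        cut = [k for k in range(s0 + 1, e0 + 1)
               if pos[k] - pos[k - 1] > p.max_gap_bp]
        if cut and not p.split_at_gaps:
            continue
        bounds = [s0] + cut + [e0 + 1]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segs.append((a, b - 1))

    out = []
    for s0, e0 in segs:
        n_snp = e0 - s0 + 1
        length = int(pos[e0] - pos[s0])
        if n_snp < p.min_snp or length < p.min_length_bp:
            continue
        if n_snp / length < p.min_density:
            continue
        out.append((s0, e0, n_snp, length))
    return out


def _detect(g: GenotypeMatrix, snpmap: pd.DataFrame, p: DetectionParams,
            samples: pd.DataFrame | None, method: str) -> pd.DataFrame:
    validate_map(snpmap)
    if len(snpmap) != g.n_snp:
        raise ValueError("map length does not match genotype columns")
    breed_of = {}
    if samples is not None:
        breed_of = dict(zip(samples["sample_id"], samples["breed"]))

    chrom_arr = snpmap["chrom"].to_numpy()
    # contiguous chromosome blocks in map order
    blocks = []
    start = 0
    for j in range(1, len(chrom_arr) + 1):
        if j == len(chrom_arr) or chrom_arr[j] != chrom_arr[start]:
            blocks.append((chrom_arr[start], start, j))
            start = j
    pos_all = snpmap["pos_bp"].to_numpy()

    scan = _scan_consecutive if method == "CR" else _scan_sliding
    records = []
    for i, sid in enumerate(g.samples):
        row_all = g.codes[i]
        for chrom, lo, hi in blocks:
            pos = pos_all[lo:hi]
            for s, e, n_snp, length in scan(row_all[lo:hi], pos, p):
                records.append((
                    sid, breed_of.get(sid, ""), method, chrom,
                    int(pos[s]), int(pos[e]), n_snp, length,
                ))
    return pd.DataFrame(records, columns=RUN_COLUMNS)


def detect_consecutive(g, snpmap, p: DetectionParams,
                       samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Consecutive-runs detection; returns a run table."""
    return _detect(g, snpmap, p, samples, "CR")


def detect_sliding(g, snpmap, p: DetectionParams,
                   samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sliding-window detection; returns a run table."""
    return _detect(g, snpmap, p, samples, "SW")


def sweep_params(g, snpmap, grid: list[DetectionParams],
                 samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run both detectors for every parameter set in the grid.

    One row per (params, method) with the total run count and mean run
    length; the screening harness for parameter sensitivity.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for k, p in enumerate(grid):
        for method, fn in (("CR", detect_consecutive), ("SW", detect_sliding)):
            runs = fn(g, snpmap, p, samples)
            rows.append({
                "grid_index": k,
                **asdict(p),
                "method": method,
                "total_runs": len(runs),
                "mean_length_bp": float(runs["length_bp"].mean()) if len(runs) else np.nan,
            })
    return pd.DataFrame(rows)


def runs_to_tsv(runs: pd.DataFrame, path) -> None:
    runs[RUN_COLUMNS].to_csv(path, sep="\t", index=False)


def params_from_dict(d: dict) -> DetectionParams:
    return replace(DetectionParams(), **d)
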