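"""Inter-individual and inter-breed relationship analyses.

Identity-by-state (IBS) distances between individuals with classical
(Torgerson) multidimensional scaling, and Reynolds' coancestry-based
genetic distances between breeds from per-breed allele frequencies,
with PHYLIP/NEXUS export for external split-network tools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class MdsResult:
    coords: np.ndarray          # individuals x k
    var_explained: np.ndarray   # fraction of positive-eigenvalue mass per axis
    labels: list[str]


def ibs_distance(g: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Pairwise IBS distance matrix.

    similarity = (2 n_IBS2 + n_IBS1) / (2 n_pair) over SNPs called in
    both individuals; het-vs-het counts as IBS2.  With codes 0/1/2 the
    number of shared alleles at a SNP is ``2 - |g_i - g_j|``, so the
    distance reduces to ``mean(|g_i - g_j|) / 2``.
    """
    if g.n_ind < 2:
        raise ValueError("IBS distance needs at least two individuals")
    codes = g.codes.astype(np.int16)
    called = codes != MISSING
    n = g.n_ind
    d = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1:]
        diff = np.abs(codes[i] - codes[i + 1:]) * both
        n_pair = both.sum(axis=1)
        zero = n_pair == 0
        if zero.any():
            j = i + 1 + int(np.flatnonzero(zero)[0])
            raise ValueError(
                f"no co-called SNPs between {g.samples[i]!r} and {g.samples[j]!r}"
            )
        d[i, i + 1:] = diff.sum(axis=1) / (2.0 * n_pair)
    d = d + d.T
    return d, list(g.samples)


def classical_mds(d: np.ndarray, k: int, labels: list[str] | None = None) -> MdsResult:
    """Torgerson MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns
    the top-k coordinates (eigenvector * sqrt(eigenvalue)).  Explained
    variance is each eigenvalue's share of the positive spectrum.  Axis
    signs are fixed so the largest-magnitude loading is positive.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    if not np.any(d > 0):
        raise ValueError("all distances are zero")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals[evals > 1e-12]
    total = pos.sum()
    coords = np.zeros((n, k))
    var = np.zeros(k)
    for i in range(k):
        lam = evals[i]
        if lam > 1e-12:
            axis = evecs[:, i] * np.sqrt(lam)
            if axis[np.argmax(np.abs(axis))] < 0:
                axis = -axis
            coords[:, i] = axis
            var[i] = lam / total
    return MdsResult(coords, var, list(labels) if labels is not None else
                     [str(i) for i in range(n)])


def reynolds_distance(freqs: pd.DataFrame, counts: pd.DataFrame | None = None,
                      corrected: bool = False) -> tuple[np.ndarray, list[str]]:
    """Pairwise Reynolds' distances between breeds.

    ``freqs``: SNPs x breeds table of allele1 frequencies (NaN allowed).
    Default is the least-squares coancestry form without sample-size
    correction:

        theta_AB = sum_l (pA - pB)^2 / sum_l [pA + pB - 2 pA pB]

    restricted per pair to loci with a frequency in both breeds.  With
    ``corrected=True`` (requires ``counts`` of called individuals per
    SNP and breed) the numerator subtracts the binomial sampling terms
    ``p(1-p)/(2n-1)`` for each breed.
    """
    breeds = list(freqs.columns)
    if len(breeds) < 2:
        raise ValueError("Reynolds distance needs at least two breeds")
    if corrected and counts is None:
        raise ValueError("corrected form requires per-breed call counts")
    P = freqs.to_numpy(dtype=float)
    m = len(breeds)
    d = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            pa, pb = P[:, a], P[:, b]
            ok = ~np.isnan(pa) & ~np.isnan(pb)
            pa, pb = pa[ok], pb[ok]
            num = np.sum((pa - pb) ** 2)
            if corrected:
                na = counts.to_numpy(dtype=float)[ok, a]
                nb = counts.to_numpy(dtype=float)[ok, b]
                num -= np.sum(pa * (1 - pa) / (2 * na - 1) +
                              pb * (1 - pb) / (2 * nb - 1))
                num = max(num, 0.0)
            den = np.sum(pa + pb - 2.0 * pa * pb)
            if den == 0:
                raise ValueError(
                    f"breeds {breeds[a]!r} and {breeds[b]!r} are jointly "
                    "monomorphic at every shared locus"
                )
            d[a, b] = d[b, a] = num / den
    return d, breeds


# ---------------------------------------------------------------------------
# Distance-matrix exchange formats
# ---------------------------------------------------------------------------

def sanitize_labels(labels: list[str], width: int = 10) -> list[str]:
    """PHYLIP-safe labels: no whitespace, <= width chars, unique."""
    out, seen = [], {}
    for lab in labels:
        tok = re.sub(r"\s+", "_", lab.strip())[:width]
        if tok in seen:
            seen[tok] += 1
            suffix = str(seen[tok])
            tok = tok[: width - len(suffix)] + suffix
        seen.setdefault(tok, 0)
        out.append(tok)
    return out


def export_distances(d: np.ndarray, labels: list[str], path,
                     fmt: str = "phylip") -> None:
    """Write a square PHYLIP distance file or a NEXUS distances block."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if fmt == "phylip":
        labs = sanitize_labels(labels)
        with open(path, "w") as fh:
            fh.write(f"{n}\n")
            for i in range(n):
                vals = " ".join(f"{x:.6f}" for x in d[i])
                fh.write(f"{labs[i]:<10s} {vals}\n")
    elif fmt == "nexus":
        labs = sanitize_labels(labels, width=30)
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"  DIMENSIONS NTAX={n};\n  TAXLABELS\n")
            for lab in labs:
                fh.write(f"    {lab}\n")
            fh.write("  ;\nEND;\n\nBEGIN DISTANCES;\n")
            fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n  MATRIX\n")
            for i in range(n):
                vals = " ".join(f"{x:.6f}" for x in d[i])
                fh.write(f"    {labs[i]} {vals}\n")
            fh.write("  ;\nEND;\n")
    else:
        raise ValueError(f"unknown distance format {fmt!r}")


def read_phylip_distances(path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for _ in range(n):
            tok = fh.readline().split()
            labels.append(tok[0])
            rows.append([float(x) for x in tok[1:]])
    return np.array(rows), labels


def mds_to_tsv(res: MdsResult, samples: pd.DataFrame, path) -> None:
    breed_of = dict(zip(samples["sample_id"], samples["breed"]))
    group_of = dict(zip(samples["sample_id"], samples["geo_group"]))
    k = res.coords.shape[1]
    with open(path, "w") as fh:
        fh.write("# var_explained: " +
                 " ".join(f"C{i + 1}={v:.4f}" for i, v in enumerate(res.var_explained))
                 + "\n")
        fh.write("sample\tbreed\tgroup\t" + "\t".join(f"C{i + 1}" for i in range(k)) + "\n")
        for i, lab in enumerate(res.labels):
            coords = "\t".join(f"{x:.6f}" for x in res.coords[i])
            fh.write(f"{lab}\t{breed_of.get(lab, '')}\t{group_of.get(lab, '')}\t{coords}\n")
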