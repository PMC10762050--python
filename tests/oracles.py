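"""Independent reference implementations used to check the detectors.

These are deliberately written in a different style from the package
code: the consecutive-runs oracle enumerates all maximal heterozygous
stretches by splitting index lists, and the sliding-window oracle
literally builds every window and scores every SNP with plain loops.
Both only support the zero-missing/zero-opposite parameterization.
"""

from __future__ import annotations


def cr_runs_oracle(codes, pos, min_snp=10, max_gap_bp=1_000_000,
                   min_length_bp=250_000):
    """Maximal-substring enumeration of heterozygous runs (one chromosome)."""
    het_idx = [j for j, c in enumerate(codes) if c == 1]
    # group map-consecutive het indices
    groups, cur = [], []
    for j in het_idx:
        if cur and j == cur[-1] + 1:
            cur.append(j)
        else:
            if cur:
                groups.append(cur)
            cur = [j]
    if cur:
        groups.append(cur)
    # split each group at large inter-SNP gaps
    segments = []
    for grp in groups:
        seg = [grp[0]]
        for j in grp[1:]:
            if pos[j] - pos[j - 1] > max_gap_bp:
                segments.append(seg)
                seg = []
            seg.append(j)
        segments.append(seg)
    out = []
    for seg in segments:
        n = len(seg)
        length = int(pos[seg[-1]] - pos[seg[0]])
        if n >= min_snp and length >= min_length_bp:
            out.append((int(pos[seg[0]]), int(pos[seg[-1]]), n, length))
    return out


def sw_runs_oracle(codes, pos, window_size=10, min_snp=10,
                   max_gap_bp=1_000_000, min_length_bp=250_000,
                   min_density=1.0 / 100_000, threshold=0.05,
                   max_opp_window=0, max_miss_window=0):
    """Literal window enumeration (one chromosome, heterozygous mode)."""
    M = len(codes)
    w = window_size
    if M < w:
        return []
    windows = []
    for s in range(M - w + 1):
        n_opp = sum(1 for j in range(s, s + w) if codes[j] in (0, 2))
        n_mis = sum(1 for j in range(s, s + w) if codes[j] == -1)
        windows.append(n_opp <= max_opp_window and n_mis <= max_miss_window)

    in_run = []
    for j in range(M):
        containing = [s for s in range(len(windows)) if s <= j <= s + w - 1]
        score = sum(windows[s] for s in containing) / len(containing)
        in_run.append(score > threshold)

    # group, split at gaps, filter
    stretches, cur = [], []
    for j in range(M):
        if in_run[j]:
            cur.append(j)
        elif cur:
            stretches.append(cur)
            cur = []
    if cur:
        stretches.append(cur)

    segments = []
    for grp in stretches:
        seg = [grp[0]]
        for j in grp[1:]:
            if pos[j] - pos[j - 1] > max_gap_bp:
                segments.append(seg)
                seg = []
            seg.append(j)
        segments.append(seg)

    out = []
    for seg in segments:
        n = len(seg)
        length = int(pos[seg[-1]] - pos[seg[0]])
        if n < min_snp or length < min_length_bp:
            continue
        if n / length < min_density:
            continue
        out.append((int(pos[seg[0]]), int(pos[seg[-1]]), n, length))
    return out
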