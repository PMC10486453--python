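"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — nested loops, direct definitions —
and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math


def substring_offsets(read: str, ref: str) -> list[int]:
    """All offsets where read matches ref exactly (naive all-offsets scan)."""
    out = []
    for off in range(len(ref) - len(read) + 1):
        for i in range(len(read)):
            if ref[off + i] != read[i]:
                break
        else:
            out.append(off)
    return out


def hamming1_placements(read: str, ref: str) -> list[tuple[int, int]]:
    """(offset, mismatch_position_in_ref) for every Hamming-distance-1 placement."""
    out = []
    for off in range(len(ref) - len(read) + 1):
        n_mm = 0
        pos = -1
        for i in range(len(read)):
            if ref[off + i] != read[i]:
                n_mm += 1
                if n_mm > 1:
                    break
                pos = i
        if n_mm == 1:
            out.append((off, off + pos))
    return out


def trim_enumeration(
    read: str, refs: dict[str, str], max_rounds: int = 5, min_core: int = 16
) -> list[tuple[int, str, int, int, int]]:
    """Brute-force (i, j) enumeration with exact-core matching.

    Returns all (k, ref_id, offset, i, j) in the minimal i + j stratum, or
    an empty list.
    """
    best: list[tuple[int, str, int, int, int]] = []
    for k in range(1, max_rounds + 1):
        hits = []
        for i in range(k + 1):
            j = k - i
            core = read[i : len(read) - j] if j else read[i:]
            if len(core) < min_core:
                continue
            for rid, ref in refs.items():
                for off in substring_offsets(core, ref):
                    hits.append((k, rid, off, i, j))
        if hits:
            return hits
    return best


def kendall_pair_counts(x, y) -> tuple[int, int, float]:
    """Concordant/discordant pair enumeration with tie correction.

    Returns (S, n0, tau_b) from the O(n^2) definition.
    """
    n = len(x)
    s = 0
    tie_x = 0
    tie_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = int(x[i] > x[j]) - int(x[i] < x[j])
            dy = int(y[i] > y[j]) - int(y[i] < y[j])
            s += dx * dy
            if dx == 0:
                tie_x += 1
            if dy == 0:
                tie_y += 1
    n0 = n * (n - 1) // 2
    tau = s / math.sqrt((n0 - tie_x) * (n0 - tie_y))
    return s, n0, tau


def bh_step_up(pvalues) -> list[float]:
    """Textbook Benjamini-Hochberg: p_(i) * m / i with monotone enforcement."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(1.0, pvalues[i] * m / rank)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def pooled_t(a, b) -> tuple[float, int]:
    """Pooled-variance two-sample t statistic and its degrees of freedom."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


def random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(length))
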