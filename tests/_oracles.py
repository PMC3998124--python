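"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes results from first principles (per-position
frequency lookups, exhaustive window enumeration, all-pairs distance
minimisation, closed-form normal equations) without calling the code
paths under test.
"""

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_weights(freq) -> list[dict[str, float]]:
    """Recompute 2 + log2 f from the frequency matrix alone."""
    out = []
    for row in freq:
        out.append(
            {
                b: (2 + math.log2(row[i]) if row[i] > 0 else float("-inf"))
                for i, b in enumerate("ACGT")
            }
        )
    return out


def oracle_score(weights, seq: str) -> float:
    return sum(weights[l][c] for l, c in enumerate(seq))


def oracle_scan(freq, contig_seq: str, threshold: float):
    """Enumerate every window on both strands; skip windows with non-ACGT
    bases; keep the better strand at each position (ties to '+')."""
    weights = oracle_weights(freq)
    L = len(weights)
    hits = []
    for start in range(len(contig_seq) - L + 1):
        window = contig_seq[start : start + L]
        if any(c not in _COMP for c in window):
            continue
        fwd = oracle_score(weights, window)
        rev = oracle_score(weights, oracle_revcomp(window))
        if fwd > threshold or rev > threshold:
            if fwd >= rev:
                hits.append((start, "+", fwd))
            else:
                hits.append((start, "-", rev))
    return hits


def oracle_operons(genes, gap_max: int):
    """Chain scan: genes as (gene_id, contig, start, end, strand) tuples,
    returns a list of tuples of gene_ids."""
    by_contig = {}
    for g in genes:
        by_contig.setdefault(g[1], []).append(g)
    result = []
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda g: (g[2], g[3]))
        chain = []
        for g in ordered:
            if chain and g[4] == chain[-1][4] and g[2] - chain[-1][3] < gap_max:
                chain.append(g)
            else:
                if chain:
                    result.append(tuple(x[0] for x in chain))
                chain = [g]
        if chain:
            result.append(tuple(x[0] for x in chain))
    return result


def oracle_link(site, genes, upstream: int, downstream: int):
    """All-pairs minimisation for one site (contig, start, end) over genes
    on the same contig; returns the chosen gene_id and in_promoter flag."""
    contig, s_start, s_end = site
    mid2 = s_start + s_end
    best = None
    for gene_id, g_contig, g_start, g_end, strand in genes:
        if g_contig != contig:
            continue
        tss = g_start if strand == "+" else g_end
        if strand == "+":
            lo, hi = max(g_start - upstream, 0), g_start + downstream
        else:
            lo, hi = max(g_end - downstream, 0), g_end + upstream
        contained = lo <= s_start and s_end <= hi
        key = (abs(mid2 - 2 * tss), 0 if contained else 1, g_start, gene_id)
        if best is None or key < best[0]:
            best = (key, gene_id, contained)
    if best is None:
        return None
    return best[1], best[2]


def oracle_ols(xs, ys):
    """Closed-form normal equations: slope, intercept, r2."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((y - slope * x - intercept) ** 2 for x, y in zip(xs, ys))
    ss_tot = sum((y - my) ** 2 for y in ys)
    r2 = 0.0 if ss_tot == 0 else 1 - ss_res / ss_tot
    return slope, intercept, r2
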