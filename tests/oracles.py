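"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes its quantity from first principles (pure-Python
loops, no shared code with the package) so implementation and check stay
on separate routes.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def median(xs):
    xs = sorted(xs)
    n = len(xs)
    mid = n // 2
    return xs[mid] if n % 2 else (xs[mid - 1] + xs[mid]) / 2.0


def sample_sd(xs):
    n = len(xs)
    if n < 2:
        return 0.0
    m = sum(xs) / n
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (n - 1))


def brute_force_hits(rep1, rep2, k_sd=2.0, renilla_fold=3.0):
    """Hit calling from first principles.

    rep1/rep2: dict amplicon -> (firefly, renilla) for the sample wells of
    one plate replicate.  Returns {amplicon: (is_hit, direction)}.
    """
    out = {}
    stats = []
    for rep in (rep1, rep2):
        ratios = {a: f / r for a, (f, r) in rep.items() if r > 0}
        med = median(list(ratios.values()))
        sd = sample_sd(list(ratios.values()))
        ren_med = median([r for a, (f, r) in rep.items() if r > 0])
        stats.append((ratios, med, sd, ren_med))
    for a in set(rep1) & set(rep2):
        devs, viable = [], True
        usable = True
        for rep, (ratios, med, sd, ren_med) in zip((rep1, rep2), stats):
            if a not in ratios:
                usable = False
                continue
            devs.append((ratios[a] - med) / sd if sd > 0 else 0.0)
            if rep[a][1] < ren_med / renilla_fold:
                viable = False
        if not usable or len(devs) < 2:
            out[a] = (False, "none")
            continue
        d1, d2 = devs
        exceeds = abs(d1) > k_sd and abs(d2) > k_sd
        same = (d1 > 0) == (d2 > 0)
        direction = "none"
        if exceeds and same:
            direction = "decreased" if d1 < 0 else "increased"
        out[a] = (exceeds and same and viable, direction)
    return out


def revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_off_targets(dsrna, targets, transcriptome, k=17):
    """Every gene sharing any exact k-length substring with the dsRNA
    (forward or reverse complement), by all-substring comparison."""
    ds = dsrna.upper()
    queries = [ds, revcomp(ds)]
    hits = set()
    for gene, seq in transcriptome.items():
        if gene in targets:
            continue
        seq = seq.upper()
        for q in queries:
            for i in range(len(q) - k + 1):
                if q[i:i + k] in seq:
                    hits.add(gene)
                    break
    return sorted(hits)


def brute_force_overlaps(query, subject):
    """All-pairs half-open interval overlap: list of bool per query.

    query/subject: iterables of (chrom, start, end).
    """
    out = []
    for qc, qs, qe in query:
        out.append(any(qc == sc and qs < se and ss < qe for sc, ss, se in subject))
    return out


def brute_force_column_means(matrix):
    """Missing-aware column means of a list-of-lists with None/NaN holes."""
    n_cols = len(matrix[0])
    means = []
    for j in range(n_cols):
        vals = [row[j] for row in matrix
                if row[j] is not None and row[j] == row[j]]
        means.append(sum(vals) / len(vals) if vals else float("nan"))
    return means
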