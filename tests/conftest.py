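"""Shared fixtures and independent oracles used across the suite."""

import numpy as np
import pandas as pd
import pytest

from miratlas import quantify as qt
from miratlas import simulate as sim


@pytest.fixture(scope="session")
def small_cfg():
    """A small but complete simulated study (fast, fixed seed)."""
    return sim.SimulationConfig(
        seed=11, n_loci=40, n_te=4, n_hte=4, n_reference=2,
        tissues=("liver", "brain", "heart", "kidney"),
        replicates=4, depth=200_000, alignment_depth=4000,
    )


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    genome, truth, species_sets = sim.gen_genome_and_annotation(small_cfg)
    return genome, truth, species_sets


@pytest.fixture(scope="session")
def small_expression(small_cfg, small_truth):
    _, truth, _ = small_truth
    counts, samples = sim.gen_counts(small_cfg, truth)
    cm = qt.CountMatrix(counts, counts.sum(axis=0))
    return qt.rpm_normalize(cm), samples


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_exact_scan(patterns, genome):
    """Sliding hash-set window scan: every zero-mismatch placement.

    Independent of the str.find implementation path: indexes patterns (and
    their reverse complements) by length and slides one window per length.
    Returns {pattern: [(chrom, start, end, strand), ...]}.
    """
    from miratlas.annotation import reverse_complement

    by_len: dict = {}
    for p in patterns:
        by_len.setdefault(len(p), {}).setdefault(p, []).append((p, "+"))
        # a palindromic pattern matches the same window on both strands
        by_len[len(p)].setdefault(reverse_complement(p), []).append((p, "-"))
    hits = {p: [] for p in patterns}
    for chrom in sorted(genome):
        contig = genome[chrom]
        for L, table in by_len.items():
            for i in range(len(contig) - L + 1):
                for pat, strand in table.get(contig[i: i + L], ()):
                    hits[pat].append((chrom, i, i + L, strand))
    return hits


def brute_force_clusters(intervals, gap_tolerance=0):
    """Transitive interval clustering by pairwise union-find.

    ``intervals``: list of (chrom, start, end, strand).  Mergeable when on
    the same chrom/strand and ``b.start < a.end + gap_tolerance`` in either
    order.  Returns a set of frozensets of indices.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        ci, si, ei, sti = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej, stj = intervals[j]
            if ci != cj or sti != stj:
                continue
            if sj < ei + gap_tolerance and si < ej + gap_tolerance:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in groups.values()}


def brute_force_assign(reads, loci, overlap_frac=0.7, max_locations=10,
                       stranded=True):
    """Per-read, per-locus dense overlap counting.

    ``reads``: DataFrame with chrom/start/end/n_hits/strand; ``loci``: list
    of MiRNALocus.  Returns a per-locus-name count Series.
    """
    counts = pd.Series(0, index=[l.name for l in loci], dtype=int)
    for _, r in reads.iterrows():
        if r["n_hits"] > max_locations:
            continue
        for l in loci:
            if l.chrom != r["chrom"]:
                continue
            if stranded and l.strand != r["strand"]:
                continue
            ov = min(r["end"], l.end) - max(r["start"], l.start)
            if ov > 0 and ov / (l.end - l.start) >= overlap_frac:
                counts[l.name] += 1
    return counts


def enumerate_rank_sum_p(x, y, alternative="greater"):
    """Exact one-sided rank-sum p by full enumeration of rank assignments.

    Requires tie-free data; enumerates all C(n, |x|) subsets.
    """
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle needs tie-free data"
    ranks = rankdata(pooled)
    obs = ranks[: len(x)].sum()
    total = 0
    at_least = 0
    for combo in combinations(range(len(pooled)), len(x)):
        s = ranks[list(combo)].sum()
        total += 1
        if alternative == "greater" and s >= obs:
            at_least += 1
        elif alternative == "two_sided":
            mid = len(x) * (len(pooled) + 1) / 2
            if abs(s - mid) >= abs(obs - mid):
                at_least += 1
    return at_least / total


def hand_bh(p):
    """Step-up BH computed directly from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m / rank * p[order[rank - 1]])
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
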