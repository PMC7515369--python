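"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain double loops over Python lists so
that it shares no code path with the package's vectorised estimators.
"""

import itertools
import math


def _windows(x, n):
    return [tuple(x[i:i + n]) for i in range(len(x) - n + 1)]


def _shannon(counts):
    total = sum(counts)
    return -sum(c / total * math.log(c / total) for c in counts)


def naive_pen(x, n, normalize=True):
    """Permutation entropy via explicit pattern dictionaries; ties are
    ranked by order of appearance (stable sort by value, then index)."""
    hist = {}
    for w in _windows(list(x), n):
        perm = tuple(sorted(range(n), key=lambda i: (w[i], i)))
        hist[perm] = hist.get(perm, 0) + 1
    h = _shannon(list(hist.values()))
    if normalize:
        h /= math.log(math.factorial(n))
    return h


def naive_mpen(x, n, normalize=True):
    """Tie-inclusive permutation entropy via dense ranks."""
    hist = {}
    for w in _windows(list(x), n):
        distinct = sorted(set(w))
        pattern = tuple(distinct.index(v) for v in w)
        hist[pattern] = hist.get(pattern, 0) + 1
    h = _shannon(list(hist.values()))
    if normalize:
        h /= math.log(naive_pattern_universe(n))
    return h


def naive_pattern_universe(n):
    """Count tie-inclusive rank patterns by generating all weak
    orderings from strict permutations with tie masks."""
    patterns = set()
    for perm in itertools.permutations(range(n)):
        for mask in itertools.product([0, 1], repeat=n - 1):
            # mask[i] == 1 ties the (i+1)-th smallest to the i-th smallest
            rank_of_sorted = [0]
            for tie in mask:
                rank_of_sorted.append(rank_of_sorted[-1] + (0 if tie else 1))
            ranks = [0] * n
            for pos_in_sorted, orig in enumerate(perm):
                ranks[orig] = rank_of_sorted[pos_in_sorted]
            patterns.add(tuple(ranks))
    return len(patterns)


def _sd(x):
    m = sum(x) / len(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / len(x))


def naive_sen(x, m, r):
    """Sample entropy by direct O(N^2) pair counting (Chebyshev,
    self-matches excluded, N - m templates at both lengths)."""
    x = list(x)
    sd = _sd(x)
    if sd == 0:
        return 0.0
    tol = r * sd
    n_t = len(x) - m
    b = a = 0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            dm = max(abs(x[i + q] - x[j + q]) for q in range(m))
            if dm <= tol:
                b += 1
                if abs(x[i + m] - x[j + m]) <= tol:
                    a += 1
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def naive_qsen(x, m, r):
    return naive_sen(x, m, r) + math.log(2 * r)


def naive_fen(x, n, m, r):
    """Fuzzy entropy by direct double loops over baseline-removed
    vectors."""
    x = list(x)
    sd = _sd(x)
    if sd == 0:
        return 0.0
    tol = r * sd
    n_t = len(x) - m
    phis = []
    for length in (m, m + 1):
        vecs = []
        for i in range(n_t):
            v = x[i:i + length]
            mean = sum(v) / length
            vecs.append([u - mean for u in v])
        total = 0.0
        for i in range(n_t):
            for j in range(n_t):
                if i == j:
                    continue
                d = max(abs(a - b) for a, b in zip(vecs[i], vecs[j]))
                total += math.exp(-(d ** n) / tol)
        phis.append(total / (n_t * (n_t - 1)))
    return -math.log(phis[1] / phis[0])


def logistic_orbit_period(mu, x0=0.3, burn_in=1000, tol=1e-6, n_check=10000):
    """Brute-force orbit enumeration: count distinct values visited."""
    x = x0
    for _ in range(burn_in):
        x = mu * x * (1 - x)
    vals = []
    for _ in range(n_check):
        x = mu * x * (1 - x)
        vals.append(x)
    vals.sort()
    distinct = 1
    for a, b in zip(vals, vals[1:]):
        if b - a > tol:
            distinct += 1
    return distinct


def mannwhitney_exact_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group
    assignments of the combined sample (assumes no ties)."""
    combined = sorted(list(a) + list(b))
    n_a = len(a)

    def u_stat(group_a):
        ranks = {v: i + 1 for i, v in enumerate(combined)}
        r_a = sum(ranks[v] for v in group_a)
        return r_a - n_a * (n_a + 1) / 2

    u_obs = min(u_stat(list(a)), len(a) * len(b) - u_stat(list(a)))
    count = total = 0
    for subset in itertools.combinations(combined, n_a):
        u = u_stat(list(subset))
        total += 1
        if min(u, n_a * len(b) - u) <= u_obs:
            count += 1
    return count / total


def wilcoxon_exact_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign flips
    (assumes no zero and no tied absolute differences)."""
    absd = sorted(abs(d) for d in diffs)
    ranks = {v: i + 1 for i, v in enumerate(absd)}
    w_plus = sum(ranks[abs(d)] for d in diffs if d > 0)
    n = len(diffs)
    w_total = n * (n + 1) // 2
    w_obs = min(w_plus, w_total - w_plus)
    count = total = 0
    for signs in itertools.product([1, -1], repeat=n):
        w = sum(r for s, r in zip(signs, range(1, n + 1)) if s > 0)
        total += 1
        if min(w, w_total - w) <= w_obs:
            count += 1
    return count / total
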